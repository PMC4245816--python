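import numpy as np
import pytest

from edcscan import (
    GenomeSequence,
    PipelineConfig,
    assemble_gene_models,
    filter_gene_models,
    find_exon1,
    reverse_complement,
    run_pipeline,
    scan_coding_exons,
    scan_splice_acceptors,
)
from edcscan.synthetic_data import generate_locus

from conftest import random_dna
from _oracles import brute_acceptors, brute_coding_exons, brute_exon1


class TestSpliceAcceptors:
    def test_pure_pyrimidine_tract_accepted(self, cfg):
        seq = GenomeSequence("s", "T" * 12 + "AG")
        sites = scan_splice_acceptors(seq, cfg)
        assert len(sites) == 1
        site = sites[0]
        assert (site.strand, site.ag_end, site.pyrimidine_fraction) == ("+", 14, 1.0)

    def test_purine_window_rejected(self, cfg):
        seq = GenomeSequence("s", "G" * 12 + "AG")
        assert scan_splice_acceptors(seq, cfg) == []

    def test_window_with_n_rejected(self, cfg):
        seq = GenomeSequence("s", "T" * 11 + "N" + "AG")
        assert scan_splice_acceptors(seq, cfg) == []

    def test_too_short_sequence_errors(self, cfg):
        with pytest.raises(ValueError, match="shorter"):
            scan_splice_acceptors(GenomeSequence("s", "TTAG"), cfg)

    def test_matches_brute_force_enumeration(self, cfg):
        rng = np.random.default_rng(17)
        for _ in range(10):
            seq = GenomeSequence("r", random_dna(rng, 10_000))
            got = {
                (s.strand, s.ag_end, round(s.pyrimidine_fraction, 9))
                for s in scan_splice_acceptors(seq, cfg)
            }
            want = set()
            for strand, s in (("+", seq.residues), ("-", reverse_complement(seq.residues))):
                for ag_end, frac in brute_acceptors(s):
                    want.add((strand, ag_end, round(frac, 9)))
            assert got == want

    def test_threshold_relaxation_is_monotone(self, cfg):
        rng = np.random.default_rng(23)
        seq = GenomeSequence("r", random_dna(rng, 5_000))
        strict = scan_splice_acceptors(seq, cfg)
        relaxed_cfg = PipelineConfig(polypyrimidine_min_fraction=0.5)
        relaxed = scan_splice_acceptors(seq, relaxed_cfg)
        strict_keys = {(s.strand, s.ag_end) for s in strict}
        relaxed_keys = {(s.strand, s.ag_end) for s in relaxed}
        assert strict_keys <= relaxed_keys


class TestCodingExons:
    def test_orf_at_acceptor_distance(self):
        cfg = PipelineConfig(min_orf_codons=3)
        dna = "T" * 12 + "AG" + "C" * 22 + "ATGAAATGCTGA" + "C" * 10
        seq = GenomeSequence("s", dna)
        acceptors = scan_splice_acceptors(seq, cfg)
        cands = [
            c
            for c in scan_coding_exons(seq, acceptors, cfg)
            if c.strand == "+" and c.acceptor.ag_end == 14
        ]
        assert len(cands) == 1
        cand = cands[0]
        assert cand.protein == "MKC"
        assert cand.utr_length == 22
        assert cand.orf_span == (36, 48)

    def test_atg_outside_distance_window_rejected(self):
        # ATG at 30 nt past the AG: outside the 20-25 nt acceptor window
        cfg = PipelineConfig(min_orf_codons=3)
        dna = "T" * 12 + "AG" + "C" * 30 + "ATGAAATGCTGA" + "C" * 10
        seq = GenomeSequence("s", dna)
        acceptors = [a for a in scan_splice_acceptors(seq, cfg) if a.strand == "+"]
        assert scan_coding_exons(seq, acceptors, cfg) == []

    def test_matches_brute_force_orf_scan(self):
        cfg = PipelineConfig(min_orf_codons=20)  # shorter ORFs: more candidates
        rng = np.random.default_rng(31)
        for _ in range(5):
            seq = GenomeSequence("r", random_dna(rng, 20_000))
            acceptors = scan_splice_acceptors(seq, cfg)
            got = {
                (c.strand, c.acceptor.ag_end, c.utr_length, c.orf_span)
                for c in scan_coding_exons(seq, acceptors, cfg)
            }
            want = set()
            for strand, s in (("+", seq.residues), ("-", reverse_complement(seq.residues))):
                ag_ends = {a.ag_end for a in acceptors if a.strand == strand}
                for ag_end, utr, span in brute_coding_exons(
                    s, ag_ends, min_codons=cfg.min_orf_codons
                ):
                    want.add((strand, ag_end, utr, span))
            assert got == want


class TestExon1:
    def _candidate(self, seq, cfg, ag_end=None):
        acceptors = [a for a in scan_splice_acceptors(seq, cfg) if a.strand == "+"]
        if ag_end is not None:
            acceptors = [a for a in acceptors if a.ag_end == ag_end]
        cands = scan_coding_exons(seq, acceptors, cfg)
        assert cands, "test construction must yield a coding-exon candidate"
        return cands[0]

    def _build(self, tata_gap: int, donor: str = "GGTAAG") -> str:
        # TATA + gap + donor G|GTAAG + intron filler + tract + AG + UTR + ORF
        return (
            "CACAC"
            + "TATAAAA"
            + "C" * tata_gap
            + donor
            + "C" * 30
            + "T" * 12
            + "AG"
            + "C" * 22
            + "ATGAAATGCTGA"
            + "CACAC"
        )

    def test_exon1_found_at_valid_distance(self):
        cfg = PipelineConfig(min_orf_codons=3)
        seq = GenomeSequence("s", self._build(75))
        cand = self._candidate(seq, cfg)
        exon1 = find_exon1(seq, cand, cfg)
        assert exon1 is not None
        assert exon1.tata_pos == 5
        assert exon1.donor_pos == 5 + 7 + 75
        assert exon1.tata_donor_distance == 75

    def test_tata_too_close_gives_none(self):
        cfg = PipelineConfig(min_orf_codons=3)
        seq = GenomeSequence("s", self._build(40))
        cand = self._candidate(seq, cfg)
        assert find_exon1(seq, cand, cfg) is None

    def test_donor_mismatch_gives_none(self):
        cfg = PipelineConfig(min_orf_codons=3)
        seq = GenomeSequence("s", self._build(75, donor="GGTGAG"))
        cand = self._candidate(seq, cfg)
        assert find_exon1(seq, cand, cfg) is None

    def test_wrong_contig_errors(self, cfg):
        seq = GenomeSequence("s", self._build(75))
        other = GenomeSequence("other", self._build(75))
        cfg3 = PipelineConfig(min_orf_codons=3)
        cand = self._candidate(seq, cfg3)
        with pytest.raises(ValueError, match="contig"):
            find_exon1(other, cand, cfg3)


def _mirror(model, L):
    """Map a model found on the reverse complement back to original coords."""

    def iv(span):
        return None if span is None else (L - span[1], L - span[0])

    return (
        "-" if model.strand == "+" else "+",
        iv(model.cds_span),
        iv(model.ag_span),
        None if model.donor_g is None else L - 1 - model.donor_g,
        iv(model.tata_span),
        model.status,
    )


def _key(model):
    return (
        model.strand,
        model.cds_span,
        model.ag_span,
        model.donor_g,
        model.tata_span,
        model.status,
    )


class TestAssembly:
    def test_single_embedded_gene_recovered_exactly(self, cfg):
        scaffold, truth = generate_locus(n_genes=1, n_decoys=0, seed=2)
        models = run_pipeline(scaffold, cfg)
        assert len(models) == 1
        m, g = models[0], truth.genes[0]
        assert m.status == "two_exon"
        assert m.strand == g.strand
        assert m.cds_span == g.cds_span
        assert m.ag_span == g.ag_span
        assert m.donor_g == g.donor_g
        assert m.tata_span == g.tata_span
        assert m.utr_length == g.utr_length
        assert m.protein == g.protein

    def test_strand_symmetry(self, cfg):
        scaffold, _ = generate_locus(n_genes=3, n_decoys=5, seed=9)
        L = scaffold.length
        fwd = assemble_gene_models(scaffold, cfg)
        rev = assemble_gene_models(scaffold.reverse_complement(), cfg)
        assert {_key(m) for m in fwd} == {_mirror(m, L) for m in rev}

    def test_decoy_only_contig_yields_no_accepted_models(self, cfg):
        scaffold, truth = generate_locus(n_genes=0, n_decoys=20, seed=13)
        assert len(truth.genes) == 0
        models = run_pipeline(scaffold, cfg)
        assert models == []

    def test_filter_keeps_composition_or_motif_positive(self, cfg, small_locus):
        scaffold, truth = small_locus
        models = assemble_gene_models(scaffold, cfg)
        kept = filter_gene_models(models, cfg)
        # every embedded gene is class-biased and must survive the filter
        kept_cds = {(m.strand, m.cds_span) for m in kept}
        for g in truth.genes:
            assert (g.strand, g.cds_span) in kept_cds


class TestExon1Brute:
    def test_exon1_matches_brute_force(self, cfg, small_locus):
        scaffold, _ = small_locus
        acceptors = scan_splice_acceptors(scaffold, cfg)
        cands = scan_coding_exons(scaffold, acceptors, cfg)
        strands = {
            "+": scaffold.residues,
            "-": reverse_complement(scaffold.residues),
        }
        for cand in cands[:40]:
            exon1 = find_exon1(scaffold, cand, cfg)
            want = brute_exon1(strands[cand.strand], cand.acceptor.ag_end)
            if want is None:
                assert exon1 is None
            else:
                assert exon1 is not None
                assert (exon1.donor_pos, exon1.tata_pos) == want
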