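import re

import numpy as np
import pytest

from edcscan import (
    GenomeSequence,
    SyntheticGeneSpec,
    generate_locus,
    generate_protein,
    load_motif_catalog,
    recovery_report,
    reverse_complement,
    run_pipeline,
    scan_coding_exons,
    scan_splice_acceptors,
    scan_motif,
    translate,
    write_gff3,
)

TATA_RE = re.compile("TATA[AT]A[AT]")


def _strand_local(span, strand, L):
    """Map a forward interval to strand-local coordinates."""
    return span if strand == "+" else (L - span[1], L - span[0])


class TestGenerateProtein:
    def test_seeded_determinism(self):
        spec = SyntheticGeneSpec(composition_class="C_rich", protein_length=150)
        a = generate_protein(spec, np.random.default_rng(4))
        b = generate_protein(spec, np.random.default_rng(4))
        assert a == b

    def test_starts_with_methionine(self):
        for cls in ("GS_rich", "C_rich", "P_rich", "Q_rich"):
            spec = SyntheticGeneSpec(composition_class=cls, protein_length=100)
            assert generate_protein(spec, np.random.default_rng(1))[0] == "M"

    def test_gs_rich_class_exceeds_threshold(self):
        spec = SyntheticGeneSpec(composition_class="GS_rich", protein_length=500)
        rng = np.random.default_rng(10)
        for _ in range(20):
            protein = generate_protein(spec, rng)
            gs = (protein.count("G") + protein.count("S")) / len(protein)
            assert gs >= 0.5

    def test_requested_motifs_are_exact_hits(self):
        catalog = {m.name: m for m in load_motif_catalog()}
        spec = SyntheticGeneSpec(
            composition_class="Q_rich",
            protein_length=120,
            include_n_motif=True,
            include_c_motif=True,
        )
        protein = generate_protein(spec, np.random.default_rng(3))
        n_hits = scan_motif(protein, catalog["sedc_n_terminal"], max_mismatches=0)
        c_hits = scan_motif(protein, catalog["sedc_c_terminal"], max_mismatches=0)
        assert len(n_hits) == 1 and n_hits[0].start == 0
        assert len(c_hits) == 1

    def test_too_short_for_motifs_errors(self):
        spec = SyntheticGeneSpec(
            protein_length=20, include_n_motif=True, include_c_motif=True
        )
        with pytest.raises(ValueError, match="too short"):
            generate_protein(spec, np.random.default_rng(0))


class TestGenerateLocus:
    def test_byte_identical_under_same_seed(self, small_locus):
        scaffold, truth = small_locus
        scaffold2, truth2 = generate_locus(n_genes=8, n_decoys=20, seed=5)
        assert scaffold.residues == scaffold2.residues
        assert truth == truth2

    def test_truth_counts(self, small_locus):
        _, truth = small_locus
        assert len(truth.genes) == 8
        assert len(truth.decoys) == 20
        kinds = {d.kind for d in truth.decoys}
        assert kinds == {"orf_no_acceptor", "acceptor_no_orf"}

    def test_truth_signals_reextract_from_fasta(self, small_locus):
        """Every planted signal window must satisfy its own rule in the
        emitted sequence."""
        scaffold, truth = small_locus
        L = scaffold.length
        strands = {"+": scaffold.residues, "-": reverse_complement(scaffold.residues)}
        for g in truth.genes:
            s = strands[g.strand]
            ag = _strand_local(g.ag_span, g.strand, L)
            assert s[ag[0] : ag[1]] == "AG"
            tract = s[ag[0] - 12 : ag[0]]
            assert set(tract) <= set("CT")
            donor = g.donor_g if g.strand == "+" else L - 1 - g.donor_g
            assert s[donor : donor + 6] == "GGTAAG"
            tata = _strand_local(g.tata_span, g.strand, L)
            assert TATA_RE.fullmatch(s[tata[0] : tata[1]])
            assert 60 <= donor - tata[1] <= 90
            assert donor - tata[1] == g.tata_donor_distance
            cds = _strand_local(g.cds_span, g.strand, L)
            assert s[cds[0] : cds[0] + 3] == "ATG"
            assert 20 <= cds[0] - ag[1] <= 25
            assert cds[0] - ag[1] == g.utr_length
            assert translate(s[cds[0] : cds[1]]) == g.protein

    def test_decoys_fail_exactly_their_rule(self, small_locus, cfg):
        scaffold, truth = small_locus
        L = scaffold.length
        strands = {"+": scaffold.residues, "-": reverse_complement(scaffold.residues)}
        for d in truth.decoys:
            s = strands[d.strand]
            span = _strand_local(d.span, d.strand, L)
            if d.kind == "orf_no_acceptor":
                # the ORF is real: ATG start and a clean >= 60-codon frame
                assert s[span[0] : span[0] + 3] == "ATG"
                protein = translate(s[span[0] : span[1]])
                assert len(protein) >= 60
                # ...but no accepted acceptor sits at UTR distance upstream
                region = GenomeSequence("d", s[span[0] - 60 : span[1] + 10])
                acceptors = [
                    a for a in scan_splice_acceptors(region, cfg) if a.strand == "+"
                ]
                atg_local = 60
                assert not any(
                    20 <= atg_local - a.ag_end <= 25 for a in acceptors
                )
            else:  # acceptor_no_orf
                # the acceptor is real (perfect pyrimidine tract + AG)...
                ag_end_local = span[0] + 14
                assert s[ag_end_local - 2 : ag_end_local] == "AG"
                assert set(s[span[0] : span[0] + 12]) <= set("CT")
                # ...but no qualifying ORF follows it
                region = GenomeSequence("d", s[span[0] - 10 : span[1] + 200])
                acceptors = [
                    a
                    for a in scan_splice_acceptors(region, cfg)
                    if a.strand == "+" and a.ag_end == 24
                ]
                assert acceptors, "planted acceptor must be detected"
                assert scan_coding_exons(region, acceptors, cfg) == []

    def test_zero_genes_zero_predictions(self, cfg):
        scaffold, truth = generate_locus(n_genes=0, n_decoys=10, seed=21)
        assert truth.genes == ()
        assert run_pipeline(scaffold, cfg) == []


class TestRecoveryReport:
    def test_perfect_predictions(self, small_locus):
        _, truth = small_locus
        report = recovery_report(truth.to_gene_models(), truth)
        assert report.sensitivity == 1.0
        assert report.precision == 1.0
        assert report.acceptor_exact == 1.0
        assert report.donor_exact == 1.0
        assert report.tata_exact == 1.0

    def test_half_missing_predictions(self, small_locus):
        _, truth = small_locus
        models = truth.to_gene_models()[: len(truth.genes) // 2]
        report = recovery_report(models, truth)
        assert report.sensitivity == pytest.approx(0.5)
        assert report.precision == 1.0

    def test_round_trips_through_gff3(self, small_locus, tmp_path, cfg):
        scaffold, truth = small_locus
        pred_path = tmp_path / "pred.gff3"
        truth_path = tmp_path / "truth.gff3"
        models = run_pipeline(scaffold, cfg)
        write_gff3(models, pred_path)
        truth.write_truth_gff3(truth_path)
        from_files = recovery_report(pred_path, truth_path)
        from_objects = recovery_report(models, truth)
        assert from_files == from_objects

    def test_end_to_end_recovery_on_small_locus(self, small_locus, cfg):
        scaffold, truth = small_locus
        report = recovery_report(run_pipeline(scaffold, cfg), truth)
        assert report.sensitivity == 1.0
        assert report.donor_exact == 1.0
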