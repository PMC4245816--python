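"""De novo discovery of candidate two-exon EDC gene models in genomic DNA.

The target gene architecture is: TATA box -> short noncoding exon 1 ending in
the splice donor G|GTAAG -> intron -> polypyrimidine tract + AG splice
acceptor -> 20-25 nt 5'UTR -> single-exon ORF.  The scan proceeds in stages:

1. splice acceptors: every AG whose upstream window is pyrimidine-rich,
2. coding exons: ATG at the prescribed acceptor distance opening an ORF
   within the codon-length bounds,
3. exon 1: nearest upstream donor motif with a TATA box at the prescribed
   distance.

All stages run on both strands.  Scanning operates in strand-local
coordinates (positions on the scanned strand's own sequence); assembled gene
models are converted to forward-strand intervals with a strand flag.  Any
window containing an N fails its signal test.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from typing import Sequence

from .io_formats import GenomeSequence, PipelineConfig
from .motif_repeat import load_motif_catalog, scan_motif
from .protein_features import (
    CompositionThresholds,
    classify_composition,
    composition_profile,
    translate,
)

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "[AG]", "Y": "[CT]", "S": "[CG]", "W": "[AT]",
    "K": "[GT]", "M": "[AC]", "B": "[CGT]", "D": "[AGT]",
    "H": "[ACT]", "V": "[ACG]", "N": "[ACGT]",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@functools.lru_cache(maxsize=16)
def _iupac_regex(pattern: str) -> re.Pattern:
    return re.compile("".join(_IUPAC[c] for c in pattern.upper()))


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpliceAcceptorSite:
    """An accepted splice acceptor: AG preceded by a pyrimidine-rich window.

    ``ag_end`` is the strand-local 0-based position immediately after the AG
    dinucleotide on the indicated strand.
    """

    contig: str
    strand: str
    ag_end: int
    pyrimidine_fraction: float


@dataclass(frozen=True)
class CodingExonCandidate:
    """An ORF at acceptor distance: the putative coding exon 2.

    ``orf_span`` is strand-local, 0-based half-open, and includes the stop
    codon; ``protein`` excludes the stop.
    """

    contig: str
    strand: str
    acceptor: SpliceAcceptorSite
    utr_length: int
    orf_span: tuple[int, int]
    protein: str


@dataclass(frozen=True)
class Exon1Candidate:
    """Noncoding exon 1 evidence: donor motif plus upstream TATA box.

    ``donor_pos`` is the strand-local position of the exon-terminal G of the
    donor (the intron starts with GTAAG at ``donor_pos + 1``); ``tata_pos``
    is the start of the TATA-pattern match.  ``tata_donor_distance`` counts
    the nucleotides between the end of the TATA match and the donor G.
    """

    contig: str
    strand: str
    donor_pos: int
    tata_pos: int
    tata_donor_distance: int
    exon1_span: tuple[int, int]


@dataclass(frozen=True)
class GeneModel:
    """A predicted two-exon gene, in forward-strand coordinates.

    Spans are 0-based half-open forward-strand intervals; ``donor_g`` is the
    forward coordinate of the exon-terminal donor G base.  ``cds_span``
    includes the stop codon.  ``status`` is ``two_exon`` when exon 1 was
    found, else ``coding_exon_only``.
    """

    id: str
    contig: str
    strand: str
    status: str
    protein: str
    cds_span: tuple[int, int]
    exon2_span: tuple[int, int]
    ag_span: tuple[int, int]
    utr_length: int
    pyrimidine_fraction: float
    exon1_span: tuple[int, int] | None = None
    intron_span: tuple[int, int] | None = None
    donor_g: int | None = None
    tata_span: tuple[int, int] | None = None
    tata_donor_distance: int | None = None


# ---------------------------------------------------------------------------
# Coordinate helpers
# ---------------------------------------------------------------------------


def _fwd_interval(span: tuple[int, int], length: int, strand: str) -> tuple[int, int]:
    if strand == "+":
        return span
    return (length - span[1], length - span[0])


def _fwd_pos(pos: int, length: int, strand: str) -> int:
    if strand == "+":
        return pos
    return length - 1 - pos


def _strand_residues(seq: GenomeSequence, strand: str) -> str:
    return seq.residues if strand == "+" else reverse_complement(seq.residues)


# ---------------------------------------------------------------------------
# Stage 1: splice acceptors
# ---------------------------------------------------------------------------


def scan_splice_acceptors(
    seq: GenomeSequence, cfg: PipelineConfig | None = None
) -> list[SpliceAcceptorSite]:
    """Every AG (both strands) whose upstream ``polypyrimidine_window`` has a
    C+T fraction at or above threshold and contains no N.

    Sites are sorted by (strand, position) and the scan is deterministic.
    """
    cfg = cfg or PipelineConfig()
    w = cfg.polypyrimidine_window
    if seq.length < w + 2:
        raise ValueError(
            f"sequence {seq.id!r} shorter than polypyrimidine window + 2 ({w + 2})"
        )
    sites = []
    for strand in "+-":
        s = _strand_residues(seq, strand)
        for m in re.finditer("(?=AG)", s):
            i = m.start()
            if i < w:
                continue
            window = s[i - w : i]
            if "N" in window:
                continue
            frac = (window.count("C") + window.count("T")) / w
            if frac >= cfg.polypyrimidine_min_fraction:
                sites.append(SpliceAcceptorSite(seq.id, strand, i + 2, frac))
    sites.sort(key=lambda site: (site.strand, site.ag_end))
    return sites


# ---------------------------------------------------------------------------
# Stage 2: coding exons
# ---------------------------------------------------------------------------

_STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def _extend_orf(s: str, start: int, cfg: PipelineConfig) -> tuple[int, str] | None:
    """Extend an ORF from an ATG at ``start``; return (end-after-stop, protein)
    or None if no in-frame stop within bounds or an N interrupts."""
    pos = start
    n_codons = 0
    while pos + 3 <= len(s):
        codon = s[pos : pos + 3]
        if "N" in codon:
            return None
        if codon in _STOP_CODONS:
            if cfg.min_orf_codons <= n_codons <= cfg.max_orf_codons:
                return pos + 3, translate(s[start : pos + 3])
            return None
        n_codons += 1
        if n_codons > cfg.max_orf_codons:
            return None
        pos += 3
    return None


def scan_coding_exons(
    seq: GenomeSequence,
    acceptors: Sequence[SpliceAcceptorSite],
    cfg: PipelineConfig | None = None,
) -> list[CodingExonCandidate]:
    """For each acceptor, every ATG at UTR distance within
    ``acceptor_distance_range`` that opens an ORF within the codon-length
    bounds yields one candidate (standard genetic code; stop excluded from
    the protein)."""
    cfg = cfg or PipelineConfig()
    lo, hi = cfg.acceptor_distance_range
    strands = {"+": seq.residues, "-": reverse_complement(seq.residues)}
    out = []
    for acc in acceptors:
        if acc.contig != seq.id:
            raise ValueError(f"acceptor contig {acc.contig!r} != sequence {seq.id!r}")
        s = strands[acc.strand]
        for utr in range(lo, hi + 1):
            start = acc.ag_end + utr
            if s[start : start + 3] != "ATG":
                continue
            orf = _extend_orf(s, start, cfg)
            if orf is None:
                continue
            end, protein = orf
            out.append(
                CodingExonCandidate(
                    contig=seq.id,
                    strand=acc.strand,
                    acceptor=acc,
                    utr_length=utr,
                    orf_span=(start, end),
                    protein=protein,
                )
            )
    return out


# ---------------------------------------------------------------------------
# Stage 3: exon 1 (donor + TATA)
# ---------------------------------------------------------------------------

#: nominal TATA-to-transcription-start spacing used for the exon-1 5' end
_TSS_OFFSET = 25


def _nearest_tata(s: str, donor_pos: int, cfg: PipelineConfig) -> int | None:
    """Largest tata start t with a pattern match whose end sits
    ``tata_distance_range`` nt upstream of the donor G."""
    pattern = _iupac_regex(cfg.tata_pattern)
    plen = len(cfg.tata_pattern)
    lo, hi = cfg.tata_distance_range
    for t in range(donor_pos - lo - plen, donor_pos - hi - plen - 1, -1):
        if t < 0:
            break
        if pattern.fullmatch(s, t, t + plen):
            return t
    return None


def find_exon1(
    seq: GenomeSequence,
    candidate: CodingExonCandidate,
    cfg: PipelineConfig | None = None,
    max_upstream: int | None = None,
) -> Exon1Candidate | None:
    """Nearest upstream donor-motif match (on the transcription strand, 5' of
    the acceptor) that has a TATA-pattern match within
    ``tata_distance_range``; None if absent within ``max_upstream`` nt."""
    cfg = cfg or PipelineConfig()
    if candidate.contig != seq.id:
        raise ValueError(
            f"candidate contig {candidate.contig!r} != sequence {seq.id!r}"
        )
    max_upstream = max_upstream if max_upstream is not None else cfg.max_upstream
    if max_upstream <= 0:
        raise ValueError("max_upstream must be positive")
    s = _strand_residues(seq, candidate.strand)
    ag_end = candidate.acceptor.ag_end
    motif = cfg.donor_motif
    # intron = [donor_pos + 1, ag_end); enforce a minimal intron length
    d_max = ag_end - cfg.min_intron_length - 1
    d_min = max(0, (ag_end - 2) - max_upstream)
    plen = len(cfg.tata_pattern)
    for d in range(d_max, d_min - 1, -1):
        if s[d : d + len(motif)] != motif:
            continue
        t = _nearest_tata(s, d, cfg)
        if t is None:
            continue
        distance = d - (t + plen)
        exon1_start = t + plen + _TSS_OFFSET
        return Exon1Candidate(
            contig=seq.id,
            strand=candidate.strand,
            donor_pos=d,
            tata_pos=t,
            tata_donor_distance=distance,
            exon1_span=(exon1_start, d + 1),
        )
    return None


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------


def _dedupe_candidates(
    candidates: Sequence[CodingExonCandidate],
) -> list[CodingExonCandidate]:
    """One candidate per (strand, ORF span): keep the acceptor with the
    highest pyrimidine fraction, ties toward the shortest UTR."""
    best: dict[tuple[str, tuple[int, int]], CodingExonCandidate] = {}
    for cand in candidates:
        key = (cand.strand, cand.orf_span)
        prev = best.get(key)
        if prev is None or (
            cand.acceptor.pyrimidine_fraction,
            -cand.utr_length,
        ) > (prev.acceptor.pyrimidine_fraction, -prev.utr_length):
            best[key] = cand
    return list(best.values())


def _resolve_overlaps(models: list[GeneModel]) -> list[GeneModel]:
    """Among same-strand models with overlapping CDS spans keep the longest
    ORF (ties toward the leftmost start)."""
    kept: list[GeneModel] = []
    for strand in "+-":
        group = sorted(
            (m for m in models if m.strand == strand), key=lambda m: m.cds_span
        )
        cluster: list[GeneModel] = []
        cluster_end = None
        for m in group:
            if cluster and m.cds_span[0] < cluster_end:
                cluster.append(m)
                cluster_end = max(cluster_end, m.cds_span[1])
            else:
                if cluster:
                    kept.append(_pick_longest(cluster))
                cluster = [m]
                cluster_end = m.cds_span[1]
        if cluster:
            kept.append(_pick_longest(cluster))
    return kept


def _pick_longest(cluster: list[GeneModel]) -> GeneModel:
    return max(
        cluster,
        key=lambda m: (m.cds_span[1] - m.cds_span[0], -m.cds_span[0]),
    )


def assemble_gene_models(
    seq: GenomeSequence,
    cfg: PipelineConfig | None = None,
    max_upstream: int | None = None,
) -> list[GeneModel]:
    """Run acceptor -> coding-exon -> exon-1 stages and assemble gene models.

    One model per surviving coding-exon candidate; overlapping same-strand
    candidates are resolved by keeping the longest ORF (ties toward the
    leftmost).  Deterministic; models are sorted by forward CDS start and
    numbered in that order.
    """
    cfg = cfg or PipelineConfig()
    acceptors = scan_splice_acceptors(seq, cfg)
    candidates = _dedupe_candidates(scan_coding_exons(seq, acceptors, cfg))
    L = seq.length
    plen = len(cfg.tata_pattern)

    models = []
    for cand in candidates:
        exon1 = find_exon1(seq, cand, cfg, max_upstream)
        strand = cand.strand
        ag_local = (cand.acceptor.ag_end - 2, cand.acceptor.ag_end)
        exon2_local = (cand.acceptor.ag_end, cand.orf_span[1])
        kwargs = dict(
            id="pending",
            contig=seq.id,
            strand=strand,
            status="coding_exon_only",
            protein=cand.protein,
            cds_span=_fwd_interval(cand.orf_span, L, strand),
            exon2_span=_fwd_interval(exon2_local, L, strand),
            ag_span=_fwd_interval(ag_local, L, strand),
            utr_length=cand.utr_length,
            pyrimidine_fraction=cand.acceptor.pyrimidine_fraction,
        )
        if exon1 is not None:
            intron_local = (exon1.donor_pos + 1, cand.acceptor.ag_end)
            tata_local = (exon1.tata_pos, exon1.tata_pos + plen)
            kwargs.update(
                status="two_exon",
                exon1_span=_fwd_interval(exon1.exon1_span, L, strand),
                intron_span=_fwd_interval(intron_local, L, strand),
                donor_g=_fwd_pos(exon1.donor_pos, L, strand),
                tata_span=_fwd_interval(tata_local, L, strand),
                tata_donor_distance=exon1.tata_donor_distance,
            )
        models.append(GeneModel(**kwargs))

    models = _resolve_overlaps(models)
    models.sort(key=lambda m: (m.cds_span, m.strand))
    return [
        GeneModel(**{**m.__dict__, "id": f"{seq.id}.g{i + 1}"})
        for i, m in enumerate(models)
    ]


# ---------------------------------------------------------------------------
# Protein-level filtering
# ---------------------------------------------------------------------------


def filter_gene_models(
    models: Sequence[GeneModel],
    cfg: PipelineConfig | None = None,
    motifs=None,
) -> list[GeneModel]:
    """Keep models whose protein resembles an EDC protein: a compositional
    class label OR a conserved-motif hit (the two criteria combine by OR)."""
    cfg = cfg or PipelineConfig()
    thresholds = CompositionThresholds.from_config(cfg)
    if motifs is None:
        motifs = load_motif_catalog()
    kept = []
    for m in models:
        profile = composition_profile(m.protein, m.id, thresholds)
        labels = classify_composition(profile, thresholds)
        if labels != frozenset({"unclassified"}):
            kept.append(m)
            continue
        if any(scan_motif(m.protein, motif, m.id) for motif in motifs):
            kept.append(m)
    return kept


def run_pipeline(
    seq: GenomeSequence,
    cfg: PipelineConfig | None = None,
    max_upstream: int | None = None,
    apply_filter: bool = True,
) -> list[GeneModel]:
    """Full discovery pipeline on one contig: assemble gene models, then
    apply the protein composition/motif filter (unless disabled)."""
    cfg = cfg or PipelineConfig()
    models = assemble_gene_models(seq, cfg, max_upstream)
    if apply_filter:
        models = filter_gene_models(models, cfg)
    return models
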