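"""Synthetic genomic loci with embedded two-exon EDC-like genes and ground
truth, plus recovery scoring of predictions against that truth.

Each embedded gene follows the canonical architecture: TATA box -> short
noncoding exon 1 ending in the G|GTAAG splice donor -> intron ->
polypyrimidine tract + AG acceptor -> 20-25 nt 5'UTR -> single-exon ORF whose
protein carries a compositional bias (GS/C/P/Q-rich) and, optionally, the
conserved terminal motifs.  Decoys carry either an ORF without acceptor
context or an acceptor context without a qualifying ORF, so each decoy fails
exactly one discovery rule.  Background DNA is uniform over ACGT.

Embedded gene segments are verified at generation time: a segment is redrawn
until the discovery pipeline, run on the segment in its local sequence
context, recovers exactly the planted gene with exact signal coordinates.
Chance gene-like configurations can still arise in the random spacers between
segments, which is why recovery precision is bounded away from 1 in
expectation rather than guaranteed.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Data import CodonTable

from .gene_finder import (
    GeneModel,
    assemble_gene_models,
    reverse_complement,
    run_pipeline,
)
from .io_formats import GenomeSequence, PipelineConfig, read_gff3, write_gff3
from .locus_map import Anchor
from .motif_repeat import load_motif_catalog

COMPOSITION_CLASSES = ("GS_rich", "C_rich", "P_rich", "Q_rich")

#: class-specific residue sampling distributions.  The biased residues are
#: set to emulate the extremes observed among real EDC proteins (loricrin-like
#: G+S around 70%, cysteine-rich proteins at 35-40% C) with enough margin over
#: the classifier thresholds that sampling noise rarely drops a protein below
#: its class cut-off.
_AA20 = "ACDEFGHIKLMNPQRSTVWY"


def _class_distribution(biased: dict[str, float]) -> dict[str, float]:
    rest = (1.0 - sum(biased.values())) / (20 - len(biased))
    return {aa: biased.get(aa, rest) for aa in _AA20}


CLASS_DISTRIBUTIONS: dict[str, dict[str, float]] = {
    "GS_rich": _class_distribution({"G": 0.35, "S": 0.35}),
    "C_rich": _class_distribution({"C": 0.35}),
    "P_rich": _class_distribution({"P": 0.25}),
    "Q_rich": _class_distribution({"Q": 0.25}),
}

_STOPS = ("TAA", "TAG", "TGA")

_table = CodonTable.unambiguous_dna_by_id[1]
_CODONS_BY_AA: dict[str, list[str]] = {}
for codon, aa in sorted(_table.forward_table.items()):
    _CODONS_BY_AA.setdefault(aa, []).append(codon)

_TATA_RE = re.compile("TATA[AT]A[AT]")
_DONOR = "GGTAAG"


@dataclass(frozen=True)
class SyntheticGeneSpec:
    """Parameters of one embedded gene."""

    composition_class: str = "GS_rich"
    protein_length: int = 120
    include_n_motif: bool = False
    include_c_motif: bool = False
    utr_length: int = 22
    tata_donor_distance: int = 75
    intron_length: int = 200
    exon1_length: int = 45

    def __post_init__(self) -> None:
        if self.composition_class not in COMPOSITION_CLASSES:
            raise ValueError(f"unknown composition class {self.composition_class!r}")
        if not 20 <= self.utr_length <= 25:
            raise ValueError("utr_length must be in [20, 25]")
        if not 60 <= self.tata_donor_distance <= 90:
            raise ValueError("tata_donor_distance must be in [60, 90]")
        if self.intron_length < 40:
            raise ValueError("intron_length must be >= 40")
        if not 10 <= self.exon1_length <= self.tata_donor_distance:
            raise ValueError("exon1_length must be in [10, tata_donor_distance]")


@dataclass(frozen=True)
class SyntheticGeneTruth:
    """Ground-truth record of one embedded gene (forward scaffold coords)."""

    gene_id: str
    strand: str
    cds_span: tuple[int, int]
    exon2_span: tuple[int, int]
    ag_span: tuple[int, int]
    donor_g: int
    tata_span: tuple[int, int]
    exon1_span: tuple[int, int]
    intron_span: tuple[int, int]
    utr_length: int
    tata_donor_distance: int
    protein: str
    composition_class: str
    include_n_motif: bool
    include_c_motif: bool


@dataclass(frozen=True)
class SyntheticDecoyTruth:
    decoy_id: str
    kind: str  # "orf_no_acceptor" or "acceptor_no_orf"
    strand: str
    span: tuple[int, int]


@dataclass(frozen=True)
class SyntheticLocusTruth:
    scaffold_id: str
    scaffold_length: int
    genes: tuple[SyntheticGeneTruth, ...]
    decoys: tuple[SyntheticDecoyTruth, ...]
    anchors: tuple[Anchor, Anchor]

    def to_gene_models(self) -> list[GeneModel]:
        models = []
        for g in self.genes:
            models.append(
                GeneModel(
                    id=g.gene_id,
                    contig=self.scaffold_id,
                    strand=g.strand,
                    status="two_exon",
                    protein=g.protein,
                    cds_span=g.cds_span,
                    exon2_span=g.exon2_span,
                    ag_span=g.ag_span,
                    utr_length=g.utr_length,
                    pyrimidine_fraction=1.0,
                    exon1_span=g.exon1_span,
                    intron_span=g.intron_span,
                    donor_g=g.donor_g,
                    tata_span=g.tata_span,
                    tata_donor_distance=g.tata_donor_distance,
                )
            )
        return models

    def write_truth_gff3(self, path: str | Path) -> None:
        write_gff3(self.to_gene_models(), path, source="edcscan-truth")


# ---------------------------------------------------------------------------
# Random sequence helpers
# ---------------------------------------------------------------------------

_ACGT = np.array(list("ACGT"))
_CT = np.array(list("CT"))


def _random_dna(rng: np.random.Generator, n: int) -> str:
    if n <= 0:
        return ""
    return "".join(rng.choice(_ACGT, size=n))


def _random_dna_avoiding(
    rng: np.random.Generator, n: int, banned: Sequence[re.Pattern | str]
) -> str:
    for _ in range(1000):
        s = _random_dna(rng, n)
        hit = False
        for b in banned:
            if isinstance(b, str):
                if b in s:
                    hit = True
                    break
            elif b.search(s):
                hit = True
                break
        if not hit:
            return s
    raise RuntimeError("could not sample constrained random DNA")


def _map_interval(span: tuple[int, int], length: int) -> tuple[int, int]:
    """Interval coordinates after reverse complementation."""
    return (length - span[1], length - span[0])


# ---------------------------------------------------------------------------
# Proteins and gene segments
# ---------------------------------------------------------------------------


def _motif_consensus(name: str) -> str:
    for m in load_motif_catalog():
        if m.name == name:
            return m.consensus
    raise KeyError(name)


def generate_protein(spec: SyntheticGeneSpec, rng: np.random.Generator) -> str:
    """Sample a protein from the class-specific residue distribution.

    The first residue is always M (the CDS starts with ATG).  Requested
    terminal motifs overwrite the corresponding end, with wildcard positions
    keeping the sampled (class-distributed) residue.  No internal stop can
    arise, by construction.
    """
    dist = CLASS_DISTRIBUTIONS[spec.composition_class]
    aas = list(dist)
    probs = np.array([dist[a] for a in aas])
    n_motif = _motif_consensus("sedc_n_terminal") if spec.include_n_motif else ""
    c_motif = _motif_consensus("sedc_c_terminal") if spec.include_c_motif else ""
    if spec.protein_length < len(n_motif) + len(c_motif):
        raise ValueError(
            f"protein_length {spec.protein_length} too short for requested motifs"
        )
    residues = list(rng.choice(aas, size=spec.protein_length, p=probs))
    residues[0] = "M"
    for i, c in enumerate(n_motif):
        if c != "x":
            residues[i] = c
    offset = spec.protein_length - len(c_motif)
    for i, c in enumerate(c_motif):
        if c != "x":
            residues[offset + i] = c
    return "".join(residues)


def _reverse_translate(protein: str, rng: np.random.Generator) -> str:
    return "".join(rng.choice(_CODONS_BY_AA[aa]) for aa in protein)


def _build_gene_segment(
    spec: SyntheticGeneSpec, strand: str, rng: np.random.Generator
) -> tuple[str, dict]:
    """Assemble one gene segment and its local (segment-forward) truth."""
    protein = generate_protein(spec, rng)
    cds = _reverse_translate(protein, rng) + str(rng.choice(_STOPS))

    pad = 15
    tata = "TATA" + str(rng.choice(["A", "T"])) + "A" + str(rng.choice(["A", "T"]))
    gap_len = spec.tata_donor_distance - spec.exon1_length + 1
    gap = _random_dna_avoiding(rng, gap_len, [_DONOR, _TATA_RE])
    exon1_body = _random_dna_avoiding(rng, spec.exon1_length - 1, [_DONOR, _TATA_RE])
    filler = _random_dna_avoiding(rng, spec.intron_length - 19, [_DONOR])
    tract = "".join(rng.choice(_CT, size=12))
    utr = _random_dna_avoiding(rng, spec.utr_length, ["ATG"])

    seg = (
        _random_dna(rng, pad)
        + tata
        + gap
        + exon1_body
        + "G"
        + "GTAAG"
        + filler
        + tract
        + "AG"
        + utr
        + cds
        + _random_dna(rng, pad)
    )
    t = pad
    tata_end = t + 7
    d = tata_end + gap_len + (spec.exon1_length - 1)  # exon-terminal donor G
    ag_end = d + 1 + spec.intron_length
    m = ag_end + spec.utr_length
    cds_end = m + len(cds)
    L = len(seg)

    truth = {
        "strand": strand,
        "cds_span": (m, cds_end),
        "exon2_span": (ag_end, cds_end),
        "ag_span": (ag_end - 2, ag_end),
        "donor_g": d,
        "tata_span": (t, t + 7),
        "exon1_span": (d + 1 - spec.exon1_length, d + 1),
        "intron_span": (d + 1, ag_end),
        "utr_length": spec.utr_length,
        "tata_donor_distance": spec.tata_donor_distance,
        "protein": protein,
        "composition_class": spec.composition_class,
        "include_n_motif": spec.include_n_motif,
        "include_c_motif": spec.include_c_motif,
    }
    if strand == "-":
        seg = reverse_complement(seg)
        for key in ("cds_span", "exon2_span", "ag_span", "tata_span",
                    "exon1_span", "intron_span"):
            truth[key] = _map_interval(truth[key], L)
        truth["donor_g"] = L - 1 - truth["donor_g"]
    return seg, truth


def _build_decoy_segment(
    kind: str, strand: str, rng: np.random.Generator
) -> tuple[str, dict]:
    if kind == "orf_no_acceptor":
        n_codons = int(rng.integers(60, 151))
        cls = str(rng.choice(COMPOSITION_CLASSES))
        spec = SyntheticGeneSpec(composition_class=cls, protein_length=n_codons)
        protein = generate_protein(spec, rng)
        cds = _reverse_translate(protein, rng) + str(rng.choice(_STOPS))
        seg = _random_dna(rng, 45) + cds + _random_dna(rng, 15)
        span = (45, 45 + len(cds))
    elif kind == "acceptor_no_orf":
        tract = "".join(rng.choice(_CT, size=12))
        utr = _random_dna_avoiding(rng, 22, ["ATG"])
        mini = "ATG" + _reverse_translate(
            "".join(rng.choice(list(_AA20.replace("M", "")), size=10)), rng
        ) + str(rng.choice(_STOPS))
        seg = _random_dna(rng, 15) + tract + "AG" + utr + mini + _random_dna(rng, 15)
        span = (15, len(seg) - 15)
    else:
        raise ValueError(f"unknown decoy kind {kind!r}")
    L = len(seg)
    if strand == "-":
        seg = reverse_complement(seg)
        span = _map_interval(span, L)
    return seg, {"kind": kind, "strand": strand, "span": span}


# ---------------------------------------------------------------------------
# Locus generation
# ---------------------------------------------------------------------------


def _gene_recovered_exactly(
    context: str, offset: int, truth: dict, cfg: PipelineConfig
) -> bool:
    models = run_pipeline(GenomeSequence("ctx", context), cfg)
    if len(models) != 1:
        return False
    m = models[0]

    def shift(span):
        return (span[0] + offset, span[1] + offset)

    return (
        m.status == "two_exon"
        and m.strand == truth["strand"]
        and m.cds_span == shift(truth["cds_span"])
        and m.ag_span == shift(truth["ag_span"])
        and m.donor_g == truth["donor_g"] + offset
        and m.tata_span == shift(truth["tata_span"])
    )


def _decoy_is_silent(context: str, cfg: PipelineConfig) -> bool:
    return not assemble_gene_models(GenomeSequence("ctx", context), cfg)


def _draw_gene_spec(rng: np.random.Generator, composition_class: str) -> SyntheticGeneSpec:
    u = rng.random()
    if u < 0.75:
        length = int(rng.integers(70, 171))
    elif u < 0.90:
        length = int(rng.integers(171, 301))
    else:
        length = int(rng.integers(301, 451))
    dist = int(rng.integers(60, 91))
    return SyntheticGeneSpec(
        composition_class=composition_class,
        protein_length=length,
        include_n_motif=bool(rng.random() < 0.5),
        include_c_motif=bool(rng.random() < 0.5),
        utr_length=int(rng.integers(20, 26)),
        tata_donor_distance=dist,
        intron_length=int(rng.integers(100, 401)),
        exon1_length=int(rng.integers(30, min(56, dist + 1))),
    )


def generate_locus(
    n_genes: int = 50,
    n_decoys: int = 200,
    seed: int | None = None,
    cfg: PipelineConfig | None = None,
    spacer_length: int = 500,
    scaffold_id: str = "synthetic_scaffold",
    block_by_class: bool = True,
    rng: np.random.Generator | None = None,
    max_tries: int = 50,
) -> tuple[GenomeSequence, SyntheticLocusTruth]:
    """Generate one synthetic scaffold with embedded genes, decoys, truth.

    Genes are placed non-overlapping with ``spacer_length`` nt of uniform
    random DNA between elements.  With ``block_by_class`` (default) genes of
    the same compositional class are placed in contiguous blocks, emulating
    the duplication-derived arrangement of a real EDC.  Two anchor regions at
    the scaffold ends play the role of the flanking S100A boundary genes.
    Identical seeds reproduce byte-identical output.
    """
    if n_genes < 0 or n_decoys < 0:
        raise ValueError("n_genes and n_decoys must be non-negative")
    cfg = cfg or PipelineConfig()
    if rng is None:
        rng = np.random.default_rng(seed)

    # class assignment (blocked or shuffled)
    classes: list[str] = []
    if n_genes:
        order = [COMPOSITION_CLASSES[i] for i in rng.permutation(len(COMPOSITION_CLASSES))]
        base, extra = divmod(n_genes, len(order))
        for i, cls in enumerate(order):
            classes.extend([cls] * (base + (1 if i < extra else 0)))
        if not block_by_class:
            classes = [classes[i] for i in rng.permutation(n_genes)]

    labels = ["g"] * n_genes + ["d"] * n_decoys
    labels = [labels[i] for i in rng.permutation(len(labels))]
    decoy_kinds = ["orf_no_acceptor", "acceptor_no_orf"]

    anchor_len = 200
    parts: list[str] = [_random_dna(rng, anchor_len), _random_dna(rng, spacer_length)]
    total = anchor_len + spacer_length
    tail = parts[-1][-100:]

    genes: list[SyntheticGeneTruth] = []
    decoys: list[SyntheticDecoyTruth] = []
    gene_i = decoy_i = 0
    for label in labels:
        for attempt in range(max_tries):
            strand = "+" if rng.random() < 0.5 else "-"
            next_spacer = _random_dna(rng, spacer_length)
            if label == "g":
                spec = _draw_gene_spec(rng, classes[gene_i])
                seg, truth = _build_gene_segment(spec, strand, rng)
                context = tail + seg + next_spacer[:100]
                ok = _gene_recovered_exactly(context, len(tail), truth, cfg)
            else:
                kind = decoy_kinds[decoy_i % 2]
                seg, truth = _build_decoy_segment(kind, strand, rng)
                context = tail + seg + next_spacer[:100]
                ok = _decoy_is_silent(context, cfg)
            if ok:
                break
        else:
            raise RuntimeError(f"failed to place element after {max_tries} tries")

        offset = total
        if label == "g":
            genes.append(
                SyntheticGeneTruth(
                    gene_id=f"truth_gene_{gene_i + 1}",
                    strand=truth["strand"],
                    cds_span=(truth["cds_span"][0] + offset, truth["cds_span"][1] + offset),
                    exon2_span=(truth["exon2_span"][0] + offset, truth["exon2_span"][1] + offset),
                    ag_span=(truth["ag_span"][0] + offset, truth["ag_span"][1] + offset),
                    donor_g=truth["donor_g"] + offset,
                    tata_span=(truth["tata_span"][0] + offset, truth["tata_span"][1] + offset),
                    exon1_span=(truth["exon1_span"][0] + offset, truth["exon1_span"][1] + offset),
                    intron_span=(truth["intron_span"][0] + offset, truth["intron_span"][1] + offset),
                    utr_length=truth["utr_length"],
                    tata_donor_distance=truth["tata_donor_distance"],
                    protein=truth["protein"],
                    composition_class=truth["composition_class"],
                    include_n_motif=truth["include_n_motif"],
                    include_c_motif=truth["include_c_motif"],
                )
            )
            gene_i += 1
        else:
            decoys.append(
                SyntheticDecoyTruth(
                    decoy_id=f"decoy_{decoy_i + 1}",
                    kind=truth["kind"],
                    strand=truth["strand"],
                    span=(truth["span"][0] + offset, truth["span"][1] + offset),
                )
            )
            decoy_i += 1
        parts.append(seg)
        parts.append(next_spacer)
        total += len(seg) + spacer_length
        tail = (tail + seg + next_spacer)[-100:]

    parts.append(_random_dna(rng, anchor_len))
    total += anchor_len
    scaffold = "".join(parts)
    assert len(scaffold) == total
    anchors = (
        Anchor("anchor_left", scaffold_id, 0, anchor_len),
        Anchor("anchor_right", scaffold_id, total - anchor_len, total),
    )
    truth_obj = SyntheticLocusTruth(
        scaffold_id=scaffold_id,
        scaffold_length=total,
        genes=tuple(genes),
        decoys=tuple(decoys),
        anchors=anchors,
    )
    return GenomeSequence(scaffold_id, scaffold), truth_obj


# ---------------------------------------------------------------------------
# Recovery scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RecoveryReport:
    """Gene-level recovery of truth by predictions, with per-signal exactness."""

    n_truth: int
    n_predicted: int
    n_matched: int
    sensitivity: float
    precision: float
    acceptor_exact: float
    donor_exact: float
    tata_exact: float


def _records_from_gff3(path: str | Path) -> list[dict]:
    df = read_gff3(path)
    if df.empty:
        return []
    gene_rows = {row.attrs["ID"]: row for row in df[df["type"] == "gene"].itertuples()}
    records = []
    for row in df[df["type"] == "CDS"].itertuples():
        parent = row.attrs.get("Parent", "")
        gene_id = parent[:-3] if parent.endswith(".t1") else parent
        g = gene_rows.get(gene_id)
        if g is None:
            continue

        def _int(key):
            v = g.attrs.get(key)
            return int(v) if v not in (None, "", "None") else None

        records.append(
            {
                "id": gene_id,
                "contig": row.seqid,
                "strand": row.strand,
                "cds_span": (row.start0, row.end0),
                "ag_start": _int("ag_start"),
                "donor_g": _int("donor_g"),
                "tata_start": _int("tata_start"),
            }
        )
    return records


def _records_from_models(models: Sequence[GeneModel]) -> list[dict]:
    return [
        {
            "id": m.id,
            "contig": m.contig,
            "strand": m.strand,
            "cds_span": m.cds_span,
            "ag_start": m.ag_span[0],
            "donor_g": m.donor_g,
            "tata_start": m.tata_span[0] if m.tata_span else None,
        }
        for m in models
    ]


def recovery_report(predicted, truth) -> RecoveryReport:
    """Score predictions against truth.

    A prediction matches a truth gene iff contig, strand, and CDS coordinates
    are identical.  Among matched genes, the acceptor/donor/TATA exactness
    rates compare the respective signal coordinates.  ``predicted`` and
    ``truth`` may each be a GFF3 path, a list of :class:`GeneModel`, or a
    :class:`SyntheticLocusTruth`.
    """

    def normalize(obj):
        if isinstance(obj, (str, Path)):
            return _records_from_gff3(obj)
        if isinstance(obj, SyntheticLocusTruth):
            return _records_from_models(obj.to_gene_models())
        return _records_from_models(obj)

    pred = normalize(predicted)
    true = normalize(truth)

    pred_by_key = {(r["contig"], r["strand"], r["cds_span"]): r for r in pred}
    matched = []
    for t in true:
        p = pred_by_key.get((t["contig"], t["strand"], t["cds_span"]))
        if p is not None:
            matched.append((t, p))

    n_truth, n_pred, n_matched = len(true), len(pred), len(matched)
    sensitivity = n_matched / n_truth if n_truth else 1.0
    precision = n_matched / n_pred if n_pred else 1.0

    def exact_rate(key):
        if not matched:
            return 1.0
        return sum(
            1 for t, p in matched if t[key] is not None and t[key] == p[key]
        ) / len(matched)

    return RecoveryReport(
        n_truth=n_truth,
        n_predicted=n_pred,
        n_matched=n_matched,
        sensitivity=sensitivity,
        precision=precision,
        acceptor_exact=exact_rate("ag_start"),
        donor_exact=exact_rate("donor_g"),
        tata_exact=exact_rate("tata_start"),
    )
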