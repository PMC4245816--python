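"""Input/output for the standard formats the pipeline touches, plus run configuration.

Internal coordinates are 0-based, half-open, on the forward strand throughout
the package.  Minus-strand features are stored as forward-strand intervals with
a strand flag.  GFF3 output converts to the 1-based inclusive convention that
format requires; GFF3 *attributes* written by this package carry 0-based
internal coordinates (they are round-trip metadata, not positional columns).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

DNA_ALPHABET = frozenset("ACGTN")
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: canonical residue order used for composition vectors and feature tables
AA_ORDER = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class GenomeSequence:
    """A named DNA contig over the alphabet {A, C, G, T, N}."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        residues = self.residues.upper()
        bad = set(residues) - DNA_ALPHABET
        if bad:
            raise ValueError(
                f"illegal DNA residue(s) {sorted(bad)} in sequence {self.id!r}"
            )
        object.__setattr__(self, "residues", residues)

    @property
    def length(self) -> int:
        return len(self.residues)

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.id, str(Seq(self.residues).reverse_complement()))


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence over the 20 standard amino acids."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        residues = self.residues.upper()
        bad = set(residues) - PROTEIN_ALPHABET
        if bad:
            raise ValueError(
                f"illegal protein residue(s) {sorted(bad)} in record {self.id!r}"
            )
        object.__setattr__(self, "residues", residues)

    @property
    def length(self) -> int:
        return len(self.residues)


@dataclass
class PipelineConfig:
    """Tunable parameters of the gene-discovery pipeline.

    The splice-distance defaults encode the canonical two-exon EDC gene
    architecture: the coding ORF sits 20-25 nt downstream of the splice
    acceptor AG, and the TATA box sits 60-90 nt upstream of the exon-1
    splice donor.  The remaining knobs (polypyrimidine window, ORF length
    bounds, classifier thresholds, expansion score threshold) are
    operational choices exposed for configuration.
    """

    acceptor_distance_range: tuple[int, int] = (20, 25)
    tata_distance_range: tuple[int, int] = (60, 90)
    donor_motif: str = "GGTAAG"
    polypyrimidine_window: int = 12
    polypyrimidine_min_fraction: float = 0.7
    tata_pattern: str = "TATAWAW"
    min_orf_codons: int = 60
    max_orf_codons: int = 2000
    min_intron_length: int = 30
    max_upstream: int = 10_000
    # protein composition-class thresholds (fractions of total residues)
    gs_rich_min: float = 0.5
    c_rich_min: float = 0.15
    p_rich_min: float = 0.15
    q_rich_min: float = 0.15
    # iterative similarity expansion
    similarity_threshold: float = 40.0
    max_iterations: int = 20
    random_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("acceptor_distance_range", "tata_distance_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must satisfy low <= high, got ({lo}, {hi})")
            setattr(self, name, (int(lo), int(hi)))
        for name in ("polypyrimidine_min_fraction", "gs_rich_min", "c_rich_min",
                     "p_rich_min", "q_rich_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be a fraction in [0, 1], got {v}")
        if self.min_orf_codons > self.max_orf_codons:
            raise ValueError("min_orf_codons must not exceed max_orf_codons")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["acceptor_distance_range"] = list(d["acceptor_distance_range"])
        d["tata_distance_range"] = list(d["tata_distance_range"])
        return d

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.as_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("acceptor_distance_range", "tata_distance_range"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def read_fasta(path: str | Path, kind: str = "dna"):
    """Read a FASTA file into :class:`GenomeSequence` or :class:`ProteinRecord` lists.

    Residues are uppercased; record order is preserved.  An illegal residue
    raises ``ValueError`` naming the record id and the 1-based position.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if kind not in ("dna", "protein"):
        raise ValueError(f"kind must be 'dna' or 'protein', got {kind!r}")
    alphabet = DNA_ALPHABET if kind == "dna" else PROTEIN_ALPHABET
    cls = GenomeSequence if kind == "dna" else ProteinRecord

    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        for pos, ch in enumerate(residues, start=1):
            if ch not in alphabet:
                raise ValueError(
                    f"illegal residue {ch!r} in record {rec.id!r} at position {pos}"
                )
        records.append(cls(rec.id, residues))
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable, path: str | Path, width: int = 70) -> None:
    """Write GenomeSequence/ProteinRecord objects as FASTA."""
    seq_records = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_GFF3_COLUMNS = [
    "seqid", "source", "type", "start", "end", "score", "strand", "phase",
    "attributes",
]


def _format_attributes(attrs: dict) -> str:
    return ";".join(f"{k}={v}" for k, v in attrs.items() if v is not None)


def _parse_attributes(text: str) -> dict:
    out = {}
    for part in text.strip().split(";"):
        if not part:
            continue
        key, _, value = part.partition("=")
        out[key] = value
    return out


def write_gff3(models: Sequence, path: str | Path, source: str = "edcscan") -> None:
    """Serialize gene models as GFF3 (gene/mRNA/exon/CDS rows).

    Internal 0-based half-open spans are converted to 1-based inclusive
    columns.  Signal coordinates (acceptor AG start, donor G, TATA start)
    are carried as 0-based integers in the gene row's attributes so that a
    round-trip read reproduces them exactly.
    """
    lines = ["##gff-version 3"]
    for model in models:
        if model.exon2_span is None or model.cds_span is None:
            raise ValueError(f"model {model.id!r} lacks a coding exon")
        spans = [model.cds_span, model.exon2_span]
        if model.exon1_span is not None:
            spans.append(model.exon1_span)
        if model.tata_span is not None:
            spans.append(model.tata_span)
        g_start = min(s[0] for s in spans)
        g_end = max(s[1] for s in spans)

        attrs = {
            "ID": model.id,
            "status": model.status,
            "ag_start": model.ag_span[0] if model.ag_span is not None else None,
            "donor_g": model.donor_g,
            "tata_start": model.tata_span[0] if model.tata_span is not None else None,
            "utr_length": model.utr_length,
        }
        if getattr(model, "pyrimidine_fraction", None) is not None:
            attrs["pyrimidine_fraction"] = f"{model.pyrimidine_fraction:.4f}"

        def row(ftype, span, attr_dict, phase="."):
            return "\t".join([
                model.contig, source, ftype, str(span[0] + 1), str(span[1]),
                ".", model.strand, phase, _format_attributes(attr_dict),
            ])

        mrna_id = f"{model.id}.t1"
        lines.append(row("gene", (g_start, g_end), attrs))
        lines.append(row("mRNA", (g_start, g_end), {"ID": mrna_id, "Parent": model.id}))
        if model.exon1_span is not None:
            lines.append(row("exon", model.exon1_span, {"Parent": mrna_id}))
        lines.append(row("exon", model.exon2_span, {"Parent": mrna_id}))
        lines.append(row("CDS", model.cds_span, {"Parent": mrna_id}, phase="0"))
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> pd.DataFrame:
    """Read a GFF3 file into a DataFrame with a parsed ``attrs`` dict column.

    ``start0``/``end0`` columns give the 0-based half-open interval.
    """
    rows = []
    for line in Path(path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 9:
            raise ValueError(f"malformed GFF3 line: {line!r}")
        rows.append(parts)
    df = pd.DataFrame(rows, columns=_GFF3_COLUMNS)
    if df.empty:
        df = pd.DataFrame(columns=_GFF3_COLUMNS + ["start0", "end0", "attrs"])
        return df
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    df["start0"] = df["start"] - 1
    df["end0"] = df["end"]
    df["attrs"] = df["attributes"].map(_parse_attributes)
    return df


# ---------------------------------------------------------------------------
# Feature tables
# ---------------------------------------------------------------------------


def write_feature_table(profiles: Sequence, path: str | Path) -> None:
    """Write one row per protein: residue fractions, length, pI, class labels.

    Fractions are printed to 4 decimals; re-parsing reproduces them at that
    precision.
    """
    if not profiles:
        raise ValueError("profiles must be non-empty")
    rows = []
    for p in profiles:
        row = {"id": p.protein_id, "length": p.length}
        for aa in AA_ORDER:
            row[f"frac_{aa}"] = p.fractions[aa]
        row["gs_fraction"] = p.gs_fraction
        row["q_count"] = p.q_count
        row["k_count"] = p.k_count
        row["pi"] = p.pi
        row["size_class"] = p.size_class
        row["class_labels"] = ",".join(sorted(p.class_labels))
        rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(path, sep="\t", index=False, float_format="%.4f")


def read_feature_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
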