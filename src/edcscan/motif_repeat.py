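"""Consensus-motif matching with wildcards and anchoring, position frequency
matrices for sequence logos, and a self-match periodicity score for the
internal repeats typical of long EDC proteins."""

from __future__ import annotations

import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .io_formats import AA_ORDER

ANCHORS = ("n_terminal", "c_terminal", "internal")


@dataclass(frozen=True)
class MotifDefinition:
    """A wildcard consensus motif.

    ``consensus`` is residue text in which lowercase ``x`` matches any
    residue; ``anchor`` constrains where in the protein the motif may sit.
    Wildcard positions never count toward the mismatch budget.
    """

    name: str
    consensus: str
    anchor: str
    max_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"motif {self.name!r}: consensus must be non-empty")
        if self.anchor not in ANCHORS:
            raise ValueError(f"motif {self.name!r}: anchor must be one of {ANCHORS}")
        n_fixed = sum(1 for c in self.consensus if c != "x")
        if self.max_mismatches >= max(n_fixed, 1):
            raise ValueError(
                f"motif {self.name!r}: max_mismatches must be below the number "
                f"of non-wildcard positions ({n_fixed})"
            )

    def __len__(self) -> int:
        return len(self.consensus)


@dataclass(frozen=True)
class MotifHit:
    protein_id: str
    motif_name: str
    start: int  # 0-based offset in the protein
    mismatches: int


@dataclass(frozen=True)
class RepeatReport:
    """Periodicity summary of a protein's best tandem-repeat block."""

    protein_id: str
    best_period: int
    copy_number: int
    repeat_fraction: float


def _mismatches_at(protein: str, consensus: str, offset: int) -> int:
    n = 0
    for i, c in enumerate(consensus):
        if c == "x":
            continue
        if protein[offset + i] != c.upper():
            n += 1
    return n


def scan_motif(
    protein: str,
    motif: MotifDefinition,
    protein_id: str = "protein",
    max_mismatches: int | None = None,
) -> list[MotifHit]:
    """All anchor-consistent matches with at most ``max_mismatches``
    non-wildcard mismatches (default: the motif's own budget).

    N-terminal motifs are tested only at offset 0, C-terminal motifs only
    flush with the protein end; internal motifs at every offset.  A protein
    shorter than the consensus yields no hits.
    """
    protein = protein.upper()
    budget = motif.max_mismatches if max_mismatches is None else max_mismatches
    m = len(motif.consensus)
    if len(protein) < m:
        return []
    if motif.anchor == "n_terminal":
        offsets = [0]
    elif motif.anchor == "c_terminal":
        offsets = [len(protein) - m]
    else:
        offsets = range(len(protein) - m + 1)
    hits = []
    for off in offsets:
        mm = _mismatches_at(protein, motif.consensus, off)
        if mm <= budget:
            hits.append(MotifHit(protein_id, motif.name, off, mm))
    return hits


def load_motif_catalog(path: str | Path | None = None) -> list[MotifDefinition]:
    """Load the packaged motif catalogue (or a user-supplied YAML file).

    Entries whose consensus is empty/null are placeholders (e.g. the
    beta-keratin core box, for which no consensus string is published) and
    are skipped.
    """
    if path is None:
        text = resources.files("edcscan.data").joinpath("motifs.yaml").read_text()
    else:
        text = Path(path).read_text()
    entries = yaml.safe_load(text) or []
    motifs = []
    for entry in entries:
        if not entry.get("consensus"):
            continue
        motifs.append(
            MotifDefinition(
                name=entry["name"],
                consensus=entry["consensus"],
                anchor=entry["anchor"],
                max_mismatches=int(entry.get("max_mismatches", 0)),
            )
        )
    return motifs


@dataclass(frozen=True)
class PositionFrequencyMatrix:
    """Per-position residue frequencies of an aligned block, with the
    information content (log2(20) - entropy) per column."""

    frequencies: pd.DataFrame  # index: 20 residues, columns: positions
    information: np.ndarray


def position_frequency_matrix(aligned_blocks: Sequence[str]) -> PositionFrequencyMatrix:
    """Column-wise residue frequencies of an alignment (gaps ``-`` are
    excluded from column counts)."""
    if len(aligned_blocks) < 2:
        raise ValueError("need at least 2 aligned sequences")
    lengths = {len(s) for s in aligned_blocks}
    if len(lengths) != 1:
        raise ValueError(f"aligned sequences have unequal lengths: {sorted(lengths)}")
    ncol = lengths.pop()
    seqs = [s.upper() for s in aligned_blocks]
    freq = np.zeros((len(AA_ORDER), ncol))
    aa_index = {aa: i for i, aa in enumerate(AA_ORDER)}
    for col in range(ncol):
        column = [s[col] for s in seqs if s[col] != "-"]
        if not column:
            continue
        for ch in column:
            if ch not in aa_index:
                raise ValueError(f"illegal residue {ch!r} in alignment column {col}")
            freq[aa_index[ch], col] += 1
        freq[:, col] /= len(column)
    info = np.zeros(ncol)
    for col in range(ncol):
        p = freq[:, col]
        p = p[p > 0]
        entropy = -np.sum(p * np.log2(p)) if p.size else math.log2(20)
        info[col] = math.log2(20) - entropy
    return PositionFrequencyMatrix(
        frequencies=pd.DataFrame(freq, index=list(AA_ORDER)),
        information=info,
    )


def repeat_score(
    protein: str,
    min_period: int = 2,
    max_period: int | None = None,
    protein_id: str = "protein",
) -> RepeatReport:
    """Flag internal repetitiveness via a self-match period profile.

    For each candidate period ``p`` the protein is compared against itself
    shifted by ``p``; the longest contiguous run of matches defines a tandem
    block of length ``run + p``.  A block counts only if it contains at least
    two full copies (``run >= p``).  The best period maximizes block coverage
    of the protein (ties broken toward the smallest period).  This is an
    approximation sufficient for flagging repeats, not a full tandem-repeat
    alignment.
    """
    protein = protein.upper()
    L = len(protein)
    if min_period < 2:
        raise ValueError("min_period must be >= 2")
    if L < 2 * min_period:
        raise ValueError(f"protein length {L} too short for min_period {min_period}")
    if max_period is None:
        max_period = L // 2

    best_period = min_period
    best_block = 0
    for period in range(min_period, max_period + 1):
        run = longest = 0
        for i in range(L - period):
            if protein[i] == protein[i + period]:
                run += 1
                if run > longest:
                    longest = run
            else:
                run = 0
        block = longest + period if longest >= period else 0
        if block > best_block:
            best_block = block
            best_period = period
    if best_block == 0:
        return RepeatReport(protein_id, min_period, 1, 0.0)
    return RepeatReport(
        protein_id,
        best_period,
        best_block // best_period,
        min(1.0, best_block / L),
    )
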