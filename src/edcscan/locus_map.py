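"""Assemble predicted genes into an EDC locus view between anchor genes
(e.g. S100A9 and S100A11) and quantify the tendency of neighboring genes to
encode proteins of similar amino-acid composition — the signature expected
when a locus grew by local gene duplication."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .protein_features import CompositionProfile


@dataclass(frozen=True)
class Anchor:
    """A boundary gene span (forward 0-based half-open interval)."""

    name: str
    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"anchor {self.name!r}: start must be < end")


@dataclass(frozen=True)
class LocusGene:
    gene_id: str
    strand: str
    midpoint: float
    inside: bool


@dataclass(frozen=True)
class EDCLocusMap:
    """Genes ordered along the contig with inside-the-locus flags."""

    contig: str
    anchors: tuple[Anchor, Anchor]
    genes: tuple[LocusGene, ...]

    def inside_genes(self) -> list[LocusGene]:
        return [g for g in self.genes if g.inside]

    def rank(self, gene_id: str) -> int:
        for i, g in enumerate(self.genes):
            if g.gene_id == gene_id:
                return i
        raise KeyError(gene_id)


def read_anchors(path: str | Path) -> tuple[Anchor, Anchor]:
    """Read two anchor genes from a BED-like TSV (contig, start, end, name)."""
    df = pd.read_csv(
        path, sep="\t", header=None, names=["contig", "start", "end", "name"],
        comment="#",
    )
    if len(df) != 2:
        raise ValueError(f"expected exactly 2 anchors, got {len(df)}")
    anchors = tuple(
        Anchor(row["name"], row["contig"], int(row["start"]), int(row["end"]))
        for row in df.to_dict("records")
    )
    return anchors  # type: ignore[return-value]


def build_locus_map(models: Sequence, anchors: Sequence[Anchor]) -> EDCLocusMap:
    """Order gene models by midpoint and flag those strictly between anchors."""
    a1, a2 = sorted(anchors, key=lambda a: a.start)
    if a1.contig != a2.contig:
        raise ValueError("anchors are on different contigs")
    if a1.end > a2.start:
        raise ValueError("anchors overlap")
    inner_lo, inner_hi = a1.end, a2.start
    genes = []
    for m in models:
        if m.contig != a1.contig:
            raise ValueError(
                f"model {m.id!r} on contig {m.contig!r}, anchors on {a1.contig!r}"
            )
        midpoint = 0.5 * (m.cds_span[0] + m.cds_span[1])
        inside = inner_lo < midpoint < inner_hi
        genes.append(LocusGene(m.id, m.strand, midpoint, inside))
    genes.sort(key=lambda g: (g.midpoint, g.gene_id))
    return EDCLocusMap(a1.contig, (a1, a2), tuple(genes))


def neighbor_composition_statistic(
    locus: EDCLocusMap,
    profiles: Mapping[str, CompositionProfile],
    n_permutations: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Test whether neighboring genes encode compositionally similar proteins.

    The statistic is the mean Euclidean distance between the 20-dimensional
    composition fraction vectors of adjacent genes in locus order (inside
    genes only).  The p-value is the add-one permutation fraction of random
    gene orderings whose mean adjacent distance is <= the observed one.
    """
    inside = locus.inside_genes()
    if len(inside) < 3:
        raise ValueError(f"need at least 3 inside genes, got {len(inside)}")
    if n_permutations < 100:
        raise ValueError("n_permutations must be >= 100")
    vectors = np.array([profiles[g.gene_id].fraction_vector() for g in inside])

    def mean_adjacent(order: np.ndarray) -> float:
        v = vectors[order]
        return float(np.mean(np.linalg.norm(np.diff(v, axis=0), axis=1)))

    n = len(inside)
    observed = mean_adjacent(np.arange(n))
    rng = np.random.default_rng(seed)
    hits = sum(
        mean_adjacent(rng.permutation(n)) <= observed + 1e-12
        for _ in range(n_permutations)
    )
    p_value = (1 + hits) / (n_permutations + 1)
    return observed, p_value


def compare_loci(
    map_a: EDCLocusMap,
    map_b: EDCLocusMap,
    ortholog_pairs: Sequence[tuple[str, str]],
) -> pd.DataFrame:
    """Synteny table for ortholog pairs across two locus maps.

    Each pair gets its rank position in both loci, the number of other pairs
    with which it is in the same relative order in the two loci, and a
    concordance flag (in the same relative order with every other pair).
    """
    rows = []
    ranks = []
    for ida, idb in ortholog_pairs:
        ranks.append((map_a.rank(ida), map_b.rank(idb)))
    for i, (ida, idb) in enumerate(ortholog_pairs):
        ra, rb = ranks[i]
        n_conc = sum(
            1
            for j, (oa, ob) in enumerate(ranks)
            if j != i and (ra - oa) * (rb - ob) > 0
        )
        rows.append(
            {
                "gene_a": ida,
                "gene_b": idb,
                "rank_a": ra,
                "rank_b": rb,
                "n_concordant": n_conc,
                "concordant": n_conc == len(ortholog_pairs) - 1,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["gene_a", "gene_b", "rank_a", "rank_b", "n_concordant", "concordant"],
    )
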