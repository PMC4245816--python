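"""Iterative similarity-driven candidate expansion and reciprocal-best-hit
orthology calls.

Pairwise similarity uses exact Smith-Waterman local alignment (BLOSUM62,
affine gaps) rather than a heuristic seeded search: EDC proteins are low
complexity, which makes heuristic seeding unreliable, and candidate pools are
small enough for exact dynamic programming.  A gap of length k is penalized
``gap_open + k * gap_extend``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping

from Bio import Align
from Bio.Align import substitution_matrices


@dataclass(frozen=True)
class SimilarityEdge:
    """A scored pairwise local alignment between two proteins."""

    query: str
    subject: str
    score: float
    identity: float  # fraction of identical positions over aligned columns


def _make_aligner(matrix="BLOSUM62", gap_open: float = 11.0, gap_extend: float = 1.0):
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    if isinstance(matrix, str):
        matrix = substitution_matrices.load(matrix)
    aligner.substitution_matrix = matrix
    # Biopython scores the first gap position with open_gap_score and the
    # rest with extend_gap_score; shift so a length-k gap costs open + k*extend.
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    return aligner


def local_align(
    a: str,
    b: str,
    matrix="BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    query_id: str = "query",
    subject_id: str = "subject",
) -> SimilarityEdge:
    """Optimal Smith-Waterman local alignment score and identity."""
    if not a or not b:
        raise ValueError("both sequences must be non-empty")
    aligner = _make_aligner(matrix, gap_open, gap_extend)
    alphabet = set(str(c) for c in aligner.substitution_matrix.alphabet)
    for name, seq in ((query_id, a), (subject_id, b)):
        bad = set(seq.upper()) - alphabet
        if bad:
            raise ValueError(f"residue(s) {sorted(bad)} in {name!r} outside matrix alphabet")
    a, b = a.upper(), b.upper()
    score = float(aligner.score(a, b))
    if score <= 0.0:
        return SimilarityEdge(query_id, subject_id, 0.0, 0.0)
    alignment = aligner.align(a, b)[0]
    counts = alignment.counts()
    gaps, identities, mismatches = counts.gaps, counts.identities, counts.mismatches
    columns = gaps + identities + mismatches
    identity = identities / columns if columns else 0.0
    return SimilarityEdge(query_id, subject_id, score, identity)


ScoreFn = Callable[[str, str], float]


def _default_score_fn(matrix, gap_open, gap_extend) -> ScoreFn:
    aligner = _make_aligner(matrix, gap_open, gap_extend)

    def score(a: str, b: str) -> float:
        return float(aligner.score(a.upper(), b.upper()))

    return score


def iterative_expand(
    seeds: Mapping[str, str],
    pool: Mapping[str, str],
    threshold: float,
    max_iterations: int | None = 20,
    score_fn: ScoreFn | None = None,
    matrix="BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
) -> tuple[set[str], int]:
    """Iterative similarity screening: newly accepted proteins become queries.

    Round k adds every pool member scoring at or above ``threshold`` against
    any member accepted in an earlier round; the process stops at a fixed
    point (or after ``max_iterations``).  The result is the connected-
    component closure of the seeds in the >=threshold similarity graph and is
    independent of within-round processing order.

    Returns ``(accepted ids including seeds, rounds used)`` where rounds used
    counts the expansion rounds that added members (at least 1 when seeds are
    non-empty, 0 for an empty seed set).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if not seeds:
        return set(), 0
    if score_fn is None:
        score_fn = _default_score_fn(matrix, gap_open, gap_extend)
    sequences = {**pool, **seeds}
    accepted = set(seeds)
    frontier = list(seeds)
    remaining = [pid for pid in pool if pid not in accepted]
    rounds_with_additions = 0
    iterations = 0
    while frontier and remaining:
        if max_iterations is not None and iterations >= max_iterations:
            break
        iterations += 1
        added = [
            pid
            for pid in remaining
            if any(score_fn(sequences[q], sequences[pid]) >= threshold for q in frontier)
        ]
        if not added:
            break
        rounds_with_additions += 1
        accepted.update(added)
        remaining = [pid for pid in remaining if pid not in accepted]
        frontier = added
    return accepted, max(rounds_with_additions, 1)


def reciprocal_best_hits(
    set_a: Mapping[str, str],
    set_b: Mapping[str, str],
    matrix="BLOSUM62",
    gap_open: float = 11.0,
    gap_extend: float = 1.0,
    score_fn: ScoreFn | None = None,
) -> list[tuple[str, str]]:
    """Ortholog pairs by mutual unique highest similarity.

    ``(a, b)`` is reported iff b is a's unique highest-scoring partner in
    ``set_b`` and vice versa; score ties produce no pair (conservative).
    """
    if not set_a or not set_b:
        raise ValueError("both sets must be non-empty")
    if score_fn is None:
        score_fn = _default_score_fn(matrix, gap_open, gap_extend)
    scores = {
        (ida, idb): score_fn(sa, sb)
        for ida, sa in set_a.items()
        for idb, sb in set_b.items()
    }

    def unique_best(candidates: list[tuple[str, float]]) -> str | None:
        best = max(s for _, s in candidates)
        winners = [i for i, s in candidates if s == best]
        return winners[0] if len(winners) == 1 else None

    best_in_b = {
        ida: unique_best([(idb, scores[ida, idb]) for idb in set_b]) for ida in set_a
    }
    best_in_a = {
        idb: unique_best([(ida, scores[ida, idb]) for ida in set_a]) for idb in set_b
    }
    pairs = [
        (ida, idb)
        for ida, idb in best_in_b.items()
        if idb is not None and best_in_a.get(idb) == ida
    ]
    return sorted(pairs)
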