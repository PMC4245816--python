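"""Independent brute-force oracles used by the test suite.

These re-derive the scanner and alignment results from first principles with
deliberately simple code paths, so that they stay independent of the package
implementation they check.
"""

from __future__ import annotations

import re

PYRIMIDINES = set("CT")
STOPS = {"TAA", "TAG", "TGA"}
TATA_RE = re.compile("TATA[AT]A[AT]")


def brute_acceptors(s: str, window: int = 12, min_frac: float = 0.7):
    """All (ag_end, pyrimidine_fraction) on one strand, by direct enumeration."""
    out = []
    for i in range(window, len(s) - 1):
        if s[i : i + 2] != "AG":
            continue
        win = s[i - window : i]
        if "N" in win:
            continue
        frac = sum(1 for c in win if c in PYRIMIDINES) / window
        if frac >= min_frac:
            out.append((i + 2, frac))
    return out


def brute_coding_exons(
    s: str,
    accepted_ag_ends: set[int],
    lo: int = 20,
    hi: int = 25,
    min_codons: int = 60,
    max_codons: int = 2000,
):
    """All (ag_end, utr, orf_span) via a global ATG scan intersected with the
    acceptor-distance rule (independent of the per-acceptor scan order)."""
    out = []
    for start in range(len(s) - 2):
        if s[start : start + 3] != "ATG":
            continue
        # extend to the first in-frame stop
        end = None
        n_codons = 0
        bad = False
        pos = start
        while pos + 3 <= len(s):
            codon = s[pos : pos + 3]
            if "N" in codon:
                bad = True
                break
            if codon in STOPS:
                end = pos + 3
                break
            n_codons += 1
            pos += 3
            if n_codons > max_codons:
                bad = True
                break
        if bad or end is None or not (min_codons <= n_codons <= max_codons):
            continue
        for ag_end in accepted_ag_ends:
            utr = start - ag_end
            if lo <= utr <= hi:
                out.append((ag_end, utr, (start, end)))
    return sorted(out)


def brute_exon1(
    s: str,
    ag_end: int,
    min_intron: int = 30,
    max_upstream: int = 10_000,
    donor: str = "GGTAAG",
    dist_lo: int = 60,
    dist_hi: int = 90,
):
    """Nearest upstream donor with a TATA at valid distance, by full
    enumeration of (donor, TATA) pairs."""
    pairs = []
    d_lo = max(0, (ag_end - 2) - max_upstream)
    for d in range(d_lo, ag_end - min_intron):
        if s[d : d + 6] != donor:
            continue
        for t in range(max(0, d - dist_hi - 7), d - dist_lo - 7 + 1):
            m = TATA_RE.match(s, t)
            if m and m.end() == t + 7:
                pairs.append((d, t))
    if not pairs:
        return None
    d_best = max(d for d, _ in pairs)
    t_best = max(t for d, t in pairs if d == d_best)
    return d_best, t_best


def sw_affine_score(a: str, b: str, sub, gap_open: float = 11.0, gap_extend: float = 1.0):
    """Smith-Waterman local alignment score, Gotoh affine gaps: a gap of
    length k costs gap_open + k * gap_extend."""
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (consumes b)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (consumes a)
    first = gap_open + gap_extend
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - first, E[i][j - 1] - gap_extend)
            F[i][j] = max(H[i - 1][j] - first, F[i - 1][j] - gap_extend)
            H[i][j] = max(
                0.0, H[i - 1][j - 1] + sub[a[i - 1], b[j - 1]], E[i][j], F[i][j]
            )
            if H[i][j] > best:
                best = H[i][j]
    return best


def closure_by_reachability(seeds: set[str], pool: set[str], score, threshold: float):
    """Connected-component closure of the seeds in the >= threshold similarity
    graph, by plain breadth-first search over all ids."""
    ids = sorted(seeds | pool)
    accepted = set(seeds)
    frontier = sorted(seeds)
    while frontier:
        new = [
            v
            for v in ids
            if v not in accepted and any(score(u, v) >= threshold for u in frontier)
        ]
        accepted.update(new)
        frontier = new
    return accepted
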