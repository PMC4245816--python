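"""Per-protein analyses: translation, amino-acid composition, compositional
class, size class, isoelectric point, and cross-linking residue counts.

EDC proteins are substrates of transglutaminase-mediated cornification, so the
analyses focus on the residues that matter for that biology: glutamine and
lysine (cross-linking targets), cysteine (disulfide bridges), and the strong
compositional biases (glycine/serine-, cysteine-, proline- or glutamine-rich)
that distinguish the protein families encoded in the locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from Bio.Seq import Seq

from .io_formats import AA_ORDER, PROTEIN_ALPHABET, PipelineConfig

#: EMBOSS-style pKa values used for net-charge / isoelectric-point calculation.
#: Keys: terminal groups plus the titratable side chains.
PKA_SETS: dict[str, dict[str, float]] = {
    "emboss": {
        "n_term": 8.6,
        "c_term": 3.6,
        "C": 8.5,
        "D": 3.9,
        "E": 4.1,
        "H": 6.5,
        "K": 10.8,
        "R": 12.5,
        "Y": 10.1,
    },
}

_POSITIVE_SIDECHAINS = ("H", "K", "R")
_NEGATIVE_SIDECHAINS = ("C", "D", "E", "Y")


def translate(cds: str) -> str:
    """Translate a coding sequence with the standard genetic code.

    The CDS must start with ATG and have length divisible by 3.  A trailing
    stop codon is removed; an internal stop raises ``ValueError``.
    """
    cds = cds.upper()
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} is not a multiple of 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS does not start with ATG")
    bad = set(cds) - set("ACGT")
    if bad:
        raise ValueError(f"CDS contains non-ACGT symbol(s): {sorted(bad)}")
    aa = str(Seq(cds).translate(table=1))
    if aa.endswith("*"):
        aa = aa[:-1]
    if "*" in aa:
        raise ValueError(f"internal stop codon at codon {aa.index('*') + 1}")
    return aa


def _validate_protein(protein: str) -> str:
    if not protein:
        raise ValueError("protein must be non-empty")
    protein = protein.upper()
    bad = set(protein) - PROTEIN_ALPHABET
    if bad:
        raise ValueError(f"illegal protein residue(s): {sorted(bad)}")
    return protein


def net_charge(protein: str, ph: float, pka_set: str | Mapping[str, float] = "emboss") -> float:
    """Henderson-Hasselbalch net charge of a protein at a given pH.

    Sums the partial charges of the N-terminus, C-terminus, and the D, E, C,
    Y, H, K, R side chains.
    """
    protein = _validate_protein(protein)
    pka = PKA_SETS[pka_set] if isinstance(pka_set, str) else pka_set
    charge = 1.0 / (1.0 + 10.0 ** (ph - pka["n_term"]))
    charge -= 1.0 / (1.0 + 10.0 ** (pka["c_term"] - ph))
    for aa in _POSITIVE_SIDECHAINS:
        n = protein.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (ph - pka[aa]))
    for aa in _NEGATIVE_SIDECHAINS:
        n = protein.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (pka[aa] - ph))
    return charge


def isoelectric_point(protein: str, pka_set: str | Mapping[str, float] = "emboss") -> float:
    """pH at which the net charge is zero, found by bisection on [0, 14].

    Bisection continues until the bracketing interval is below 1e-6 pH units,
    which keeps the residual net charge at the returned pI well below 1e-3
    even for long, highly titratable proteins.
    """
    protein = _validate_protein(protein)
    lo, hi = 0.0, 14.0
    # net charge is monotone decreasing in pH
    if net_charge(protein, lo, pka_set) < 0:
        return lo
    if net_charge(protein, hi, pka_set) > 0:
        return hi
    while hi - lo > 1e-6:
        mid = 0.5 * (lo + hi)
        if net_charge(protein, mid, pka_set) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def count_crosslink_residues(protein: str) -> tuple[int, int]:
    """Counts of glutamine (Q) and lysine (K), the transglutamination targets."""
    protein = _validate_protein(protein)
    return protein.count("Q"), protein.count("K")


def size_class(protein: str) -> str:
    """Length class: short (<70), typical_70_170, intermediate (171-300),
    long_gt300 (>300 residues)."""
    n = len(_validate_protein(protein))
    if n < 70:
        return "short"
    if n <= 170:
        return "typical_70_170"
    if n <= 300:
        return "intermediate"
    return "long_gt300"


@dataclass(frozen=True)
class CompositionThresholds:
    """Fraction cut-offs for compositional class labels."""

    gs_rich_min: float = 0.5
    c_rich_min: float = 0.15
    p_rich_min: float = 0.15
    q_rich_min: float = 0.15

    @classmethod
    def from_config(cls, cfg: PipelineConfig) -> "CompositionThresholds":
        return cls(cfg.gs_rich_min, cfg.c_rich_min, cfg.p_rich_min, cfg.q_rich_min)


@dataclass(frozen=True)
class CompositionProfile:
    """Composition, charge, and class summary of one protein."""

    protein_id: str
    length: int
    counts: Mapping[str, int]
    fractions: Mapping[str, float]
    gs_fraction: float
    q_count: int
    k_count: int
    pi: float
    size_class: str
    class_labels: frozenset[str]

    def fraction_vector(self) -> list[float]:
        """Composition fractions in canonical residue order (20-dim)."""
        return [self.fractions[aa] for aa in AA_ORDER]


def classify_composition(
    profile: CompositionProfile,
    thresholds: CompositionThresholds | None = None,
) -> frozenset[str]:
    """Assign compositional class labels (not mutually exclusive).

    GS_rich if the combined G+S fraction reaches the GS threshold; C_rich,
    P_rich, Q_rich if the single-residue fraction reaches its threshold.
    A profile matching no rule is labeled ``unclassified``.
    """
    t = thresholds or CompositionThresholds()
    labels = set()
    if profile.gs_fraction >= t.gs_rich_min:
        labels.add("GS_rich")
    if profile.fractions["C"] >= t.c_rich_min:
        labels.add("C_rich")
    if profile.fractions["P"] >= t.p_rich_min:
        labels.add("P_rich")
    if profile.fractions["Q"] >= t.q_rich_min:
        labels.add("Q_rich")
    if not labels:
        labels.add("unclassified")
    return frozenset(labels)


def composition_profile(
    protein: str,
    protein_id: str = "protein",
    thresholds: CompositionThresholds | None = None,
    pka_set: str | Mapping[str, float] = "emboss",
) -> CompositionProfile:
    """Exact residue counting plus derived per-protein features."""
    protein = _validate_protein(protein)
    length = len(protein)
    counts = {aa: protein.count(aa) for aa in AA_ORDER}
    fractions = {aa: counts[aa] / length for aa in AA_ORDER}
    gs_fraction = fractions["G"] + fractions["S"]
    q_count, k_count = counts["Q"], counts["K"]
    pi = isoelectric_point(protein, pka_set)
    sclass = size_class(protein)
    profile = CompositionProfile(
        protein_id=protein_id,
        length=length,
        counts=counts,
        fractions=fractions,
        gs_fraction=gs_fraction,
        q_count=q_count,
        k_count=k_count,
        pi=pi,
        size_class=sclass,
        class_labels=frozenset(),
    )
    labels = classify_composition(profile, thresholds)
    return CompositionProfile(
        protein_id=protein_id,
        length=length,
        counts=counts,
        fractions=fractions,
        gs_fraction=gs_fraction,
        q_count=q_count,
        k_count=k_count,
        pi=pi,
        size_class=sclass,
        class_labels=labels,
    )
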