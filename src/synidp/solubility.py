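"""Sequence-based solubility prediction for repeat-protein tags.

Two predictors are provided.

*Mean Urry hydropathy.*  The Urry scale ranks residues by the inverse
phase-transition temperature of elastin-like (VPGXG)n polypeptides carrying
that residue as guest: strongly hydrophobic residues (W, Y, F) have very low
values, hydrophilic and charged residues high ones.  Averaging the
per-residue values over a tag gives a hydropathy score; an integer threshold
separating experimentally insoluble from soluble tags can be fitted with
:func:`separation_threshold`.  Because the published per-residue table has
several normalizations in circulation, the scale is injectable and no
absolute threshold is hard-coded.

*Wilkinson-Harrison canonical variable.*  A two-feature composite of
turn-forming residue fraction (N, G, P, S) and absolute deviation of the
mean residue charge from 0.03, mapped through a quadratic to a probability
of soluble expression in E. coli.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio.SeqUtils import molecular_weight

STANDARD_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

# Urry guest-residue hydrophobicity values (inverse transition temperature
# ordering of (VPGXG)n hosts, degrees C at reference conditions).  Injectable:
# any residue->value map with all 20 residues may be passed instead.
URRY_SCALE: dict[str, float] = {
    "W": -90.0, "Y": -55.0, "F": -30.0, "H": -10.0, "P": -8.0,
    "L": 5.0, "I": 10.0, "M": 20.0, "V": 24.0, "C": 30.0,
    "A": 45.0, "T": 50.0, "N": 50.0, "S": 50.0, "G": 55.0,
    "R": 60.0, "Q": 60.0, "K": 120.0, "D": 170.0, "E": 250.0,
}


@dataclass(frozen=True)
class HydropathyScale:
    name: str
    values: dict[str, float] = field(default_factory=lambda: dict(URRY_SCALE))

    def __post_init__(self) -> None:
        missing = STANDARD_RESIDUES - set(self.values)
        if missing:
            raise ValueError(f"scale {self.name!r} missing residues {sorted(missing)}")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise ValueError("scale values must be finite")


URRY = HydropathyScale(name="urry", values=dict(URRY_SCALE))


@dataclass(frozen=True)
class SolubilityThresholds:
    """Integer hydropathy cutoffs for tags alone and fused to a cargo."""

    standalone: int = 42
    fusion: int = 47

    def __post_init__(self) -> None:
        if self.fusion < self.standalone:
            raise ValueError("fusion threshold must be >= standalone threshold")


@dataclass(frozen=True)
class ConstructSpec:
    """A tag expression construct: leader + repeats + TEV/His6 tail."""

    unit: str                      # hexapeptide in GXXXXP phase, e.g. GQSGLP
    n_repeats: int = 24
    leader: str = "MSKGP"
    tail: str = "GENLYFQGHHHHHHG"
    cargo: str = ""

    def __post_init__(self) -> None:
        if self.n_repeats < 0:
            raise ValueError("n_repeats must be >= 0")


def assemble_construct(spec: ConstructSpec) -> str:
    """Leader + unit*n + tail (+ cargo), in order.

    The leader ends in P, so writing the repeats in GXXXXP phase after the
    leader is identical to writing MSKG + (PGXXXX)n + P + tail.
    """
    return spec.leader + spec.unit * spec.n_repeats + spec.tail + spec.cargo


def _check_sequence(seq: str) -> None:
    if not seq:
        raise ValueError("empty sequence")
    bad = set(seq) - STANDARD_RESIDUES
    if bad:
        raise ValueError(f"unknown residues {sorted(bad)}")


def mean_hydropathy(seq: str, scale: HydropathyScale = URRY) -> float:
    """Arithmetic mean of per-residue scale values (order-invariant)."""
    _check_sequence(seq)
    return float(np.mean([scale.values[r] for r in seq]))


def separation_threshold(scores, labels) -> int | None:
    """Smallest integer t with every insoluble score < t and soluble > t.

    ``labels`` are truthy for soluble.  Returns None when the class ranges
    overlap (no strictly separating integer exists).
    """
    scores = list(scores)
    labels = list(labels)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    sol = [s for s, l in zip(scores, labels) if l]
    insol = [s for s, l in zip(scores, labels) if not l]
    if not sol or not insol:
        raise ValueError("need at least one score per class")
    lo, hi = max(insol), min(sol)
    t = int(np.floor(lo)) + 1
    if lo < t < hi:
        return t
    return None


def classify_solubility(score: float, context: str = "standalone",
                        thresholds: SolubilityThresholds | None = None) -> str:
    """'soluble' above the context threshold, 'insoluble' below,
    'indeterminate' exactly on it."""
    th = thresholds or SolubilityThresholds()
    cutoff = {"standalone": th.standalone, "fusion": th.fusion}[context]
    if score > cutoff:
        return "soluble"
    if score < cutoff:
        return "insoluble"
    return "indeterminate"


@dataclass(frozen=True)
class WHModelParams:
    """Constants of the Wilkinson-Harrison canonical-variable model."""

    lambda_turn: float = 15.43
    lambda_charge: float = -29.56
    charge_offset: float = 0.03
    cv_prime: float = 1.71
    poly: tuple[float, float, float] = (0.4934, 0.276, 0.0392)
    half_weight_his: bool = False
    turn_formers: frozenset[str] = frozenset("NGPS")


def net_charge(seq: str, half_weight_his: bool = False) -> float:
    """Integer-charge model at neutral pH: +1 K/R, -1 D/E, optional +0.5 H."""
    _check_sequence(seq)
    charge = sum(seq.count(r) for r in "KR") - sum(seq.count(r) for r in "DE")
    if half_weight_his:
        charge += 0.5 * seq.count("H")
    return float(charge)


def wilkinson_harrison(seq: str, params: WHModelParams | None = None) -> dict:
    """Canonical variable CV, its excess over CV', class and probability.

    CV = l1 * (turn-former fraction) + l2 * |mean residue charge - 0.03|;
    insoluble iff CV - CV' > 0; the probability of the predicted class is
    clip(a + b|CV-CV'| - c(CV-CV')^2, 0, 1), which equals a = 0.4934 at the
    CV = CV' boundary.
    """
    p = params or WHModelParams()
    _check_sequence(seq)
    n = len(seq)
    turn_fraction = sum(seq.count(r) for r in p.turn_formers) / n
    mean_charge = net_charge(seq, p.half_weight_his) / n
    cv = (p.lambda_turn * turn_fraction
          + p.lambda_charge * abs(mean_charge - p.charge_offset))
    dcv = cv - p.cv_prime
    a, b, c = p.poly
    prob = float(np.clip(a + b * abs(dcv) - c * dcv ** 2, 0.0, 1.0))
    label = "insoluble" if dcv > 0 else "soluble" if dcv < 0 else "boundary"
    return {"CV": cv, "CV_minus_CVprime": dcv, "class": label,
            "probability": prob}


def composition_report(seq: str, half_weight_his: bool = False) -> dict:
    """Residue-composition summary relevant to tag solubility."""
    _check_sequence(seq)
    n = len(seq)
    aromatics = sum(seq.count(r) for r in "FYW")
    positives = sum(seq.count(r) for r in "KR") + (
        seq.count("H") if half_weight_his else 0)
    return {
        "length": n,
        "fraction_P": seq.count("P") / n,
        "fraction_G": seq.count("G") / n,
        "fraction_aromatic": aromatics / n,
        "fraction_positive": positives / n,
        "net_charge": net_charge(seq, half_weight_his),
    }


def average_mass(seq: str, monoisotopic: bool = False) -> float:
    """Protein mass in Da (average by default), including one water."""
    _check_sequence(seq)
    return float(molecular_weight(seq, seq_type="protein",
                                  monoisotopic=monoisotopic))
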