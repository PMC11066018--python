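"""Rolling-circle amplification and methylation-protected digestion model.

Phi29 RCA around a circular 72-nt template produces a tandem-repeat
concatemer with one SexAI site per repeat junction.  Substituting a fraction
``f_mC`` of dCTP with 5-methyl-dCTP during synthesis randomly methylates the
dcm-context cytosines of each CCWGG core; a site with any of its
``c_blocking`` relevant cytosines methylated resists cleavage.  Sites are
therefore protected independently with probability

    q = 1 - (1 - f_mC) ** c_blocking

and complete digestion cuts at every unprotected site, so internal fragment
lengths (in repeat units) follow a geometric law P(L = k) = q**(k-1) (1 - q)
with mean 1/(1 - q).  With the bench condition f_mC = 0.25 and c_blocking =
4 this gives q ~ 0.68 and a mean spacing of about three to four repeats,
i.e. a methyl block roughly every four repeats.

Fragments are measured in base pairs (one repeat = 72 bp); a gel size window
of 360-576 bp retains 5-8 repeat units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

UNIT_LEN = 72  # bp per repeat


@dataclass(frozen=True)
class ProtectionModel:
    """Per-site methylation protection of restriction sites."""

    f_mC: float = 0.25
    c_blocking: int = 4

    def __post_init__(self) -> None:
        if not 0.0 <= self.f_mC <= 1.0:
            raise ValueError("f_mC must lie in [0, 1]")
        if self.c_blocking < 0:
            raise ValueError("c_blocking must be >= 0")

    @property
    def q(self) -> float:
        return protection_probability(self.f_mC, self.c_blocking)


# Fig-1-style preset: 10% 5mCTP substitution (the Methods use 25%).
FIG1_MODEL = ProtectionModel(f_mC=0.10, c_blocking=4)


def protection_probability(f_mC: float, c_blocking: int) -> float:
    """q = 1 - (1 - f_mC)^c_blocking: chance a site carries >=1 methyl-C."""
    if not 0.0 <= f_mC <= 1.0:
        raise ValueError("f_mC must lie in [0, 1]")
    if c_blocking < 0:
        raise ValueError("c_blocking must be >= 0")
    return 1.0 - (1.0 - f_mC) ** c_blocking


@dataclass
class Concatemer:
    """A linear RCA product: n_units repeats with a site at every junction."""

    n_units: int
    unit_len: int = UNIT_LEN
    methylation_mask: np.ndarray | None = None  # True = protected

    @property
    def n_sites(self) -> int:
        return max(self.n_units - 1, 0)


@dataclass
class DigestResult:
    """Fragment lengths (bp) from one simulated digestion."""

    internal: np.ndarray        # complete repeat-bounded fragments
    terminal: np.ndarray        # the two concatemer-end fragments
    unit_len: int = UNIT_LEN

    @property
    def all_fragments(self) -> np.ndarray:
        return np.concatenate([self.internal, self.terminal])


def simulate_concatemer(n_units: int, model: ProtectionModel,
                        rng: np.random.Generator) -> Concatemer:
    if n_units < 1:
        raise ValueError("n_units must be >= 1")
    mask = rng.random(max(n_units - 1, 0)) < model.q
    return Concatemer(n_units=n_units, methylation_mask=mask)


def simulate_digest(n_units: int, model: ProtectionModel, seed: int | None = None,
                    unit_len: int = UNIT_LEN,
                    rng: np.random.Generator | None = None) -> DigestResult:
    """Digest a simulated concatemer at every unprotected junction site.

    All fragments are multiples of ``unit_len``; the first and last fragment
    of the linear concatemer are reported separately (``terminal``) because
    their lengths are censored by the molecule ends rather than by two cuts,
    so they do not follow the geometric law.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    conc = simulate_concatemer(n_units, model, rng)
    cut_sites = np.flatnonzero(~conc.methylation_mask) + 1  # in repeat units
    bounds = np.concatenate([[0], cut_sites, [n_units]])
    lengths = np.diff(bounds) * unit_len
    if len(lengths) == 1:  # no cuts: single fragment, wholly terminal
        return DigestResult(internal=np.empty(0, dtype=int), terminal=lengths,
                            unit_len=unit_len)
    return DigestResult(internal=lengths[1:-1], terminal=lengths[[0, -1]],
                        unit_len=unit_len)


@dataclass(frozen=True)
class FragmentDistribution:
    """Geometric law for complete-fragment lengths in repeat units."""

    q: float
    k_max: int = 50

    def __post_init__(self) -> None:
        if not 0.0 <= self.q < 1.0:
            raise ValueError("q must lie in [0, 1); q = 1 leaves the product uncut")

    @property
    def mean(self) -> float:
        return 1.0 / (1.0 - self.q)

    def pmf(self, k) -> np.ndarray:
        """P(L = k) = q^(k-1) (1-q) for k >= 1 repeat units."""
        return stats.geom.pmf(k, 1.0 - self.q)

    def pmf_table(self) -> np.ndarray:
        return self.pmf(np.arange(1, self.k_max + 1))


def fragment_length_pmf(q: float, k_max: int = 50) -> FragmentDistribution:
    return FragmentDistribution(q=q, k_max=k_max)


@dataclass
class SizeSelection:
    retained: np.ndarray
    count_fraction: float
    mass_fraction: float


def size_select(fragments, lo: int = 360, hi: int = 576) -> SizeSelection:
    """Gel-window selection: keep lo <= length <= hi (bp)."""
    if lo > hi:
        raise ValueError("lo must be <= hi")
    frags = np.asarray(fragments)
    if frags.size == 0:
        return SizeSelection(retained=frags, count_fraction=0.0, mass_fraction=0.0)
    keep = (frags >= lo) & (frags <= hi)
    total_mass = frags.sum()
    return SizeSelection(
        retained=frags[keep],
        count_fraction=keep.mean(),
        mass_fraction=float(frags[keep].sum() / total_mass) if total_mass else 0.0,
    )


def window_number_fraction(q: float, k_lo: int, k_hi: int | None) -> float:
    """P(k_lo <= L <= k_hi) = q^(k_lo - 1) - q^k_hi under the geometric law."""
    if k_hi is None:
        return q ** (k_lo - 1)
    return q ** (k_lo - 1) - q ** k_hi


def optimize_protection(k_lo: int = 5, k_hi: int | None = 8,
                        c_blocking: int = 4) -> dict:
    """Protection probability maximizing the in-window number fraction.

    Maximizes f(q) = q^(k_lo-1) - q^k_hi.  Setting f'(q) = 0 gives the
    closed form q* = ((k_lo - 1) / k_hi) ** (1 / (k_hi - k_lo + 1)); the
    window [5, 8] yields q* = 2^(-1/4) with a retained fraction of 1/4.
    Also reports the methyl fraction realizing q* for ``c_blocking``
    relevant cytosines per site.
    """
    if k_lo < 1 or (k_hi is not None and k_hi < k_lo):
        raise ValueError("require 1 <= k_lo <= k_hi")
    if k_lo == 1:
        # every chain length >= 1 is in-window at any q once k_hi = inf;
        # with finite k_hi the maximand 1 - q^k_hi is maximized at q = 0.
        q_star = 0.0
    else:
        if k_hi is None:
            q_star = 1.0  # degenerate: push all mass to long fragments
        else:
            q_star = ((k_lo - 1) / k_hi) ** (1.0 / (k_hi - k_lo + 1))
    max_fraction = window_number_fraction(q_star, k_lo, k_hi) if q_star < 1 else 0.0
    f_mC = 1.0 - (1.0 - q_star) ** (1.0 / c_blocking) if c_blocking else math.nan
    return {"q_star": q_star, "max_fraction": max_fraction, "f_mC": f_mC,
            "window": (k_lo, k_hi)}


def fragments_to_sequences(design_nt: str, digest: DigestResult) -> list[str]:
    """Nucleotide sequences of complete fragments for a given 72-nt design."""
    unit = design_nt
    out = []
    for length in digest.internal:
        k = int(length) // len(unit)
        out.append(unit * k)
    return out
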