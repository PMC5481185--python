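"""Thermodynamic model of transcription initiation under binding-site competition.

A promoter is bound by an RNAP-like activator or a repressor, which compete
for a single (overlapping) site. With Boltzmann weights 1 (empty),
``B = [P] e^{-beta E_P}`` (RNAP bound) and ``A = [R] e^{-beta E_R}``
(repressor bound), the probability of a transcription-competent
configuration is

    p_ON = B / (1 + A + B)

Point mutations perturb the binding energies additively: a mutation with
effect ``(p, r)`` shifts E_P by ``p`` and E_R by ``r`` (positive = weaker
binding), and double-mutant energies are the sums of the single-mutant
perturbations. Epistasis on the multiplicative scale is

    eps = (p_ON^WT * p_ON^m12) / (p_ON^m1 * p_ON^m2)

which has the closed form

    eps = (1 + A e^{-r1} + B e^{-p1}) (1 + A e^{-r2} + B e^{-p2})
          / ((1 + A + B) (1 + A e^{-r1-r2} + B e^{-p1-p2}))

All arithmetic is carried out in log space so that effects of tens of kT
and activities spanning many decades do not overflow. Energies are in
natural units (kT, beta = 1).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np

__all__ = [
    "ThermoParams",
    "MutationEffect",
    "EpistasisSign",
    "SignTrajectory",
    "SignTrajectoryResult",
    "UnclassifiedSignSequenceError",
    "p_on",
    "log_epistasis",
    "thermo_epistasis",
    "sign_no_repressor",
    "sign_at_concentration",
    "sign_trajectory",
    "derive_sign_table",
    "default_r_grid",
]

_LOG_EPS_TOL_DEFAULT = 1e-9


def _require_finite(name: str, *values: float) -> None:
    for v in values:
        if not math.isfinite(v):
            raise ValueError(f"{name} must be finite, got {v!r}")


@dataclass(frozen=True)
class ThermoParams:
    """Binding energies and activities of the two competing proteins.

    E_P, E_R : binding free energies of RNAP and repressor (kT).
    P, R     : dimensionless activities (exponential of the chemical
               potential, treated as concentrations), both >= 0.
    beta     : inverse temperature; fixed at 1 (natural units).
    """

    E_P: float
    E_R: float
    P: float
    R: float
    beta: float = 1.0

    def __post_init__(self) -> None:
        _require_finite("E_P", self.E_P)
        _require_finite("E_R", self.E_R)
        _require_finite("P", self.P)
        _require_finite("R", self.R)
        if self.P < 0:
            raise ValueError(f"P must be >= 0, got {self.P}")
        if self.R < 0:
            raise ValueError(f"R must be >= 0, got {self.R}")
        if self.beta != 1.0:
            raise ValueError("beta is fixed at 1 (energies in kT)")

    @property
    def log_A(self) -> float:
        """log of the repressor Boltzmann weight A = R e^{-beta E_R}."""
        return -np.inf if self.R == 0 else math.log(self.R) - self.beta * self.E_R

    @property
    def log_B(self) -> float:
        """log of the RNAP Boltzmann weight B = P e^{-beta E_P}."""
        return -np.inf if self.P == 0 else math.log(self.P) - self.beta * self.E_P

    @property
    def A(self) -> float:
        return math.exp(self.log_A) if math.isfinite(self.log_A) else 0.0

    @property
    def B(self) -> float:
        return math.exp(self.log_B) if math.isfinite(self.log_B) else 0.0

    def with_R(self, R: float) -> "ThermoParams":
        return ThermoParams(self.E_P, self.E_R, self.P, R, self.beta)


@dataclass(frozen=True)
class MutationEffect:
    """Energetic perturbation of one mutation: ``p`` on RNAP binding,
    ``r`` on repressor binding (kT; positive = weaker binding)."""

    p: float
    r: float

    def __post_init__(self) -> None:
        _require_finite("p", self.p)
        _require_finite("r", self.r)

    def __add__(self, other: "MutationEffect") -> "MutationEffect":
        return MutationEffect(self.p + other.p, self.r + other.r)


NEUTRAL = MutationEffect(0.0, 0.0)


class EpistasisSign(Enum):
    POSITIVE = "positive"
    NEGATIVE = "negative"
    NONE = "none"


class SignTrajectory(Enum):
    """How the sign of epistasis behaves as repressor activity sweeps 0 -> inf."""

    ALWAYS_POSITIVE = "always_positive"
    ALWAYS_NEGATIVE = "always_negative"
    NEG_TO_POS = "neg_to_pos"
    POS_TO_NEG = "pos_to_neg"
    ZERO_THEN_POS = "zero_then_pos"
    ZERO_THEN_NEG = "zero_then_neg"
    NO_EPISTASIS = "no_epistasis"


class UnclassifiedSignSequenceError(ValueError):
    """A collapsed sign sequence that maps to no trajectory category."""

    def __init__(self, sequence: Sequence[EpistasisSign]):
        self.sequence = tuple(sequence)
        super().__init__(
            "sign sequence does not match any trajectory category: "
            + " -> ".join(s.value for s in self.sequence)
        )


@dataclass(frozen=True)
class SignTrajectoryResult:
    category: SignTrajectory
    breakpoints: tuple[float, ...]
    signs: tuple[EpistasisSign, ...]  # collapsed sequence along the sweep

    def __post_init__(self) -> None:
        if any(b2 <= b1 for b1, b2 in zip(self.breakpoints, self.breakpoints[1:])):
            raise ValueError("breakpoints must be strictly increasing")


# ---------------------------------------------------------------------------
# Core occupancy / epistasis arithmetic (log space throughout)

def _log_partition(log_A: float, log_B: float, p: float, r: float) -> float:
    """log(1 + A e^{-r} + B e^{-p}), safe for A or B equal to zero."""
    return np.logaddexp(0.0, np.logaddexp(log_A - r, log_B - p))


def p_on(params: ThermoParams, effect: MutationEffect = NEUTRAL) -> float:
    """Probability of the transcription-competent configuration.

    Returns B e^{-p} / (1 + A e^{-r} + B e^{-p}); strictly decreasing in
    ``p`` and (for A > 0) strictly increasing in ``r``.
    """
    log_num = params.log_B - effect.p
    if log_num == -np.inf:  # no polymerase, no transcription
        return 0.0
    return float(math.exp(log_num - _log_partition(params.log_A, params.log_B, effect.p, effect.r)))


def log_epistasis(params: ThermoParams, m1: MutationEffect, m2: MutationEffect) -> float:
    """log of eps = p_ON^WT p_ON^m12 / (p_ON^m1 p_ON^m2).

    The B e^{-p} numerators cancel exactly, leaving a combination of the
    four log partition functions. Requires B > 0 (otherwise all p_ON
    vanish and epistasis is undefined).
    """
    if params.P == 0:
        raise ValueError("epistasis is undefined when the RNAP activity P is 0 (p_ON = 0)")
    lA, lB = params.log_A, params.log_B
    return float(
        _log_partition(lA, lB, m1.p, m1.r)
        + _log_partition(lA, lB, m2.p, m2.r)
        - _log_partition(lA, lB, 0.0, 0.0)
        - _log_partition(lA, lB, m1.p + m2.p, m1.r + m2.r)
    )


def thermo_epistasis(params: ThermoParams, m1: MutationEffect, m2: MutationEffect) -> float:
    """Multiplicative epistasis eps between two mutation effects (symmetric in m1, m2)."""
    return float(math.exp(log_epistasis(params, m1, m2)))


def log_epistasis_array(
    log_A: np.ndarray | float,
    log_B: np.ndarray | float,
    p1: np.ndarray | float,
    r1: np.ndarray | float,
    p2: np.ndarray | float,
    r2: np.ndarray | float,
) -> np.ndarray:
    """Vectorised ``log_epistasis`` over broadcastable arrays (log activities)."""
    def L(p, r):
        return np.logaddexp(0.0, np.logaddexp(log_A - r, log_B - p))

    return L(p1, r1) + L(p2, r2) - L(0.0, 0.0) - L(p1 + p2, r1 + r2)


# ---------------------------------------------------------------------------
# Sign analysis

def _sign_of(x: float) -> int:
    return (x > 0) - (x < 0)


def sign_no_repressor(p1: float, p2: float) -> EpistasisSign:
    """Sign of epistasis in the repressor-free limit (A = 0).

    Expanding eps - 1 at A = 0 gives sign(eps - 1) =
    -sign((1 - e^{-p1})(1 - e^{-p2})) for every B > 0: same-sign effects
    are always in negative epistasis, opposite-sign effects in positive
    epistasis, and a neutral effect on RNAP gives none.
    """
    _require_finite("p1", p1)
    _require_finite("p2", p2)
    s1, s2 = _sign_of(p1), _sign_of(p2)
    if s1 == 0 or s2 == 0:
        return EpistasisSign.NONE
    return EpistasisSign.NEGATIVE if s1 == s2 else EpistasisSign.POSITIVE


def sign_at_concentration(
    params: ThermoParams,
    m1: MutationEffect,
    m2: MutationEffect,
    tol: float = _LOG_EPS_TOL_DEFAULT,
) -> EpistasisSign:
    """Thresholded sign of epistasis: POSITIVE if eps > 1+tol, NEGATIVE if eps < 1-tol."""
    if tol <= 0:
        raise ValueError("tol must be > 0")
    le = log_epistasis(params, m1, m2)
    if le > math.log1p(tol):
        return EpistasisSign.POSITIVE
    if le < math.log1p(-tol):
        return EpistasisSign.NEGATIVE
    return EpistasisSign.NONE


def default_r_grid(E_R: float, decades: float = 12.0, points: int = 241) -> np.ndarray:
    """R = 0 plus log-spaced activities over [1e-decades, 1e+decades] * e^{E_R}.

    Centred on e^{E_R} so the repressor weight A sweeps the same decades
    regardless of the baseline energy.
    """
    return np.concatenate(
        [[0.0], np.logspace(-decades, decades, points) * math.exp(E_R)]
    )


_SEQUENCE_TO_CATEGORY = {
    (EpistasisSign.NEGATIVE,): SignTrajectory.ALWAYS_NEGATIVE,
    (EpistasisSign.POSITIVE,): SignTrajectory.ALWAYS_POSITIVE,
    (EpistasisSign.NEGATIVE, EpistasisSign.POSITIVE): SignTrajectory.NEG_TO_POS,
    (EpistasisSign.POSITIVE, EpistasisSign.NEGATIVE): SignTrajectory.POS_TO_NEG,
    (EpistasisSign.NONE, EpistasisSign.POSITIVE): SignTrajectory.ZERO_THEN_POS,
    (EpistasisSign.NONE, EpistasisSign.NEGATIVE): SignTrajectory.ZERO_THEN_NEG,
}


def _classify_sequence(signs: tuple[EpistasisSign, ...]) -> SignTrajectory:
    if all(s is EpistasisSign.NONE for s in signs):
        return SignTrajectory.NO_EPISTASIS
    # eps -> 1 as R -> inf, so a trailing NONE is the universal asymptote,
    # not a sign change; strip it before matching.
    core = signs[:-1] if signs[-1] is EpistasisSign.NONE else signs
    try:
        return _SEQUENCE_TO_CATEGORY[core]
    except KeyError:
        raise UnclassifiedSignSequenceError(signs) from None


def _refine_breakpoint(
    params0: ThermoParams,
    m1: MutationEffect,
    m2: MutationEffect,
    lo: float,
    hi: float,
    sign_lo: EpistasisSign,
    tol: float,
    rel_precision: float = 1e-6,
) -> float:
    """Bisect [lo, hi] for the R where the sign stops being ``sign_lo``."""
    for _ in range(200):
        if lo > 0 and (hi - lo) <= rel_precision * lo:
            break
        if lo == 0 and hi <= rel_precision:
            break
        mid = math.sqrt(lo * hi) if lo > 0 else 0.5 * (lo + hi)
        if sign_at_concentration(params0.with_R(mid), m1, m2, tol) is sign_lo:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def sign_trajectory(
    E_P: float,
    E_R: float,
    P: float,
    m1: MutationEffect,
    m2: MutationEffect,
    R_grid: np.ndarray | None = None,
    tol: float = _LOG_EPS_TOL_DEFAULT,
) -> SignTrajectoryResult:
    """Category of sign-of-epistasis behaviour across a repressor sweep.

    Evaluates the thresholded sign along ``R_grid`` (default: R = 0 plus 241
    log-spaced activities over 24 decades around e^{E_R}), collapses
    consecutive duplicates, locates each sign change by bisection to
    relative precision 1e-6, and maps the sequence to a category. A
    sequence matching no category raises
    :class:`UnclassifiedSignSequenceError` (never silently coerced).
    """
    if R_grid is None:
        R_grid = default_r_grid(E_R)
    R_grid = np.asarray(R_grid, dtype=float)
    if R_grid.size < 2 or R_grid[0] != 0.0:
        raise ValueError("R_grid must start at 0 and contain at least two points")
    base = ThermoParams(E_P, E_R, P, 0.0)

    signs: list[EpistasisSign] = []
    change_intervals: list[tuple[float, float, EpistasisSign]] = []
    prev_R = None
    for R in R_grid:
        s = sign_at_concentration(base.with_R(float(R)), m1, m2, tol)
        if not signs:
            signs.append(s)
        elif s is not signs[-1]:
            change_intervals.append((prev_R, float(R), signs[-1]))
            signs.append(s)
        prev_R = float(R)

    breakpoints = tuple(
        _refine_breakpoint(base, m1, m2, lo, hi, s_lo, tol)
        for lo, hi, s_lo in change_intervals
    )
    category = _classify_sequence(tuple(signs))
    return SignTrajectoryResult(category, breakpoints, tuple(signs))


# ---------------------------------------------------------------------------
# Sign table across all combinations of single-mutation effect signs

SignPair = tuple[int, int]  # (sign of p, sign of r), each in {-1, 0, +1}


def derive_sign_table(
    magnitude: float = 1.0,
    E_P: float = 0.0,
    E_R: float = 0.0,
    P: float = 1.0,
    dominance_ratio: float = 0.5,
    tol: float = _LOG_EPS_TOL_DEFAULT,
    R_grid: np.ndarray | None = None,
) -> dict[tuple[SignPair, SignPair], SignTrajectoryResult]:
    """Trajectory category for every combination of single-effect signs.

    Each cell is evaluated on a representative pair of mutations in which
    the two members differ in their relative impact on the two proteins:
    the lexicographically first sign pair is realised RNAP-dominantly
    (|p| = magnitude, |r| = magnitude * dominance_ratio) and the second
    repressor-dominantly (|p| = magnitude * dominance_ratio,
    |r| = magnitude). This is the generic situation for two random point
    mutations in overlapping sites; a pair with *identical* relative
    effects provably never changes sign (the cross term
    -A*B*(e^{-p1}-e^{-r1})(e^{-p2}-e^{-r2}) of eps-1 vanishes or is
    negative), so equal magnitudes would hide every transition. The table
    is symmetric under swapping the two mutations by construction.
    """
    if magnitude <= 0:
        raise ValueError("magnitude must be > 0")
    if not 0 < dominance_ratio <= 1:
        raise ValueError("dominance_ratio must be in (0, 1]")
    if R_grid is None:
        R_grid = default_r_grid(E_R)

    signs = (-1, 0, 1)
    table: dict[tuple[SignPair, SignPair], SignTrajectoryResult] = {}
    cache: dict[tuple[SignPair, SignPair], SignTrajectoryResult] = {}
    for sp1 in signs:
        for sr1 in signs:
            for sp2 in signs:
                for sr2 in signs:
                    key = ((sp1, sr1), (sp2, sr2))
                    a, b = sorted(key)
                    canon = (a, b)
                    if canon not in cache:
                        m1 = MutationEffect(a[0] * magnitude, a[1] * magnitude * dominance_ratio)
                        m2 = MutationEffect(b[0] * magnitude * dominance_ratio, b[1] * magnitude)
                        cache[canon] = sign_trajectory(E_P, E_R, P, m1, m2, R_grid, tol)
                    table[key] = cache[canon]
    return table
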