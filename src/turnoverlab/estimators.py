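"""Per-animal inversion of the turnover model: FSR, FBR, k_deg, k_syn, P_eq.

A single terminal time point gives three measurements per pool: the initial
pool-size proxy ``P0``, the terminal proxy ``P_t`` and the fraction new
``f = E(t)/E*``.  These identify the two kinetic parameters exactly, because
unlabelled ("old") protein decays first-order — its survivors at time t are
``P_t (1 - f) = P0 e^(-k_deg t)`` — giving

    k_deg = -(1/t) * ln[(1 - f) * (P_t / P0)]

and, substituting back into the mass closed form,

    P_eq  = (P_t - P0 e^(-k_deg t)) / (1 - e^(-k_deg t)),
    k_syn = k_deg * P_eq.

Rate conventions (percent per day):

    FSR_ss  = 100 * f / t                       steady-state fractional synthesis
    FSR_nss = (100/t) (1/P0) [P0 - P_t (1-f)]   non-steady-state, normalised to P0
    FBR     = 100 * k_deg                       fractional breakdown

Apparent negative degradation (the log argument above 1, e.g. a growing pool
whose unlabelled mass seems to rise) is clamped to ``k_deg = 0`` with an
explicit flag rather than raised: fully inhibited degradation is a real
outcome.  In that zero-degradation branch synthesis is estimated from the
labelled accrual, ``k_syn = f * P_t / t`` (exact when the true k_deg is 0),
and ``P_eq`` is undefined.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import FrozenSet

__all__ = [
    "GROUPS",
    "POOLS",
    "STEADY_ASSUMED",
    "KDEG_CLAMPED_ZERO",
    "FRACTION_EXCEEDS_ONE",
    "PEQ_NEGATIVE",
    "PoolObservation",
    "TurnoverResult",
    "fsr_steady",
    "kdeg_nonsteady",
    "peq_from_trajectory",
    "ksyn",
    "fsr_nonsteady",
    "fbr",
    "analyze_pool",
    "collagen_pool_mass",
]

GROUPS = ("denervated", "sham", "nonsurgical")
POOLS = ("myofibrillar", "collagen", "RNA", "DNA")

# validity flags carried on TurnoverResult
STEADY_ASSUMED = "steady_assumed"
KDEG_CLAMPED_ZERO = "kdeg_clamped_zero"
FRACTION_EXCEEDS_ONE = "fraction_exceeds_one"
PEQ_NEGATIVE = "peq_negative"

# log arguments this close to (or above) 1 are treated as the zero-degradation branch
_DEGENERATE_RTOL = 1e-12


@dataclass(frozen=True)
class PoolObservation:
    """One animal x one pool: size proxies, fraction new, labelling duration."""

    subject_id: str
    group: str
    pool: str
    p0: float
    p_t: float
    f: float
    t: float

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(f"group must be one of {GROUPS}, got {self.group!r}")
        if self.pool not in POOLS:
            raise ValueError(f"pool must be one of {POOLS}, got {self.pool!r}")
        if not (self.p0 > 0 and self.p_t > 0):
            raise ValueError("pool-size proxies must be positive")
        if not (self.t > 0):
            raise ValueError("labelling duration must be positive")
        if self.f < 0:
            raise ValueError("fraction new must be non-negative")


@dataclass(frozen=True)
class TurnoverResult:
    """All derived rates for one observation, with validity flags.

    Invariants: ``fbr == 100 * k_deg`` and ``k_syn == k_deg * p_eq`` exactly,
    except in flagged degenerate branches where ``p_eq`` is undefined.
    """

    subject_id: str
    group: str
    pool: str
    mode: str
    fsr_ss: float
    fsr_nss: float
    k_deg: float
    fbr: float
    p_eq: float
    k_syn: float
    flags: FrozenSet[str] = field(default_factory=frozenset)


def fsr_steady(f: float, t: float) -> float:
    """Steady-state fractional synthesis rate, 100*f/t (%/day)."""
    if t <= 0:
        raise ValueError("labelling duration must be positive")
    return 100.0 * f / t


def kdeg_nonsteady(f: float, p0: float, p_t: float, t: float):
    """Degradation constant from unlabelled-survivor decay; returns (k_deg, flags).

    ``k_deg = -(1/t) ln[(1-f)(P_t/P0)]``. If the argument is >= 1 (apparent
    negative degradation) the estimate is clamped to 0 and flagged
    ``kdeg_clamped_zero`` — unless the observation is trivially static
    (f = 0 and P_t = P0), where zero is exact and unremarkable. ``f >= 1``
    leaves no unlabelled survivors to date and yields NaN with the
    ``fraction_exceeds_one`` flag.
    """
    if t <= 0:
        raise ValueError("labelling duration must be positive")
    if f >= 1.0:
        return math.nan, frozenset({FRACTION_EXCEEDS_ONE})
    arg = (1.0 - f) * (p_t / p0)
    if arg >= 1.0 - _DEGENERATE_RTOL:
        if f == 0.0 and p_t == p0:
            return 0.0, frozenset()
        return 0.0, frozenset({KDEG_CLAMPED_ZERO})
    return -math.log(arg) / t, frozenset()


def peq_from_trajectory(p0: float, p_t: float, k_deg: float, t: float) -> float:
    """Equilibrium mass solved from the closed-form trajectory.

    ``P_eq = (P_t - P0 e^(-k_deg t)) / (1 - e^(-k_deg t))``; requires
    ``k_deg > 0`` (with no degradation the pool approaches no equilibrium).
    """
    if k_deg <= 0:
        raise ValueError("P_eq is undefined without degradation (k_deg must be > 0)")
    if t <= 0:
        raise ValueError("labelling duration must be positive")
    decay = math.exp(-k_deg * t)
    return (p_t - p0 * decay) / (1.0 - decay)


def ksyn(k_deg: float, p_eq: float) -> float:
    """Absolute synthesis rate k_syn = k_deg * P_eq (mass/day)."""
    return k_deg * p_eq


def fsr_nonsteady(f: float, p0: float, p_t: float, t: float) -> float:
    """Non-steady-state FSR, (100/t)(1/P0)[P0 - P_t(1-f)] (%/day).

    New mass made over the interval, normalised to the initial pool.
    Reduces to ``fsr_steady`` when ``P_t = P0`` (taken as an explicit branch
    so the algebraic identity holds exactly in floating point).
    """
    if t <= 0:
        raise ValueError("labelling duration must be positive")
    if p_t == p0:
        return fsr_steady(f, t)
    return (100.0 / t) * (p0 - p_t * (1.0 - f)) / p0


def fbr(k_deg: float) -> float:
    """Fractional breakdown rate, 100 * k_deg (%/day)."""
    return 100.0 * k_deg


def analyze_pool(obs: PoolObservation, mode: str = "nonsteady") -> TurnoverResult:
    """Full per-observation inversion.

    ``mode="steady"`` assumes the pool size did not change (``P_t := P0``;
    synthesis equals breakdown, so ``k_deg = -ln(1-f)/t``) and flags the
    assumption.  ``mode="nonsteady"`` runs the full inversion with the
    degenerate branches described in the module docstring.
    """
    if mode not in ("steady", "nonsteady"):
        raise ValueError(f"mode must be 'steady' or 'nonsteady', got {mode!r}")

    f, t, p0 = obs.f, obs.t, obs.p0
    p_t = p0 if mode == "steady" else obs.p_t
    fss = fsr_steady(f, t)
    flags = {STEADY_ASSUMED} if mode == "steady" else set()

    k_deg, kflags = kdeg_nonsteady(f, p0, p_t, t)
    flags |= kflags

    if FRACTION_EXCEEDS_ONE in flags:
        return TurnoverResult(
            obs.subject_id, obs.group, obs.pool, mode,
            fsr_ss=fss, fsr_nss=fsr_nonsteady(f, p0, p_t, t),
            k_deg=math.nan, fbr=math.nan, p_eq=math.nan, k_syn=math.nan,
            flags=frozenset(flags),
        )

    if k_deg == 0.0:
        # zero-degradation (linear) branch: synthesis from labelled accrual
        k_s = f * p_t / t
        p_eq = p0 if k_s == 0.0 else math.nan
    else:
        p_eq = peq_from_trajectory(p0, p_t, k_deg, t)
        if p_eq < 0:
            flags.add(PEQ_NEGATIVE)
        k_s = ksyn(k_deg, p_eq)

    return TurnoverResult(
        obs.subject_id, obs.group, obs.pool, mode,
        fsr_ss=fss,
        fsr_nss=fsr_nonsteady(f, p0, p_t, t),
        k_deg=k_deg,
        fbr=fbr(k_deg),
        p_eq=p_eq,
        k_syn=k_s,
        flags=frozenset(flags),
    )


def collagen_pool_mass(
    muscle_mass: float, hydroxyproline_conc: float, mode: str = "mass_scaled"
) -> float:
    """Collagen pool-size proxy from hydroxyproline.

    ``mode="mass_scaled"`` (default) returns muscle wet mass (mg) times
    hydroxyproline concentration (ug/mg), a ug-equivalent collagen mass;
    ``mode="concentration"`` returns the concentration alone (pool tracked
    per unit tissue).  Which proxy is appropriate depends on whether whole-
    muscle collagen or collagen density is the quantity of interest, so both
    are exposed.
    """
    if muscle_mass <= 0 or hydroxyproline_conc <= 0:
        raise ValueError("muscle mass and hydroxyproline concentration must be positive")
    if mode == "mass_scaled":
        return muscle_mass * hydroxyproline_conc
    if mode == "concentration":
        return hydroxyproline_conc
    raise ValueError(f"unknown collagen proxy mode: {mode!r}")
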