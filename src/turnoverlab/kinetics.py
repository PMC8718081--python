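"""Forward model of a protein pool under zero-order synthesis and first-order degradation.

The pool mass ``P(t)`` obeys

.. math:: \\frac{dP}{dt} = k_{syn} - k_{deg} \\, P(t)

where ``k_syn`` is an absolute synthesis rate (mass/day) and ``k_deg`` a
degradation rate constant (1/day).  The closed-form solution is

.. math:: P(t) = P_0 e^{-k_{deg} t} + P_{eq} (1 - e^{-k_{deg} t}),
          \\qquad P_{eq} = k_{syn} / k_{deg}.

Under a step label switched on at ``t = 0`` (a heavy-water bolus followed by
enriched drinking water, producing a body-water plateau), newly synthesised
protein is labelled and old protein decays first-order, so the labelled
("enriched") mass is

.. math:: M(t) = P_{eq} (1 - e^{-k_{deg} t}),

which notably does not depend on the initial mass ``P_0``.  The fraction of
the pool that is new, ``M(t)/P(t)``, is what a tracer experiment measures as
product enrichment over precursor enrichment.

``k_deg = 0`` is handled as an explicit degenerate branch (linear growth
``P(t) = P_0 + k_syn t``, ``M(t) = k_syn t``) rather than a numerical limit:
fully inhibited degradation is a physiologically reachable state (e.g. muscle
collagen after denervation), not an edge case.

All times are in days; rates are per day.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "KineticParams",
    "PoolTrajectory",
    "forward_mass",
    "forward_enriched_mass",
    "forward_fraction_new",
    "trajectory",
]

#: relative tolerance for the P_eq = k_syn / k_deg consistency check
_PEQ_RTOL = 1e-12


@dataclass(frozen=True)
class KineticParams:
    """Kinetic parameters of one protein pool.

    Parameters
    ----------
    k_syn : float
        Zero-order synthesis rate, mass-units/day. Non-negative.
    k_deg : float
        First-order degradation rate constant, 1/day. Non-negative.
    p0 : float
        Initial pool mass ``P(0)``, mass-units. Positive.
    p_eq : float, optional
        Equilibrium pool mass. If ``k_deg > 0`` it must equal
        ``k_syn / k_deg`` (checked to 1e-12 relative); left unset it is
        derived. With ``k_deg = 0`` the pool has no finite equilibrium
        unless ``k_syn = 0``, in which case ``p_eq = p0``.
    """

    k_syn: float
    k_deg: float
    p0: float
    p_eq: float = field(default=math.nan)

    def __post_init__(self) -> None:
        if not (self.k_syn >= 0):
            raise ValueError(f"k_syn must be >= 0, got {self.k_syn}")
        if not (self.k_deg >= 0):
            raise ValueError(f"k_deg must be >= 0, got {self.k_deg}")
        if not (self.p0 > 0):
            raise ValueError(f"p0 must be > 0, got {self.p0}")
        if self.k_deg > 0:
            implied = self.k_syn / self.k_deg
            if math.isnan(self.p_eq):
                object.__setattr__(self, "p_eq", implied)
            elif not math.isclose(self.p_eq, implied, rel_tol=_PEQ_RTOL, abs_tol=0.0):
                raise ValueError(
                    f"inconsistent parameters: p_eq={self.p_eq} but "
                    f"k_syn/k_deg={implied}"
                )
        else:
            implied = math.inf if self.k_syn > 0 else self.p0
            if math.isnan(self.p_eq):
                object.__setattr__(self, "p_eq", implied)
            elif self.p_eq != implied:
                raise ValueError(
                    "with k_deg=0 the pool has no finite equilibrium "
                    f"(expected p_eq={implied}, got {self.p_eq})"
                )

    @classmethod
    def from_equilibrium(cls, p0: float, k_deg: float, p_eq: float) -> "KineticParams":
        """Build parameters from ``(P0, k_deg, P_eq)``, deriving ``k_syn = k_deg * P_eq``."""
        if not (k_deg > 0):
            raise ValueError("from_equilibrium requires k_deg > 0")
        return cls(k_syn=k_deg * p_eq, k_deg=k_deg, p0=p0, p_eq=p_eq)


def _check_times(t):
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("negative times are not allowed")
    return t


def forward_mass(params: KineticParams, t):
    """Total pool mass ``P(t)``.

    ``P(t) = P0 e^(-k_deg t) + P_eq (1 - e^(-k_deg t))`` for ``k_deg > 0``;
    ``P0 + k_syn t`` when degradation is fully inhibited (``k_deg = 0``).
    Accepts a scalar or array of non-negative times (days).
    """
    t = _check_times(t)
    if params.k_deg == 0:
        out = params.p0 + params.k_syn * t
    else:
        decay = np.exp(-params.k_deg * t)
        out = params.p0 * decay + params.p_eq * (1.0 - decay)
    return out if out.ndim else float(out)


def forward_enriched_mass(params: KineticParams, t):
    """Labelled (newly synthesised) pool mass ``M(t)``, with ``M(0) = 0``.

    ``M(t) = P_eq (1 - e^(-k_deg t))`` for ``k_deg > 0`` — independent of
    ``P0`` — and ``k_syn t`` in the degenerate ``k_deg = 0`` branch. Assumes
    new protein is made fully labelled at the precursor enrichment from
    ``t = 0`` onwards (step label).
    """
    t = _check_times(t)
    if params.k_deg == 0:
        out = params.k_syn * t
    else:
        out = params.p_eq * (1.0 - np.exp(-params.k_deg * t))
    return out if out.ndim else float(out)


def forward_fraction_new(params: KineticParams, t):
    """Fraction of the pool that is newly synthesised, ``f(t) = M(t)/P(t)`` in [0, 1].

    This is the quantity a tracer experiment measures as product enrichment
    divided by precursor enrichment, ``E(t)/E*``.
    """
    return forward_enriched_mass(params, t) / forward_mass(params, t)


@dataclass(frozen=True)
class PoolTrajectory:
    """Sampled trajectory of one pool: P(t), M(t) and the fraction new."""

    times: np.ndarray
    total_mass: np.ndarray
    enriched_mass: np.ndarray
    fraction_new: np.ndarray

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        if times.size == 0:
            raise ValueError("trajectory needs at least one time point")
        if np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", times)


def trajectory(params: KineticParams, times) -> PoolTrajectory:
    """Evaluate the closed-form trajectory at strictly increasing times (days)."""
    times = np.atleast_1d(np.asarray(times, dtype=float))
    total = np.atleast_1d(forward_mass(params, times))
    enriched = np.atleast_1d(forward_enriched_mass(params, times))
    return PoolTrajectory(
        times=times,
        total_mass=total,
        enriched_mass=enriched,
        fraction_new=enriched / total,
    )
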