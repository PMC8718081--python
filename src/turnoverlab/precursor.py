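"""Precursor enrichment: body-water plateau and MIDA exchangeable-site adjustment.

Heavy-water labelling enriches the body water pool to a plateau (bolus +
enriched drinking water).  The deuterium then equilibrates onto the
exchangeable hydrogen positions of biosynthetic precursors — alanine for
proteins, purine ribose/deoxyribose for RNA/DNA — so the effective precursor
enrichment seen by mass spectrometry exceeds the body-water enrichment.

With ``n`` exchangeable sites each labelled independently with probability
``p_w`` (the body-water D2O mole fraction), the asymptotic excess singly
labelled (M+1) fraction is the binomial term

.. math:: E^* = \\binom{n}{1} p_w (1 - p_w)^{n-1}.

Inputs and outputs are *excess* enrichments: the natural-abundance baseline
is assumed subtracted upstream (the instrument-side correction), so ``E* = 0``
at ``p_w = 0``.

Default site counts follow common practice for D2O labelling: alanine 4,
ribose 5, deoxyribose 7; all are configurable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Union

import numpy as np

__all__ = [
    "DEFAULT_N_SITES",
    "BodyWaterSeries",
    "PrecursorModel",
    "plateau_body_water",
    "mida_precursor_enrichment",
    "fraction_new",
]

#: exchangeable-hydrogen site counts per analyte (configurable)
DEFAULT_N_SITES = {"alanine": 4, "ribose": 5, "deoxyribose": 7}

#: physiological ceiling on body-water D2O mole fraction
MAX_BODY_WATER = 0.2


@dataclass(frozen=True)
class BodyWaterSeries:
    """Plasma body-water D2O enrichment over time.

    ``times`` in days (non-negative, strictly increasing), ``enrichment`` as
    D2O mole fractions in [0, 0.2].  A single terminal sample is the common
    design; a series allows time-averaging.
    """

    times: np.ndarray
    enrichment: np.ndarray

    def __post_init__(self) -> None:
        times = np.atleast_1d(np.asarray(self.times, dtype=float))
        enr = np.atleast_1d(np.asarray(self.enrichment, dtype=float))
        if times.size == 0:
            raise ValueError("body-water series needs at least one sample")
        if times.shape != enr.shape:
            raise ValueError("times and enrichment must have the same length")
        if np.any(times < 0):
            raise ValueError("times must be non-negative")
        if times.size > 1 and np.any(np.diff(times) <= 0):
            raise ValueError("times must be strictly increasing")
        if np.any((enr < 0) | (enr > MAX_BODY_WATER)):
            raise ValueError(f"enrichment must lie in [0, {MAX_BODY_WATER}]")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "enrichment", enr)


def plateau_body_water(series: BodyWaterSeries, method: str = "last") -> float:
    """Collapse a body-water series to a scalar plateau enrichment.

    ``method="last"`` takes the terminal sample (the usual single
    end-of-study plasma distillation); ``method="time_weighted_mean"`` takes
    the trapezoidal time average over the sampled interval.
    """
    if method == "last":
        return float(series.enrichment[-1])
    if method == "time_weighted_mean":
        if series.times.size == 1:
            return float(series.enrichment[0])
        span = series.times[-1] - series.times[0]
        return float(np.trapezoid(series.enrichment, series.times) / span)
    raise ValueError(f"unknown plateau method: {method!r}")


def mida_precursor_enrichment(n_sites: int, p_w: float) -> float:
    """True precursor enrichment E* from body-water enrichment.

    Returns the excess M+1 fraction of an analyte with ``n_sites``
    exchangeable hydrogens, ``E* = n p_w (1 - p_w)^(n-1)``: the probability
    that exactly one site carries a deuterium when each is labelled
    independently at the body-water mole fraction. Strictly increasing in
    ``p_w`` while ``p_w < 1/n_sites``, which covers the physiological
    plateau range (a few percent) for all supported site counts.
    """
    if not (1 <= int(n_sites) <= 10) or int(n_sites) != n_sites:
        raise ValueError(f"n_sites must be an integer in [1, 10], got {n_sites}")
    if not (0 <= p_w <= MAX_BODY_WATER):
        raise ValueError(f"body-water enrichment {p_w} outside [0, {MAX_BODY_WATER}]")
    n = int(n_sites)
    return float(n * p_w * (1.0 - p_w) ** (n - 1))


@dataclass(frozen=True)
class PrecursorModel:
    """Analyte-specific precursor: exchangeable-site count plus body water.

    ``body_water`` may be a :class:`BodyWaterSeries` or a scalar plateau.
    """

    analyte: str
    body_water: Union[BodyWaterSeries, float]
    n_sites: int = 0
    plateau_method: str = "last"

    def __post_init__(self) -> None:
        if self.n_sites == 0:
            if self.analyte not in DEFAULT_N_SITES:
                raise ValueError(
                    f"unknown analyte {self.analyte!r}; supply n_sites explicitly"
                )
            object.__setattr__(self, "n_sites", DEFAULT_N_SITES[self.analyte])
        if not (1 <= self.n_sites <= 10):
            raise ValueError(f"n_sites must be in [1, 10], got {self.n_sites}")

    def plateau(self) -> float:
        if isinstance(self.body_water, BodyWaterSeries):
            return plateau_body_water(self.body_water, self.plateau_method)
        p_w = float(self.body_water)
        if not (0 <= p_w <= MAX_BODY_WATER):
            raise ValueError(f"body-water enrichment {p_w} outside [0, {MAX_BODY_WATER}]")
        return p_w

    def enrichment(self) -> float:
        """The precursor enrichment E* for this analyte."""
        return mida_precursor_enrichment(self.n_sites, self.plateau())


def fraction_new(e_t: float, e_star: float) -> float:
    """Fraction new ``f = E(t) / E*`` of a product pool.

    ``e_t`` is the product's excess enrichment over the labelling period and
    ``e_star`` the true precursor enrichment.  Values above 1 are physically
    impossible under the model and are returned unclipped with a warning so
    downstream code can flag them.
    """
    if e_star <= 0:
        raise ValueError("precursor enrichment must be positive")
    if e_t < 0:
        raise ValueError("product enrichment must be non-negative")
    f = e_t / e_star
    if f > 1:
        warnings.warn(
            f"fraction new {f:.4g} exceeds 1 (product more enriched than precursor)",
            stacklevel=2,
        )
    return f
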