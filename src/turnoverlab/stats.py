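"""Group-level statistics: normality screen, t tests, correlation, ROUT outliers.

The statistical layer mirrors a conventional small-animal turnover analysis:
Kolmogorov-Smirnov normality screening (advisory), paired two-tailed t tests
for within-animal limb contrasts, unpaired t for between-group contrasts,
Pearson correlation, ROUT outlier removal, and mean +/- SEM summaries.

ROUT was published for robust nonlinear regression; applied to scalar rate
values the "model" is a constant, so the robust fit degenerates to the
median with the RSDR (robust standard deviation of the residuals, the 68.27th
percentile of absolute residuals with a small-sample correction).  Each
point's absolute residual is converted to a two-tailed t-distribution p-value
and outliers are declared by Benjamini-Hochberg FDR control at rate Q.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.diagnostic import lilliefors

__all__ = [
    "GroupComparison",
    "ks_normality",
    "paired_t",
    "unpaired_t",
    "pearson_r",
    "rout_outliers",
    "mean_sem",
]


def _as1d(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a 1-D sample")
    return x


def mean_sem(values) -> Tuple[float, float]:
    """Mean and standard error of the mean (sd/sqrt(n), sample sd with ddof=1)."""
    x = _as1d(values)
    if x.size < 2:
        return float(np.mean(x)), math.nan
    return float(np.mean(x)), float(np.std(x, ddof=1) / math.sqrt(x.size))


def ks_normality(values) -> float:
    """Kolmogorov-Smirnov normality screen against N(sample mean, sample sd).

    Returns the p-value (Lilliefors-corrected, since the parameters are
    estimated from the sample). Advisory: callers warn and proceed on
    rejection rather than aborting a batch run.
    """
    x = _as1d(values)
    if x.size < 3:
        raise ValueError("normality screen needs at least 3 values")
    if np.std(x, ddof=1) == 0:
        raise ValueError("normality screen undefined for a constant sample")
    _, p = lilliefors(x, dist="norm")
    return float(p)


def paired_t(x, y) -> Tuple[float, float]:
    """Paired two-tailed t test; returns (t, p).

    Degenerate cases: identical samples return ``(0.0, 1.0)`` with a warning
    (no evidence either way by convention); a constant non-zero difference
    (zero-variance differences) returns ``(inf, 0.0)`` signed by the shift,
    also with a warning.
    """
    x, y = _as1d(x), _as1d(y)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    if x.size < 2:
        raise ValueError("paired t test needs at least 2 pairs")
    d = x - y
    if np.all(d == d[0]):
        if d[0] == 0:
            warnings.warn("identical paired samples; returning t=0, p=1", stacklevel=2)
            return 0.0, 1.0
        warnings.warn(
            "zero-variance non-zero paired differences; returning t=+/-inf, p=0",
            stacklevel=2,
        )
        return math.copysign(math.inf, d[0]), 0.0
    t, p = sps.ttest_rel(x, y)
    return float(t), float(p)


def unpaired_t(x, y, equal_var: bool = True) -> Tuple[float, float]:
    """Unpaired two-tailed t test (Student by default); returns (t, p)."""
    x, y = _as1d(x), _as1d(y)
    if x.size < 2 or y.size < 2:
        raise ValueError("unpaired t test needs at least 2 values per group")
    t, p = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(t), float(p)


def pearson_r(x, y) -> Tuple[float, float]:
    """Pearson correlation coefficient and two-tailed p; returns (r, p)."""
    x, y = _as1d(x), _as1d(y)
    if x.size != y.size:
        raise ValueError("samples must have equal length")
    if x.size < 3:
        raise ValueError("correlation needs at least 3 points")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a zero-variance sample")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def rout_outliers(values, q: float = 1.0) -> np.ndarray:
    """Univariate ROUT outlier detection; returns a boolean keep-mask.

    Robust location is the median; robust scale is the RSDR: the 68.27th
    percentile of absolute residuals scaled by n/(n-1) (one location
    parameter consumed). Each residual gets a two-tailed p from a
    t-distribution with n-1 degrees of freedom, and points are declared
    outliers by Benjamini-Hochberg FDR control at rate ``q`` (percent).
    Symmetric by construction: the mask is invariant under reflecting the
    sample about its median.
    """
    x = _as1d(values)
    n = x.size
    if n < 4:
        raise ValueError("ROUT needs at least 4 values")
    if not (0 < q <= 10):
        raise ValueError("Q must be in (0, 10] percent")

    resid = x - np.median(x)
    abs_resid = np.abs(resid)
    rsdr = np.percentile(abs_resid, 68.27) * n / (n - 1)
    if rsdr == 0:
        # majority of points identical: anything off the median is an outlier
        return abs_resid == 0

    pvals = 2.0 * sps.t.sf(abs_resid / rsdr, df=n - 1)
    order = np.argsort(pvals)
    thresh = (q / 100.0) * (np.arange(1, n + 1)) / n
    below = pvals[order] <= thresh
    keep = np.ones(n, dtype=bool)
    if below.any():
        k = int(np.max(np.nonzero(below)[0])) + 1  # BH step-up
        keep[order[:k]] = False
    return keep


@dataclass(frozen=True)
class GroupComparison:
    """One metric contrasted between two groups, with mean +/- SEM per group."""

    metric: str
    pool: str
    group_a: str
    group_b: str
    paired: bool
    n_a: int
    n_b: int
    mean_a: float
    sem_a: float
    mean_b: float
    sem_b: float
    t: float
    p: float
    pct_difference: float  # 100*(mean_b - mean_a)/mean_b: deficit of a vs comparator b
    outliers_removed: Tuple[str, ...] = field(default_factory=tuple)


def compare_groups(
    metric: str,
    pool: str,
    group_a: str,
    values_a,
    group_b: str,
    values_b,
    paired: bool,
    subject_ids_a: Optional[Sequence[str]] = None,
    rout_q: Optional[float] = None,
) -> GroupComparison:
    """Build a :class:`GroupComparison`, optionally ROUT-screening each group.

    For paired designs ``values_a`` and ``values_b`` must already be matched
    by subject; removing an outlying animal removes the pair. Test statistics
    are NaN when a group is too small.
    """
    a, b = _as1d(values_a), _as1d(values_b)
    ids = list(subject_ids_a) if subject_ids_a is not None else [""] * a.size
    removed: list[str] = []

    if rout_q is not None and a.size >= 4 and b.size >= 4:
        keep_a = rout_outliers(a, rout_q)
        keep_b = rout_outliers(b, rout_q)
        if paired:
            keep = keep_a & keep_b
            removed = [i for i, k in zip(ids, keep) if not k]
            a, b = a[keep], b[keep]
            ids = [i for i, k in zip(ids, keep) if k]
        else:
            removed = [i for i, k in zip(ids, keep_a) if not k]
            a, b = a[keep_a], b[keep_b]
            ids = [i for i, k in zip(ids, keep_a) if k]

    mean_a, sem_a = mean_sem(a) if a.size else (math.nan, math.nan)
    mean_b, sem_b = mean_sem(b) if b.size else (math.nan, math.nan)
    t = p = math.nan
    if paired:
        if a.size >= 2 and a.size == b.size:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                t, p = paired_t(a, b)
    elif a.size >= 2 and b.size >= 2:
        t, p = unpaired_t(a, b)
    pct = 100.0 * (mean_b - mean_a) / mean_b if mean_b not in (0.0,) else math.nan

    return GroupComparison(
        metric=metric, pool=pool, group_a=group_a, group_b=group_b, paired=paired,
        n_a=int(a.size), n_b=int(b.size),
        mean_a=mean_a, sem_a=sem_a, mean_b=mean_b, sem_b=sem_b,
        t=t, p=p, pct_difference=pct, outliers_removed=tuple(removed),
    )
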