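"""Deep-vs-shallow size regressions: OLS, SMA, and the common-slope test.

The null hypothesis of no effect of deep-sea colonization predicts that a
genus's deep and shallow log sizes are equal on average, so the best-fit
line of y (deep) on x (shallow) should have slope one; a shallower slope —
small genera getting larger, large genera smaller — is the island-rule
signature.

Two line fits are provided.  Ordinary least squares with the standard
t-test of slope = 1 is the test historically used in the island-rule
literature; it is biased below one whenever x carries lineage-specific
drift variance, which is why the permutation machinery exists.
Standardized-major-axis (SMA) regression treats both axes symmetrically:
|b| = sd(y)/sd(x) with the sign of the x–y correlation.  Its natural test
statistic is the Pearson correlation between (x+y) and (x−y), whose
expectation is zero exactly when var(x) = var(y), i.e. when the SMA slope
is one.

The common-slope test compares the likelihood of a single shared SMA slope
against per-group slopes via the correlation between fitted-axis and
residual-axis scores within each group, referring
``-2 log LR = -sum_i n_i log(1 - r_i^2(b))`` at the common-slope optimum to
a chi-square with (groups - 1) degrees of freedom.  A small-sample
Bartlett-type correction (weights ``n_i - 5/2``) is available but off by
default.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Literal, Mapping, Sequence

import numpy as np
from scipy import optimize, stats

from bathyrule.errors import DegenerateDataError
from bathyrule.pairing import GenusPair


@dataclass(frozen=True)
class RegressionResult:
    """A fitted slope with its test statistic.

    For OLS the statistic is t = (b - 1)/SE(b) on n - 2 df and ``p_value``
    is its two-sided tail.  For SMA the statistic is r(x+y, x−y) and
    ``p_value`` is None — significance comes from the permutation test.
    """

    method: Literal["ols", "sma"]
    slope: float
    intercept: float
    statistic: float
    p_value: float | None
    n: int


@dataclass(frozen=True)
class CommonSlopeResult:
    groups: tuple[str, ...]
    common_slope: float
    lr_statistic: float
    df: int
    p_value: float


def _as_xy(pairs: Sequence[GenusPair] | tuple[np.ndarray, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(pairs, tuple) and len(pairs) == 2:
        x, y = np.asarray(pairs[0], dtype=float), np.asarray(pairs[1], dtype=float)
    else:
        x = np.array([p.x_shallow_logsize for p in pairs], dtype=float)
        y = np.array([p.y_deep_logsize for p in pairs], dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-d arrays")
    return x, y


def ols_fit(
    pairs: Sequence[GenusPair] | tuple[np.ndarray, np.ndarray],
    null_slope: float = 1.0,
) -> RegressionResult:
    """Least-squares fit of deep on shallow size, t-tested against slope 1."""
    x, y = _as_xy(pairs)
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need at least 3 genera, got {n}")
    if np.ptp(x) == 0:
        raise DegenerateDataError("zero variance in shallow sizes (x)")
    fit = stats.linregress(x, y)
    if fit.stderr == 0.0:
        # exact fit: the null is either met exactly or contradicted exactly
        t = 0.0 if fit.slope == null_slope else math.copysign(math.inf, fit.slope - null_slope)
    else:
        t = (fit.slope - null_slope) / fit.stderr
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return RegressionResult(
        method="ols",
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        statistic=float(t),
        p_value=float(p),
        n=n,
    )


def sma_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation between (x+y) and (x−y).

    Its sign follows var(x) − var(y): positive when shallow sizes vary more
    than deep ones, i.e. when the SMA slope is below one.
    """
    s, d = x + y, x - y
    if np.ptp(s) == 0 or np.ptp(d) == 0:
        raise DegenerateDataError("zero variance in x+y or x−y")
    return float(stats.pearsonr(s, d).statistic)


def sma_fit(pairs: Sequence[GenusPair] | tuple[np.ndarray, np.ndarray]) -> RegressionResult:
    """Standardized-major-axis fit: |b| = sd(y)/sd(x), sign from corr(x, y)."""
    x, y = _as_xy(pairs)
    n = x.size
    if n < 3:
        raise DegenerateDataError(f"need at least 3 genera, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateDataError("zero variance in x or y")
    sx, sy = np.std(x, ddof=1), np.std(y, ddof=1)
    r = float(stats.pearsonr(x, y).statistic)
    if r == 0:
        warnings.warn("x and y are exactly uncorrelated; SMA slope sign set to +1")
    sign = -1.0 if r < 0 else 1.0
    slope = sign * sy / sx
    intercept = float(np.mean(y) - slope * np.mean(x))
    try:
        statistic = sma_statistic(x, y)
    except DegenerateDataError:
        # the slope is still defined (e.g. an exact anti-correlation makes
        # x+y constant); only the test statistic is undefined
        warnings.warn("x+y or x−y has zero variance; SMA statistic undefined")
        statistic = float("nan")
    return RegressionResult(
        method="sma",
        slope=float(slope),
        intercept=intercept,
        statistic=statistic,
        p_value=None,
        n=n,
    )


def _group_residual_fitted_rsq(b: float, x: np.ndarray, y: np.ndarray) -> float:
    """Squared correlation between residual (y − b x) and fitted (y + b x) axes."""
    res = y - b * x
    fit = y + b * x
    vr, vf = np.var(res), np.var(fit)
    if vr == 0 or vf == 0:
        return 0.0
    c = np.mean(res * fit) - np.mean(res) * np.mean(fit)
    return float(c * c / (vr * vf))


def common_slope_test(
    grouped: Mapping[str, Sequence[GenusPair] | tuple[np.ndarray, np.ndarray]],
    correction: bool = False,
) -> CommonSlopeResult:
    """Likelihood-ratio test of one shared SMA slope against per-group slopes.

    ``correction=True`` applies the small-sample weight ``n_i - 5/2`` in the
    LR sum instead of ``n_i``.
    """
    if len(grouped) < 2:
        raise ValueError("need at least two groups")
    labels: list[str] = []
    data: list[tuple[np.ndarray, np.ndarray]] = []
    slopes: list[float] = []
    for label, pairs in grouped.items():
        x, y = _as_xy(pairs)
        if x.size < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
            raise DegenerateDataError(f"group {label!r} is degenerate for SMA fitting")
        labels.append(str(label))
        data.append((x, y))
        slopes.append(sma_fit((x, y)).slope)

    signs = set(np.sign(slopes))
    if len(signs) > 1:
        raise DegenerateDataError("groups have SMA slopes of opposite sign; no common slope")
    sign = slopes[0] / abs(slopes[0])

    weights = [x.size - 2.5 if correction else x.size for x, _ in data]

    def neg2loglik(log_b: float) -> float:
        b = sign * np.exp(log_b)
        total = 0.0
        for w, (x, y) in zip(weights, data):
            rsq = _group_residual_fitted_rsq(b, x, y)
            total += -w * np.log1p(-rsq)
        return total

    log_abs = np.log(np.abs(slopes))
    res = optimize.minimize_scalar(
        neg2loglik,
        bounds=(log_abs.min() - 3.0, log_abs.max() + 3.0),
        method="bounded",
        options={"xatol": 1e-10},
    )
    common = float(sign * np.exp(res.x))
    lr = float(max(res.fun, 0.0))
    df = len(data) - 1
    p = float(stats.chi2.sf(lr, df))
    return CommonSlopeResult(
        groups=tuple(labels),
        common_slope=common,
        lr_statistic=lr,
        df=df,
        p_value=p,
    )
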