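"""Regional change indicators from piecewise fits and cross-metric tests.

Three indicators summarize each region's trajectory: the onset of major
change (first breakpoint psi1), its duration (psi2 - psi1, reported as a
positive number of years), and the post-onset rate (segment slope b + c).
Onsets are compared between metrics (or against agricultural area) with
OLS regressions and a joint F-test of {intercept = 0, slope = 1} against a
1:1 relationship.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from cropdiv.errors import InstabilityError, InsufficientDataError
from cropdiv.temporal_models import PiecewiseFit

__all__ = [
    "BreakpointIndicators",
    "RegressionResult",
    "cross_regress",
    "indicators",
    "summarize",
    "test_one_to_one",
]


@dataclass(frozen=True)
class BreakpointIndicators:
    """Onset year, duration (years), and post-onset slope for one series."""

    region: str
    metric: str
    onset: float
    duration: float
    post_break_slope: float


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


def indicators(
    fit: PiecewiseFit, region: str = "", metric: str = ""
) -> BreakpointIndicators:
    """Derive the three change indicators from a (bootstrapped) piecewise fit.

    Bootstrap medians are used when present, the point estimates otherwise.
    """
    if fit.bootstrap is not None:
        med = fit.bootstrap.medians
        psi1, psi2 = med["psi1"], med["psi2"]
        slope = med["b"] + med["c"]
    else:
        psi1, psi2 = fit.psi1, fit.psi2
        slope = fit.params["b"] + fit.params["c"]
    if not psi1 < psi2:
        raise InstabilityError(
            f"breakpoint medians out of order: psi1={psi1}, psi2={psi2}"
        )
    return BreakpointIndicators(region, metric, psi1, psi2 - psi1, slope)


def _paired(x: Mapping[str, float], y: Mapping[str, float]):
    regions = sorted(set(x) & set(y))
    if len(regions) < 3:
        raise InsufficientDataError(
            f"need >= 3 paired regions, got {len(regions)}"
        )
    xv = np.array([x[r] for r in regions], dtype=float)
    yv = np.array([y[r] for r in regions], dtype=float)
    return regions, xv, yv


def cross_regress(x: Mapping[str, float], y: Mapping[str, float]) -> RegressionResult:
    """OLS of y-onsets on x-onsets, paired by region label.

    Returns the slope, intercept, r^2, the t-based two-sided p-value for
    the slope, and the number of paired regions.
    """
    _, xv, yv = _paired(x, y)
    res = stats.linregress(xv, yv)
    return RegressionResult(
        float(res.slope), float(res.intercept),
        float(res.rvalue**2), float(res.pvalue), xv.size,
    )


def test_one_to_one(x: Mapping[str, float], y: Mapping[str, float]) -> tuple[float, float]:
    """Joint F-test of {intercept = 0, slope = 1} against the OLS line.

    F = ((RSS_restricted - RSS_full)/2) / (RSS_full/(n-2)) with the
    restricted predictions y-hat = x; p from F(2, n-2). When both the OLS
    line and the restriction fit exactly, p = 1 by convention.
    """
    _, xv, yv = _paired(x, y)
    n = xv.size
    X = np.column_stack([np.ones(n), xv])
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid_full = yv - X @ beta
    rss_full = float(resid_full @ resid_full)
    rss_restr = float(np.sum((yv - xv) ** 2))
    if rss_full <= 1e-12 * max(1.0, float(np.sum(yv**2))):
        if rss_restr <= 1e-12 * max(1.0, float(np.sum(yv**2))):
            return 0.0, 1.0
        return float("inf"), 0.0
    F = ((rss_restr - rss_full) / 2.0) / (rss_full / (n - 2))
    F = max(F, 0.0)
    p = float(stats.f.sf(F, 2, n - 2))
    return float(F), p


def summarize(values: Mapping[str, float], robust: bool = False) -> tuple[float, float]:
    """Cross-region summary: mean +/- sd, or median +/- MAD when robust."""
    v = np.asarray(list(values.values()), dtype=float)
    if robust:
        med = float(np.median(v))
        return med, float(np.median(np.abs(v - med)))
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0
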