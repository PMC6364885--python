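"""Temporal models of diversity versus year, AIC selection, and bootstrap.

Six candidate mean functions for a diversity series D(year):

  linear      D = a + b*year
  piecewise2  D = a + b*year + c*(year-psi1)*I(year>psi1)
                            + d*(year-psi2)*I(year>psi2)
  quadratic   D = a + b*year + c*year^2
  unimodal    D = a * b^((year-c)^2)            (bump at c when 0 < b < 1)
  asymptotic  D = a + b*exp(-exp(c)*(year-year0))
  logistic4   D = a + (b-a) / (1 + exp((c-year)/d))

The two-breakpoint piecewise family is fitted by iterative linearization:
at each step an OLS fit on the working basis {1, year, (year-psi)_+,
-I(year>psi)} updates each breakpoint by (gap coefficient)/(slope-change
coefficient) until the update is below tolerance; inadmissible or
non-converging starts fall back to a quantile grid of initial breakpoint
pairs, and the best-RSS admissible solution wins. Parameter uncertainty is
summarized by case-resampling bootstrap with the median taken over
replicates for every parameter, AIC, and r^2.

AIC is computed as n*ln(RSS/n) + 2k with k counting the mean-function
parameters plus the error variance; the additive constant is dropped, so
values are comparable only within one series. RSS numerically
indistinguishable from zero maps to a -inf sentinel, ordered below every
finite AIC with ties broken in favor of fewer parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import least_squares

from cropdiv.errors import ConvergenceError, InstabilityError, InsufficientDataError
from cropdiv.alpha_diversity import DiversitySeries

__all__ = [
    "ModelFit",
    "ModelSelection",
    "PiecewiseFit",
    "BootstrapSummary",
    "aic",
    "bootstrap_piecewise",
    "fit_asymptotic",
    "fit_linear",
    "fit_logistic4",
    "fit_piecewise2",
    "fit_quadratic",
    "fit_unimodal",
    "select_model",
]

FAMILIES = ("linear", "piecewise2", "quadratic", "unimodal", "asymptotic", "logistic4")

# mean-function parameter counts (k for AIC adds 1 for the error variance)
_N_PARAMS = {
    "linear": 2,
    "piecewise2": 6,
    "quadratic": 3,
    "unimodal": 3,
    "asymptotic": 3,
    "logistic4": 4,
}


def _xy(series, y=None) -> tuple[np.ndarray, np.ndarray]:
    if y is not None:
        x = np.asarray(series, dtype=float)
        y = np.asarray(y, dtype=float)
    elif isinstance(series, DiversitySeries):
        x = series.years.astype(float)
        y = series.values.astype(float)
    else:
        x, y = (np.asarray(v, dtype=float) for v in series)
    if x.shape != y.shape or x.ndim != 1:
        raise InsufficientDataError("series must be parallel 1-d year/value arrays")
    order = np.argsort(x, kind="mergesort")
    return x[order], y[order]


def _zero_floor(y: np.ndarray) -> float:
    energy = float(np.sum((y - y.mean()) ** 2) + 1e-6 * np.sum(y**2))
    return 1e-12 * energy + 1e-300


def _aic_value(n: int, rss: float, k: int, floor: float) -> float:
    if rss <= floor:
        return -math.inf
    return n * math.log(rss / n) + 2 * k


def _r2(y: np.ndarray, rss: float, floor: float) -> float:
    tss = float(np.sum((y - y.mean()) ** 2))
    if tss <= floor:
        return 1.0 if rss <= floor else 0.0
    return 1.0 - rss / tss


@dataclass
class ModelFit:
    """One fitted mean function with its fit statistics."""

    family: str
    params: dict[str, float]
    n: int
    rss: float
    aic: float
    r2: float
    delta_aic: float | None = None

    @property
    def k(self) -> int:
        """AIC parameter count (mean-function parameters + error variance)."""
        return _N_PARAMS[self.family] + 1

    def predict(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return _PREDICT[self.family](self.params, x)


@dataclass
class BootstrapSummary:
    """Case-resampling bootstrap medians and replicate distributions."""

    medians: dict[str, float]
    replicates: dict[str, np.ndarray]
    n_boot: int
    n_success: int


@dataclass
class PiecewiseFit(ModelFit):
    """Two-breakpoint piecewise fit; slopes are b, b+c, b+c+d per segment."""

    bootstrap: BootstrapSummary | None = None

    @property
    def psi1(self) -> float:
        return self.params["psi1"]

    @property
    def psi2(self) -> float:
        return self.params["psi2"]

    @property
    def segment_slopes(self) -> tuple[float, float, float]:
        b, c, d = (self.params[k] for k in ("b", "c", "d"))
        return (b, b + c, b + c + d)


# --------------------------------------------------------------------------
# prediction functions

def _predict_linear(p, x):
    return p["a"] + p["b"] * x


def _predict_piecewise2(p, x):
    out = p["a"] + p["b"] * x
    out = out + p["c"] * np.clip(x - p["psi1"], 0.0, None)
    out = out + p["d"] * np.clip(x - p["psi2"], 0.0, None)
    return out


def _predict_quadratic(p, x):
    return p["a"] + p["b"] * x + p["c"] * x * x


def _predict_unimodal(p, x):
    return p["a"] * np.power(p["b"], (x - p["c"]) ** 2)


def _predict_asymptotic(p, x):
    return p["a"] + p["b"] * np.exp(-np.exp(p["c"]) * (x - p["x0"]))


def _predict_logistic4(p, x):
    z = np.clip((p["c"] - x) / p["d"], -500.0, 500.0)
    return p["a"] + (p["b"] - p["a"]) / (1.0 + np.exp(z))


_PREDICT: dict[str, Callable] = {
    "linear": _predict_linear,
    "piecewise2": _predict_piecewise2,
    "quadratic": _predict_quadratic,
    "unimodal": _predict_unimodal,
    "asymptotic": _predict_asymptotic,
    "logistic4": _predict_logistic4,
}


def aic(fit: ModelFit) -> float:
    """AIC of a fit (n*ln(RSS/n) + 2k); -inf sentinel for RSS = 0."""
    return fit.aic


def _require_points(x: np.ndarray, needed: int, family: str) -> None:
    if x.size < needed:
        raise InsufficientDataError(
            f"{family} needs >= {needed} points, got {x.size}"
        )


# --------------------------------------------------------------------------
# OLS families

def fit_linear(series, y=None) -> ModelFit:
    """Ordinary least squares line D = a + b*year."""
    x, yv = _xy(series, y)
    _require_points(x, 3, "linear")
    X = np.column_stack([np.ones_like(x), x])
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    rss = float(resid @ resid)
    floor = _zero_floor(yv)
    params = {"a": float(beta[0]), "b": float(beta[1])}
    return ModelFit(
        "linear", params, x.size, rss,
        _aic_value(x.size, rss, 3, floor), _r2(yv, rss, floor),
    )


def fit_quadratic(series, y=None) -> ModelFit:
    """OLS parabola D = a + b*year + c*year^2 (fit on centered years)."""
    x, yv = _xy(series, y)
    _require_points(x, 5, "quadratic")
    xbar = x.mean()
    z = x - xbar
    X = np.column_stack([np.ones_like(z), z, z * z])
    beta, _, _, _ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    rss = float(resid @ resid)
    alpha, bet, gam = (float(v) for v in beta)
    params = {
        "a": alpha - bet * xbar + gam * xbar * xbar,
        "b": bet - 2.0 * gam * xbar,
        "c": gam,
    }
    floor = _zero_floor(yv)
    return ModelFit(
        "quadratic", params, x.size, rss,
        _aic_value(x.size, rss, 4, floor), _r2(yv, rss, floor),
    )


# --------------------------------------------------------------------------
# piecewise two-breakpoint family

def _segment_counts(x: np.ndarray, psi: np.ndarray) -> tuple[int, int, int]:
    s1 = int(np.sum(x <= psi[0]))
    s2 = int(np.sum((x > psi[0]) & (x <= psi[1])))
    s3 = int(np.sum(x > psi[1]))
    return s1, s2, s3


def _admissible(x: np.ndarray, psi: np.ndarray) -> bool:
    if not np.isfinite(psi).all():
        return False
    if not (x.min() < psi[0] < psi[1] < x.max()):
        return False
    return min(_segment_counts(x, psi)) >= 2


def _muggeo(x, y, psi0, tol, max_iter):
    """One Muggeo-style run from initial breakpoints; None when it fails."""
    psi = np.asarray(psi0, dtype=float).copy()
    if not _admissible(x, psi):
        return None
    yscale = max(float(np.max(np.abs(y))), 1.0)
    xspan = float(x.max() - x.min())
    slope_eps = 1e-9 * yscale / max(xspan, 1.0)
    for _ in range(max_iter):
        U = np.column_stack([np.clip(x - p, 0.0, None) for p in psi])
        V = np.column_stack([-(x > p).astype(float) for p in psi])
        X = np.column_stack([np.ones_like(x), x, U, V])
        try:
            beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        except np.linalg.LinAlgError:
            return None
        if not np.isfinite(beta).all():
            return None
        slope_change = beta[2:4]
        gaps = beta[4:6]
        delta = np.zeros(2)
        for m in range(2):
            if abs(slope_change[m]) < slope_eps:
                if abs(gaps[m]) < 1e-8 * yscale:
                    delta[m] = 0.0  # flat-change segment; breakpoint immaterial
                else:
                    return None
            else:
                delta[m] = gaps[m] / slope_change[m]
        # step-halving keeps the update admissible where possible; a start
        # fails only when even a heavily damped step crosses the breakpoints,
        # exits the data range, or under-fills a segment. Reaching the
        # iteration cap is a stop, not a failure (best RSS over starts wins).
        for damp in (1.0, 0.5, 0.25, 0.125, 0.0625):
            psi_new = psi + damp * delta
            if psi_new[0] <= psi_new[1] and _admissible(x, psi_new):
                delta = damp * delta
                break
        else:
            return None
        psi = psi_new
        if float(np.max(np.abs(delta))) < tol:
            break
    U = np.column_stack([np.clip(x - p, 0.0, None) for p in psi])
    X = np.column_stack([np.ones_like(x), x, U])
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    rss = float(resid @ resid)
    return psi, beta, rss


def _init_grid(x: np.ndarray, quantiles: Sequence[float]) -> list[tuple[float, float]]:
    qs = np.unique(np.quantile(x, list(quantiles)))
    pairs = []
    for i in range(len(qs)):
        for j in range(i + 1, len(qs)):
            if qs[i] < qs[j]:
                pairs.append((float(qs[i]), float(qs[j])))
    return pairs


def fit_piecewise2(
    series,
    y=None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-6,
    max_iter: int = 50,
    grid_quantiles: Sequence[float] = tuple(np.arange(0.1, 0.95, 0.1)),
) -> PiecewiseFit:
    """Two-breakpoint piecewise-linear fit by iterative linearization.

    Starts from ``init`` when given, then from every pair on a quantile
    grid of the year axis; each start must converge (max breakpoint update
    below ``tol`` years within ``max_iter`` iterations) to an admissible
    solution (ordered breakpoints strictly inside the data range with at
    least 2 observations per segment). The best-RSS solution is returned.
    """
    x, yv = _xy(series, y)
    _require_points(x, 8, "piecewise2")
    starts: list[tuple[float, float]] = []
    if init is not None:
        starts.append((float(init[0]), float(init[1])))
    starts.extend(_init_grid(x, grid_quantiles))
    best = None
    n_tried = n_failed = 0
    for psi0 in starts:
        n_tried += 1
        res = _muggeo(x, yv, np.asarray(psi0), tol, max_iter)
        if res is None:
            n_failed += 1
            continue
        if best is None or res[2] < best[2]:
            best = res
    if best is None:
        raise ConvergenceError(
            "no admissible converged piecewise solution",
            diagnostics={"starts_tried": n_tried, "starts_failed": n_failed,
                         "n": int(x.size)},
        )
    psi, beta, rss = best
    params = {
        "a": float(beta[0]), "b": float(beta[1]),
        "c": float(beta[2]), "d": float(beta[3]),
        "psi1": float(psi[0]), "psi2": float(psi[1]),
    }
    floor = _zero_floor(yv)
    return PiecewiseFit(
        "piecewise2", params, x.size, rss,
        _aic_value(x.size, rss, 7, floor), _r2(yv, rss, floor),
    )


# --------------------------------------------------------------------------
# nonlinear least-squares families (Gaussian ML)

def _nls_best(x, yv, residual, starts, bounds=(-np.inf, np.inf)):
    best = None
    for p0 in starts:
        try:
            sol = least_squares(residual, p0, bounds=bounds, method="trf",
                                max_nfev=2000)
        except ValueError:
            continue
        if not np.isfinite(sol.cost):
            continue
        rss = float(2.0 * sol.cost)
        if best is None or rss < best[1]:
            best = (sol.x, rss)
    if best is None:
        raise ConvergenceError("all nonlinear starts diverged")
    return best


def fit_unimodal(series, y=None, form: str = "bump") -> ModelFit:
    """Fit D = a*b^((year-c)^2); b < 1 gives a bump peaking at year c.

    ``form="scaled_parabola"`` selects the alternative reading
    D = a*b*(year-c)^2 (a plain parabola through zero at year c).
    """
    x, yv = _xy(series, y)
    _require_points(x, 5, "unimodal")
    if form == "scaled_parabola":
        # a and b enter only through their product; fit ab jointly
        xbar = x.mean()
        z = x - xbar
        def residual(p):
            ab, c = p
            return ab * (z - c) ** 2 - yv
        i_ext = int(np.argmax(np.abs(yv)))
        starts = [(1.0, float(z[i_ext])), (-1.0, float(z[i_ext])), (0.1, 0.0)]
        p, rss = _nls_best(x, yv, residual, starts)
        params = {"a": float(p[0]), "b": 1.0, "c": float(p[1] + xbar)}
        floor = _zero_floor(yv)
        return ModelFit(
            "unimodal", params, x.size, rss,
            _aic_value(x.size, rss, 4, floor), _r2(yv, rss, floor),
        )
    if form != "bump":
        raise ConvergenceError(f"unknown unimodal form {form!r}")
    xbar = x.mean()
    z = x - xbar

    def residual(p):
        a, q, c = p  # q = ln b
        return a * np.exp(np.clip(q * (z - c) ** 2, -50.0, 50.0)) - yv

    a0 = float(yv.mean()) or 1.0
    i_ext = int(np.argmax(np.abs(yv - a0)))
    c0 = float(z[i_ext])
    z_end = z[0] if abs(z[0] - c0) > abs(z[-1] - c0) else z[-1]
    y_end = yv[0] if z_end == z[0] else yv[-1]
    q0 = -1e-3
    if a0 != 0 and y_end / a0 > 0 and z_end != c0:
        q0 = float(np.log(y_end / a0) / (z_end - c0) ** 2)
    starts = [
        (a0, q0, c0),
        (a0, -1e-3, c0),
        (a0, 1e-4, c0),
        (float(yv[i_ext]) or 1.0, -1e-2, c0),
        (a0, 0.0, 0.0),
    ]
    p, rss = _nls_best(x, yv, residual, starts)
    params = {"a": float(p[0]), "b": float(np.exp(p[1])), "c": float(p[2] + xbar)}
    floor = _zero_floor(yv)
    return ModelFit(
        "unimodal", params, x.size, rss,
        _aic_value(x.size, rss, 4, floor), _r2(yv, rss, floor),
    )


def fit_asymptotic(series, y=None) -> ModelFit:
    """Fit D = a + b*exp(-exp(c)*(year-year0)), year0 = first observed year.

    a is the asymptote, b the offset of the year0 intercept from it, and c
    the log rate constant (origin-invariant). b is reported relative to
    year0 (stored in the parameters) because the year-zero origin form
    overflows for calendar years.
    """
    x, yv = _xy(series, y)
    _require_points(x, 5, "asymptotic")
    x0 = float(x.min())
    z = x - x0
    span = float(z.max()) or 1.0

    def residual(p):
        a, b, c = p
        return a + b * np.exp(-np.exp(np.clip(c, -30.0, 10.0)) * z) - yv

    a0 = float(yv[-1])
    b0 = float(yv[0] - yv[-1])
    c_mid = float(np.log(3.0 / span))
    starts = [
        (a0, b0, c_mid),
        (a0, b0, c_mid + 1.5),
        (a0, b0, c_mid - 1.5),
        (float(yv.mean()), 0.0, c_mid),
    ]
    bounds = ([-np.inf, -np.inf, -30.0], [np.inf, np.inf, 10.0])
    p, rss = _nls_best(x, yv, residual, starts, bounds=bounds)
    params = {"a": float(p[0]), "b": float(p[1]), "c": float(p[2]), "x0": x0}
    floor = _zero_floor(yv)
    return ModelFit(
        "asymptotic", params, x.size, rss,
        _aic_value(x.size, rss, 4, floor), _r2(yv, rss, floor),
    )


def fit_logistic4(series, y=None) -> ModelFit:
    """Fit the four-parameter logistic D = a + (b-a)/(1+exp((c-year)/d))."""
    x, yv = _xy(series, y)
    _require_points(x, 6, "logistic4")
    xbar = x.mean()
    z = x - xbar
    span = float(z.max() - z.min()) or 1.0

    def residual(p):
        a, b, c, d = p
        d = d if abs(d) > 1e-8 else 1e-8
        arg = np.clip((c - z) / d, -500.0, 500.0)
        return a + (b - a) / (1.0 + np.exp(arg)) - yv

    lo, hi = float(yv.min()), float(yv.max())
    starts = [
        (lo, hi, 0.0, span / 4.0),
        (hi, lo, 0.0, span / 4.0),
        (lo, hi, 0.0, -span / 4.0),
        (lo, hi, float(z[len(z) // 2]), span / 8.0),
    ]
    p, rss = _nls_best(x, yv, residual, starts)
    params = {
        "a": float(p[0]), "b": float(p[1]),
        "c": float(p[2] + xbar), "d": float(p[3]),
    }
    floor = _zero_floor(yv)
    return ModelFit(
        "logistic4", params, x.size, rss,
        _aic_value(x.size, rss, 5, floor), _r2(yv, rss, floor),
    )


_FITTERS = {
    "linear": fit_linear,
    "piecewise2": fit_piecewise2,
    "quadratic": fit_quadratic,
    "unimodal": fit_unimodal,
    "asymptotic": fit_asymptotic,
    "logistic4": fit_logistic4,
}


@dataclass
class ModelSelection:
    """All-family fits ranked by AIC (ties: fewer parameters first)."""

    fits: list[ModelFit]
    failures: dict[str, str] = field(default_factory=dict)

    @property
    def best(self) -> ModelFit:
        return self.fits[0]


def select_model(series, y=None) -> ModelSelection:
    """Fit all six families and rank by AIC ascending.

    Families whose preconditions fail or that do not converge are recorded
    as failures, never silently skipped. Delta-AIC is filled relative to
    the best finite-or-sentinel AIC.
    """
    fits: list[ModelFit] = []
    failures: dict[str, str] = {}
    for family, fitter in _FITTERS.items():
        try:
            fits.append(fitter(series, y))
        except Exception as exc:  # carried as annotation, per contract
            failures[family] = f"{type(exc).__name__}: {exc}"
    if not fits:
        raise ConvergenceError("no family could be fitted", diagnostics=failures)
    fits.sort(key=lambda f: (f.aic, f.k))
    best_aic = fits[0].aic
    for f in fits:
        if f.aic == best_aic:
            f.delta_aic = 0.0
        elif math.isinf(best_aic):
            f.delta_aic = math.inf
        else:
            f.delta_aic = f.aic - best_aic
    return ModelSelection(fits, failures)


def bootstrap_piecewise(
    series,
    y=None,
    n_boot: int = 500,
    seed: int = 0,
    min_success: float = 0.8,
    tol: float = 1e-6,
) -> PiecewiseFit:
    """Case-resampling bootstrap of the two-breakpoint fit.

    Resamples (year, D) pairs with replacement at the original n, refits
    each replicate (initialized at the point-estimate breakpoints, quantile
    grid as fallback), and reports the median over successful replicates of
    every parameter, the AIC, and r^2. Fails when fewer than
    ``min_success * n_boot`` replicates converge.
    """
    x, yv = _xy(series, y)
    point = fit_piecewise2(x, yv, tol=tol)
    rng = np.random.default_rng(seed)
    keys = ["a", "b", "c", "d", "psi1", "psi2", "aic", "r2"]
    rows: dict[str, list[float]] = {k: [] for k in keys}
    n = x.size
    n_failed = 0
    for _ in range(int(n_boot)):
        idx = rng.integers(0, n, n)
        xb, yb = x[idx], yv[idx]
        try:
            fit = fit_piecewise2(
                xb, yb, init=(point.psi1, point.psi2), tol=tol,
                grid_quantiles=(0.2, 0.4, 0.6, 0.8),
            )
        except Exception:
            n_failed += 1
            continue
        for k in ("a", "b", "c", "d", "psi1", "psi2"):
            rows[k].append(fit.params[k])
        rows["aic"].append(fit.aic)
        rows["r2"].append(fit.r2)
    n_success = int(n_boot) - n_failed
    if n_success < min_success * n_boot:
        raise InstabilityError(
            f"only {n_success}/{n_boot} bootstrap replicates converged",
            diagnostics={"n_success": n_success, "n_boot": int(n_boot)},
        )
    replicates = {k: np.asarray(v) for k, v in rows.items()}
    medians = {k: float(np.median(v)) for k, v in replicates.items()}
    point.bootstrap = BootstrapSummary(medians, replicates, int(n_boot), n_success)
    return point
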