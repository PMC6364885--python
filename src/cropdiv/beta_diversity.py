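"""Beta diversity among region-year communities.

Bray-Curtis dissimilarities at commodity-group granularity over every
region-year sample, nonmetric multidimensional scaling (Kruskal stress-1),
a permutational multivariate ANOVA partitioning the Gower-centered squared
dissimilarities by region, year (numeric covariate), and their interaction
with sequential (Type-I) sums of squares, and the within-year pairwise
dissimilarity trend through time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression
from sklearn.manifold import MDS

from cropdiv.errors import (
    ConfigError,
    DegenerateSolutionError,
    InsufficientDataError,
    UndefinedValueError,
    ValidationError,
)
from cropdiv.io_fao import CommunityVector, Panel
from cropdiv.breakpoints import RegressionResult
from cropdiv.temporal_models import PiecewiseFit, fit_piecewise2

__all__ = [
    "DissimilarityMatrix",
    "OrdinationResult",
    "PermanovaResult",
    "TrendResult",
    "bray_curtis",
    "dissimilarity_matrix",
    "kruskal_stress",
    "nmds",
    "permanova",
    "similarity_trend",
    "within_year_pairs",
]


def bray_curtis(x: CommunityVector, y: CommunityVector) -> float:
    """Bray-Curtis dissimilarity sum|x-y| / sum(x+y) on the taxon union."""
    if len(x) == 0 and len(y) == 0:
        raise UndefinedValueError("Bray-Curtis undefined for two empty communities")
    taxa = sorted(set(x.taxa) | set(y.taxa))
    xv = np.zeros(len(taxa))
    yv = np.zeros(len(taxa))
    lut = {t: i for i, t in enumerate(taxa)}
    for t, a in zip(x.taxa, x.abundances):
        xv[lut[t]] = a
    for t, a in zip(y.taxa, y.abundances):
        yv[lut[t]] = a
    return float(np.abs(xv - yv).sum() / (xv + yv).sum())


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Symmetric Bray-Curtis matrix over ordered (region, year) samples."""

    labels: tuple[tuple[str, int], ...]
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValidationError("matrix shape does not match labels")
        if not np.allclose(v, v.T):
            raise ValidationError("dissimilarity matrix must be symmetric")
        if (np.diag(v) != 0).any():
            raise ValidationError("diagonal must be zero")
        if v.min() < 0 or v.max() > 1 + 1e-12:
            raise ValidationError("Bray-Curtis values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def regions(self) -> np.ndarray:
        return np.array([r for r, _ in self.labels])

    @property
    def years(self) -> np.ndarray:
        return np.array([y for _, y in self.labels], dtype=int)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def to_frame(self) -> pd.DataFrame:
        idx = pd.MultiIndex.from_tuples(self.labels, names=["region", "year"])
        return pd.DataFrame(self.values, index=idx, columns=idx)


def dissimilarity_matrix(panel: Panel) -> DissimilarityMatrix:
    """All pairwise Bray-Curtis values among non-empty region-year communities.

    Sample order is (region lexicographic, year ascending); empty
    communities are excluded with a warning.
    """
    wide = panel.to_wide()
    # covered region-years with nothing grown are legitimate empty samples
    full_index = pd.MultiIndex.from_tuples(
        [(r, y) for r in panel.regions for y in panel.years(r)],
        names=["region", "year"],
    )
    wide = wide.reindex(full_index, fill_value=0.0).sort_index()
    totals = wide.sum(axis=1)
    empty = totals[totals <= 0]
    if len(empty):
        warnings.warn(
            f"excluding {len(empty)} empty region-year communities", stacklevel=2
        )
        wide = wide.loc[totals > 0]
    if len(wide) < 2:
        raise InsufficientDataError("need >= 2 non-empty communities")
    labels = tuple((str(r), int(y)) for r, y in wide.index)
    values = squareform(pdist(wide.to_numpy(), metric="braycurtis"))
    return DissimilarityMatrix(labels, values)


# --------------------------------------------------------------------------
# NMDS

@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray
    stress: float
    restarts: int
    seed: int


def kruskal_stress(dm: DissimilarityMatrix, coords: np.ndarray) -> float:
    """Kruskal stress-1 of a configuration against the dissimilarities.

    Disparities come from isotonic regression of configuration distances on
    the dissimilarity order with the primary (unweighted) tie treatment:
    tied dissimilarities are ordered by their configuration distances, so
    they are free to take distinct disparities.
    """
    d = dm.condensed()
    dist = pdist(np.asarray(coords, dtype=float))
    order = np.lexsort((dist, d))  # primary tie treatment
    iso = IsotonicRegression(increasing=True)
    dhat_sorted = iso.fit_transform(np.arange(d.size), dist[order])
    dhat = np.empty_like(dhat_sorted)
    dhat[order] = dhat_sorted
    denom = float(np.sum(dist**2))
    if denom <= 0:
        return float("inf")
    return float(np.sqrt(np.sum((dist - dhat) ** 2) / denom))


def _pcoa_init(values: np.ndarray, k: int) -> np.ndarray:
    a = -0.5 * values**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    w, v = np.linalg.eigh(g)
    idx = np.argsort(w)[::-1][:k]
    coords = v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))
    return coords


def nmds(
    dm: DissimilarityMatrix,
    k: int = 2,
    restarts: int = 20,
    seed: int = 0,
) -> OrdinationResult:
    """Best-of-restarts nonmetric MDS minimizing Kruskal stress-1.

    One restart is initialized from metric (principal-coordinate) scaling,
    the rest from seeded random configurations; the reported stress is
    recomputed in-package from the returned configuration, so the result is
    self-consistent by construction.
    """
    if dm.n < k + 2:
        raise InsufficientDataError(f"need >= {k + 2} samples for k={k}")
    offdiag = dm.condensed()
    if np.allclose(offdiag, offdiag[0]):
        raise DegenerateSolutionError("all dissimilarities equal; no ordination")
    rng = np.random.default_rng(seed)
    inits = [_pcoa_init(dm.values, k)]
    inits += [rng.standard_normal((dm.n, k)) for _ in range(max(0, restarts - 1))]
    best_coords, best_stress = None, np.inf
    for init in inits:
        mds = MDS(
            n_components=k,
            metric=False,
            n_init=1,
            max_iter=500,
            eps=1e-9,
            dissimilarity="precomputed",
            normalized_stress=True,
            random_state=0,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            coords = mds.fit_transform(dm.values, init=init)
        stress = kruskal_stress(dm, coords)
        if stress < best_stress:
            best_coords, best_stress = coords, stress
    return OrdinationResult(best_coords, float(best_stress), restarts, seed)


# --------------------------------------------------------------------------
# PERMANOVA

@dataclass(frozen=True)
class PermanovaResult:
    """Sequential (Type-I) partition of the Gower-centered dissimilarities."""

    table: pd.DataFrame  # rows: terms, Residual, Total; cols: df, ss, r2, F, p
    permutations: int
    seed: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "r2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _design_blocks(
    regions: np.ndarray, years: np.ndarray, terms: Sequence[str]
) -> list[tuple[str, np.ndarray]]:
    levels = sorted(set(regions))
    dummies = np.column_stack([(regions == lv).astype(float) for lv in levels])
    zyear = (years - years.mean()).astype(float)[:, None]
    blocks = []
    for term in terms:
        if term == "region":
            blocks.append((term, dummies))
        elif term == "year":
            blocks.append((term, zyear))
        elif term in ("region:year", "year:region"):
            blocks.append((term, dummies * zyear))
        else:
            raise ConfigError(f"unknown model term {term!r}")
    return blocks


def permanova(
    dm: DissimilarityMatrix,
    regions: np.ndarray | None = None,
    years: np.ndarray | None = None,
    terms: Sequence[str] = ("region", "year", "region:year"),
    permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """Permutational multivariate ANOVA with sequential sums of squares.

    Partitions G = J(-D^2/2)J (J the centering matrix) over the model
    terms in order; region enters as a categorical factor, year as a
    centered numeric covariate, and the interaction as their product.
    p-values come from free permutation of sample labels with
    p = (exceedances + 1) / (permutations + 1).
    """
    if permutations < 1:
        raise ConfigError("permutations must be >= 1")
    regions = dm.regions if regions is None else np.asarray(regions)
    years = dm.years if years is None else np.asarray(years, dtype=float)
    n = dm.n
    if len(regions) != n or len(years) != n:
        raise ValidationError("factor table must align with samples")
    a = -0.5 * dm.values**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    ss_total = float(np.trace(g))

    # sequential orthonormal basis; intercept first
    q = np.ones((n, 1)) / np.sqrt(n)
    term_bases: list[tuple[str, np.ndarray, int]] = []
    for term, block in _design_blocks(regions, years.astype(float), terms):
        b = block - q @ (q.T @ block)
        qb, rb = np.linalg.qr(b)
        keep = np.abs(np.diag(rb)) > 1e-9 * max(1.0, np.abs(rb).max())
        q_add = qb[:, keep]
        # re-orthogonalize for numerical safety
        q_add = q_add - q @ (q.T @ q_add)
        norms = np.linalg.norm(q_add, axis=0)
        q_add = q_add[:, norms > 1e-9] / np.clip(norms[norms > 1e-9], 1e-12, None)
        term_bases.append((term, q_add, q_add.shape[1]))
        if q_add.shape[1]:
            q = np.column_stack([q, q_add])

    df_terms = {t: df for t, _, df in term_bases}
    df_res = n - 1 - sum(df_terms.values())

    def partition(g_mat: np.ndarray) -> tuple[dict[str, float], float]:
        ss = {}
        for term, q_add, df in term_bases:
            ss[term] = float(np.sum(q_add * (g_mat @ q_add))) if df else 0.0
        ss_res = ss_total - sum(ss.values())
        return ss, ss_res

    ss_obs, ss_res_obs = partition(g)

    def fstats(ss: dict[str, float], ss_res: float) -> dict[str, float]:
        out = {}
        floor = 1e-12 * max(ss_total, 1.0)
        for term, df in df_terms.items():
            if df == 0 or df_res <= 0:
                out[term] = np.nan
            elif ss_res <= floor:
                # exact fit: infinite pseudo-F when the term explains anything
                out[term] = np.inf if ss[term] > floor else np.nan
            else:
                out[term] = (ss[term] / df) / (ss_res / df_res)
        return out

    f_obs = fstats(ss_obs, ss_res_obs)
    exceed = {t: 0 for t in df_terms}
    rng = np.random.default_rng(seed)
    for _ in range(int(permutations)):
        perm = rng.permutation(n)
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_res_p = partition(gp)
        f_p = fstats(ss_p, ss_res_p)
        for t in df_terms:
            if not np.isnan(f_p[t]) and f_p[t] >= f_obs[t]:
                exceed[t] += 1

    rows = []
    for term, df in df_terms.items():
        pval = (
            (exceed[term] + 1) / (permutations + 1)
            if not np.isnan(f_obs[term])
            else np.nan
        )
        rows.append(
            (term, df, ss_obs[term], ss_obs[term] / ss_total, f_obs[term], pval)
        )
    rows.append(("Residual", df_res, ss_res_obs, ss_res_obs / ss_total, np.nan, np.nan))
    rows.append(("Total", n - 1, ss_total, 1.0, np.nan, np.nan))
    table = pd.DataFrame(
        rows, columns=["term", "df", "ss", "r2", "F", "p"]
    ).set_index("term")
    return PermanovaResult(table, int(permutations), seed)


# --------------------------------------------------------------------------
# within-year similarity trend

def within_year_pairs(dm: DissimilarityMatrix) -> tuple[np.ndarray, np.ndarray]:
    """(years, BC values) over all same-year region pairs."""
    years = dm.years
    iu, ju = np.triu_indices(dm.n, k=1)
    same = years[iu] == years[ju]
    return years[iu][same], dm.values[iu, ju][same]


@dataclass(frozen=True)
class TrendResult:
    linear: RegressionResult
    piecewise: PiecewiseFit
    years: np.ndarray
    values: np.ndarray

    @property
    def n_pairs(self) -> int:
        return int(self.years.size)


def similarity_trend(dm: DissimilarityMatrix) -> TrendResult:
    """OLS and two-breakpoint fits of within-year pairwise BC against year.

    The response is the Bray-Curtis dissimilarity of each same-year region
    pair (pair-level data, not yearly averages); a negative slope means the
    regions' crop portfolios are becoming more similar (homogenization).
    """
    years, values = within_year_pairs(dm)
    if np.unique(years).size < 3:
        raise InsufficientDataError("need >= 3 distinct years for a trend")
    from scipy import stats

    res = stats.linregress(years.astype(float), values)
    linear = RegressionResult(
        float(res.slope), float(res.intercept),
        float(res.rvalue**2), float(res.pvalue), int(years.size),
    )
    pw = fit_piecewise2(years.astype(float), values)
    return TrendResult(linear, pw, years, values)
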