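"""Per-region-year alpha diversity: SR, Gini-Simpson, Faith's PD, Rao's QE.

Taxonomic metrics work at commodity-group granularity (one species per
group). Phylogenetic metrics need species on the tree, so each present
group is resolved to exactly one of its candidate species; when a group
maps to several species the choice is randomized and the reported value is
the median over replicate draws (the abundance of a group attaches to its
drawn species; two groups drawing the same species pool their areas, and
presence-based metrics use the species *set*).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from cropdiv.errors import UndefinedValueError, UnknownTaxaError, ValidationError
from cropdiv.io_fao import CommunityVector, GroupSpeciesMap, Panel
from cropdiv.phylo import DatedTree, TreeIndex

__all__ = [
    "DiversitySeries",
    "faith_pd",
    "randomized_series",
    "rao_qe",
    "series_table",
    "simpson_diversity",
    "species_richness",
]

METRICS = ("SR", "SD", "PD", "QEphy")


@dataclass(frozen=True)
class DiversitySeries:
    """Yearly values of one diversity metric D for one region."""

    region: str
    metric: str
    years: np.ndarray
    values: np.ndarray
    n_rep: int = 1

    def __post_init__(self):
        years = np.asarray(self.years, dtype=int)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "values", values)
        if years.size != values.size:
            raise ValidationError("years and values must be parallel")
        if years.size > 1 and not (np.diff(years) > 0).all():
            raise ValidationError("years must be strictly increasing")
        if self.metric not in METRICS:
            raise ValidationError(f"unknown metric {self.metric!r}")

    def __len__(self) -> int:
        return len(self.years)


def species_richness(c: CommunityVector) -> int:
    """Number of taxa present (abundance > 0)."""
    return c.richness


def simpson_diversity(c: CommunityVector) -> float:
    """Gini-Simpson index 1 - sum(p_i^2); 0 = single taxon, ->1 with evenness."""
    if c.richness == 0:
        raise UndefinedValueError("Simpson diversity undefined for an empty community")
    p = c.proportions
    return float(1.0 - np.sum(p * p))


def _resolve_draw(
    c: CommunityVector,
    mapping: GroupSpeciesMap,
    draw: Mapping[str, str],
) -> tuple[list[str], np.ndarray]:
    """Species and pooled areas for a one-species-per-group assignment."""
    pooled: dict[str, float] = {}
    for group, area in zip(c.taxa, c.abundances):
        if area <= 0:
            continue
        if group not in mapping:
            raise ValidationError(f"group {group!r} missing from species mapping")
        species = draw[group]
        if species not in mapping[group]:
            raise ValidationError(
                f"draw assigns {species!r} to group {group!r}, not a candidate"
            )
        pooled[species] = pooled.get(species, 0.0) + float(area)
    labels = sorted(pooled)
    return labels, np.array([pooled[s] for s in labels])


def _as_index(tree: DatedTree | TreeIndex) -> TreeIndex:
    return tree if isinstance(tree, TreeIndex) else TreeIndex.from_tree(tree)


def faith_pd(
    tree: DatedTree | TreeIndex,
    c: CommunityVector,
    mapping: GroupSpeciesMap,
    draw: Mapping[str, str],
) -> float:
    """Faith's PD (My) of the species drawn for the present groups.

    Sum of branch lengths of the minimal subtree connecting the drawn
    species set to the root; duplicate draws count once (set semantics).
    """
    if c.richness == 0:
        return 0.0
    index = _as_index(tree)
    labels, _ = _resolve_draw(c, mapping, draw)
    lut = index.index_of
    unknown = [s for s in labels if s not in lut]
    if unknown:
        raise UnknownTaxaError(unknown)
    return index.pd(np.array([lut[s] for s in labels], dtype=int))


def rao_qe(
    tree: DatedTree | TreeIndex,
    c: CommunityVector,
    mapping: GroupSpeciesMap,
    draw: Mapping[str, str],
) -> float:
    """Rao's quadratic entropy (My): sum_{i != j} d_ij p_i p_j.

    d_ij is the patristic distance between drawn species; p_i are area
    proportions after pooling duplicate draws.
    """
    if c.richness == 0:
        raise UndefinedValueError("QE undefined for an empty community")
    index = _as_index(tree)
    labels, areas = _resolve_draw(c, mapping, draw)
    lut = index.index_of
    unknown = [s for s in labels if s not in lut]
    if unknown:
        raise UnknownTaxaError(unknown)
    idx = np.array([lut[s] for s in labels], dtype=int)
    p = areas / areas.sum()
    d = index.distances[np.ix_(idx, idx)]
    return float(p @ d @ p)  # diagonal is zero, so i == j contributes nothing


def _substream(seed: int, *key: int) -> np.random.Generator:
    """Deterministic named substream of a master seed (parallel-safe)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(key)))


def randomized_series(
    panel: Panel,
    region: str,
    tree: DatedTree | TreeIndex,
    mapping: GroupSpeciesMap,
    n_rep: int = 100,
    seed: int = 0,
    per_year_draw: bool = True,
) -> tuple[DiversitySeries, DiversitySeries]:
    """Median PD and QE series over replicate one-species-per-group draws.

    Per replicate (and, by default, independently per year) each present
    group draws one of its candidate species uniformly at random; the
    reported value per year is the median over replicates (even counts:
    midpoint of the two central order statistics). ``per_year_draw=False``
    holds one assignment per replicate across the whole series. Seeded runs
    are reproducible: each (region, year, replicate) uses a deterministic
    substream of the master seed.
    """
    if n_rep < 1:
        raise ValidationError("n_rep must be >= 1")
    index = _as_index(tree)
    years = panel.years(region)
    region_key = zlib.crc32(region.encode("utf-8")) & 0x7FFFFFFF
    pd_rows = np.empty((len(years), n_rep))
    qe_rows = np.empty((len(years), n_rep))
    for yi, year in enumerate(years):
        c = panel.community(region, year)
        groups = c.taxa
        for rep in range(n_rep):
            if per_year_draw:
                rng = _substream(seed, region_key, int(year), rep)
            else:
                rng = _substream(seed, region_key, rep)
            draw = {
                g: mapping[g][rng.integers(len(mapping[g]))] if len(mapping[g]) > 1
                else mapping[g][0]
                for g in groups
            }
            pd_rows[yi, rep] = faith_pd(index, c, mapping, draw) if groups else 0.0
            qe_rows[yi, rep] = rao_qe(index, c, mapping, draw) if groups else 0.0
    years_arr = np.asarray(years, dtype=int)
    pd_series = DiversitySeries(
        region, "PD", years_arr, np.median(pd_rows, axis=1), n_rep=n_rep
    )
    qe_series = DiversitySeries(
        region, "QEphy", years_arr, np.median(qe_rows, axis=1), n_rep=n_rep
    )
    return pd_series, qe_series


def taxonomic_series(panel: Panel, region: str) -> tuple[DiversitySeries, DiversitySeries]:
    """SR and Gini-Simpson series at commodity-group granularity."""
    years = panel.years(region)
    sr = np.empty(len(years))
    sd = np.empty(len(years))
    for yi, year in enumerate(years):
        c = panel.community(region, year)
        sr[yi] = species_richness(c)
        sd[yi] = simpson_diversity(c) if c.richness else np.nan
    years_arr = np.asarray(years, dtype=int)
    return (
        DiversitySeries(region, "SR", years_arr, sr),
        DiversitySeries(region, "SD", years_arr, sd),
    )


def series_table(series: list[DiversitySeries], seed: int | None = None) -> pd.DataFrame:
    """Tidy (region, year, metric, value, n_rep[, seed]) table for downstream fits."""
    frames = []
    for s in series:
        df = pd.DataFrame(
            {
                "region": s.region,
                "year": s.years,
                "metric": s.metric,
                "value": s.values,
                "n_rep": s.n_rep,
            }
        )
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if seed is not None:
        out["seed"] = seed
    return out
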