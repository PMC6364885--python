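"""Synthetic panels, trees, and mappings with known ground truth.

The generator emulates the statistical structure the pipeline assumes:
~22 regions observed over 54 calendar years across a pool of ~157
commodity groups, piecewise-linear richness trajectories with known
breakpoints, heavy-tailed (log-normal) area distributions, region-specific
crop pools realized as preference orderings (so richness changes produce
nested, persistent gains rather than random churn, matching how new
commodity groups appear once and persist in FAO reporting), and one region
with a truncated year range. Multi-species commodity groups (default 20%
of the pool with 2-5 candidate species) exercise the one-species-per-group
randomization.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from cropdiv.errors import ValidationError
from cropdiv.io_fao import GroupSpeciesMap, Panel
from cropdiv.phylo import AgeTable, DatedTree

__all__ = [
    "PanelScenario",
    "ScenarioSpec",
    "TreeScenario",
    "generate_homogenization_panel",
    "generate_panel",
    "generate_tree",
    "write_scenario",
]


def eq3(year, a, b, c, d, psi1, psi2):
    """Two-breakpoint piecewise-linear mean function."""
    year = np.asarray(year, dtype=float)
    return (
        a
        + b * year
        + c * np.clip(year - psi1, 0.0, None)
        + d * np.clip(year - psi2, 0.0, None)
    )


@dataclass(frozen=True)
class ScenarioSpec:
    """Study conditions for a synthetic panel.

    Defaults mirror the dimensions of the real area-harvested panel the
    pipeline targets: 22 regions, years 1961-2014, 157 commodity groups,
    337 species, one region truncated to 1992 onward. Per-region richness
    trajectories are two-breakpoint piecewise-linear; when ``trajectories``
    is None they are drawn from realistic ranges (flat-ish before a
    1975-1987 onset, a 5-15 year diversification burst of 1-3 groups/year,
    then a levelling-off).
    """

    n_regions: int = 22
    year_start: int = 1961
    year_end: int = 2014
    pool_size: int = 157
    species_pool: int = 337
    trajectories: Sequence[Mapping[str, float]] | None = None
    noise_sd: float = 2.0
    log_area_mean: float = 9.0
    log_area_sd: float = 2.0
    multi_species_frac: float = 0.2
    multi_species_range: tuple[int, int] = (2, 5)
    truncated_region: bool = True
    truncated_start: int = 1992
    seed: int = 0

    def __post_init__(self):
        if self.year_start >= self.year_end:
            raise ValidationError("year range must be non-empty")
        if self.noise_sd < 0 or self.log_area_sd < 0:
            raise ValidationError("standard deviations must be >= 0")
        if self.trajectories is not None:
            if len(self.trajectories) != self.n_regions:
                raise ValidationError("one trajectory per region required")
            for tr in self.trajectories:
                if not (self.year_start < tr["psi1"] < tr["psi2"] < self.year_end):
                    raise ValidationError(
                        "breakpoints must satisfy start < psi1 < psi2 < end"
                    )


@dataclass(frozen=True)
class PanelScenario:
    """A generated panel with its mapping and exact ground truth."""

    panel: Panel
    mapping: GroupSpeciesMap
    truth: pd.DataFrame  # region, a, b, c, d, psi1, psi2, start_year


def _region_names(n: int) -> list[str]:
    return [f"region{r:02d}" for r in range(n)]


def _draw_trajectories(spec: ScenarioSpec, rng: np.random.Generator):
    out = []
    for _ in range(spec.n_regions):
        psi1 = rng.uniform(1975.0, 1987.0)
        psi2 = psi1 + rng.uniform(5.0, 15.0)
        slope0 = rng.uniform(-0.1, 0.2)
        burst = rng.uniform(1.0, 3.0)
        a0 = rng.uniform(40.0, 80.0)
        # parameterize so richness at year_start is a0
        a = a0 - slope0 * spec.year_start
        c = burst - slope0
        d = -burst + rng.uniform(-0.1, 0.2)
        out.append(
            {"a": a, "b": slope0, "c": c, "d": d, "psi1": psi1, "psi2": min(psi2, spec.year_end - 3)}
        )
    return out


def _generate_mapping(spec: ScenarioSpec, rng: np.random.Generator) -> GroupSpeciesMap:
    groups = [f"grp{g:03d}" for g in range(spec.pool_size)]
    n_multi = int(round(spec.multi_species_frac * spec.pool_size))
    multi = set(rng.choice(spec.pool_size, size=n_multi, replace=False).tolist())
    entries: dict[str, list[str]] = {}
    species_counter = 0

    def next_species():
        nonlocal species_counter
        name = f"sp{species_counter:04d}"
        species_counter += 1
        return name

    lo, hi = spec.multi_species_range
    for gi, group in enumerate(groups):
        k = int(rng.integers(lo, hi + 1)) if gi in multi else 1
        entries[group] = [next_species() for _ in range(k)]
    return GroupSpeciesMap(entries)


def _panel_from_presence(
    spec: ScenarioSpec,
    rng: np.random.Generator,
    present_fn,
) -> tuple[Panel, list[str]]:
    """Assemble records given a (region index, year) -> present groups callable."""
    regions = _region_names(spec.n_regions)
    rows = []
    coverage = {}
    for ri, region in enumerate(regions):
        start = (
            spec.truncated_start
            if spec.truncated_region and ri == spec.n_regions - 1
            else spec.year_start
        )
        years = range(start, spec.year_end + 1)
        coverage[region] = set(years)
        for year in years:
            for group in present_fn(ri, year):
                area = float(rng.lognormal(spec.log_area_mean, spec.log_area_sd))
                rows.append((region, year, group, max(area, 1e-6)))
    df = pd.DataFrame(rows, columns=["region", "year", "group", "area"])
    return Panel(df, coverage=coverage), regions


def generate_panel(spec: ScenarioSpec) -> PanelScenario:
    """Generate a panel whose per-region richness follows known breakpoints.

    Target richness per region-year is the piecewise-linear trajectory plus
    Gaussian noise, rounded and clamped to [1, pool]; the groups present
    are the first k of a per-region preference ordering, so composition
    turns over gradually and gains persist. Same seed, same panel.
    """
    rng = np.random.default_rng(spec.seed)
    trajectories = (
        list(spec.trajectories)
        if spec.trajectories is not None
        else _draw_trajectories(spec, rng)
    )
    years_all = np.arange(spec.year_start, spec.year_end + 1)
    for tr in trajectories:
        richness = eq3(years_all, **tr)
        if richness.max() > spec.pool_size:
            raise ValidationError(
                f"trajectory exceeds group pool ({richness.max():.1f} > {spec.pool_size})"
            )
    mapping = _generate_mapping(spec, rng)
    orderings = [
        rng.permutation(spec.pool_size) for _ in range(spec.n_regions)
    ]
    groups = [f"grp{g:03d}" for g in range(spec.pool_size)]

    noise = {
        ri: rng.normal(0.0, spec.noise_sd, size=years_all.size)
        for ri in range(spec.n_regions)
    }

    def present(ri: int, year: int):
        tr = trajectories[ri]
        target = eq3(year, **tr) + noise[ri][year - spec.year_start]
        k = int(np.clip(round(float(target)), 1, spec.pool_size))
        return [groups[g] for g in orderings[ri][:k]]

    panel, regions = _panel_from_presence(spec, rng, present)
    truth = pd.DataFrame(
        [
            {
                "region": regions[ri],
                **trajectories[ri],
                "start_year": (
                    spec.truncated_start
                    if spec.truncated_region and ri == spec.n_regions - 1
                    else spec.year_start
                ),
            }
            for ri in range(spec.n_regions)
        ]
    )
    return PanelScenario(panel, mapping, truth)


def generate_homogenization_panel(
    spec: ScenarioSpec,
    window: tuple[int, int] = (1983, 1992),
    richness: int = 40,
) -> PanelScenario:
    """Panel whose region crop pools converge linearly across a window.

    Each region's preference scores interpolate toward a common ordering
    over ``window``: before it regions grow distinct crop sets, after it
    nearly identical ones, so within-year Bray-Curtis declines over the
    window (emulating cross-region homogenization with a known timing).
    """
    if not (spec.year_start <= window[0] < window[1] <= spec.year_end):
        raise ValidationError("convergence window must lie inside the year range")
    rng = np.random.default_rng(spec.seed)
    mapping = _generate_mapping(spec, rng)
    groups = [f"grp{g:03d}" for g in range(spec.pool_size)]
    common = rng.standard_normal(spec.pool_size)
    regional = [
        rng.standard_normal(spec.pool_size) for _ in range(spec.n_regions)
    ]

    def weight(year: int) -> float:
        if window[1] == window[0]:
            return 0.0
        return float(np.clip((year - window[0]) / (window[1] - window[0]), 0.0, 1.0))

    def present(ri: int, year: int):
        w = weight(year)
        scores = (1.0 - w) * regional[ri] + w * common
        top = np.argsort(-scores, kind="stable")[:richness]
        return [groups[g] for g in top]

    panel, regions = _panel_from_presence(spec, rng, present)
    truth = pd.DataFrame(
        {
            "region": regions,
            "window_start": window[0],
            "window_end": window[1],
            "richness": richness,
        }
    )
    return PanelScenario(panel, mapping, truth)


# --------------------------------------------------------------------------
# trees

@dataclass(frozen=True)
class TreeScenario:
    """A generated dated tree, the exposed age table, and full true ages."""

    tree: DatedTree
    ages: AgeTable
    true_ages: dict[str, float]


def generate_tree(
    n_taxa: int,
    root_age: float = 150.0,
    seed: int = 0,
    dated_fraction: float = 1.0,
    taxon_labels: Sequence[str] | None = None,
) -> TreeScenario:
    """Random bifurcating dated tree by sequential random joins.

    True node ages are drawn top-down uniformly in (0, parent age), giving
    ancestor > descendant everywhere; the exposed :class:`AgeTable` covers
    a ``dated_fraction`` of internal nodes (the root always), which makes
    interpolation round-trips testable against the withheld true ages.
    """
    if n_taxa < 2:
        raise ValidationError("need >= 2 taxa")
    if root_age <= 0:
        raise ValidationError("root age must be > 0")
    rng = np.random.default_rng(seed)
    labels = (
        list(taxon_labels)
        if taxon_labels is not None
        else [f"sp{t:04d}" for t in range(n_taxa)]
    )
    if len(labels) != n_taxa:
        raise ValidationError("taxon_labels length must equal n_taxa")

    taxa = dendropy.TaxonNamespace()
    tree = dendropy.Tree(taxon_namespace=taxa)
    subtrees = []
    for label in labels:
        node = dendropy.Node()
        node.taxon = taxa.new_taxon(label)
        subtrees.append(node)
    internal_counter = 0
    while len(subtrees) > 1:
        i, j = sorted(rng.choice(len(subtrees), size=2, replace=False))
        right = subtrees.pop(j)
        left = subtrees.pop(i)
        parent = dendropy.Node()
        parent.label = f"node{internal_counter:03d}"
        internal_counter += 1
        parent.add_child(left)
        parent.add_child(right)
        subtrees.append(parent)
    root = subtrees[0]
    root.label = "root"
    tree.seed_node = root

    true_ages: dict[str, float] = {}
    root.age = float(root_age)
    true_ages["root"] = float(root_age)
    for node in tree.preorder_node_iter():
        if node is root:
            continue
        if node.is_leaf():
            node.age = 0.0
        else:
            node.age = float(rng.uniform(0.0, node.parent_node.age))
            true_ages[node.label] = node.age

    internal = [lbl for lbl in true_ages if lbl != "root"]
    n_dated = int(round(dated_fraction * len(internal)))
    dated = set(rng.choice(internal, size=n_dated, replace=False).tolist()) if n_dated else set()
    exposed = {"root": root_age}
    exposed.update({lbl: true_ages[lbl] for lbl in dated})
    return TreeScenario(DatedTree(tree, dated=True), AgeTable(exposed), true_ages)


def write_scenario(scenario: PanelScenario, outdir, sep: str = ",") -> dict[str, str]:
    """Write panel, mapping, and truth as the delimited formats the readers use."""
    import os

    os.makedirs(outdir, exist_ok=True)
    paths = {}
    panel_path = os.path.join(outdir, "panel.csv")
    rec = scenario.panel.records
    rec["Element"] = "Area harvested"
    rec = rec.rename(
        columns={"region": "Area", "year": "Year", "group": "Item", "area": "Value"}
    )
    rec.to_csv(panel_path, index=False, sep=sep)
    paths["panel"] = panel_path
    map_path = os.path.join(outdir, "mapping.csv")
    rows = [
        {"group": g, "species": s}
        for g in scenario.mapping.groups
        for s in scenario.mapping[g]
    ]
    pd.DataFrame(rows).to_csv(map_path, index=False, sep=sep)
    paths["mapping"] = map_path
    truth_path = os.path.join(outdir, "truth.csv")
    scenario.truth.to_csv(truth_path, index=False, sep=sep)
    paths["truth"] = truth_path
    return paths
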