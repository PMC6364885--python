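"""Reading and validating area-harvested panels (FAOSTAT long-format dialect).

The panel holds one non-negative area (hectares) per (region, year,
commodity-group) key. Zero or missing areas are absences: FAO omits crops
that are not grown rather than reporting zeros, so a missing row and an
explicit zero are treated identically. A region's year coverage is tracked
separately from its positive records so that "region-year observed but
nothing grown" (empty community) is distinguishable from "region-year not in
the data" (lookup error).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from cropdiv.errors import PanelLookupError, SchemaError, ValidationError

__all__ = [
    "CommunityVector",
    "GroupSpeciesMap",
    "Panel",
    "PanelDialect",
    "read_dialect",
    "read_group_species_map",
    "read_panel",
]


@dataclass(frozen=True)
class CommunityVector:
    """One region-year community: taxa present and their areas (ha).

    Taxa are ordered lexicographically; a taxon is present iff its
    abundance is strictly positive. Abundance proportions p_i =
    abundance_i / total are the weights used by the abundance-sensitive
    diversity metrics.
    """

    taxa: tuple[str, ...]
    abundances: np.ndarray

    def __post_init__(self):
        ab = np.asarray(self.abundances, dtype=float)
        object.__setattr__(self, "abundances", ab)
        object.__setattr__(self, "taxa", tuple(self.taxa))
        if len(self.taxa) != ab.size:
            raise ValidationError("taxa and abundances must be parallel")
        if ab.size and (ab < 0).any():
            raise ValidationError("community abundances must be non-negative")

    def __len__(self) -> int:
        return len(self.taxa)

    @property
    def richness(self) -> int:
        """Number of taxa present (abundance strictly positive)."""
        return int(np.count_nonzero(self.abundances > 0))

    @property
    def present(self) -> tuple[str, ...]:
        return tuple(t for t, a in zip(self.taxa, self.abundances) if a > 0)

    @property
    def total(self) -> float:
        return float(self.abundances.sum())

    @property
    def proportions(self) -> np.ndarray:
        return self.abundances / self.abundances.sum()


class GroupSpeciesMap:
    """Commodity-group -> ordered list of candidate crop species."""

    def __init__(self, entries: Mapping[str, Sequence[str]]):
        clean: dict[str, tuple[str, ...]] = {}
        for group, species in entries.items():
            sp = tuple(str(s).strip() for s in species)
            if not sp:
                raise ValidationError(f"group {group!r} maps to no species")
            if len(set(sp)) != len(sp):
                raise ValidationError(f"group {group!r} lists duplicate species")
            clean[str(group).strip()] = sp
        self._entries = clean

    def __getitem__(self, group: str) -> tuple[str, ...]:
        return self._entries[group]

    def __contains__(self, group: str) -> bool:
        return group in self._entries

    def __len__(self) -> int:
        return len(self._entries)

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self._entries))

    @property
    def species(self) -> tuple[str, ...]:
        out: set[str] = set()
        for sp in self._entries.values():
            out.update(sp)
        return tuple(sorted(out))

    def require(self, groups: Iterable[str]) -> None:
        """Raise if any of *groups* is missing from the mapping."""
        missing = sorted(set(groups) - set(self._entries))
        if missing:
            raise ValidationError(
                f"groups without a species mapping: {', '.join(missing)}"
            )

    def restricted_to(
        self, taxa: Iterable[str], drop_missing: bool = False
    ) -> "GroupSpeciesMap":
        """Mapping limited to species in *taxa* (e.g. tips of the tree).

        By default any species outside *taxa* is a hard error — silently
        dropping taxa would bias phylogenetic metrics downward invisibly.
        With ``drop_missing=True`` the offenders are dropped with a warning;
        a group losing all candidates is removed entirely.
        """
        taxa = set(taxa)
        missing = sorted(set(self.species) - taxa)
        if missing and not drop_missing:
            raise ValidationError(
                f"species absent from the tree: {', '.join(missing[:10])}"
                + ("..." if len(missing) > 10 else "")
            )
        entries: dict[str, tuple[str, ...]] = {}
        dropped_groups = []
        for group, species in self._entries.items():
            kept = tuple(s for s in species if s in taxa)
            if kept:
                entries[group] = kept
            else:
                dropped_groups.append(group)
        if missing:
            warnings.warn(
                f"dropped {len(missing)} species absent from the tree"
                + (f" and {len(dropped_groups)} now-empty groups" if dropped_groups else ""),
                stacklevel=2,
            )
        return GroupSpeciesMap(entries)


@dataclass
class PanelDialect:
    """Column naming and element filter for a long-format panel file."""

    region_col: str = "Area"
    year_col: str = "Year"
    item_col: str = "Item"
    element_col: str = "Element"
    value_col: str = "Value"
    element: str = "Area harvested"
    sep: str | None = None  # None => sniff comma vs tab


class Panel:
    """Area-harvested records keyed by (region, year, commodity group).

    Only strictly positive areas are stored; the year coverage per region
    records which region-years were observed at all (so empty communities
    remain queryable). Years within a region are expected to be contiguous;
    interior gaps are permitted but reported by :meth:`gap_years`.
    """

    def __init__(
        self,
        records: pd.DataFrame,
        coverage: Mapping[str, Iterable[int]] | None = None,
    ):
        required = {"region", "year", "group", "area"}
        missing = required - set(records.columns)
        if missing:
            raise SchemaError(f"panel records missing columns: {sorted(missing)}")
        df = records.loc[:, ["region", "year", "group", "area"]].copy()
        df["region"] = df["region"].astype(str).str.strip()
        df["group"] = df["group"].astype(str).str.strip()
        df["year"] = df["year"].astype(int)
        df["area"] = df["area"].astype(float)
        if (df["area"] < 0).any():
            bad = df.loc[df["area"] < 0].iloc[0]
            raise ValidationError(
                f"negative area {bad['area']} for "
                f"({bad['region']}, {bad['year']}, {bad['group']})"
            )
        dup = df.duplicated(["region", "year", "group"])
        if dup.any():
            bad = df.loc[dup].iloc[0]
            raise ValidationError(
                "duplicate record for "
                f"({bad['region']}, {bad['year']}, {bad['group']})"
            )
        if coverage is None:
            cov = {
                r: frozenset(g["year"].tolist())
                for r, g in df.groupby("region", sort=False)
            }
        else:
            cov = {str(r).strip(): frozenset(int(y) for y in ys) for r, ys in coverage.items()}
            extra = set(df["region"]) - set(cov)
            if extra:
                raise ValidationError(f"records outside declared coverage: {sorted(extra)}")
        self._coverage: dict[str, frozenset[int]] = cov
        # absences are not stored
        df = df.loc[df["area"] > 0].reset_index(drop=True)
        self._df = df.sort_values(["region", "year", "group"], kind="mergesort").reset_index(drop=True)

    # -- introspection -------------------------------------------------

    @property
    def records(self) -> pd.DataFrame:
        """Positive-area records (region, year, group, area), sorted."""
        return self._df.copy()

    @property
    def regions(self) -> tuple[str, ...]:
        return tuple(sorted(self._coverage))

    def years(self, region: str) -> tuple[int, ...]:
        if region not in self._coverage:
            raise PanelLookupError(region)
        return tuple(sorted(self._coverage[region]))

    @property
    def groups(self) -> tuple[str, ...]:
        return tuple(sorted(self._df["group"].unique()))

    def gap_years(self, region: str) -> tuple[int, ...]:
        """Years missing inside the region's observed min..max range."""
        ys = self.years(region)
        if not ys:
            return ()
        full = set(range(ys[0], ys[-1] + 1))
        return tuple(sorted(full - set(ys)))

    # -- queries -------------------------------------------------------

    def _check_key(self, region: str, year: int) -> None:
        if region not in self._coverage:
            raise PanelLookupError(f"unknown region {region!r}")
        if int(year) not in self._coverage[region]:
            raise PanelLookupError(f"year {year} not covered for region {region!r}")

    def community(self, region: str, year: int) -> CommunityVector:
        """Community vector (lexicographic taxa, positive areas) for a region-year."""
        self._check_key(region, year)
        sel = self._df[(self._df["region"] == region) & (self._df["year"] == int(year))]
        return CommunityVector(tuple(sel["group"]), sel["area"].to_numpy())

    def present_groups(self, region: str, year: int) -> frozenset[str]:
        return frozenset(self.community(region, year).taxa)

    def net_group_change(self, region: str, first: int, last: int) -> int:
        """Count of groups present in *last* minus count present in *first*."""
        return len(self.present_groups(region, last)) - len(
            self.present_groups(region, first)
        )

    # -- export --------------------------------------------------------

    def to_wide(self) -> pd.DataFrame:
        """Region-year x group area matrix (absences as 0), for audit output."""
        wide = self._df.pivot_table(
            index=["region", "year"], columns="group", values="area", fill_value=0.0
        )
        return wide.sort_index()

    def write_wide(self, path, sep: str = ",") -> None:
        self.to_wide().to_csv(path, sep=sep)


def _sniff_sep(path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") >= header.count(",") and "\t" in header else ","


def read_panel(path, dialect: PanelDialect | None = None) -> Panel:
    """Read a long-format area-harvested file into a :class:`Panel`.

    Keeps only rows of the dialect's element ("Area harvested" by default);
    zero/missing values become absences; duplicate (region, year, group)
    rows raise a :class:`ValidationError`.
    """
    dialect = dialect or PanelDialect()
    sep = dialect.sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    colmap = {
        dialect.region_col: "region",
        dialect.year_col: "year",
        dialect.item_col: "group",
        dialect.value_col: "area",
    }
    missing = [c for c in colmap if c not in df.columns]
    if dialect.element_col not in df.columns:
        missing.append(dialect.element_col)
    if missing:
        raise SchemaError(f"missing required columns: {missing}")
    df = df[df[dialect.element_col].astype(str).str.strip() == dialect.element]
    df = df.rename(columns=colmap).loc[:, ["region", "year", "group", "area"]]
    df["area"] = pd.to_numeric(df["area"], errors="coerce")
    # coverage includes zero/NaN observations; records keep only positives
    df["region"] = df["region"].astype(str).str.strip()
    dupes = df.duplicated(["region", "year", "group"])
    if dupes.any():
        bad = df.loc[dupes].iloc[0]
        raise ValidationError(
            f"duplicate rows for ({bad['region']}, {bad['year']}, {bad['group']})"
        )
    coverage = {r: set(g["year"].astype(int)) for r, g in df.groupby("region")}
    df = df.dropna(subset=["area"])
    if (df["area"] < 0).any():
        raise ValidationError("negative area harvested encountered")
    panel = Panel(df[df["area"] > 0], coverage=coverage)
    for region in panel.regions:
        gaps = panel.gap_years(region)
        if gaps:
            warnings.warn(
                f"region {region!r} has missing years inside its range: {gaps}",
                stacklevel=2,
            )
    return panel


def read_group_species_map(path, sep: str | None = None) -> GroupSpeciesMap:
    """Read a two-column (group, species) table; one row per species."""
    sep = sep or _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, comment="#")
    cols = {c.lower(): c for c in df.columns}
    try:
        gcol, scol = cols["group"], cols["species"]
    except KeyError as exc:
        raise SchemaError("mapping file needs 'group' and 'species' columns") from exc
    entries: dict[str, list[str]] = {}
    for g, s in zip(df[gcol], df[scol]):
        entries.setdefault(str(g).strip(), []).append(str(s).strip())
    return GroupSpeciesMap(entries)


def read_dialect(path) -> PanelDialect:
    """Read a key=value config file declaring the panel dialect."""
    kwargs = {}
    valid = set(PanelDialect.__dataclass_fields__)
    with open(path, "r", encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            if "=" not in line:
                raise SchemaError(f"malformed dialect line: {line!r}")
            key, value = (part.strip() for part in line.split("=", 1))
            if key not in valid:
                raise SchemaError(f"unknown dialect key: {key!r}")
            kwargs[key] = value
    return PanelDialect(**kwargs)
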