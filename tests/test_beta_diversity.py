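import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cropdiv.beta_diversity import (
    DissimilarityMatrix,
    bray_curtis,
    dissimilarity_matrix,
    kruskal_stress,
    nmds,
    permanova,
    similarity_trend,
    within_year_pairs,
)
from cropdiv.errors import (
    DegenerateSolutionError,
    InsufficientDataError,
    UndefinedValueError,
)
from cropdiv.io_fao import CommunityVector, Panel
from cropdiv.synthetic_data import ScenarioSpec, generate_panel


def community(**areas) -> CommunityVector:
    taxa = tuple(sorted(areas))
    return CommunityVector(taxa, [areas[t] for t in taxa])


class TestBrayCurtis:
    def test_identical_communities(self):
        c = community(a=3.0, b=5.0)
        assert bray_curtis(c, c) == 0.0

    def test_disjoint_support(self):
        assert bray_curtis(community(a=3.0), community(b=9.0)) == 1.0

    def test_hand_value(self):
        # |6-2| + |2-2| = 4 over 6+2+2+2 = 12
        x = community(a=6.0, b=2.0)
        y = community(a=2.0, b=2.0)
        assert bray_curtis(x, y) == pytest.approx(4.0 / 12.0)

    def test_both_empty_undefined(self):
        with pytest.raises(UndefinedValueError):
            bray_curtis(CommunityVector((), []), CommunityVector((), []))

    @given(
        xs=st.lists(st.floats(0.0, 1e5), min_size=1, max_size=8),
        ys=st.lists(st.floats(0.0, 1e5), min_size=1, max_size=8),
    )
    @settings(max_examples=60, deadline=None)
    def test_bounds_and_taxon_permutation_invariance(self, xs, ys):
        if sum(xs) + sum(ys) == 0:
            return
        taxa = tuple(f"t{i}" for i in range(max(len(xs), len(ys))))
        x = CommunityVector(taxa[: len(xs)], xs)
        y = CommunityVector(taxa[: len(ys)], ys)
        bc = bray_curtis(x, y)
        assert 0.0 <= bc <= 1.0
        x_perm = CommunityVector(x.taxa[::-1], x.abundances[::-1])
        assert bray_curtis(x_perm, y) == pytest.approx(bc, rel=1e-12)
        assert bray_curtis(y, x) == pytest.approx(bc, rel=1e-12)


def small_panel(rows):
    return Panel(pd.DataFrame(rows, columns=["region", "year", "group", "area"]))


class TestDissimilarityMatrix:
    def test_two_samples_match_direct_computation(self):
        panel = small_panel(
            [("r1", 2000, "a", 6.0), ("r1", 2000, "b", 2.0),
             ("r2", 2000, "a", 2.0), ("r2", 2000, "b", 2.0)]
        )
        dm = dissimilarity_matrix(panel)
        direct = bray_curtis(panel.community("r1", 2000), panel.community("r2", 2000))
        assert dm.values[0, 1] == pytest.approx(direct)

    def test_row_order_invariance(self):
        rows = [("r1", 2000, "a", 6.0), ("r2", 2000, "a", 2.0),
                ("r1", 2001, "b", 3.0), ("r2", 2001, "b", 4.0)]
        dm1 = dissimilarity_matrix(small_panel(rows))
        dm2 = dissimilarity_matrix(small_panel(rows[::-1]))
        assert dm1.labels == dm2.labels
        assert np.array_equal(dm1.values, dm2.values)

    def test_empty_community_excluded_with_warning(self):
        panel = Panel(
            pd.DataFrame(
                [("r1", 2000, "a", 1.0), ("r2", 2000, "a", 2.0)],
                columns=["region", "year", "group", "area"],
            ),
            coverage={"r1": [2000, 2001], "r2": [2000]},
        )
        with pytest.warns(UserWarning, match="empty"):
            dm = dissimilarity_matrix(panel)
        assert dm.n == 2

    def test_within_year_pair_count_identity_small(self):
        # R regions over Y years, one truncated to y years:
        # pairs = (Y-y)*C(R-1,2) + y*C(R,2)
        spec = ScenarioSpec(
            n_regions=5, year_start=2000, year_end=2009, pool_size=30,
            trajectories=[dict(a=5.0, b=0.0, c=0.5, d=-0.5,
                               psi1=2003.0, psi2=2006.0)] * 5,
            noise_sd=0.0, truncated_region=True, truncated_start=2006, seed=3,
        )
        sc = generate_panel(spec)
        dm = dissimilarity_matrix(sc.panel)
        years, values = within_year_pairs(dm)
        R, Y, y = 5, 10, 4
        expected = (Y - y) * (R - 1) * (R - 2) // 2 + y * R * (R - 1) // 2
        assert years.size == expected
        assert dm.n == (R - 1) * Y + y


class TestNMDS:
    def planar_square_dm(self):
        pts = np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]])
        from scipy.spatial.distance import pdist, squareform

        d = squareform(pdist(pts)) / 2.0
        labels = tuple((f"r{i}", 2000) for i in range(4))
        return DissimilarityMatrix(labels, d)

    def test_embeddable_configuration_has_near_zero_stress(self):
        res = nmds(self.planar_square_dm(), k=2, restarts=8, seed=1)
        assert res.stress < 1e-3

    def test_more_restarts_never_increase_best_stress(self):
        rng = np.random.default_rng(5)
        n = 10
        raw = rng.uniform(0.2, 1.0, size=(n, n))
        d = np.clip((raw + raw.T) / 2.0, 0, 1)
        np.fill_diagonal(d, 0.0)
        labels = tuple((f"r{i}", 2000) for i in range(n))
        dm = DissimilarityMatrix(labels, d)
        s_few = nmds(dm, restarts=2, seed=9).stress
        s_many = nmds(dm, restarts=6, seed=9).stress
        assert s_many <= s_few + 1e-12

    def test_reported_stress_recomputes_from_configuration(self):
        dm = self.planar_square_dm()
        res = nmds(dm, k=2, restarts=4, seed=2)
        assert kruskal_stress(dm, res.coordinates) == pytest.approx(res.stress)

    def test_cluster_recovery(self):
        # two groups of samples: within-BC small, between-BC large
        n = 12
        d = np.full((n, n), 0.9)
        for block in (slice(0, 6), slice(6, 12)):
            d[block, block] = 0.1
        np.fill_diagonal(d, 0.0)
        labels = tuple((f"r{i}", 2000) for i in range(n))
        res = nmds(DissimilarityMatrix(labels, d), restarts=6, seed=3)
        coords = res.coordinates
        from scipy.spatial.distance import cdist

        within = np.concatenate(
            [cdist(coords[:6], coords[:6]).ravel(), cdist(coords[6:], coords[6:]).ravel()]
        )
        between = cdist(coords[:6], coords[6:]).ravel()
        frac = np.mean(between[:, None] > within[None, :])
        assert frac >= 0.95

    def test_degenerate_equal_dissimilarities(self):
        n = 5
        d = np.full((n, n), 0.5)
        np.fill_diagonal(d, 0.0)
        labels = tuple((f"r{i}", 2000) for i in range(n))
        with pytest.raises(DegenerateSolutionError):
            nmds(DissimilarityMatrix(labels, d), seed=0)


class TestPermanova:
    def two_cluster_dm(self):
        labels = tuple(
            (g, 2000) for g in ["A1", "A2", "A3", "B1", "B2", "B3"]
        )
        v = np.zeros((6, 6))
        v[:3, 3:] = 1.0
        v[3:, :3] = 1.0
        return DissimilarityMatrix(labels, v)

    def test_perfect_separation_hand_partition(self):
        dm = self.two_cluster_dm()
        regions = np.array(["a", "a", "a", "b", "b", "b"])
        res = permanova(dm, regions=regions, terms=("region",), permutations=99, seed=0)
        # total SS = sum d^2 / n = 9/6; the group split explains all of it
        assert res.table.loc["Total", "ss"] == pytest.approx(1.5)
        assert res.r2("region") == pytest.approx(1.0, abs=1e-10)
        assert res.table.loc["Residual", "ss"] == pytest.approx(0.0, abs=1e-10)

    def test_single_level_factor_has_zero_ss(self):
        dm = self.two_cluster_dm()
        regions = np.array(["same"] * 6)
        res = permanova(dm, regions=regions, terms=("region",), permutations=9, seed=0)
        assert res.table.loc["region", "df"] == 0
        assert res.r2("region") == 0.0

    def test_r2_sums_to_one(self):
        spec = ScenarioSpec(
            n_regions=3, year_start=2000, year_end=2007, pool_size=25,
            trajectories=[dict(a=6.0, b=0.0, c=0.5, d=-0.5,
                               psi1=2002.0, psi2=2005.0)] * 3,
            noise_sd=1.0, truncated_region=False, seed=11,
        )
        dm = dissimilarity_matrix(generate_panel(spec).panel)
        res = permanova(dm, permutations=49, seed=1)
        terms_r2 = res.table.drop(index="Total")["r2"].sum()
        assert terms_r2 == pytest.approx(1.0, abs=1e-9)
        assert (res.table["ss"].drop(index="Total") >= -1e-9).all()

    def test_matches_vegan_adonis2_frozen_values(self):
        """SS/r2/F frozen from R vegan adonis2 (by='terms', numeric year)
        on this exact generated fixture."""
        spec = ScenarioSpec(
            n_regions=4, pool_size=30, species_pool=40,
            trajectories=[dict(a=8.0, b=0.0, c=0.3, d=-0.3,
                               psi1=1964.0, psi2=1969.0)] * 4,
            noise_sd=1.0, truncated_region=False,
            year_start=1961, year_end=1972, seed=42,
        )
        dm = dissimilarity_matrix(generate_panel(spec).panel)
        res = permanova(dm, permutations=199, seed=0)
        assert res.table.loc["region", "ss"] == pytest.approx(4.891545944, rel=1e-8)
        assert res.table.loc["year", "ss"] == pytest.approx(0.513896276, rel=1e-8)
        assert res.table.loc["region:year", "ss"] == pytest.approx(1.096444732, rel=1e-8)
        assert res.table.loc["Residual", "ss"] == pytest.approx(12.903505333, rel=1e-8)
        assert res.table.loc["Total", "ss"] == pytest.approx(19.405392286, rel=1e-8)
        assert res.table.loc["region", "F"] == pytest.approx(5.05449, rel=1e-5)
        assert res.table.loc["year", "F"] == pytest.approx(1.59304, rel=1e-5)
        assert res.table.loc["region:year", "F"] == pytest.approx(1.13297, rel=1e-5)
        # permutation p-values are seed-dependent; both runs called them significant
        assert res.p("region") < 0.05


class TestSimilarityTrend:
    def test_identical_regions_give_zero_slope(self):
        rows = []
        for region in ("r1", "r2", "r3"):
            for year in range(2000, 2012):
                rows.append((region, year, "a", 10.0))
                rows.append((region, year, "b", 5.0))
        dm = dissimilarity_matrix(small_panel(rows))
        trend = similarity_trend(dm)
        assert np.allclose(trend.values, 0.0)
        assert trend.linear.slope == pytest.approx(0.0, abs=1e-12)

    def test_insufficient_years(self):
        rows = [("r1", 2000, "a", 1.0), ("r2", 2000, "b", 1.0),
                ("r1", 2001, "a", 1.0), ("r2", 2001, "b", 1.0)]
        with pytest.raises(InsufficientDataError):
            similarity_trend(dissimilarity_matrix(small_panel(rows)))
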