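import math

import numpy as np
import pytest

from cropdiv.errors import ConvergenceError, InsufficientDataError
from cropdiv.synthetic_data import eq3
from cropdiv.temporal_models import (
    _aic_value,
    bootstrap_piecewise,
    fit_asymptotic,
    fit_linear,
    fit_logistic4,
    fit_piecewise2,
    fit_quadratic,
    fit_unimodal,
    select_model,
)

YEARS = np.arange(1961.0, 2015.0)


class TestLinear:
    def test_exact_line(self):
        fit = fit_linear(YEARS, 5 + 2 * (YEARS - 1961))
        assert fit.params["b"] == pytest.approx(2.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-15)
        assert fit.aic == -math.inf

    def test_constant_series_zero_slope(self):
        fit = fit_linear(YEARS, np.full_like(YEARS, 7.0))
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-12)

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 7.0, 11.0])
        y = np.array([2.0, 3.0, 3.5, 9.0, 12.5])
        X = np.column_stack([np.ones_like(x), x])
        beta_oracle = np.linalg.solve(X.T @ X, X.T @ y)
        fit = fit_linear(x, y)
        assert fit.params["a"] == pytest.approx(beta_oracle[0])
        assert fit.params["b"] == pytest.approx(beta_oracle[1])

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_linear(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


class TestAIC:
    def test_unit_variance_case(self):
        # n * ln(RSS/n) + 2k with RSS = n gives exactly 2k
        assert _aic_value(54, 54.0, 3, 0.0) == pytest.approx(6.0)

    def test_half_variance_case(self):
        assert _aic_value(54, 27.0, 5, 0.0) == pytest.approx(
            54 * math.log(0.5) + 10
        )

    def test_better_fit_wins_despite_penalty(self):
        assert _aic_value(54, 27.0, 5, 0.0) < _aic_value(54, 54.0, 3, 0.0)

    def test_zero_rss_sentinel_orders_below_everything(self):
        assert _aic_value(54, 0.0, 7, 1e-12) == -math.inf


class TestPiecewise:
    def test_noiseless_recovery(self):
        truth = dict(a=10.0, b=0.0, c=2.0, d=-2.0, psi1=1980.0, psi2=1990.0)
        fit = fit_piecewise2(YEARS, eq3(YEARS, **truth))
        assert abs(fit.psi1 - 1980.0) < 0.5
        assert abs(fit.psi2 - 1990.0) < 0.5
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_pure_line_degenerates_to_single_slope(self):
        fit = fit_piecewise2(YEARS, 3.0 + 0.7 * YEARS)
        s1, s2, s3 = fit.segment_slopes
        assert s1 == pytest.approx(0.7, abs=1e-6)
        assert s2 == pytest.approx(0.7, abs=1e-6)
        assert s3 == pytest.approx(0.7, abs=1e-6)

    def test_prediction_continuous_at_breakpoints(self):
        truth = dict(a=5.0, b=0.1, c=1.5, d=-1.0, psi1=1975.0, psi2=1995.0)
        rng = np.random.default_rng(2)
        fit = fit_piecewise2(YEARS, eq3(YEARS, **truth) + rng.normal(0, 1, YEARS.size))
        for psi in (fit.psi1, fit.psi2):
            below = fit.predict(np.array([psi - 1e-7]))[0]
            above = fit.predict(np.array([psi + 1e-7]))[0]
            assert above == pytest.approx(below, abs=1e-4)

    def test_noisy_recovery_median_within_1p5_years(self):
        truth = dict(a=10.0, b=0.1, c=2.0, d=-2.0, psi1=1978.0, psi2=1989.0)
        clean = eq3(YEARS, **truth)
        sd = 0.05 * (clean.max() - clean.min())
        rng = np.random.default_rng(7)
        errs = [
            abs(fit_piecewise2(YEARS, clean + rng.normal(0, sd, YEARS.size)).psi1
                - truth["psi1"])
            for _ in range(40)
        ]
        assert np.median(errs) <= 1.5

    def test_breakpoints_stay_inside_data_range(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            y = eq3(YEARS, 10, 0.05, 1.5, -1.5, 1972, 1999) + rng.normal(0, 2, YEARS.size)
            fit = fit_piecewise2(YEARS, y)
            assert YEARS.min() < fit.psi1 < fit.psi2 < YEARS.max()

    def test_too_few_points(self):
        with pytest.raises(InsufficientDataError):
            fit_piecewise2(np.arange(7.0), np.arange(7.0))


class TestNonlinearFamilies:
    def test_logistic_generator_inversion(self):
        y = 10 + (110 - 10) / (1 + np.exp((1985 - YEARS) / 3.0))
        fit = fit_logistic4(YEARS, y)
        for key, truth in zip("abcd", (10.0, 110.0, 1985.0, 3.0)):
            assert fit.params[key] == pytest.approx(truth, rel=1e-3)

    def test_asymptotic_constant_series(self):
        fit = fit_asymptotic(YEARS, np.full_like(YEARS, 7.0))
        assert fit.params["a"] == pytest.approx(7.0, abs=1e-6)
        assert fit.params["b"] == pytest.approx(0.0, abs=1e-6)

    def test_asymptotic_generator_inversion(self):
        rate = 0.08
        y = 50.0 - 30.0 * np.exp(-rate * (YEARS - 1961.0))
        fit = fit_asymptotic(YEARS, y)
        assert fit.params["a"] == pytest.approx(50.0, rel=1e-4)
        assert math.exp(fit.params["c"]) == pytest.approx(rate, rel=1e-3)

    def test_unimodal_flat_limit_matches_mean(self):
        rng = np.random.default_rng(1)
        y = np.full_like(YEARS, 5.0) + rng.normal(0, 0.01, YEARS.size)
        fit = fit_unimodal(YEARS, y)
        pred = fit.predict(YEARS)
        assert np.allclose(pred, y.mean(), atol=0.05)

    def test_unimodal_bump_recovery(self):
        y = 40.0 * np.power(0.995, (YEARS - 1988.0) ** 2)
        fit = fit_unimodal(YEARS, y)
        assert fit.params["a"] == pytest.approx(40.0, rel=1e-4)
        assert fit.params["b"] == pytest.approx(0.995, rel=1e-5)
        assert fit.params["c"] == pytest.approx(1988.0, abs=0.05)

    def test_quadratic_matches_generator(self):
        y = 3.0 - 0.2 * YEARS + 0.001 * YEARS**2
        fit = fit_quadratic(YEARS, y)
        assert fit.params["a"] == pytest.approx(3.0, abs=1e-4)
        assert fit.params["b"] == pytest.approx(-0.2, rel=1e-6)
        assert fit.params["c"] == pytest.approx(0.001, rel=1e-6)


class TestSelectModel:
    def test_piecewise_wins_on_breakpoint_truth(self):
        rng = np.random.default_rng(5)
        truth = dict(a=10.0, b=0.0, c=2.5, d=-2.5, psi1=1979.0, psi2=1990.0)
        y = eq3(YEARS, **truth) + rng.normal(0, 1.0, YEARS.size)
        sel = select_model(YEARS, y)
        assert sel.best.family == "piecewise2"

    def test_noiseless_line_ranks_linear_first(self):
        sel = select_model(YEARS, 5 + 2 * (YEARS - 1961))
        assert sel.best.family == "linear"
        families = [f.family for f in sel.fits]
        assert families.index("linear") < families.index("piecewise2")

    def test_sigmoid_ranks_logistic_above_linear(self):
        rng = np.random.default_rng(6)
        y = 10 + 100 / (1 + np.exp((1985 - YEARS) / 3.0)) + rng.normal(0, 2, YEARS.size)
        sel = select_model(YEARS, y)
        families = [f.family for f in sel.fits]
        assert families.index("logistic4") < families.index("linear")

    def test_all_six_families_attempted(self):
        rng = np.random.default_rng(8)
        y = 10 + 0.3 * YEARS + rng.normal(0, 1, YEARS.size)
        sel = select_model(YEARS, y)
        assert len(sel.fits) + len(sel.failures) == 6
        assert sel.fits[0].delta_aic == 0.0

    def test_aic_ranking_invariant_to_affine_year_rescaling(self):
        rng = np.random.default_rng(9)
        y = eq3(YEARS, 10, 0.1, 2, -2, 1978, 1989) + rng.normal(0, 1, YEARS.size)
        base = select_model(YEARS, y)
        shifted = select_model((YEARS - 1961.0) / 10.0, y)
        assert [f.family for f in base.fits] == [f.family for f in shifted.fits]
        for fb, fs in zip(base.fits, shifted.fits):
            if math.isfinite(fb.delta_aic) and math.isfinite(fs.delta_aic):
                assert fb.delta_aic == pytest.approx(fs.delta_aic, abs=0.2)


class TestLocalOptimality:
    def test_fitted_rss_beats_parameter_grid(self):
        rng = np.random.default_rng(10)
        y = eq3(YEARS, 10, 0.1, 2, -2, 1978, 1989) + rng.normal(0, 1.5, YEARS.size)
        fit = fit_piecewise2(YEARS, y)
        for psi1 in np.arange(1965.0, 2010.0, 5.0):
            for psi2 in np.arange(psi1 + 3, 2012.0, 5.0):
                X = np.column_stack(
                    [np.ones_like(YEARS), YEARS,
                     np.clip(YEARS - psi1, 0, None),
                     np.clip(YEARS - psi2, 0, None)]
                )
                beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
                rss_grid = float(np.sum((y - X @ beta) ** 2))
                assert fit.rss <= rss_grid + 1e-9


class TestBootstrap:
    def test_noiseless_medians_match_point_estimates(self):
        y = eq3(YEARS, 10, 0.0, 2.0, -2.0, 1980.0, 1990.0)
        fit = bootstrap_piecewise(YEARS, y, n_boot=50, seed=1)
        assert abs(fit.bootstrap.medians["psi1"] - fit.psi1) < 0.1
        assert abs(fit.bootstrap.medians["psi2"] - fit.psi2) < 0.1
        assert fit.bootstrap.n_success == 50

    def test_seeded_rerun_is_bit_identical(self):
        rng = np.random.default_rng(11)
        y = eq3(YEARS, 10, 0.1, 2, -2, 1978, 1989) + rng.normal(0, 1, YEARS.size)
        a = bootstrap_piecewise(YEARS, y, n_boot=30, seed=42)
        b = bootstrap_piecewise(YEARS, y, n_boot=30, seed=42)
        assert a.bootstrap.medians == b.bootstrap.medians
        assert np.array_equal(
            a.bootstrap.replicates["psi1"], b.bootstrap.replicates["psi1"]
        )

    def test_replicate_count_recorded(self):
        y = eq3(YEARS, 10, 0.0, 2.0, -2.0, 1980.0, 1990.0)
        fit = bootstrap_piecewise(YEARS, y, n_boot=25, seed=2)
        assert fit.bootstrap.n_boot == 25
        assert len(fit.bootstrap.replicates["psi1"]) == fit.bootstrap.n_success


class TestUnimodalAlternativeForm:
    def test_scaled_parabola_reading(self):
        y = 0.5 * (YEARS - 1985.0) ** 2
        fit = fit_unimodal(YEARS, y, form="scaled_parabola")
        assert fit.params["a"] * fit.params["b"] == pytest.approx(0.5, rel=1e-6)
        assert fit.params["c"] == pytest.approx(1985.0, abs=1e-3)
        assert fit.rss == pytest.approx(0.0, abs=1e-9)
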