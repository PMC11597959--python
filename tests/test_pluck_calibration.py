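"""d→h calibration: OLS vs normal-equations oracle, boundary coverage."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from pluckvision.errors import InsufficientDataError, NoCalibrationError
from pluckvision.pluck_calibration import (
    BoundaryLine,
    CalibrationModel,
    evaluate_underestimation,
    fit_all_species,
    fit_species_model,
    load_calibration_config,
    load_packaged_coefficients,
    predict_h,
    upper_boundary,
    write_calibration_config,
)
from pluckvision.scene_io import Measurement
from pluckvision.synthetic_scenes import make_measurements


def ols_oracle(d, h):
    """Closed-form normal equations for simple linear regression."""
    x = np.asarray(d, float)
    y = np.asarray(h, float)
    a = ((x * y).mean() - x.mean() * y.mean()) / ((x ** 2).mean() - x.mean() ** 2)
    b = y.mean() - a * x.mean()
    return a, b


def meas(species, d, h):
    return [Measurement(species, float(di), float(hi)) for di, hi in zip(d, h)]


def marigold_sample(rng, n, sigma=8.0):
    """Synthetic marigold caliper data around the published line.

    The rare (≈0.1%) negative-h Gaussian draw is replaced by the linear
    mean, mirroring the measurement generator.
    """
    d = rng.uniform(26, 46, n)
    h = 0.66 * d + 7.10 + rng.normal(0, sigma, n)
    h = np.where(h <= 0, 0.66 * d + 7.10, h)
    return meas("marigold", d, h)


class TestFitSpeciesModel:
    def test_noiseless_exact(self):
        d = np.linspace(10, 60, 50)
        model = fit_species_model(meas("pansy", d, 0.5 * d + 10), "pansy", seed=0)
        assert model.slope == pytest.approx(0.5, abs=1e-9)
        assert model.intercept == pytest.approx(10.0, abs=1e-9)
        assert model.residuals == pytest.approx(np.zeros(model.n_train), abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(42)
        data = marigold_sample(rng, 240)
        model = fit_species_model(data, "marigold", train_frac=0.8, seed=5)
        assert model.n_train == 192 and model.n_test == 48
        d_tr = np.array([data[i].d for i in model.train_indices])
        h_tr = np.array([data[i].h for i in model.train_indices])
        a_ref, b_ref = ols_oracle(d_tr, h_tr)
        assert model.slope == pytest.approx(a_ref, abs=1e-12)
        assert model.intercept == pytest.approx(b_ref, abs=1e-12)
        assert float(np.mean(model.residuals)) == pytest.approx(0.0, abs=1e-9)

    def test_insufficient_data(self):
        d = np.array([10.0, 20, 30, 40])
        with pytest.raises(InsufficientDataError):
            fit_species_model(meas("pansy", d, d), "pansy", train_frac=0.8)

    def test_split_is_seeded_and_disjoint(self):
        d = np.linspace(10, 60, 40)
        data = meas("pansy", d, 0.4 * d + 20)
        m1 = fit_species_model(data, "pansy", seed=3)
        m2 = fit_species_model(data, "pansy", seed=3)
        np.testing.assert_array_equal(m1.train_indices, m2.train_indices)
        assert set(m1.train_indices).isdisjoint(m1.test_indices)
        assert len(m1.train_indices) + len(m1.test_indices) == 40

    def test_parameter_recovery_improves_with_n(self):
        errs = {}
        for n in (60, 240):
            diffs = []
            for seed in range(50):
                rng = np.random.default_rng(1000 + seed)
                m = fit_species_model(marigold_sample(rng, n), "marigold", seed=seed)
                diffs.append(abs(m.slope - 0.66))
            errs[n] = float(np.mean(diffs))
        assert errs[240] < errs[60]


class TestUpperBoundary:
    def test_zero_residuals_identity(self):
        model = CalibrationModel("x", 0.5, 10.0, residuals=np.zeros(20))
        for cov in (0.5, 0.85, 0.99):
            assert upper_boundary(model, cov).intercept_upper == pytest.approx(10.0)

    def test_empirical_quantile_matches_sorting(self):
        model = CalibrationModel("x", 1.0, 0.0, residuals=np.array([-1.0, 0.0, 1.0, 2.0]))
        line = upper_boundary(model, coverage=0.85)
        # order-statistic oracle: smallest r_(k) with k = ceil(0.85 * 4) = 4
        assert line.intercept_upper == pytest.approx(2.0)
        rng = np.random.default_rng(9)
        r = rng.normal(0, 5, 101)
        model = CalibrationModel("x", 1.0, 3.0, residuals=r)
        line = upper_boundary(model, coverage=0.85)
        expected = 3.0 + np.sort(r)[int(np.ceil(0.85 * 101)) - 1]
        assert line.intercept_upper == pytest.approx(expected, abs=1e-12)

    def test_normal_theory_matches_inverse_cdf(self):
        rng = np.random.default_rng(10)
        r = rng.normal(0, 10.0, 400)
        r = r - r.mean()
        model = CalibrationModel("x", 1.0, 0.0, residuals=r)
        line = upper_boundary(model, coverage=0.85, method="normal_theory")
        sd = np.sqrt((r ** 2).sum() / (r.size - 2))
        assert line.intercept_upper == pytest.approx(stats.norm.ppf(0.85) * sd, abs=1e-12)

    def test_slope_parallel_and_above_regression(self):
        rng = np.random.default_rng(11)
        d = rng.uniform(20, 60, 100)
        h = 0.4 * d + 20 + rng.normal(0, 6, 100)
        model = fit_species_model(meas("pansy", d, h), "pansy", seed=1)
        line = upper_boundary(model, coverage=0.85)
        assert line.slope == model.slope
        assert line.intercept_upper >= model.intercept

    def test_coverage_toward_half_approaches_median(self):
        rng = np.random.default_rng(12)
        r = rng.normal(0, 5, 501)
        model = CalibrationModel("x", 1.0, 0.0, residuals=r)
        c = upper_boundary(model, coverage=0.5).intercept_upper
        assert c == pytest.approx(np.median(r), abs=0.5)

    def test_invalid_coverage(self):
        model = CalibrationModel("x", 1.0, 0.0, residuals=np.zeros(5))
        for bad in (0.3, 1.0, 1.2):
            with pytest.raises(ValueError):
                upper_boundary(model, coverage=bad)

    @settings(max_examples=30, deadline=None)
    @given(st.lists(st.floats(-50, 50), min_size=5, max_size=60),
           st.floats(0.5, 0.99))
    def test_training_coverage_invariant(self, residuals, coverage):
        """The empirical boundary covers >= the requested training fraction."""
        r = np.array(residuals)
        model = CalibrationModel("x", 1.0, 0.0, residuals=r)
        line = upper_boundary(model, coverage=coverage)
        c = line.intercept_upper
        assert np.mean(r <= c + 1e-12) >= coverage


class TestPredictAndUnderestimation:
    def test_packaged_lines_at_zero_diameter(self):
        _, pansy_line = load_packaged_coefficients("pansy")
        assert predict_h(pansy_line, 0.0) == 43.20
        marigold_model, marigold_line = load_packaged_coefficients("marigold")
        assert predict_h(marigold_model, 0.0) == 7.10
        assert predict_h(marigold_line, 1.0) - predict_h(marigold_line, 0.0) == pytest.approx(
            0.66, abs=1e-12
        )

    def test_packaged_snapdragon(self):
        model, line = load_packaged_coefficients("snapdragon")
        assert (model.slope, model.intercept, line.intercept_upper) == (0.38, 5.33, 34.57)

    def test_unknown_species_lists_known(self):
        with pytest.raises(NoCalibrationError, match="marigold"):
            load_packaged_coefficients("rose")

    def test_monotone_in_diameter(self):
        _, line = load_packaged_coefficients("pansy")
        d = np.linspace(0, 80, 50)
        h = predict_h(line, d)
        assert np.all(np.diff(h) >= 0)

    def test_negative_diameter_rejected(self):
        _, line = load_packaged_coefficients("pansy")
        with pytest.raises(ValueError):
            predict_h(line, -1.0)

    def test_boundary_above_all_counts_zero(self):
        data = meas("pansy", [30, 40, 50], [20, 25, 30])
        model = CalibrationModel("pansy", 0.0, 0.0)
        line = BoundaryLine("pansy", 0.0, 100.0, 0.85)
        assert evaluate_underestimation(model, line, data) == (0, 3)

    def test_constructed_two_above(self):
        line = BoundaryLine("pansy", 1.0, 0.0, 0.85)  # h_pred = d
        model = CalibrationModel("pansy", 1.0, 0.0)
        data = meas("pansy", [10, 20, 30, 40], [5, 25, 35, 39])  # 2 strictly above
        assert evaluate_underestimation(model, line, data) == (2, 4)

    def test_heldout_under_rate_near_15_percent(self):
        """Monte-Carlo: Gaussian residuals, 85% boundary -> ~15% underestimated."""
        rng = np.random.default_rng(77)
        rates = []
        for _ in range(20):
            data = marigold_sample(rng, 440)
            model = fit_species_model(data, "marigold", train_frac=0.8,
                                      seed=int(rng.integers(2 ** 31)))
            line = upper_boundary(model, coverage=0.85)
            test_data = [data[i] for i in model.test_indices]
            under, n = evaluate_underestimation(model, line, test_data)
            rates.append(under / n)
        mean_rate = float(np.mean(rates))
        # binomial s.e. of the pooled estimate (20 * 88 trials) ~ 0.0085
        assert abs(mean_rate - 0.15) < 3 * np.sqrt(0.15 * 0.85 / (20 * 88))


class TestConfigIO:
    def test_round_trip(self, tmp_path):
        data = make_measurements(n_per_species=40, seed=2)
        cal = fit_all_species(data, seed=2)
        write_calibration_config(cal, tmp_path / "c.csv")
        back = load_calibration_config(tmp_path / "c.csv")
        assert set(back) == set(cal)
        for sp in cal:
            assert back[sp][0].slope == pytest.approx(cal[sp][0].slope, abs=1e-12)
            assert back[sp][1].intercept_upper == pytest.approx(
                cal[sp][1].intercept_upper, abs=1e-12
            )
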