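"""Linear QSAR fitting, perturbation sensitivities and growth rates."""

import numpy as np
import pandas as pd
import pytest

from musksynth.sensitivity import (LinearQsarModel, fit_linear_model, growth_rates,
                                   load_formula_models, rank_descriptors,
                                   sensitivity_coefficients)

from conftest import make_table


class TestRankDescriptors:
    def test_descriptor_equal_to_target_ranks_first_with_unit_score(self):
        rng = np.random.default_rng(0)
        y = rng.standard_normal(30)
        X = np.column_stack([rng.standard_normal(30), y, rng.standard_normal(30)])
        table = make_table(X, [1] + [0] * 29)
        ranked = rank_descriptors(table, y)
        assert ranked[0][0] == "x1"
        assert ranked[0][1] == pytest.approx(1.0)

    def test_pure_noise_scores_stay_small_at_large_n(self):
        rng = np.random.default_rng(1)
        table = make_table(rng.standard_normal((500, 10)), [1] + [0] * 499)
        ranked = rank_descriptors(table, rng.standard_normal(500))
        assert all(score < 0.15 for _, score in ranked)

    def test_top_half_cut_of_sixteen_is_eight(self):
        rng = np.random.default_rng(2)
        table = make_table(rng.standard_normal((40, 16)), [1] + [0] * 39)
        ranked = rank_descriptors(table, rng.standard_normal(40))
        assert len(ranked[:len(ranked) // 2]) == 8

    def test_constant_descriptor_excluded_with_warning(self):
        X = np.column_stack([np.ones(20), np.arange(20.0)])
        table = make_table(X, [1] + [0] * 19)
        with pytest.warns(UserWarning, match="constant"):
            ranked = rank_descriptors(table, np.arange(20.0))
        assert [n for n, _ in ranked] == ["x1"]


class TestFitLinearModel:
    def test_noiseless_line_recovered_exactly(self):
        x = np.linspace(0, 5, 20)
        X = pd.DataFrame({"a": x})
        model = fit_linear_model(X, 2.0 * x - 3.0)
        assert model.intercept == pytest.approx(-3.0, abs=1e-10)
        assert model.coefficients["a"] == pytest.approx(2.0, abs=1e-10)
        assert model.fit_stats["R2"] == pytest.approx(1.0)

    def test_residuals_orthogonal_to_design(self):
        rng = np.random.default_rng(3)
        X = pd.DataFrame(rng.standard_normal((50, 3)), columns=["a", "b", "c"])
        y = X["a"].to_numpy() - 2 * X["c"].to_numpy() + rng.standard_normal(50)
        model = fit_linear_model(X, y)
        resid = y - model.predict(X)
        for col in X.columns:
            assert abs(resid @ X[col].to_numpy()) < 1e-8
        assert abs(resid.sum()) < 1e-8

    def test_no_signal_gives_near_zero_coefficients(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.standard_normal((500, 4)), columns=list("abcd"))
        y = 1.5 + 0.01 * rng.standard_normal(500)
        model = fit_linear_model(X, y)
        assert all(abs(b) < 0.01 for b in model.coefficients.values())
        assert model.fit_stats["R2"] < 0.05

    def test_rank_deficient_design_rejected(self):
        x = np.arange(10.0)
        X = pd.DataFrame({"a": x, "b": 2 * x})
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_linear_model(X, x)

    def test_published_formula_evaluates_at_origin_to_its_intercept(self):
        models = load_formula_models()
        zeros = {n: 0.0 for n in models["rf"].descriptor_names}
        assert models["rf"].predict(zeros) == pytest.approx(0.64848)
        assert models["ert"].predict(zeros) == pytest.approx(0.76458)
        assert models["gbc"].predict(zeros) == pytest.approx(0.75092)
        assert len(models["rf"].coefficients) == 9

    def test_parameter_recovery_within_three_standard_errors(self):
        """OLS on data generated from the published model recovers it."""
        formula = load_formula_models()["rf"]
        names = formula.descriptor_names
        n = 500
        failures = 0
        for seed in range(10):
            rng = np.random.default_rng(seed)
            X = pd.DataFrame(rng.standard_normal((n, len(names))) * 0.1, columns=names)
            y = formula.predict(X) + rng.normal(0.0, 0.01, n)
            fit = fit_linear_model(X, y)
            for name in names:
                err = abs(fit.coefficients[name] - formula.coefficients[name])
                if err > 3.0 * fit.std_errors[name]:
                    failures += 1
        # 3-sigma misses are rare but not impossible over 90 coefficients
        assert failures <= 2


class TestSensitivityCoefficients:
    def simple_model(self):
        return LinearQsarModel(intercept=0.5, coefficients={"x": 0.1})

    def test_base_convention_is_delta_invariant_for_linear_model(self):
        report = sensitivity_coefficients(self.simple_model(), {"x": 1.0},
                                          convention="base")
        for delta in report.deltas:
            assert report.sc("x", delta) == pytest.approx(1.0 / 6.0)

    def test_perturbed_convention_hand_value(self):
        report = sensitivity_coefficients(self.simple_model(), {"x": 1.0},
                                          convention="perturbed")
        assert report.sc("x", 0.10) == pytest.approx(0.16393, abs=1e-5)

    def test_zero_coefficient_descriptor_has_zero_sc(self):
        model = LinearQsarModel(intercept=0.5, coefficients={"x": 0.1, "z": 0.0})
        report = sensitivity_coefficients(model, {"x": 1.0, "z": 4.0})
        assert all(report.sc("z", d) == 0.0 for d in report.deltas)

    def test_base_convention_closed_form(self):
        model = LinearQsarModel(intercept=0.3, coefficients={"a": -0.2, "b": 0.7})
        baseline = {"a": 1.5, "b": 0.4}
        y0 = model.predict(baseline)
        report = sensitivity_coefficients(model, baseline, convention="base")
        for name in ("a", "b"):
            want = abs(model.coefficients[name] * baseline[name] / y0)
            for delta in report.deltas:
                assert report.sc(name, delta) == pytest.approx(want)

    def test_perturbed_sc_monotone_when_dy_negative(self):
        # negative coefficient: Y shrinks as x grows, so |SC| rises with delta
        model = LinearQsarModel(intercept=1.0, coefficients={"x": -0.3})
        report = sensitivity_coefficients(model, {"x": 1.0}, convention="perturbed")
        values = [report.sc("x", d) for d in report.deltas]
        assert all(b > a for a, b in zip(values, values[1:]))


class TestGrowthRates:
    def test_ten_percent_band(self):
        model = LinearQsarModel(intercept=1.0, coefficients={"x": -0.3})
        report = sensitivity_coefficients(model, {"x": 1.0}, deltas=(0.1, 0.2),
                                          convention="perturbed")
        # overwrite grid with a clean hand case
        report.grid = {("x", 0.1): 0.10, ("x", 0.2): 0.11}
        report.deltas = (0.1, 0.2)
        rates = growth_rates(report)
        assert rates["x"]["10%-20%"] == pytest.approx(10.0)
        assert rates["x"]["average"] == pytest.approx(10.0)

    def test_delta_invariant_sc_gives_zero_bands(self):
        model = LinearQsarModel(intercept=0.5, coefficients={"x": 0.1})
        report = sensitivity_coefficients(model, {"x": 1.0}, convention="base")
        rates = growth_rates(report)
        assert all(v == 0.0 for v in rates["x"].values())

    def test_increasing_grid_gives_positive_bands(self):
        model = LinearQsarModel(intercept=1.0, coefficients={"x": -0.3})
        report = sensitivity_coefficients(model, {"x": 1.0}, convention="perturbed")
        rates = growth_rates(report)
        bands = [v for k, v in rates["x"].items() if k != "average"]
        assert all(v > 0 for v in bands)
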