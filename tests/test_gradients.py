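import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from beachmix.io import DataError
from beachmix.gradients import (
    DegenerateFitError,
    GradientReport,
    arcsine_sqrt,
    fit_gaussian3,
    fit_hyperbola2,
    fit_linear,
    gradient_analysis,
    log10_density,
    stepwise_select,
)


class TestTransforms:
    @pytest.mark.parametrize(
        "p, expected",
        [(0.0, 0.0), (1.0, math.pi / 2), (0.25, math.pi / 6)],
    )
    def test_arcsine_sqrt_closed_forms(self, p, expected):
        assert arcsine_sqrt(p) == pytest.approx(expected, abs=1e-12)

    def test_arcsine_sqrt_domain(self):
        with pytest.raises(DataError):
            arcsine_sqrt(1.2)

    @given(a=st.floats(0, 1), b=st.floats(0, 1))
    def test_arcsine_sqrt_monotone(self, a, b):
        lo, hi = sorted((a, b))
        assert arcsine_sqrt(lo) <= arcsine_sqrt(hi)

    def test_log10_density_values_and_zero_offset(self):
        assert log10_density(1.0) == (0.0, False)
        assert log10_density(100.0) == (2.0, False)
        value, flagged = log10_density(0.0)
        assert flagged and value == pytest.approx(math.log10(0.01))
        with pytest.raises(DataError):
            log10_density(-1.0)


def _noise(rng, n, sd=1.0):
    return rng.normal(0, sd, n)


class TestStepwise:
    def test_exact_signal_selected_alone(self):
        rng = np.random.default_rng(0)
        n = 16
        x1 = np.linspace(0, 10, n)
        cands = {"x1": x1, "x2": _noise(rng, n), "x3": _noise(rng, n)}
        fit = stepwise_select(3.0 * x1 - 1.0, cands)
        assert fit.predictors == ["x1"]
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.coefficients["x1"] == pytest.approx(3.0)
        assert set(fit.f_to_enter) == {"x2", "x3"}

    def test_pure_noise_usually_yields_empty_model(self):
        """On pure noise the model stays empty exactly when no candidate's
        partial F clears the entry threshold (direct-F oracle), which is
        the typical outcome (analytic rate ~76% for 4 candidates, n=16)."""
        empty = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            y = _noise(rng, 16)
            cands = {f"x{i}": _noise(rng, 16) for i in range(4)}
            # oracle: largest single-candidate partial F vs the threshold
            fs = []
            for x in cands.values():
                X = np.column_stack([np.ones(16), x])
                beta, *_ = np.linalg.lstsq(X, y, rcond=None)
                sse1 = float(((y - X @ beta) ** 2).sum())
                sse0 = float(((y - y.mean()) ** 2).sum())
                fs.append((sse0 - sse1) / (sse1 / 14))
            fit = stepwise_select(y, cands)
            assert fit.empty == (max(fs) < 4.0)
            empty += fit.empty
        assert empty >= 60

    def test_order_invariance_with_distinct_partial_f(self):
        rng = np.random.default_rng(3)
        n = 20
        x1, x2, x3 = (np.linspace(0, 1, n), _noise(rng, n), _noise(rng, n))
        y = 5 * x1 + 1.5 * x2 + _noise(rng, n, 0.3)
        f1 = stepwise_select(y, {"a": x1, "b": x2, "c": x3})
        f2 = stepwise_select(y, {"c": x3, "b": x2, "a": x1})
        assert sorted(f1.predictors) == sorted(f2.predictors)
        assert f1.r_squared == pytest.approx(f2.r_squared)

    def test_matches_exhaustive_subset_oracle(self):
        """The greedy path lands on the unique F-admissible subset."""
        rng = np.random.default_rng(12)
        n = 24
        data = {k: _noise(rng, n) for k in ("x1", "x2", "x3")}
        y = 2.0 * data["x1"] + 1.0 * data["x2"] + _noise(rng, n, 0.4)

        f_enter, f_remove = 4.0, 3.9

        def sse(subset):
            X = np.column_stack([np.ones(n)] + [data[v] for v in subset])
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            r = y - X @ beta
            return float(r @ r)

        admissible = []
        for size in range(4):
            for subset in itertools.combinations(sorted(data), size):
                ok = True
                full = sse(subset)
                df_in = n - len(subset) - 1
                for v in subset:
                    without = sse(tuple(w for w in subset if w != v))
                    if (without - full) / (full / df_in) < f_remove:
                        ok = False
                for v in sorted(data):
                    if v in subset:
                        continue
                    with_v = sse(subset + (v,))
                    df_out = n - len(subset) - 2
                    if (full - with_v) / (with_v / df_out) >= f_enter:
                        ok = False
                if ok:
                    admissible.append(set(subset))
        assert admissible == [{"x1", "x2"}]
        fit = stepwise_select(y, data, f_enter, f_remove)
        assert set(fit.predictors) == {"x1", "x2"}

    def test_collinear_candidate_skipped_with_warning(self):
        rng = np.random.default_rng(1)
        n = 16
        x1 = np.linspace(0, 1, n)
        y = 4 * x1 + _noise(rng, n, 0.1)
        with pytest.warns(UserWarning, match="collinear"):
            fit = stepwise_select(y, {"x1": x1, "dup": 2.0 * x1 + 1.0})
        assert fit.predictors == ["x1"]

    def test_p_value_mode(self):
        rng = np.random.default_rng(5)
        n = 16
        x1 = np.linspace(0, 1, n)
        y = 4 * x1 + _noise(rng, n, 0.2)
        fit = stepwise_select(y, {"x1": x1, "x2": _noise(rng, n)}, mode="p")
        assert fit.predictors == ["x1"]

    def test_standardized_coefficients(self):
        rng = np.random.default_rng(6)
        n = 30
        x = _noise(rng, n)
        y = 2.0 * x + _noise(rng, n, 0.1)
        fit = stepwise_select(y, {"x": x})
        expected = fit.coefficients["x"] * np.std(x, ddof=1) / np.std(y, ddof=1)
        assert fit.std_coefficients["x"] == pytest.approx(expected)

    def test_too_few_observations(self):
        with pytest.raises(DataError):
            stepwise_select([1.0, 2.0, 3.0], {"x": [1.0, 2.0, 3.0]})


class TestGaussian3:
    @staticmethod
    def _curve(x, a, x0, b):
        return a * np.exp(-0.5 * ((x - x0) / b) ** 2)

    def test_noiseless_recovery(self):
        x = np.linspace(10, 100, 16)
        y = self._curve(x, 2.0, 40.0, 10.0)
        fit = fit_gaussian3(x, y)
        assert fit.coefficients["a"] == pytest.approx(2.0, abs=1e-6)
        assert fit.coefficients["x0"] == pytest.approx(40.0, abs=1e-6)
        assert abs(fit.coefficients["b"]) == pytest.approx(10.0, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.df_model == 2 and fit.df_resid == 13

    def test_noisy_center_recovery_over_seeds(self):
        x = np.linspace(10, 100, 16)
        clean = self._curve(x, 2.0, 40.0, 10.0)
        errors = []
        for seed in range(50):
            rng = np.random.default_rng(seed)
            fit = fit_gaussian3(x, clean + rng.normal(0, 0.05, 16))
            errors.append(abs(fit.coefficients["x0"] - 40.0))
        assert np.median(errors) < 3.0

    def test_constant_response_degenerate(self):
        with pytest.raises(DegenerateFitError):
            fit_gaussian3(np.linspace(0, 10, 8), np.full(8, 2.0))

    def test_no_uphill_return(self):
        """Returned SSE never exceeds the SSE at any deterministic start."""
        rng = np.random.default_rng(2)
        x = np.linspace(10, 100, 16)
        y = self._curve(x, 1.5, 55.0, 18.0) + rng.normal(0, 0.2, 16)
        fit = fit_gaussian3(x, y)
        span = np.ptp(x)
        for c in np.quantile(x, [0, 0.25, 0.5, 0.75, 1.0]):
            start_sse = float(((self._curve(x, y.max(), c, span / 4) - y) ** 2).sum())
            assert fit.ss_resid <= start_sse + 1e-9


class TestHyperbola2:
    @staticmethod
    def _curve(x, a, b):
        return a * (1.0 - np.exp(-b * x))

    def test_noiseless_recovery(self):
        x = np.linspace(0, 40, 12)
        fit = fit_hyperbola2(x, self._curve(x, 3.5, 0.1))
        assert fit.coefficients["a"] == pytest.approx(3.5, abs=1e-6)
        assert fit.coefficients["b"] == pytest.approx(0.1, abs=1e-6)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.df_model == 1

    def test_curve_passes_through_origin(self):
        x = np.linspace(0, 40, 12)
        fit = fit_hyperbola2(x, self._curve(x, 2.0, 0.3))
        a, b = fit.coefficients["a"], fit.coefficients["b"]
        assert a * (1.0 - math.exp(-b * 0.0)) == 0.0

    def test_plateau_estimate_on_saturated_data(self):
        rng = np.random.default_rng(4)
        x = np.linspace(0, 100, 20)
        y = self._curve(x, 3.0, 0.5) + rng.normal(0, 0.05, 20)
        fit = fit_hyperbola2(x, y)
        plateau = y[x > 20].mean()
        assert fit.coefficients["a"] == pytest.approx(plateau, rel=0.05)

    def test_negative_x_rejected(self):
        with pytest.raises(DataError):
            fit_hyperbola2([-1.0, 0.0, 1.0], [0.0, 0.1, 0.2])


def _site_tables(n=16, seed=0):
    rng = np.random.default_rng(seed)
    width = np.linspace(15.7, 106.6, n)
    frac = (width - width.min()) / np.ptp(width)
    sites = pd.DataFrame(
        {
            "site": [f"S{i:02d}" for i in range(n)],
            "width_m": width,
            "slope_deg": 17 - 14 * frac + rng.normal(0, 1.5, n),
            "grain_mm": 1.5 - 1.3 * frac + rng.normal(0, 0.1, n),
            "wrack_g": 400 * np.exp(-0.5 * ((width - 40) / 12) ** 2) + rng.normal(0, 20, n),
            "burrow_density": np.maximum(
                0.0, 25 * np.exp(-0.5 * ((width - 40) / 15) ** 2) + rng.normal(0, 2, n)
            ),
        }
    )
    p_mole = np.clip(1 - frac + rng.normal(0, 0.05, n), 0.01, 1)
    p_coq = np.clip(frac + rng.normal(0, 0.05, n), 0.01, 1)
    p_amph = np.clip(np.exp(-0.5 * ((width - 40) / 12) ** 2) + rng.normal(0, 0.05, n), 0.01, 1)
    total = p_mole + p_coq + p_amph
    diet = pd.DataFrame(
        {
            "site": sites["site"],
            "mean_p_mole_crab": p_mole / total,
            "mean_p_amphipod": p_amph / total,
            "mean_p_coquina": p_coq / total,
        }
    )
    tp = pd.DataFrame(
        {
            "site": sites["site"],
            "d15N_gc": 8.0 + rng.normal(0, 0.1, n),
            "d15N_res": 5.0 + rng.normal(0, 0.1, n),
            "tp": 3.3 - 0.01 * width + rng.normal(0, 0.08, n),
        }
    )
    return sites, diet, tp


class TestGradientAnalysis:
    def test_battery_runs_and_finds_width_effects(self):
        sites, diet, tp = _site_tables()
        report = gradient_analysis(sites, diet, tp)
        assert isinstance(report, GradientReport)
        mole = report.fits["diet_mole_crab~physical"]
        coq = report.fits["diet_coquina~physical"]
        assert "width_m" in mole.predictors and mole.coefficients["width_m"] < 0
        assert "width_m" in coq.predictors and coq.coefficients["width_m"] > 0
        table = report.table()
        assert {"model", "variable", "coeff", "F", "P", "R2"} <= set(table.columns)

    def test_all_constant_responses_fail_cleanly(self):
        sites, diet, tp = _site_tables()
        diet.loc[:, ["mean_p_mole_crab", "mean_p_amphipod", "mean_p_coquina"]] = 1 / 3
        tp["tp"] = 3.0
        sites["burrow_density"] = 5.0
        report = gradient_analysis(sites, diet, tp)
        for name, fit in report.fits.items():
            if fit.family in ("stepwise-linear", "simple-linear"):
                assert fit.empty or fit.r_squared == pytest.approx(0.0, abs=1e-9)
        # nonlinear peak/saturation models are unidentifiable on constant data
        assert "density~width_gaussian" in report.errors
        assert "tp~p_mole_crab_hyperbola" in report.errors

    def test_exclusion_flag_changes_only_target_fit(self):
        sites, diet, tp = _site_tables()
        base = gradient_analysis(sites, diet, tp)
        excl = gradient_analysis(sites, diet, tp, exclude={"tp~p_amphipod": ["S03"]})
        assert excl.fits["tp~p_amphipod"].n == base.fits["tp~p_amphipod"].n - 1
        assert excl.fits["tp~p_coquina"].n == base.fits["tp~p_coquina"].n
        assert excl.fits["diet_mole_crab~physical"].n == base.fits["diet_mole_crab~physical"].n

    def test_missing_columns_named(self):
        sites, diet, tp = _site_tables()
        with pytest.raises(DataError, match="wrack_g"):
            gradient_analysis(sites.drop(columns=["wrack_g"]), diet, tp)


def test_simple_linear_matches_closed_form():
    x = np.array([0.0, 1.0, 2.0, 3.0, 4.0])
    y = 2.0 * x + 1.0
    fit = fit_linear(x, y, name="x")
    assert fit.coefficients["x"] == pytest.approx(2.0)
    assert fit.coefficients["constant"] == pytest.approx(1.0)
    assert fit.r_squared == pytest.approx(1.0)
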