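"""Decay-model catalogue evaluation, weighted fitting and model ranking."""

import math

import numpy as np
import pytest

from pnpaging import (
    DecayModelSpec,
    DecaySeries,
    NoiseModel,
    compare_decay_models,
    eval_decay,
    fit_decay,
    generate_decay_series,
    half_times,
)


def logistic1(a0, a_inf, t1, h1):
    return DecayModelSpec("logistic1", {"a0": a0, "a_inf": a_inf, "t1": t1, "h1": h1})


class TestEval:
    def test_logistic_midpoint_is_half_amplitude(self):
        spec = logistic1(110.0, 10.0, 40.0, -0.05)
        assert eval_decay(spec, np.array([40.0]))[0] == pytest.approx((110.0 + 10.0) / 2)

    def test_linear_at_time_zero(self):
        spec = DecayModelSpec("linear", {"k": -0.5, "a0": 80.0})
        assert eval_decay(spec, np.array([0.0]))[0] == 80.0

    def test_three_phase_reduces_to_single_phase_at_p_one(self):
        t = np.linspace(0, 300, 50)
        one = logistic1(100.0, 5.0, 60.0, -0.04)
        three = DecayModelSpec(
            "logistic3",
            {
                "a0": 100.0, "a_inf": 5.0,
                "t1": 60.0, "h1": -0.04, "t2": 10.0, "h2": -1.0, "t3": 200.0, "h3": -1.0,
                "p": 1.0, "q": 0.0,
            },
        )
        assert np.allclose(eval_decay(three, t), eval_decay(one, t), rtol=0, atol=1e-12)

    def test_logistic_plateaus(self):
        spec = logistic1(100.0, 5.0, 60.0, -0.04)
        early, late = eval_decay(spec, np.array([-1e4, 1e4]))
        assert early == pytest.approx(100.0, abs=1e-6)
        assert late == pytest.approx(5.0, abs=1e-6)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DecayModelSpec("logistic1", {"a0": 1, "a_inf": 0, "t1": -5.0, "h1": -0.1})
        with pytest.raises(ValueError):
            DecayModelSpec(
                "logistic3",
                {"a0": 1, "a_inf": 0, "t1": 1, "h1": -1, "t2": 2, "h2": -1, "t3": 3, "h3": -1,
                 "p": 0.7, "q": 0.5},
            )
        with pytest.raises(ValueError):
            DecayModelSpec("exp_linear", {"a1": 1.0, "t1": 10.0})
        with pytest.raises(ValueError):
            DecayModelSpec("unknown", {})


class TestHalfTimes:
    def test_exponential_phases_convert_time_constants(self):
        spec = DecayModelSpec("exp_linear", {"a1": 100.0, "t1": 80.0, "k": -0.02, "a2": 70.0})
        ht = half_times(spec)
        assert ht["half_time_1_days"] == pytest.approx(math.log(2) * 80.0)
        assert ht["slope_U_per_mg_per_day"] == -0.02

    def test_logistic_half_times_are_direct(self):
        ht = half_times(logistic1(100, 0, 33.0, -0.1))
        assert ht["half_time_1_days"] == 33.0


class TestFit:
    def test_exp_linear_noiseless_recovery(self):
        tau = 56.7 / math.log(2)
        spec = DecayModelSpec("exp_linear", {"a1": 146.7, "t1": tau, "k": -0.024, "a2": 73.3})
        series = generate_decay_series(spec, np.linspace(0, 1000, 40), NoiseModel(scale=0.0))
        fit = fit_decay(series, "exp_linear")
        assert fit.params["t1"] == pytest.approx(tau, rel=1e-3)
        assert fit.params["k"] == pytest.approx(-0.024, rel=1e-3)
        assert fit.params["a2"] == pytest.approx(73.3, rel=1e-3)
        assert fit.half_times["half_time_1_days"] == pytest.approx(56.7, rel=1e-3)

    def test_two_points_on_a_line_interpolated_exactly(self):
        series = DecaySeries(np.array([0.0, 10.0]), np.array([100.0, 90.0]), np.array([1.0, 1.0]))
        fit = fit_decay(series, "linear")
        assert fit.rss < 1e-18
        assert fit.params["k"] == pytest.approx(-1.0)
        assert fit.params["a0"] == pytest.approx(100.0)

    def test_weighted_fit_discounts_high_sd_points(self):
        """An aberrant point with a 10x SD barely moves the weighted estimates."""
        spec = DecayModelSpec("exp_linear", {"a1": 146.7, "t1": 80.0, "k": -0.024, "a2": 73.3})
        t = np.linspace(0, 1000, 40)
        series = generate_decay_series(spec, t, NoiseModel(scale=0.02, replicates=4, seed=3))
        base = fit_decay(series, "exp_linear", weighted=True)
        # duplicate the steepest-region point with a 10x SD: the near-zero
        # weight means it adds essentially no information
        idx = 2
        t_dup = series.t[idx] + 1e-6
        pert = DecaySeries(
            np.insert(series.t, idx + 1, t_dup),
            np.insert(series.a, idx + 1, series.a[idx]),
            np.insert(series.sd, idx + 1, 10 * series.sd[idx]),
        )
        refit = fit_decay(pert, "exp_linear", weighted=True)
        for name in ("t1", "k", "a2"):
            assert refit.params[name] == pytest.approx(base.params[name], rel=0.01)

    def test_weighted_fit_requires_positive_sds(self):
        series = DecaySeries(np.array([0.0, 1.0, 2.0]), np.array([3.0, 2.0, 1.0]))
        with pytest.raises(ValueError):
            fit_decay(series, "linear", weighted=True)
        series_bad = DecaySeries(
            np.array([0.0, 1.0, 2.0]), np.array([3.0, 2.0, 1.0]), np.array([1.0, 0.0, 1.0])
        )
        with pytest.raises(ValueError):
            fit_decay(series_bad, "linear", weighted=True)

    def test_logistic_fractions_within_simplex(self):
        spec = DecayModelSpec(
            "logistic2",
            {"a0": 100.0, "a_inf": 0.0, "t1": 30.0, "h1": -0.06, "t2": 150.0, "h2": -0.03, "p": 0.4},
        )
        series = generate_decay_series(spec, np.linspace(0, 300, 45), NoiseModel(scale=0.02, seed=1))
        fit = fit_decay(series, "logistic2")
        assert 0.0 <= fit.params["p"] <= 1.0


class TestModelComparison:
    def test_noiseless_two_phase_logistic_preferred(self):
        spec = DecayModelSpec(
            "logistic2",
            {"a0": 100.0, "a_inf": 0.0, "t1": 25.0, "h1": -0.08, "t2": 160.0, "h2": -0.03, "p": 0.5},
        )
        series = generate_decay_series(spec, np.linspace(0, 300, 45), NoiseModel(scale=0.0))
        ranking = compare_decay_models(
            series, families=("logistic1", "logistic2", "logistic3"), weighted=True
        )
        assert ranking[0][0] == "logistic2"

    def test_constant_data_prefers_linear_with_zero_slope(self):
        t = np.linspace(0, 100, 20)
        series = DecaySeries(t, np.full_like(t, 37.0), np.ones_like(t))
        ranking = compare_decay_models(series, families=("linear", "exp_linear"), weighted=True)
        fam, fit, _ = ranking[0]
        assert fam == "linear"
        assert fit.params["k"] == pytest.approx(0.0, abs=1e-10)

    def test_single_exponential_data_does_not_prefer_biexp(self):
        spec = DecayModelSpec(
            "biexp_offset", {"a1": 90.0, "t1": 40.0, "a2": 0.0, "t2": 400.0, "a_inf": 10.0}
        )
        series = generate_decay_series(spec, np.linspace(0, 300, 40), NoiseModel(scale=0.0))
        ranking = compare_decay_models(
            series, families=("exp_linear", "biexp_offset"), weighted=True
        )
        assert ranking[0][0] == "exp_linear"
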