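"""Maturation-model evaluation, model selection, fitting and summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscreen.maturation import (
    MatModel,
    average_traces,
    choose_model,
    double_exp_value,
    fit_maturation,
    single_exp_value,
    summarize_fps,
)


class TestModelValues:
    def test_single_exp_at_zero_is_c(self):
        assert single_exp_value(0.0, 100.0, 2.0, 60.0) == pytest.approx(100.0)

    def test_single_exp_plateau(self):
        assert single_exp_value(1e9, 100.0, 2.0, 60.0) == pytest.approx(300.0)

    def test_single_exp_at_tau(self):
        assert single_exp_value(60.0, 1.0, 1.0, 60.0) == pytest.approx(2 - np.e**-1)

    def test_double_exp_at_zero(self):
        c, tau_m, tau_b = 50.0, 60.0, 240.0
        expect = c * tau_b / (tau_b - tau_m)
        assert double_exp_value(0.0, c, 1.5, tau_m, tau_b) == pytest.approx(expect)

    def test_double_exp_decays_to_zero(self):
        assert double_exp_value(1e9, 50.0, 1.5, 60.0, 240.0) == pytest.approx(0.0)

    def test_double_exp_singular_at_equal_taus(self):
        with pytest.raises(ValueError):
            double_exp_value(0.0, 1.0, 1.0, 60.0, 60.0)

    def test_double_limits_to_single_as_tau_b_grows(self):
        t = np.linspace(0, 300, 301)
        np.testing.assert_allclose(
            double_exp_value(t, 80.0, 1.2, 45.0, 1e9 * 45.0),
            single_exp_value(t, 80.0, 1.2, 45.0),
            rtol=1e-6,
        )

    @given(
        alpha=st.floats(0.0, 10.0),
        tau=st.floats(1.0, 500.0),
        t1=st.floats(0.0, 300.0),
        dt=st.floats(0.0, 100.0),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_single_exp_nondecreasing_in_time(self, alpha, tau, t1, dt):
        assert single_exp_value(t1 + dt, 1.0, alpha, tau) >= single_exp_value(1.0 * t1, 1.0, alpha, tau) - 1e-12


class TestChooseModel:
    t = np.arange(0, 301, 5.0)

    def test_flat_end_selects_single(self):
        traces = [(self.t, single_exp_value(self.t, 100, 2, 60))]
        assert choose_model(traces) == "single"

    def test_bleached_selects_double(self):
        v = single_exp_value(self.t, 100, 2, 30) * np.exp(-self.t / 400)
        assert choose_model([(self.t, v)]) == "double"

    def test_boundary_ratio_is_single(self):
        """Mean end/peak exactly 0.85 stays single (strict <)."""
        v = np.ones_like(self.t)
        v[-2:] = 0.85
        v[0] = 1.0
        assert choose_model([(self.t, v)]) == "single"
        v[-2:] = 0.849999
        assert choose_model([(self.t, v)]) == "double"


class TestFitMaturation:
    t = np.arange(0, 301, 5.0)

    def test_noiseless_single_recovery_exact(self):
        truth = (100.0, 2.0, 60.0)
        f = single_exp_value(self.t, *truth)
        r = fit_maturation(self.t, f, kind="single")
        assert r.success and not r.censored
        assert r.model.c == pytest.approx(truth[0], rel=1e-6)
        assert r.model.alpha == pytest.approx(truth[1], rel=1e-6)
        assert r.model.tau_m == pytest.approx(truth[2], rel=1e-6)

    def test_noiseless_double_recovery(self):
        f = double_exp_value(self.t, 80.0, 1.5, 50.0, 300.0)
        r = fit_maturation(self.t, f, kind="double")
        assert r.model.tau_m == pytest.approx(50.0, rel=1e-5)
        assert r.model.tau_b == pytest.approx(300.0, rel=1e-4)
        assert r.model.tau_b > r.model.tau_m

    def test_censored_when_tau_exceeds_window(self):
        f = single_exp_value(self.t, 100.0, 2.0, 500.0)
        r = fit_maturation(self.t, f, kind="single", t_acq=300.0)
        assert r.censored

    def test_noisy_median_error_small(self, rng):
        """200 simulated lineages at 2% plateau noise, estimated the
        way the pipeline does (fit to the lineage-averaged curve):
        median tau_m error over repeated experiments < 2%."""
        truth = (100.0, 2.0, 60.0)
        plateau = truth[0] * (truth[1] + 1)
        errs = []
        for _ in range(11):
            f = single_exp_value(self.t, *truth) + rng.normal(
                0, 0.02 * plateau, (200, self.t.size)
            ).mean(axis=0)
            r = fit_maturation(self.t, f, kind="single")
            errs.append(abs(r.model.tau_m - truth[2]) / truth[2])
        assert np.median(errs) < 0.02

    @pytest.mark.parametrize("tau", [15.0, 60.0, 180.0])
    @pytest.mark.parametrize("alpha", [0.5, 2.0])
    def test_recovery_grid_five_percent(self, tau, alpha, rng):
        """Across the (tau_m, alpha) grid with up to 5% noise, the
        lineage-averaged fit over 100 lineages keeps the median
        relative tau_m error below 5%."""
        c = 100.0
        plateau = c * (alpha + 1)
        errs = []
        for _ in range(7):
            noise = rng.uniform(0, 0.05) * plateau
            f = single_exp_value(self.t, c, alpha, tau) + rng.normal(
                0, noise, (100, self.t.size)
            ).mean(axis=0)
            r = fit_maturation(self.t, f, kind="single")
            errs.append(abs(r.model.tau_m - tau) / tau)
        assert np.median(errs) < 0.05

    def test_censoring_independent_of_noise_for_noiseless(self):
        for tau, censored in ((100.0, False), (400.0, True)):
            f = single_exp_value(self.t, 50.0, 1.0, tau)
            assert fit_maturation(self.t, f, kind="single").censored is censored

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_maturation(self.t[:4], np.ones(4))

    def test_nonfinite_rejected(self):
        f = single_exp_value(self.t, 1, 1, 60)
        f[3] = np.nan
        with pytest.raises(ValueError):
            fit_maturation(self.t, f)


class TestSummaries:
    def test_sem_for_three_replicates(self):
        df = pd.DataFrame({
            "fp_id": ["a"] * 3, "replicate": [0, 1, 2],
            "tau_m": [50.0, 60.0, 70.0], "n_traps": [10, 10, 10],
            "n_lineages": [8, 8, 8],
        })
        out = summarize_fps(df)
        assert out.mean_tau_m[0] == pytest.approx(60.0)
        assert out.sem_tau_m[0] == pytest.approx(10 / np.sqrt(3))

    def test_single_replicate_no_sem(self):
        df = pd.DataFrame({"fp_id": ["a"], "replicate": [0], "tau_m": [80.0],
                           "n_traps": [6], "n_lineages": [7]})
        out = summarize_fps(df)
        assert out.mean_tau_m[0] == 80.0 and np.isnan(out.sem_tau_m[0])

    def test_four_trap_replicate_excluded(self):
        df = pd.DataFrame({
            "fp_id": ["a", "a"], "replicate": [0, 1], "tau_m": [50.0, 90.0],
            "n_traps": [4, 10], "n_lineages": [8, 8],
        })
        out = summarize_fps(df)
        assert out.n_replicates[0] == 1 and out.mean_tau_m[0] == 90.0

    def test_fp_without_qualifying_replicate_omitted(self):
        df = pd.DataFrame({"fp_id": ["a"], "replicate": [0], "tau_m": [50.0],
                           "n_traps": [3], "n_lineages": [8]})
        assert summarize_fps(df).empty

    def test_censored_mean_labelled(self):
        df = pd.DataFrame({"fp_id": ["a"], "replicate": [0], "tau_m": [450.0],
                           "n_traps": [8], "n_lineages": [8]})
        assert summarize_fps(df).label[0] == ">300"


def test_average_traces_requires_common_grid():
    t = np.arange(0, 50, 5.0)
    with pytest.raises(ValueError):
        average_traces([(t, np.ones_like(t)), (t + 1, np.ones_like(t))])
    tt, vv = average_traces([(t, np.full_like(t, 2.0)), (t, np.full_like(t, 4.0))])
    np.testing.assert_allclose(vv, 3.0)
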