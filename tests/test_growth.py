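"""Momentaneous GR, population binning, Gompertz fits, replicate stats."""

import numpy as np
import pandas as pd
import pytest

from surftrack.growth import (
    GompertzFitError,
    GompertzParams,
    bin_population,
    duplication_time,
    fit_gompertz,
    momentaneous_gr,
    summarize_replicates,
)


class TestMomentaneousGR:
    t = np.arange(0, 30.5, 0.5)

    def test_constant_length_zero_gr(self):
        df = momentaneous_gr(self.t, np.full_like(self.t, 3.0))
        assert np.allclose(df["gr_um_per_min"], 0.0, atol=1e-12)

    def test_linear_length_recovers_slope_exactly(self):
        df = momentaneous_gr(self.t, 2.0 + 0.02 * self.t)
        assert np.allclose(df["gr_um_per_min"], 0.02, atol=1e-12)

    def test_edge_windows_skipped(self):
        df = momentaneous_gr(self.t, 2.0 + 0.02 * self.t, half_window_min=5.0)
        assert df["t_min"].min() >= 5.0
        assert df["t_min"].max() <= 25.0

    def test_eligible_range_restricts_centres(self):
        df = momentaneous_gr(self.t, 2.0 + 0.02 * self.t, 5.0, (10.0, 20.0))
        assert df["t_min"].between(10, 20).all()

    def test_noisy_linear_unbiased_with_ols_variance(self):
        """Monte-Carlo slope sd matches the analytic OLS formula within 10%."""
        rng = np.random.default_rng(0)
        sd = 0.1
        t = np.arange(0, 10.5, 0.5)
        centre = 5.0
        slopes = []
        for _ in range(200):
            ln = 2.0 + 0.02 * t + sd * rng.standard_normal(t.size)
            df = momentaneous_gr(t, ln, 5.0)
            slopes.append(df.loc[df["t_min"] == centre, "gr_um_per_min"].iloc[0])
        slopes = np.array(slopes)
        sxx = np.sum((t - t.mean()) ** 2)
        analytic_sd = sd / np.sqrt(sxx)
        assert slopes.mean() == pytest.approx(0.02, abs=3 * analytic_sd / np.sqrt(200))
        assert slopes.std() == pytest.approx(analytic_sd, rel=0.10)


class TestBinPopulation:
    def _series(self, t, gr, length=3.0):
        return pd.DataFrame({"t_min": t, "gr_um_per_min": gr,
                             "length_um": length, "n_window": 5})

    def test_single_trajectory_median_equals_mean(self):
        gr = {0: self._series([5.0, 10.0, 15.0], [0.01, 0.02, 0.03])}
        samples, summary = bin_population(gr, 20.0)
        assert len(summary) == 1
        assert summary["median_gr"].iloc[0] == pytest.approx(0.02)

    def test_two_trajectories_median_between(self):
        gr = {0: self._series([5.0], [0.01]), 1: self._series([5.0], [0.03])}
        _, summary = bin_population(gr, 20.0)
        assert summary["median_gr"].iloc[0] == pytest.approx(0.02)

    def test_bins_partition_time_axis(self):
        gr = {0: self._series([5.0, 25.0, 45.0], [0.01, 0.02, 0.03])}
        samples, summary = bin_population(gr, 20.0)
        assert list(summary["bin_start_min"]) == [0.0, 20.0, 40.0]
        assert (samples["n_points"] == 1).all()


class TestFitGompertz:
    TRUE = GompertzParams(y0=0.01, A=0.025, k=0.05, t_i=60.0)
    t_bins = np.arange(10.0, 190.0, 20.0)

    def test_noise_free_recovery_is_exact(self):
        fit = fit_gompertz(self.t_bins, self.TRUE(self.t_bins))
        assert fit.params.t_i == pytest.approx(60.0, abs=0.5)
        assert fit.params.A == pytest.approx(0.025, rel=1e-3)
        assert fit.residual < 1e-8

    def test_recovery_under_noise_ensemble(self):
        """100 noisy datasets: median estimates within 10%, t_i within a bin."""
        rng = np.random.default_rng(1)
        est = {"y0": [], "A": [], "k": [], "t_i": []}
        ti_err = []
        for _ in range(100):
            y = self.TRUE(self.t_bins) * (1 + 0.05 * rng.standard_normal(self.t_bins.size))
            fit = fit_gompertz(self.t_bins, y)
            for name in est:
                est[name].append(getattr(fit.params, name))
            ti_err.append(abs(fit.params.t_i - 60.0))
        assert np.median(ti_err) <= 20.0
        for name in est:
            true = getattr(self.TRUE, name)
            assert np.median(est[name]) == pytest.approx(true, rel=0.10)

    def test_constant_data_raises_degenerate(self):
        with pytest.raises(GompertzFitError):
            fit_gompertz(self.t_bins, np.full_like(self.t_bins, 0.02))

    def test_too_few_points_raises(self):
        with pytest.raises(GompertzFitError):
            fit_gompertz([0, 20, 40, 60], [1, 2, 3, 4])

    def test_sigmoid_fit_residual_small(self):
        y = self.TRUE(self.t_bins)
        fit = fit_gompertz(self.t_bins, y * (1 + 1e-3))
        assert fit.residual < 0.02 * (y.max() - y.min())


class TestDuplicationTime:
    L = GompertzParams(3.0, 4.5, 0.05, 60.0)

    def test_printed_formula(self):
        """T₂ = (2/3)·L(t_end)/GR: 4.5 µm at 0.1 µm/min → 30 min."""
        gr = GompertzParams(0.0999999, 0.1, 1.0, 0.0)  # ≈ constant 0.1
        L = GompertzParams(4.4999, 4.5, 1.0, 0.0)
        assert duplication_time(L, gr, 100.0, 100.0) == pytest.approx(30.0, rel=1e-3)

    def test_doubling_gr_halves_t2(self):
        gr1 = GompertzParams(0.01, 0.02, 0.05, 60.0)
        t2a = duplication_time(self.L, gr1, 100.0, 170.0)
        gr2 = GompertzParams(0.02, 0.04, 0.05, 60.0)
        t2b = duplication_time(self.L, gr2, 100.0, 170.0)
        assert t2b == pytest.approx(t2a / 2)

    def test_scale_invariance_of_L_over_GR(self):
        """T₂(c·L, c·GR) = T₂(L, GR): only the ratio matters."""
        gr = GompertzParams(0.01, 0.02, 0.05, 60.0)
        ref = duplication_time(self.L, gr, 100.0, 170.0)
        c = 3.7
        L2 = GompertzParams(c * 3.0, c * 4.5, 0.05, 60.0)
        gr2 = GompertzParams(c * 0.01, c * 0.02, 0.05, 60.0)
        assert duplication_time(L2, gr2, 100.0, 170.0) == pytest.approx(ref)

    def test_nonpositive_gr_flagged_infinite(self):
        gr = GompertzParams(-0.01, 0.02, 0.05, 200.0)
        with pytest.warns(UserWarning):
            out = duplication_time(self.L, gr, 0.0, 170.0)
        assert np.isinf(out)


def _experiment(name, condition, grs, t_i=None):
    if t_i is None:
        t_i = 60.0 + 0.01 * (hash((name, condition)) % 97)  # avoid degenerate t-tests
    summary = pd.DataFrame({
        "t_center_min": np.arange(10.0, 10.0 + 20 * len(grs), 20.0),
        "median_gr": grs,
    })
    return {"name": name, "condition": condition, "summary": summary,
            "transition_time_min": t_i}


class TestSummarizeReplicates:
    def test_identical_experiments_zero_se(self):
        exps = [_experiment(i, "ctrl", [0.01, 0.01, 0.01, 0.02, 0.02, 0.02], t_i=60.0)
                for i in range(3)]
        out = summarize_replicates(exps)
        se = out["by_condition"].set_index("metric")["se"]
        assert (out["by_condition"]["se"].dropna() == 0).all()
        per = out["per_experiment"]
        assert (per["initial_gr"] == 0.01).all()
        assert (per["final_gr"] == 0.02).all()

    def test_single_experiment_se_missing(self):
        out = summarize_replicates([_experiment(0, "ctrl", [0.01] * 3 + [0.02] * 3)])
        assert out["by_condition"]["se"].isna().all()

    def test_power_to_detect_30pct_shift(self):
        """Δ=30%, n=5 vs 5, within-group sd 5% → p<0.01 in ≥95% of repeats."""
        rng = np.random.default_rng(2)
        hits = 0
        reps = 100
        for _ in range(reps):
            ctrl = [_experiment(i, "ctrl", list(0.02 * (1 + 0.05 * rng.standard_normal(6))))
                    for i in range(5)]
            amp = [_experiment(i, "amp", list(0.014 * (1 + 0.05 * rng.standard_normal(6))))
                   for i in range(5)]
            out = summarize_replicates(ctrl + amp)
            p = out["tests"].query("metric == 'initial_gr'")["p"].iloc[0]
            hits += p < 0.01
        assert hits / reps >= 0.95

    def test_null_type_I_error_calibrated(self):
        """Same-distribution groups → rejection rate ≈ α at α=0.05."""
        rng = np.random.default_rng(3)
        rejections = 0
        reps = 500
        for _ in range(reps):
            exps = [
                _experiment(i, cond, list(0.02 * (1 + 0.05 * rng.standard_normal(6))))
                for cond in ("a", "b") for i in range(5)
            ]
            out = summarize_replicates(exps)
            p = out["tests"].query("metric == 'initial_gr'")["p"].iloc[0]
            rejections += p < 0.05
        assert rejections / reps == pytest.approx(0.05, abs=0.03)
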