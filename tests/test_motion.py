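"""Orientation windows, wiggle profiles, pivot localisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from surftrack.growth import GompertzParams
from surftrack.motion import (
    compute_window,
    fold_angle,
    population_motion_summary,
    wiggle_profile,
)
from surftrack.synthetic import SceneConfig, simulate


def rigid_wiggle_traj(pivot_frac, amp_deg, L=3.0, n=240, theta0=20.0,
                      seed=0, theta_noise=0.0, centroid_noise=0.0, fps=2.0):
    """Kinematic oracle: a rigid rod rotating about a fixed pivot.

    The pivot sits at signed arclength ``pivot_frac·L`` from the centre; the
    angular deviation is an AR(1) (discrete OU) with stationary sd amp_deg.
    """
    rng = np.random.default_rng(seed)
    p = pivot_frac * L
    t = np.arange(n) / (fps * 60.0)
    a = np.exp(-1.0 / 10.0)
    dth = np.zeros(n)
    for i in range(1, n):
        dth[i] = a * dth[i - 1] + amp_deg * np.sqrt(1 - a * a) * rng.standard_normal()
    th_true = theta0 + dth
    u = np.stack([np.cos(np.radians(th_true)), np.sin(np.radians(th_true))], axis=1)
    c = np.array([10.0, 10.0]) - p * u
    c = c + centroid_noise * rng.standard_normal(c.shape)
    th_obs = th_true + theta_noise * rng.standard_normal(n)
    return pd.DataFrame({"traj_id": 0, "t_min": t, "x_um": c[:, 0], "y_um": c[:, 1],
                         "length_um": L, "theta_signed_deg": th_obs})


class TestComputeWindow:
    def test_rigid_immobile_cell_zero_spread(self):
        df = rigid_wiggle_traj(0.0, 0.0)
        w = compute_window(df, 0.0, 2.0)
        assert w.theta_std == pytest.approx(0.0, abs=1e-9)
        prof = wiggle_profile(w, 3.0)
        assert prof.mode == "undetermined"
        assert np.allclose(prof.sep_std_um, 0.0, atol=1e-9)

    def test_wiggle_sd_recovered(self):
        """3° synthetic wiggle → STD(θ) ≈ 3° within 10% (240 frames)."""
        sds = [compute_window(rigid_wiggle_traj(0.0, 3.0, seed=s), 0.0, 2.0).theta_std
               for s in range(10)]
        assert np.mean(sds) == pytest.approx(3.0, rel=0.10)

    def test_sparse_window_rejected(self):
        df = rigid_wiggle_traj(0.0, 2.0, n=240).iloc[::3]
        assert compute_window(df, 0.0, 2.0, frame_interval_min=1 / 120) is None

    def test_median_angle_folded(self):
        df = rigid_wiggle_traj(0.0, 1.0, theta0=110.0)
        w = compute_window(df, 0.0, 2.0)
        assert 0.0 <= w.theta_M <= 90.0
        assert w.theta_M == pytest.approx(70.0, abs=1.5)

    @settings(derandomize=True, deadline=None, max_examples=30)
    @given(theta0=st.floats(-179.0, 179.0))
    def test_theta_M_invariant_under_axis_flip(self, theta0):
        """A rod's axis has no direction: θ and θ±180° give the same θ_M."""
        a = compute_window(rigid_wiggle_traj(0.0, 1.0, theta0=theta0, seed=3), 0.0, 2.0)
        b = compute_window(
            rigid_wiggle_traj(0.0, 1.0, theta0=theta0 + 180.0, seed=3), 0.0, 2.0
        )
        assert a.theta_M == pytest.approx(b.theta_M, abs=1e-6)


class TestWiggleProfile:
    def test_central_rotation_V_profile(self):
        """Rotation about the centre: sep_std minimal at l=0, ends ≈ |l|·sd(sin∂θ)."""
        df = rigid_wiggle_traj(0.0, 3.0, seed=1)
        w = compute_window(df, 0.0, 2.0)
        prof = wiggle_profile(w, 3.0)
        assert abs(prof.pivot_hat_um) <= 0.1
        assert prof.mode == "rocking"
        mid = prof.sep_std_um[len(prof.sep_std_um) // 2]
        assert prof.sep_std_um[0] > 5 * mid
        expected_end = 1.5 * np.std(np.sin(np.radians(w.dtheta_deg)), ddof=1)
        assert prof.sep_std_um[0] == pytest.approx(expected_end, rel=0.05)

    @pytest.mark.parametrize("pivot_frac", [-0.4, -0.3, 0.25, 0.4])
    @pytest.mark.parametrize("amp", [1.0, 5.0, 10.0])
    def test_offset_pivot_localised(self, pivot_frac, amp):
        df = rigid_wiggle_traj(pivot_frac, amp, seed=int(10 * abs(pivot_frac) + amp))
        prof = wiggle_profile(compute_window(df, 0.0, 2.0), 3.0)
        assert prof.pivot_hat_um == pytest.approx(pivot_frac * 3.0, abs=0.10 * 3.0)
        assert prof.mode == "twisting"

    def test_V_vertex_unique(self):
        """The separation profile of a rigid rotation has a single minimum."""
        df = rigid_wiggle_traj(-0.3, 4.0, seed=5)
        prof = wiggle_profile(compute_window(df, 0.0, 2.0), 3.0)
        i = int(np.argmin(prof.sep_std_um))
        left = prof.sep_std_um[: i + 1]
        right = prof.sep_std_um[i:]
        assert (np.diff(left) <= 1e-12).all()
        assert (np.diff(right) >= -1e-12).all()

    def test_degenerate_length_errors(self):
        w = compute_window(rigid_wiggle_traj(0.0, 2.0), 0.0, 2.0)
        with pytest.raises(ValueError):
            wiggle_profile(w, 0.0)


class TestGeneratorRoundTrip:
    def _windows(self, pivot_frac, seed=8, realign=0.0, t0=0.0, amp=3.0):
        cfg = SceneConfig(duration_min=max(4.0, t0 + 4), frame_rate_fps=2.0,
                          image_shape=(256, 256), injection_window_min=0.0,
                          arrival_rate_per_min=0.0, initial_cells=12,
                          min_spacing_um=4.0, contact_pushing=False,
                          gr_schedule=GompertzParams(1e-4, 2e-4, 0.05, 60.0),
                          division_length_um=99.0, detach_halflife_min=np.inf,
                          realign_rate_per_min=realign, wiggle_amplitude_deg=amp,
                          pivot_offset_frac=pivot_frac, seed=seed)
        truth = simulate(cfg).truth_table()
        wins = []
        for cid, grp in truth.groupby("cell_id"):
            df = pd.DataFrame({"traj_id": cid, "t_min": grp.frame / 120.0,
                               "x_um": grp.x_um, "y_um": grp.y_um,
                               "length_um": grp.length_um,
                               "theta_signed_deg": grp.theta_deg})
            w = compute_window(df, t0, 2.0)
            if w is not None:
                wins.append((w, grp.length_um.mean()))
        return wins

    def test_upstream_pivot_recovered_from_simulation(self):
        """Cells twisting about −0.3·L: pivot within 10% of L, mode twisting."""
        for w, L in self._windows(-0.3):
            prof = wiggle_profile(w, L)
            assert prof.pivot_hat_um == pytest.approx(-0.3 * L, abs=0.10 * L)
            assert prof.mode == "twisting"

    def test_central_pivot_classified_rocking(self):
        for w, L in self._windows(0.0, seed=9):
            assert wiggle_profile(w, L).mode == "rocking"

    def test_realignment_contrast_early_vs_late(self):
        """With realignment on, θ_M late ≫ θ_M early (flow → normal)."""
        cfg = SceneConfig(duration_min=165.0, frame_rate_fps=0.5,
                          image_shape=(256, 256), injection_window_min=0.0,
                          arrival_rate_per_min=0.0, initial_cells=10,
                          min_spacing_um=4.0, contact_pushing=False,
                          gr_schedule=GompertzParams(1e-4, 2e-4, 0.05, 60.0),
                          division_length_um=99.0, detach_halflife_min=np.inf,
                          realign_rate_per_min=0.02, wiggle_amplitude_deg=2.0,
                          seed=10)
        truth = simulate(cfg).truth_table()
        med = {}
        for t0 in (30.0, 160.0):
            thetas = []
            for cid, grp in truth.groupby("cell_id"):
                sel = grp[(grp.frame / 30.0 >= t0) & (grp.frame / 30.0 < t0 + 2)]
                if len(sel):
                    thetas.append(fold_angle(sel.theta_deg).mean())
            med[t0] = np.median(thetas)
        assert med[160.0] > med[30.0] + 30.0


class TestPopulationSummary:
    def test_identical_populations_indistinguishable(self):
        wins = [compute_window(rigid_wiggle_traj(0.0, 3.0, seed=s), 0.0, 2.0)
                for s in range(12)]
        for i, w in enumerate(wins):
            w.traj_id = i
        out = population_motion_summary({30.0: wins[:6], 160.0: wins[6:]})
        assert (out["tests"]["p"] > 0.05).all()

    def test_missing_time_point_partial_output(self, caplog):
        wins = [compute_window(rigid_wiggle_traj(0.0, 3.0, seed=1), 0.0, 2.0)]
        out = population_motion_summary({30.0: wins, 160.0: []})
        assert set(out["angles"]["time_min"]) == {30.0}

    def test_twisting_majority_for_offset_pivot_population(self):
        wins = []
        for s in range(10):
            w = compute_window(rigid_wiggle_traj(-0.3, 3.0, seed=s), 0.0, 2.0)
            w.traj_id = s
            wins.append(w)
        out = population_motion_summary({30.0: wins})
        mf = out["mode_fractions"]
        frac = mf.loc[mf["mode"] == "twisting", "fraction"]
        assert float(frac.iloc[0]) > 0.5
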