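"""Scene simulator: arrival/division/detachment bookkeeping and rendering."""

import numpy as np
import pytest
from scipy import stats

from surftrack.growth import GompertzParams
from surftrack.synthetic import (
    SceneConfig,
    SceneConfigError,
    render,
    simulate,
    simulate_truth,
)

FLAT_GR = GompertzParams(1e-6, 2e-6, 0.05, 60.0)


def minimal_config(**kw) -> SceneConfig:
    base = dict(
        duration_min=5.0,
        frame_rate_fps=1 / 30,
        image_shape=(128, 128),
        injection_window_min=0.0,
        arrival_rate_per_min=0.0,
        gr_schedule=FLAT_GR,
        detach_halflife_min=np.inf,
        noise_sd=0.0,
        wiggle_amplitude_deg=0.0,
        seed=1,
    )
    base.update(kw)
    return SceneConfig(**base)


class TestSimulate:
    def test_no_input_cells_gives_empty_tracks(self):
        assert simulate_truth(minimal_config()) == []

    def test_count_conserved_without_detachment_or_division(self):
        cfg = minimal_config(duration_min=30.0, injection_window_min=10.0,
                             arrival_rate_per_min=1.0, division_length_um=1e3)
        truth = simulate(cfg).truth_table()
        counts = truth.groupby("frame").size()
        after = counts[counts.index * cfg.frame_interval_min >= 10.0]
        assert after.nunique() == 1  # constant after the injection window

    def test_exponential_residence_half_life(self):
        """500 non-dividing cells, T½=30 min → half remain at 30 min.

        Oracle: the per-cell detachment times are exponential draws, so the
        bound count at T½ is Binomial(500, 1/2).
        """
        cfg = minimal_config(duration_min=40.0, image_shape=(256, 256),
                             initial_cells=500, division_length_um=1e3,
                             detach_halflife_min=30.0, min_spacing_um=0.01,
                             contact_pushing=False)
        truth = simulate(cfg).truth_table()
        frame_at_30 = int(30.0 / cfg.frame_interval_min)
        remaining = (truth["frame"] == frame_at_30).sum()
        assert abs(remaining - 250) < 3 * np.sqrt(500 * 0.25)

    def test_survival_curve_is_exponential(self):
        """KS test of residence times against Exp(ln2/T½), n=1000."""
        cfg = minimal_config(duration_min=300.0, frame_rate_fps=1 / 60,
                             image_shape=(256, 256), initial_cells=1000,
                             division_length_um=1e3, detach_halflife_min=30.0,
                             min_spacing_um=0.01, contact_pushing=False, seed=3)
        truth = simulate(cfg).truth_table()
        last = truth.groupby("cell_id")["frame"].max()
        # exclude right-censored cells (still bound at movie end)
        times = (last[last < cfg.n_frames - 1] + 0.5) * cfg.frame_interval_min
        assert len(times) > 900
        res = stats.kstest(times, "expon", args=(0, 30.0 / np.log(2)))
        assert res.pvalue > 0.01

    def test_mass_balance_against_event_log(self):
        cfg = minimal_config(duration_min=60.0, image_shape=(384, 384),
                             injection_window_min=15.0, arrival_rate_per_min=1.0,
                             initial_length_um=(3.5, 0.3),
                             gr_schedule=GompertzParams(0.05, 0.06, 0.05, 10.0),
                             detach_halflife_min=50.0, daughter_detach_prob=0.2,
                             wiggle_amplitude_deg=2.0, seed=5)
        sim = simulate(cfg)
        truth = sim.truth_table()
        deltas = np.zeros(cfg.n_frames)
        for e in sim.events:
            if e["effective_frame"] < cfg.n_frames:
                deltas[e["effective_frame"]] += e["delta"]
        predicted = np.cumsum(deltas)
        observed = (
            truth.groupby("frame").size()
            .reindex(range(cfg.n_frames), fill_value=0)
            .to_numpy()
        )
        assert np.array_equal(predicted, observed)

    def test_daughter_lengths_sum_to_mother(self):
        cfg = minimal_config(duration_min=60.0, initial_cells=3,
                             initial_length_um=(4.2, 0.1),
                             gr_schedule=GompertzParams(0.05, 0.051, 0.05, 10.0),
                             division_length_um=4.5, division_asymmetry=0.2,
                             daughter_detach_prob=0.0, wiggle_amplitude_deg=1.0,
                             image_shape=(256, 256), seed=6)
        sim = simulate(cfg)
        truth = sim.truth_table()
        divisions = [e for e in sim.events if e["kind"] == "division"]
        assert divisions
        for e in divisions:
            mother_len = truth.loc[
                (truth.cell_id == e["cell_id"]) & (truth.frame == e["frame"]),
                "length_um",
            ].iloc[0]
            kids = truth[(truth.parent_id == e["cell_id"]) & (truth.frame == e["frame"] + 1)]
            if len(kids) == 2:
                assert kids["length_um"].sum() == pytest.approx(mother_len, rel=1e-9)

    def test_frames_consecutive_while_bound(self):
        cfg = minimal_config(duration_min=60.0, initial_cells=20,
                             image_shape=(256, 256), detach_halflife_min=20.0,
                             division_length_um=1e3, min_spacing_um=0.01,
                             contact_pushing=False, seed=7)
        truth = simulate(cfg).truth_table()
        for _, grp in truth.groupby("cell_id"):
            frames = grp["frame"].to_numpy()
            assert np.array_equal(frames, np.arange(frames[0], frames[-1] + 1))

    def test_determinism(self):
        cfg = minimal_config(duration_min=20.0, injection_window_min=10.0,
                             arrival_rate_per_min=2.0, wiggle_amplitude_deg=3.0,
                             detach_halflife_min=30.0, seed=11)
        a = simulate(cfg).truth_table()
        b = simulate(cfg).truth_table()
        assert a.equals(b)

    @pytest.mark.parametrize(
        "field,value",
        [
            ("division_asymmetry", 0.7),
            ("pivot_offset_frac", 0.8),
            ("daughter_detach_prob", 1.5),
            ("duration_min", -1.0),
            ("noise_sd", float("nan")),
        ],
    )
    def test_config_validation_names_field(self, field, value):
        cfg = minimal_config()
        setattr(cfg, field, value)
        with pytest.raises(SceneConfigError, match=field):
            cfg.validate()


class TestRender:
    def test_empty_scene_flat_illumination_is_constant(self):
        cfg = minimal_config(duration_min=2.0)
        movie = render([], cfg)
        assert movie.n_frames == 4
        assert np.ptp(movie.frames) == pytest.approx(0.0, abs=1e-12)

    def test_noise_sd_scales_residual(self):
        """Doubling noise_sd doubles the per-pixel residual sd (within 5%)."""
        sds = []
        for noise in (0.02, 0.04):
            cfg = minimal_config(duration_min=2.0, noise_sd=noise, seed=13)
            movie = render([], cfg)
            sds.append(movie.frames.std())
        assert sds[1] / sds[0] == pytest.approx(2.0, rel=0.05)

    def test_deterministic_given_seed(self):
        cfg = minimal_config(duration_min=2.0, noise_sd=0.03,
                             nanoparticle_rate_per_min=2.0, seed=17)
        tracks = simulate_truth(cfg)
        a = render(tracks, cfg)
        b = render(tracks, cfg)
        assert np.array_equal(a.frames, b.frames)

    def test_cells_darker_than_background(self):
        cfg = minimal_config(duration_min=1.0, initial_cells=1, seed=19)
        tracks = simulate_truth(cfg)
        movie = render(tracks, cfg)
        assert movie.frames[0].min() < 0.75 * np.median(movie.frames[0])
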