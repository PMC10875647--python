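"""Shared fixtures: rendered scenes reused across test modules.

The expensive fixtures (rendered movies pushed through the full chain) are
session-scoped so each scene is simulated, rendered and segmented once.
"""

from __future__ import annotations

import numpy as np
import pytest

from surftrack.growth import GompertzParams
from surftrack.pipeline import RunConfig, run_pipeline
from surftrack.segmentation import SegmentationParams, segment_stack
from surftrack.synthetic import SceneConfig, render, simulate
from surftrack.tracking import TrackingParams, link


ILLUM = [[1.0, 0.08], [0.12, 0.0]]


def division_scene_config(noise_sd: float, seed: int = 31) -> SceneConfig:
    """Five near-division cells: every initial cell divides exactly once."""
    return SceneConfig(
        duration_min=45.0,
        frame_rate_fps=1 / 30,
        image_shape=(384, 384),
        injection_window_min=0.0,
        arrival_rate_per_min=0.0,
        initial_cells=5,
        initial_length_um=(4.0, 0.2),
        gr_schedule=GompertzParams(0.04, 0.041, 0.05, 10.0),
        division_length_um=4.5,
        daughter_detach_prob=0.0,
        detach_halflife_min=np.inf,
        wiggle_amplitude_deg=1.5,
        noise_sd=noise_sd,
        illumination_coeffs=ILLUM if noise_sd else None,
        seed=seed,
    )


def _run_scene(cfg: SceneConfig, block: int = 1):
    sim = simulate(cfg)
    movie = render(sim.tracks, cfg)
    obs, avg = segment_stack(movie, SegmentationParams(averaging_block=block))
    trajs = link(obs, avg.frame_interval_min, TrackingParams())
    return {"config": cfg, "sim": sim, "truth": sim.truth_table(),
            "movie": movie, "obs": obs, "averaged": avg, "trajectories": trajs}


@pytest.fixture(scope="session")
def division_run_clean():
    """Noise-free rendered division scene through segmentation + tracking."""
    return _run_scene(division_scene_config(noise_sd=0.0))


@pytest.fixture(scope="session")
def division_run_noisy():
    """Same scene at generator-default noise."""
    return _run_scene(division_scene_config(noise_sd=0.02))


@pytest.fixture(scope="session")
def detection_run():
    """50 frames of a static field of spaced rods at default noise."""
    cfg = SceneConfig(
        duration_min=25.0,
        frame_rate_fps=1 / 30,
        image_shape=(384, 384),
        injection_window_min=0.0,
        arrival_rate_per_min=0.0,
        initial_cells=12,
        min_spacing_um=5.5,
        gr_schedule=GompertzParams(0.02, 0.021, 0.05, 10.0),
        division_length_um=5.5,
        detach_halflife_min=np.inf,
        wiggle_amplitude_deg=2.0,
        noise_sd=0.02,
        illumination_coeffs=ILLUM,
        nanoparticle_rate_per_min=0.3,
        seed=21,
    )
    return _run_scene(cfg)


def colonization_scene_config(seed: int = 42) -> SceneConfig:
    """Full colonization dynamics: arrivals, lag, divisions, detachment.

    daughter_detach_prob is zero so the configured residence half-life is
    the sole release channel the colonization-curve model has to recover.
    """
    return SceneConfig(
        duration_min=110.0,
        frame_rate_fps=1 / 30,
        image_shape=(480, 480),
        injection_window_min=20.0,
        arrival_rate_per_min=0.7,
        min_spacing_um=6.5,
        initial_length_um=(2.6, 0.3),
        detach_halflife_min=60.0,
        daughter_detach_prob=0.0,
        wiggle_amplitude_deg=2.0,
        noise_sd=0.02,
        illumination_coeffs=ILLUM,
        seed=seed,
    )


@pytest.fixture(scope="session")
def colonization_bundle(tmp_path_factory):
    """The full pipeline on the colonization scene (shared, ~1 min)."""
    cfg = RunConfig(
        scene=colonization_scene_config(),
        segmentation=SegmentationParams(averaging_block=1),
        motion_windows_min=(30.0, 100.0),
        motion_window_duration_min=5.0,
        outdir=tmp_path_factory.mktemp("bundle"),
    )
    return run_pipeline(cfg)


def suppression_experiment(y0: float, seed: int) -> dict:
    """Per-bin GR medians of one 60-min experiment (full imaging chain).

    The GR schedule is flat over the movie (transition far beyond its end),
    so every bin probes the initial growth rate.
    """
    from surftrack.growth import bin_population, momentaneous_gr
    from surftrack.tracking import filter_for_growth

    cfg = SceneConfig(
        duration_min=60.0,
        frame_rate_fps=2 / 15,
        image_shape=(256, 256),
        injection_window_min=0.0,
        arrival_rate_per_min=0.0,
        initial_cells=8,
        min_spacing_um=5.0,
        gr_schedule=GompertzParams(y0, 2.5 * y0, 0.05, 200.0),
        detach_halflife_min=np.inf,
        wiggle_amplitude_deg=2.0,
        noise_sd=0.02,
        illumination_coeffs=ILLUM,
        seed=seed,
    )
    sim = simulate(cfg)
    movie = render(sim.tracks, cfg)
    obs, avg = segment_stack(movie, SegmentationParams(averaging_block=2))
    trajs = filter_for_growth(link(obs, avg.frame_interval_min, TrackingParams()))
    gr = {
        t.traj_id: momentaneous_gr(
            t.times_min(), t.lengths_um(), 5.0, (t.gr_start_min, t.gr_end_min)
        )
        for t in trajs
    }
    _, summary = bin_population(gr, 20.0)
    return summary


@pytest.fixture(scope="session")
def suppression_trial():
    """5 control vs 5 AMP-like (25% GR-suppressed) paired experiments.

    Each entry is shaped for growth.summarize_replicates; the analysis
    horizon (t_i = movie end) marks every bin as pre-transition.
    """
    horizon = 60.0
    experiments = []
    for i in range(5):
        experiments.append({"name": f"ctrl{i}", "condition": "control",
                            "summary": suppression_experiment(0.01, 100 + i),
                            "transition_time_min": horizon})
        experiments.append({"name": f"amp{i}", "condition": "amp",
                            "summary": suppression_experiment(0.0075, 200 + i),
                            "transition_time_min": horizon})
    return {"experiments": experiments, "configured_suppression": 0.25}
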