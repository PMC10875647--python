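"""End-to-end orchestration: simulate/load → segment → track → kinetics.

`run_pipeline` executes the full analysis chain on one movie and returns a
result bundle (tables + machine-readable summary); `render_report` turns
one or more bundles into the standard figure set (colonization curve with
fit overlay, GR/length boxplots per bin, orientation scatter, wiggle
profiles, cross-condition bars).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from . import binding as binding_mod
from . import growth as growth_mod
from . import motion as motion_mod
from .io import MovieStack
from .segmentation import SegmentationParams, observations_to_frame, segment_stack
from .synthetic import SceneConfig, render, simulate
from .tracking import (
    TrackingParams,
    filter_for_growth,
    lineage_table,
    link,
    trajectories_table,
)

__all__ = ["RunConfig", "PipelineError", "run_pipeline", "render_report"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    """Everything one pipeline run needs."""

    scene: SceneConfig = field(default_factory=SceneConfig)
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    tracking: TrackingParams = field(default_factory=TrackingParams)
    condition: str = "control"
    name: str = "run"
    min_trajectory_min: float = 10.0
    edge_exclusion_min: float = 5.0
    gr_half_window_min: float = 5.0
    bin_min: float = 20.0
    motion_windows_min: tuple[float, ...] = (30.0, 160.0)
    motion_window_duration_min: float = 2.0
    outdir: str | Path | None = None


def _jsonable(x):
    if isinstance(x, dict):
        return {k: _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, (np.floating, np.integer)):
        return x.item()
    return x


def run_pipeline(config: RunConfig, movie: MovieStack | None = None) -> dict:
    """Run average → segment → track → growth → binding → motion.

    If no movie is given, one is simulated and rendered from
    ``config.scene``.  Returns a bundle dict with the intermediate tables
    and a flat ``summary``; with ``config.outdir`` set, all tables, the
    summary JSON and a parameter log are written there.
    """
    bundle: dict = {"config": config}

    def stage(name, fn):
        try:
            return fn()
        except Exception as e:  # noqa: BLE001 - abort carries the stage name
            raise PipelineError(name, e) from e

    if movie is None:
        sim = stage("simulate", lambda: simulate(config.scene))
        bundle["truth"] = sim.truth_table()
        movie = stage("render", lambda: render(sim.tracks, config.scene))
    bundle["movie"] = movie

    obs, averaged = stage(
        "segment", lambda: segment_stack(movie, config.segmentation)
    )
    bundle["observations"] = obs
    bundle["averaged_stack"] = averaged
    interval = averaged.frame_interval_min

    trajectories = stage(
        "track", lambda: link(obs, interval, config.tracking)
    )
    bundle["trajectories"] = trajectories

    growth_trajs = filter_for_growth(
        trajectories, config.min_trajectory_min, config.edge_exclusion_min
    )

    def compute_growth():
        gr_by_traj = {}
        for tr in growth_trajs:
            series = growth_mod.momentaneous_gr(
                tr.times_min(), tr.lengths_um(), config.gr_half_window_min,
                (tr.gr_start_min, tr.gr_end_min),
            )
            if not series.empty:
                gr_by_traj[tr.traj_id] = series
        return growth_mod.bin_population(gr_by_traj, config.bin_min)

    samples, bin_summary = stage("growth", compute_growth)
    bundle["gr_samples"] = samples
    bundle["gr_bins"] = bin_summary

    gr_fit = length_fit = None
    if len(bin_summary) >= 5:
        try:
            gr_fit = growth_mod.fit_gompertz(
                bin_summary["t_center_min"], bin_summary["median_gr"]
            )
            length_fit = growth_mod.fit_gompertz(
                bin_summary["t_center_min"], bin_summary["median_length"]
            )
        except growth_mod.GompertzFitError as e:
            logger.warning("Gompertz fit unavailable: %s", e)
    bundle["gr_fit"] = gr_fit
    bundle["length_fit"] = length_fit

    t_end = float(bin_summary["t_center_min"].iloc[-1]) if len(bin_summary) else np.nan
    T2_end = np.nan
    if gr_fit is not None and length_fit is not None:
        T2_end = growth_mod.duplication_time(length_fit, gr_fit, t_end, t_end)

    curve = stage(
        "binding_curve",
        lambda: binding_mod.build_curve(
            obs, interval, injection_end_min=config.scene.injection_window_min
        ),
    )
    bundle["colonization_curve"] = curve
    binding_fit = None
    if gr_fit is not None and length_fit is not None:
        try:
            T2_fn = growth_mod.duplication_time_fn(length_fit, gr_fit, t_end)
            binding_fit = binding_mod.fit_binding_time(curve, T2_fn, gr_fit.t_i)
        except (ValueError, RuntimeError) as e:
            logger.warning("binding fit unavailable: %s", e)
    bundle["binding_fit"] = binding_fit

    def compute_motion():
        # full-rate analysis only needs the frames inside each window
        from .segmentation import correct_illumination, segment_frame

        windows_by_time: dict[float, list] = {}
        interval_full = movie.frame_interval_min
        for t0 in config.motion_windows_min:
            t1 = t0 + config.motion_window_duration_min
            if t1 > movie.n_frames * interval_full:
                logger.warning("motion window at %.0f min beyond movie end", t0)
                continue
            f0, f1 = int(t0 / interval_full), int(np.ceil(t1 / interval_full))
            win_obs = {
                f: segment_frame(
                    correct_illumination(movie.frames[f]),
                    config.segmentation, movie.pixel_size_um, frame_index=f,
                )
                for f in range(f0, min(f1, movie.n_frames))
            }
            win_trajs = link(win_obs, interval_full, config.tracking)
            wins = []
            for tr in win_trajs:
                w = motion_mod.compute_window(
                    tr, t0, config.motion_window_duration_min
                )
                if w is not None:
                    wins.append(w)
            windows_by_time[t0] = wins
        return (
            motion_mod.population_motion_summary(windows_by_time)
            if any(windows_by_time.values())
            else None
        )

    bundle["motion"] = stage("motion", compute_motion)

    initial_gr = final_gr = np.nan
    if gr_fit is not None and len(bin_summary):
        before = bin_summary[bin_summary["t_center_min"] < gr_fit.t_i]["median_gr"]
        after = bin_summary[bin_summary["t_center_min"] > gr_fit.t_i]["median_gr"]
        initial_gr = float(before.median()) if len(before) else np.nan
        final_gr = float(after.median()) if len(after) else np.nan
    mode_fractions = {}
    if bundle["motion"] is not None:
        mf = bundle["motion"]["mode_fractions"]
        for row in mf.itertuples():
            mode_fractions[f"{row.mode}@{row.time_min:g}min"] = float(row.fraction)
    summary = {
        "name": config.name,
        "condition": config.condition,
        "n_trajectories": len(trajectories),
        "n_growth_trajectories": len(growth_trajs),
        "initial_gr_um_per_min": initial_gr,
        "final_gr_um_per_min": final_gr,
        "transition_time_min": gr_fit.t_i if gr_fit else np.nan,
        "T2_end_min": T2_end,
        "T_half_min": binding_fit.T_half_min if binding_fit else np.nan,
        "N0": binding_fit.N0 if binding_fit else np.nan,
        "mode_fractions": mode_fractions,
    }
    bundle["summary"] = summary

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        observations_to_frame(obs).to_csv(outdir / "observations.csv", index=False)
        trajectories_table(trajectories).to_csv(outdir / "trajectories.csv", index=False)
        lineage_table(trajectories).to_csv(outdir / "lineage.csv", index=False)
        bin_summary.to_csv(outdir / "gr_bins.csv", index=False)
        fits = {
            "gr": gr_fit.to_dict() if gr_fit else None,
            "length": length_fit.to_dict() if length_fit else None,
        }
        (outdir / "gompertz_fits.json").write_text(
            json.dumps(_jsonable(fits), indent=1, sort_keys=True)
        )
        (outdir / "summary.json").write_text(
            json.dumps(_jsonable(summary), indent=1, sort_keys=True)
        )
        (outdir / "params.json").write_text(
            json.dumps(_jsonable({
                "scene": config.scene.to_dict(),
                "segmentation": vars(config.segmentation),
                "tracking": vars(config.tracking),
            }), indent=1, sort_keys=True)
        )
    return bundle


# ---------------------------------------------------------------------------
# figures


def render_report(bundles: list[dict], outdir: str | Path) -> list[Path]:
    """Write the standard figure set for one or more result bundles."""
    if not bundles:
        raise ValueError("need at least one result bundle")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    b0 = bundles[0]

    def save(fig, name):
        p = outdir / name
        fig.savefig(p, dpi=110)
        plt.close(fig)
        written.append(p)

    # 1: colonization curve (+ model overlay when available)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    curve = b0["colonization_curve"]
    ax.plot(curve.t_min, curve.counts, ".", ms=3, label="N(t)")
    bf = b0.get("binding_fit")
    if bf is not None and np.isfinite(bf.T_half_min):
        sel = curve.t_min >= bf.t0_min
        gr_fit, length_fit = b0["gr_fit"], b0["length_fit"]
        t_end = float(b0["gr_bins"]["t_center_min"].iloc[-1])
        T2 = growth_mod.duplication_time_fn(length_fit, gr_fit, t_end)(curve.t_min[sel])
        rate = np.log(2) / T2 - np.log(2) / bf.T_half_min
        model = bf.N0 * np.exp(np.concatenate(
            [[0.0], np.cumsum(0.5 * (rate[1:] + rate[:-1]) * np.diff(curve.t_min[sel]))]
        ) + rate[0] * (curve.t_min[sel][0] - bf.t0_min))
        ax.plot(curve.t_min[sel], model, "r--", label=f"fit, T½={bf.T_half_min:.0f} min")
    else:
        logger.warning("no exponential-phase fit to overlay")
    ax.set(xlabel="time (min)", ylabel="bound bacteria", title="colonization curve")
    ax.legend(fontsize=8)
    fig.tight_layout()
    save(fig, "colonization_curve.png")

    # 2/3: GR and length boxplots per bin
    samples = b0["gr_samples"]
    for col, name, ylabel in (
        ("mean_gr_um_per_min", "gr_boxplot.png", "GR (µm/min)"),
        ("mean_length_um", "length_boxplot.png", "length (µm)"),
    ):
        fig, ax = plt.subplots(figsize=(5, 3.2))
        if len(samples):
            groups = [g[col].to_numpy() for _, g in samples.groupby("bin_start_min")]
            pos = sorted(samples["bin_start_min"].unique())
            ax.boxplot(groups, positions=pos, widths=0.6 * (pos[1] - pos[0] if len(pos) > 1 else 10))
        ax.set(xlabel="time bin (min)", ylabel=ylabel)
        fig.tight_layout()
        save(fig, name)

    # 4: theta_M vs STD(theta)
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    if b0.get("motion") is not None:
        ang = b0["motion"]["angles"]
        for t, grp in ang.groupby("time_min"):
            ax.plot(grp["theta_std"], grp["theta_M"], "o", ms=4, label=f"{t:g} min")
        ax.legend(fontsize=8)
    ax.set(xlabel="STD(θ) (deg)", ylabel="θ$_M$ (deg)", ylim=(-2, 92))
    fig.tight_layout()
    save(fig, "orientation_scatter.png")

    # 5: wiggle profile bars
    fig, ax = plt.subplots(figsize=(5, 3.2))
    if b0.get("motion") is not None:
        prof = b0["motion"]["profiles"]
        for t, grp in prof.groupby("time_min"):
            m = grp.groupby("l_rel_bin")["sep_std_um"].mean()
            ax.bar(m.index, m.values, width=0.08, alpha=0.6, label=f"{t:g} min")
        ax.legend(fontsize=8)
    ax.set(xlabel="position l / L", ylabel="sd of separation (µm)")
    fig.tight_layout()
    save(fig, "wiggle_profile.png")

    # 6: cross-condition summary bars (single-bundle: initial/final GR)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    rows = [b["summary"] for b in bundles]
    df = pd.DataFrame(rows)
    g = df.groupby("condition")["initial_gr_um_per_min"].agg(["mean", "sem", "count"])
    ax.bar(range(len(g)), g["mean"], yerr=g["sem"].fillna(0), capsize=4)
    ax.set_xticks(range(len(g)), g.index.tolist())
    ax.set(ylabel="initial GR (µm/min)")
    fig.tight_layout()
    save(fig, "condition_summary.png")
    return written
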