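"""Orientation and wiggle statistics at the original frame rate.

Over a short window (2 min at 2 fps ≈ 240 samples) a bound cell's axis
angle θ to the flow fluctuates about a time-median axis M.  The per-cell
summary (θ_M, STD(θ)) separates flow-aligned, loosely bound cells from
flow-normal, firmly bound ones.  The spatial structure of the fluctuation
localises the adhesion: the standard deviation of the instantaneous lateral
separation of each position l along the axis from M is V-shaped with its
vertex at the rotation pivot.  A pivot at the cell centre with a symmetric
profile is the signature of distributed (fimbriae-mediated) binding —
"rocking" — while an off-centre pivot marks a single adhesion patch —
"twisting".

The classical expression for the separation, l × sin(∂θ), is a pure-
rotation approximation whose sd is minimal at l = 0 by construction; to
localise an off-centre pivot the full separation including the correlated
centroid translation is used (both are computed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .tracking import Trajectory, trajectory_to_frame

__all__ = [
    "MotionWindow",
    "WiggleProfile",
    "compute_window",
    "wiggle_profile",
    "population_motion_summary",
]

logger = logging.getLogger(__name__)

DEFAULT_WINDOW_MIN = 2.0
ROCKING_PIVOT_FRAC = 0.15  # |pivot| ≤ this fraction of L counts as central
SYMMETRY_RATIO = 1.8  # max end-to-end sep_std ratio still called symmetric


def fold_angle(theta_deg):
    """Fold an axis angle to [0°, 90°] (a rod's axis has no direction)."""
    th = np.abs(np.mod(np.asarray(theta_deg, dtype=float), 180.0))
    return np.where(th > 90.0, 180.0 - th, th)


def _unwrap_axis(theta_deg: np.ndarray) -> np.ndarray:
    """Resolve the ±180° axis-direction ambiguity into a smooth series.

    The direction minimising frame-to-frame flips is chosen at the first
    frame and held fixed; subsequent samples are shifted by multiples of
    180° to stay within 90° of their predecessor.
    """
    out = np.array(theta_deg, dtype=float)
    for i in range(1, out.size):
        d = out[i] - out[i - 1]
        out[i] -= 180.0 * np.round(d / 180.0)
    return out


@dataclass
class MotionWindow:
    """Orientation statistics of one cell over one full-rate window."""

    traj_id: int
    window_start_min: float
    duration_min: float
    times_min: np.ndarray = field(repr=False)
    theta_series_deg: np.ndarray = field(repr=False)  # unwrapped, signed
    dtheta_deg: np.ndarray = field(repr=False)  # deviation from median axis
    centroids_um: np.ndarray = field(repr=False)  # (n, 2)
    median_centroid_um: tuple[float, float] = (0.0, 0.0)
    median_axis_deg: float = 0.0  # angle of the median axis M (unfolded)
    theta_M: float = 0.0  # median folded angle vs flow, [0, 90]
    theta_std: float = 0.0
    mean_length_um: float = 0.0


def compute_window(
    trajectory: Trajectory | pd.DataFrame,
    window_start_min: float,
    duration_min: float = DEFAULT_WINDOW_MIN,
    min_valid_fraction: float = 0.5,
    frame_interval_min: float | None = None,
) -> MotionWindow | None:
    """Orientation series and summary over one window of one trajectory.

    Accepts either a :class:`Trajectory` or a per-observation table with
    columns ``t_min, x_um, y_um, length_um, theta_signed_deg`` (and
    ``traj_id``).  Returns ``None`` (logged) if fewer than
    ``min_valid_fraction`` of the window's expected frames carry a valid
    observation.
    """
    if isinstance(trajectory, Trajectory):
        df = trajectory_to_frame(trajectory)
        frame_interval_min = trajectory.frame_interval_min
    else:
        df = trajectory
        if frame_interval_min is None:
            dt = np.diff(np.sort(df["t_min"].to_numpy()))
            frame_interval_min = float(np.median(dt)) if dt.size else 1.0
    t0, t1 = window_start_min, window_start_min + duration_min
    sub = df[(df["t_min"] >= t0) & (df["t_min"] < t1)].sort_values("t_min")
    expected = max(int(round(duration_min / frame_interval_min)), 1)
    if len(sub) < min_valid_fraction * expected or len(sub) < 3:
        logger.info(
            "window at %.1f min rejected: %d/%d valid frames", t0, len(sub), expected
        )
        return None
    theta = _unwrap_axis(sub["theta_signed_deg"].to_numpy())
    med = float(np.median(theta))
    dtheta = theta - med
    centroids = sub[["x_um", "y_um"]].to_numpy()
    med_c = tuple(np.median(centroids, axis=0))
    traj_id = int(sub["traj_id"].iloc[0]) if "traj_id" in sub else -1
    return MotionWindow(
        traj_id=traj_id,
        window_start_min=t0,
        duration_min=duration_min,
        times_min=sub["t_min"].to_numpy(),
        theta_series_deg=theta,
        dtheta_deg=dtheta,
        centroids_um=centroids,
        median_centroid_um=med_c,
        median_axis_deg=med,
        theta_M=float(fold_angle(med)),
        theta_std=float(np.std(dtheta, ddof=1)),
        mean_length_um=float(sub["length_um"].mean()),
    )


@dataclass
class WiggleProfile:
    """Per-position separation profile along the cell axis and its pivot."""

    positions_um: np.ndarray  # l ∈ [−L/2, L/2], 0 = cell centre
    sep_std_um: np.ndarray  # sd of the full separation (rotation + translation)
    sep_std_rotation_um: np.ndarray  # sd of the pure-rotation form l·sin(∂θ)
    pivot_hat_um: float  # argmin of sep_std
    length_um: float
    mode: str  # rocking | twisting | undetermined
    confidence: float


def wiggle_profile(
    window: MotionWindow,
    length_um: float | None = None,
    n_positions: int = 41,
    noise_floor_um: float = 1e-3,
) -> WiggleProfile:
    """Separation profile sep_std(l), pivot estimate, and binding mode.

    Per frame, the point at signed arclength l from the centroid along the
    instantaneous axis is projected onto the normal of the median axis M;
    the sd over the window at each l gives the profile.  A rigid rotation
    about a pivot p makes sep_std(l) ∝ |l − p|, so the argmin localises the
    pivot.  Classification: ``rocking`` if the pivot is within 15% of L of
    the centre and the profile is end-to-end symmetric, ``twisting``
    otherwise, ``undetermined`` (flagged) when the motion is below the
    noise floor.
    """
    L = window.mean_length_um if length_um is None else length_um
    if not np.isfinite(L) or L <= 0:
        raise ValueError(f"degenerate cell length: {L}")
    th = np.radians(window.theta_series_deg)
    dth = np.radians(window.dtheta_deg)
    u = np.stack([np.cos(th), np.sin(th)], axis=1)  # instantaneous axis
    med = np.radians(window.median_axis_deg)
    normal = np.array([-np.sin(med), np.cos(med)])
    c_off = window.centroids_um - np.asarray(window.median_centroid_um)
    ls = np.linspace(-L / 2.0, L / 2.0, n_positions)
    # full separation: (c(t) + l·u(t) − c_M) · n_M   for every l and frame
    base = c_off @ normal  # (n_frames,)
    along = u @ normal  # (n_frames,)
    sep = base[None, :] + ls[:, None] * along[None, :]  # (n_l, n_frames)
    sep_std = sep.std(axis=1, ddof=1)
    sep_rot = np.abs(ls)[:, None] * np.sin(dth)[None, :]
    sep_rot_std = sep_rot.std(axis=1, ddof=1)

    if sep_std.max() < noise_floor_um:
        logger.info("wiggle below noise floor: mode undetermined")
        return WiggleProfile(ls, sep_std, sep_rot_std, 0.0, L, "undetermined", 0.0)

    i_min = int(np.argmin(sep_std))
    # parabolic refinement of the V-vertex on the squared profile
    pivot = ls[i_min]
    if 0 < i_min < ls.size - 1:
        y0, y1, y2 = sep_std[i_min - 1 : i_min + 2] ** 2
        denom = y0 - 2 * y1 + y2
        if denom > 0:
            pivot = ls[i_min] + 0.5 * (y0 - y2) / denom * (ls[1] - ls[0])
    pivot = float(np.clip(pivot, -L / 2.0, L / 2.0))

    end_lo, end_hi = sep_std[0], sep_std[-1]
    ratio = max(end_lo, end_hi) / max(min(end_lo, end_hi), noise_floor_um)
    central = abs(pivot) <= ROCKING_PIVOT_FRAC * L
    symmetric = ratio <= SYMMETRY_RATIO
    mode = "rocking" if (central and symmetric) else "twisting"
    # confidence: distance of the pivot from the decision boundary, squashed
    margin = abs(abs(pivot) / L - ROCKING_PIVOT_FRAC) / ROCKING_PIVOT_FRAC
    confidence = float(np.tanh(margin))
    return WiggleProfile(ls, sep_std, sep_rot_std, pivot, L, mode, confidence)


def population_motion_summary(
    windows_by_time: dict[float, list[MotionWindow]],
    n_l_bins: int = 10,
) -> dict:
    """Population summaries at the requested time points.

    Returns per-cell (θ_M, STD(θ)) pairs per time point, pooled sep_std
    distributions per relative axis position, and two-sample KS tests on
    θ_M and STD(θ) between consecutive time points.
    """
    if not windows_by_time:
        raise ValueError("no windows supplied")
    angle_rows, profile_rows = [], []
    for t, windows in sorted(windows_by_time.items()):
        if not windows:
            logger.warning("no valid windows at time point %.1f min", t)
            continue
        for w in windows:
            angle_rows.append(
                {"time_min": t, "traj_id": w.traj_id,
                 "theta_M": w.theta_M, "theta_std": w.theta_std}
            )
            prof = wiggle_profile(w)
            rel = prof.positions_um / prof.length_um  # [−0.5, 0.5]
            bins = np.clip(((rel + 0.5) * n_l_bins).astype(int), 0, n_l_bins - 1)
            for b in range(n_l_bins):
                m = bins == b
                if m.any():
                    profile_rows.append(
                        {"time_min": t, "traj_id": w.traj_id,
                         "l_rel_bin": (b + 0.5) / n_l_bins - 0.5,
                         "sep_std_um": float(prof.sep_std_um[m].mean()),
                         "mode": prof.mode}
                    )
    angles = pd.DataFrame(angle_rows)
    profiles = pd.DataFrame(profile_rows)
    tests = []
    times = sorted(windows_by_time)
    for a, b in zip(times[:-1], times[1:]):
        for metric in ("theta_M", "theta_std"):
            va = angles.loc[angles["time_min"] == a, metric]
            vb = angles.loc[angles["time_min"] == b, metric]
            if len(va) >= 2 and len(vb) >= 2:
                ks, p = stats.ks_2samp(va, vb)
                tests.append({"time_a": a, "time_b": b, "metric": metric,
                              "ks": float(ks), "p": float(p)})
    mode_fractions = (
        profiles.drop_duplicates(["time_min", "traj_id"])
        .groupby("time_min")["mode"]
        .value_counts(normalize=True)
        .rename("fraction")
        .reset_index()
        if not profiles.empty
        else pd.DataFrame(columns=["time_min", "mode", "fraction"])
    )
    return {"angles": angles, "profiles": profiles,
            "tests": pd.DataFrame(tests), "mode_fractions": mode_fractions}
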