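"""Stitch per-frame observations into trajectories with lineage.

Bound cells barely move between averaged frames, so linking is greedy by
footprint overlap: an observation continues a trajectory if their pixel
footprints overlap and the length changed by less than 25%.  A trajectory
whose footprint maps onto two gated footprints whose lengths sum to about
the mother's is closed as a division, spawning two child trajectories that
record their parent.  Cells that temporarily vanish from the mask (focus
drift) are bridged for up to a configurable gap if they reappear nearby
with unaltered appearance; everything else starts a new parentless
trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .segmentation import CellObservation

__all__ = [
    "TrackingParams",
    "Trajectory",
    "link",
    "filter_for_growth",
    "trajectory_to_frame",
    "trajectories_table",
    "lineage_table",
]

_STRIDE = 1 << 20  # flattening stride for footprint pixel sets


@dataclass
class TrackingParams:
    max_length_change: float = 0.25  # fractional |ΔL|/L between frames
    gap_tolerance_min: float = 1.0  # how long a cell may vanish from the mask
    reappearance_similarity: float = 0.15  # length tolerance when resuming

    def validate(self) -> None:
        if not (0.0 < self.max_length_change < 1.0):
            raise ValueError("max_length_change must be in (0, 1)")
        if self.gap_tolerance_min < 0:
            raise ValueError("gap_tolerance_min must be ≥ 0")
        if not (0.0 < self.reappearance_similarity < 1.0):
            raise ValueError("reappearance_similarity must be in (0, 1)")


@dataclass
class Trajectory:
    """Time-ordered observations of one surface-bound cell."""

    traj_id: int
    parent_id: int | None
    observations: list[CellObservation] = field(default_factory=list)
    fate: str = "censored"  # divided | detached | censored
    frame_interval_min: float = 1.0
    gr_start_min: float | None = None  # GR-eligible interior, set by filter
    gr_end_min: float | None = None

    @property
    def start_min(self) -> float:
        return self.observations[0].frame * self.frame_interval_min

    @property
    def end_min(self) -> float:
        return self.observations[-1].frame * self.frame_interval_min

    @property
    def duration_min(self) -> float:
        return self.end_min - self.start_min

    def times_min(self) -> np.ndarray:
        return np.array([o.frame for o in self.observations]) * self.frame_interval_min

    def lengths_um(self) -> np.ndarray:
        return np.array([o.length_um for o in self.observations])


class _Open:
    __slots__ = ("traj", "fp", "length", "centroid", "last_frame")

    def __init__(self, traj, obs):
        self.traj = traj
        self.update(obs)

    def update(self, obs: CellObservation):
        self.fp = obs.footprint_set(_STRIDE)
        self.length = obs.length_um
        self.centroid = (obs.x_um, obs.y_um)
        self.last_frame = obs.frame


def link(
    obs_by_frame: dict[int, list[CellObservation]],
    frame_interval_min: float,
    params: TrackingParams | None = None,
) -> list[Trajectory]:
    """Greedy overlap-based frame-to-frame linking with lineage.

    Ties are broken by maximal overlap, then minimal relative length
    change.  No observation is ever assigned to two trajectories.
    """
    params = params or TrackingParams()
    params.validate()
    if frame_interval_min <= 0:
        raise ValueError("frame_interval_min must be positive (calibrated input)")
    frames = sorted(obs_by_frame)
    done: list[Trajectory] = []
    active: list[_Open] = []
    next_id = 0

    def start(obs, parent_id=None) -> _Open:
        nonlocal next_id
        traj = Trajectory(next_id, parent_id, [obs], frame_interval_min=frame_interval_min)
        next_id += 1
        op = _Open(traj, obs)
        active.append(op)
        return op

    for frame in frames:
        observations = obs_by_frame[frame]
        labels = [o.label for o in observations]
        if len(set(labels)) != len(labels):
            raise ValueError(f"duplicate labels in frame {frame}")
        fps = [o.footprint_set(_STRIDE) for o in observations]
        # all (track, obs) overlaps
        cand: list[tuple[int, int, int]] = []  # (overlap, track_idx, obs_idx)
        per_track: dict[int, list[tuple[int, int]]] = {}
        for ti, op in enumerate(active):
            for oi, fp in enumerate(fps):
                ov = len(op.fp & fp)
                if ov:
                    cand.append((ov, ti, oi))
                    per_track.setdefault(ti, []).append((ov, oi))

        assigned_obs: set[int] = set()
        closed_tracks: set[int] = set()

        # --- divisions: one footprint splitting into two daughters -------
        for ti, hits in per_track.items():
            if len(hits) < 2:
                continue
            hits.sort(reverse=True)
            (ov1, o1), (ov2, o2) = hits[0], hits[1]
            if o1 in assigned_obs or o2 in assigned_obs:
                continue
            op = active[ti]
            total = observations[o1].length_um + observations[o2].length_um
            if abs(total - op.length) / op.length <= params.max_length_change:
                op.traj.fate = "divided"
                done.append(op.traj)
                closed_tracks.add(ti)
                for oi in (o1, o2):
                    start(observations[oi], parent_id=op.traj.traj_id)
                    assigned_obs.add(oi)

        # --- greedy continuation -----------------------------------------
        def tie_key(c):
            ov, ti, oi = c
            dl = abs(observations[oi].length_um - active[ti].length) / active[ti].length
            return (-ov, dl)

        for ov, ti, oi in sorted(cand, key=tie_key):
            if ti in closed_tracks or oi in assigned_obs:
                continue
            op = active[ti]
            if op.last_frame == frame:  # already extended this frame
                continue
            dl = abs(observations[oi].length_um - op.length) / op.length
            if dl >= params.max_length_change:
                continue
            op.traj.observations.append(observations[oi])
            op.update(observations[oi])
            assigned_obs.add(oi)

        # --- gap bridging: reappearance with unaltered appearance --------
        waiting = [
            op for ti, op in enumerate(active)
            if ti not in closed_tracks and op.last_frame < frame
        ]
        free = [oi for oi in range(len(observations)) if oi not in assigned_obs]
        for op in waiting:
            best = None
            for oi in free:
                o = observations[oi]
                d = np.hypot(o.x_um - op.centroid[0], o.y_um - op.centroid[1])
                dl = abs(o.length_um - op.length) / op.length
                if d <= op.length and dl <= params.reappearance_similarity:
                    if best is None or d < best[0]:
                        best = (d, oi)
            if best is not None:
                oi = best[1]
                op.traj.observations.append(observations[oi])
                op.update(observations[oi])
                assigned_obs.add(oi)
                free.remove(oi)

        # --- expire tracks whose gap exceeded tolerance -------------------
        still_active: list[_Open] = []
        for ti, op in enumerate(active):
            if ti in closed_tracks:
                continue
            gap_min = (frame - op.last_frame) * frame_interval_min
            if gap_min > params.gap_tolerance_min:
                op.traj.fate = "detached"
                done.append(op.traj)
            else:
                still_active.append(op)
        active = still_active

        # --- new appearances ---------------------------------------------
        for oi in range(len(observations)):
            if oi not in assigned_obs:
                start(observations[oi])

    for op in active:
        op.traj.fate = "censored"
        done.append(op.traj)
    done.sort(key=lambda t: t.traj_id)
    return done


def filter_for_growth(
    trajectories: list[Trajectory],
    min_duration_min: float = 10.0,
    edge_exclusion_min: float = 5.0,
) -> list[Trajectory]:
    """Select trajectories usable for growth-rate estimation.

    Trajectories shorter than ``min_duration_min`` are dropped; on the
    survivors the first and last ``edge_exclusion_min`` are marked
    ineligible for GR evaluation (the observations themselves are retained
    for counting).  A trajectory exactly at the minimum survives with a
    zero-width eligible interior.
    """
    out = []
    for tr in trajectories:
        if tr.duration_min < min_duration_min:
            continue
        tr.gr_start_min = tr.start_min + edge_exclusion_min
        tr.gr_end_min = tr.end_min - edge_exclusion_min
        out.append(tr)
    return out


def trajectory_to_frame(traj: Trajectory) -> pd.DataFrame:
    """Per-observation table of one trajectory (times in minutes)."""
    return pd.DataFrame(
        {
            "traj_id": traj.traj_id,
            "parent_id": traj.parent_id if traj.parent_id is not None else -1,
            "frame": [o.frame for o in traj.observations],
            "t_min": [o.frame * traj.frame_interval_min for o in traj.observations],
            "x_um": [o.x_um for o in traj.observations],
            "y_um": [o.y_um for o in traj.observations],
            "length_um": [o.length_um for o in traj.observations],
            "theta_deg": [o.theta_deg for o in traj.observations],
            "theta_signed_deg": [o.theta_signed_deg for o in traj.observations],
        }
    )


def trajectories_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    if not trajectories:
        return pd.DataFrame(
            columns=["traj_id", "parent_id", "frame", "t_min", "x_um", "y_um",
                     "length_um", "theta_deg", "theta_signed_deg"]
        )
    return pd.concat([trajectory_to_frame(t) for t in trajectories], ignore_index=True)


def lineage_table(trajectories: list[Trajectory]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "traj_id": t.traj_id,
                "parent_id": t.parent_id if t.parent_id is not None else -1,
                "start_min": t.start_min,
                "end_min": t.end_min,
                "fate": t.fate,
            }
            for t in trajectories
        ]
    )
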