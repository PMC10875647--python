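"""Round-trip metrics against simulator ground truth.

Used to benchmark the pipeline on rendered scenes where every cell is
known: detection precision/recall under IoU matching, length and angle
errors, and lineage link errors for the tracker.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motion import fold_angle
from .segmentation import CellObservation
from .synthetic import SceneConfig, rod_mask
from .tracking import Trajectory

__all__ = ["DetectionReport", "detection_metrics", "assign_truth_ids", "lineage_errors"]


@dataclass
class DetectionReport:
    precision: float
    recall: float
    length_mae_px: float
    theta_mae_deg: float
    n_matched: int
    n_false_positive: int
    n_missed: int


def _truth_coord_sets(truth_frame: pd.DataFrame, config: SceneConfig):
    px = config.pixel_size_um
    shape = config.image_shape
    out = []
    for row in truth_frame.itertuples():
        mask = rod_mask(
            shape,
            (row.x_um / px, row.y_um / px),
            row.length_um / px,
            config.cell_width_um / px,
            row.theta_deg,
        )
        rr, cc = np.nonzero(mask)
        out.append((row, set((rr * shape[1] + cc).tolist())))
    return out


def detection_metrics(
    obs_by_frame: dict[int, list[CellObservation]],
    truth: pd.DataFrame,
    config: SceneConfig,
    frame_map: dict[int, int] | None = None,
    iou_threshold: float = 0.5,
) -> DetectionReport:
    """Greedy IoU matching of observations to ground-truth footprints.

    ``frame_map`` translates observation frame indices to truth frame
    indices (needed after block averaging); identity by default.
    """
    n_cols = config.image_shape[1]
    tp = fp = fn = 0
    len_err_px: list[float] = []
    theta_err: list[float] = []
    for f, obs in obs_by_frame.items():
        tf = frame_map.get(f, f) if frame_map else f
        rows = truth[(truth["frame"] == tf) & truth["bound"]]
        truth_sets = _truth_coord_sets(rows, config)
        obs_sets = [o.footprint_set(n_cols) for o in obs]
        pairs = []
        for oi, oset in enumerate(obs_sets):
            for ti, (_, tset) in enumerate(truth_sets):
                inter = len(oset & tset)
                if inter:
                    iou = inter / len(oset | tset)
                    if iou >= iou_threshold:
                        pairs.append((iou, oi, ti))
        pairs.sort(reverse=True)
        used_o: set[int] = set()
        used_t: set[int] = set()
        for iou, oi, ti in pairs:
            if oi in used_o or ti in used_t:
                continue
            used_o.add(oi)
            used_t.add(ti)
            row = truth_sets[ti][0]
            len_err_px.append(
                abs(obs[oi].length_um - row.length_um) / config.pixel_size_um
            )
            theta_err.append(
                float(abs(fold_angle(obs[oi].theta_deg) - fold_angle(row.theta_deg)))
            )
        tp += len(used_o)
        fp += len(obs) - len(used_o)
        fn += len(truth_sets) - len(used_t)
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return DetectionReport(
        precision=precision,
        recall=recall,
        length_mae_px=float(np.mean(len_err_px)) if len_err_px else np.nan,
        theta_mae_deg=float(np.mean(theta_err)) if theta_err else np.nan,
        n_matched=tp,
        n_false_positive=fp,
        n_missed=fn,
    )


def assign_truth_ids(
    obs: CellObservation, truth_frame: pd.DataFrame, max_dist_um: float | None = None
) -> int | None:
    """Nearest-centroid truth id for one observation (None if too far)."""
    if truth_frame.empty:
        return None
    d = np.hypot(truth_frame["x_um"] - obs.x_um, truth_frame["y_um"] - obs.y_um)
    i = int(d.idxmin())
    limit = max_dist_um if max_dist_um is not None else 0.6 * obs.length_um
    return int(truth_frame.loc[i, "cell_id"]) if d[i] <= limit else None


def lineage_errors(
    trajectories: list[Trajectory],
    truth: pd.DataFrame,
    frame_map: dict[int, int] | None = None,
) -> tuple[int, int]:
    """(wrong links, total links) between tracker output and ground truth.

    Every consecutive observation pair inside a trajectory is one link, and
    every parent→child relation is one link; a link counts as wrong when
    the two observations resolve to different truth cells (or fail to
    resolve), or when the recorded parent does not match the truth parent.
    """
    truth_by_frame = {f: g for f, g in truth[truth["bound"]].groupby("frame")}
    parent_of = (
        truth.drop_duplicates("cell_id").set_index("cell_id")["parent_id"].to_dict()
    )
    ids_per_traj: dict[int, list[int | None]] = {}
    for tr in trajectories:
        ids = []
        for o in tr.observations:
            tf = frame_map.get(o.frame, o.frame) if frame_map else o.frame
            tframe = truth_by_frame.get(tf, pd.DataFrame(columns=truth.columns))
            ids.append(assign_truth_ids(o, tframe))
        ids_per_traj[tr.traj_id] = ids
    wrong = total = 0
    majority: dict[int, int | None] = {}
    for tr in trajectories:
        ids = ids_per_traj[tr.traj_id]
        vals = [i for i in ids if i is not None]
        majority[tr.traj_id] = max(set(vals), key=vals.count) if vals else None
        for a, b in zip(ids[:-1], ids[1:]):
            total += 1
            if a is None or b is None or a != b:
                wrong += 1
    for tr in trajectories:
        if tr.parent_id is None:
            continue
        total += 1
        child = majority.get(tr.traj_id)
        mother = majority.get(tr.parent_id)
        truth_parent = parent_of.get(child) if child is not None else None
        if child is None or mother is None or not (
            pd.notna(truth_parent) and int(truth_parent) == mother
        ):
            wrong += 1
    return wrong, total
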