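"""Frame correction and rod segmentation.

The chain mirrors routine brightfield practice for surface-bound bacteria:
block-average raw frames to blur out moving (unbound) cells, flatten the
uneven illumination and subtract the background, then build a cell mask by
constant-offset subtraction, two rounds of median filtering and a
marker-controlled watershed seeded from the smoothed distance transform,
and finally gate the candidate regions on area, aspect ratio and solidity
so that round confounders (e.g. peptide nanoparticles) are excluded.

Lengths are reported as the maximum Feret (caliper) diameter of the
footprint, which for a convex rod equals its tip-to-tip extent; width and
orientation come from the moments-equivalent ellipse.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation as sk_seg

from .io import MovieStack

__all__ = [
    "SegmentationParams",
    "CellObservation",
    "average_frames",
    "correct_illumination",
    "segment_frame",
    "segment_stack",
    "observations_to_frame",
]

logger = logging.getLogger(__name__)


@dataclass
class SegmentationParams:
    """Tunable knobs of the mask-construction chain.

    ``intensity_offset`` is the user-set constant subtracted from the
    corrected (positive-going) image before masking; it should sit between
    the noise floor and the typical cell depth.  Area bounds are physical
    (µm²); shape gates reject round or ragged regions.
    """

    averaging_block: int = 20
    intensity_offset: float = 0.15
    median_radius: int = 2
    min_area_um2: float = 1.0
    max_area_um2: float = 15.0
    min_aspect_ratio: float = 1.8
    min_solidity: float = 0.85
    marker_rel_height: float = 0.7  # marker = EDT above this fraction of the
    # component's distance maximum; controls how deep a neck splits objects
    marker_smooth_px: float = 1.0

    def validate(self) -> None:
        if self.averaging_block < 1:
            raise ValueError("averaging_block must be ≥ 1")
        if not (0 < self.min_area_um2 < self.max_area_um2):
            raise ValueError("area bounds must be positive and ordered")
        if self.min_aspect_ratio < 1.0:
            raise ValueError("min_aspect_ratio must be ≥ 1")
        if not (0.0 <= self.min_solidity <= 1.0):
            raise ValueError("min_solidity must be in [0, 1]")


@dataclass
class CellObservation:
    """One segmented bacterium in one frame.

    ``theta_deg`` is the major-axis angle to the flow (+x) axis folded to
    [0°, 90°] (a rod's axis has no direction); ``theta_signed_deg`` keeps
    the sign in (−90°, 90°] for the full-rate wiggle analysis.
    """

    frame: int
    label: int
    x_um: float
    y_um: float
    length_um: float
    width_um: float
    theta_deg: float
    theta_signed_deg: float
    area_um2: float
    solidity: float
    mean_intensity: float
    coords: np.ndarray = field(repr=False)  # (n, 2) array of (row, col) pixels

    def __post_init__(self) -> None:
        if not (self.length_um >= self.width_um > 0):
            raise ValueError("require length_um ≥ width_um > 0")
        if not (0.0 <= self.theta_deg <= 90.0):
            raise ValueError("theta_deg must lie in [0, 90]")

    @property
    def aspect_ratio(self) -> float:
        return self.length_um / self.width_um

    def footprint_set(self, n_cols: int) -> set[int]:
        """Footprint as flattened pixel indices (for overlap tests)."""
        return set((self.coords[:, 0] * n_cols + self.coords[:, 1]).tolist())


# ---------------------------------------------------------------------------


def average_frames(stack: MovieStack, block: int) -> MovieStack:
    """Average every ``block`` consecutive frames.

    Divides the effective frame rate by ``block`` (20 blocks turn a 2 fps
    acquisition into 0.1 fps), averaging out cells that move between raw
    frames.  A trailing remainder of fewer than ``block`` frames is dropped.
    """
    if block < 1:
        raise ValueError("block must be ≥ 1")
    n = stack.n_frames
    if block > n:
        raise ValueError(f"block ({block}) exceeds stack length ({n})")
    if block == 1:
        return stack
    n_out = n // block
    if n % block:
        logger.info("average_frames: dropping trailing %d frame(s)", n % block)
    data = stack.frames[: n_out * block].reshape(n_out, block, *stack.frames.shape[1:])
    return MovieStack(
        frames=data.mean(axis=1),
        frame_rate_fps=stack.frame_rate_fps / block,
        pixel_size_um=stack.pixel_size_um,
        flow_axis=stack.flow_axis,
        meta=dict(stack.meta),
    )


def _poly_design(shape, order):
    yy = np.linspace(-1, 1, shape[0])
    xx = np.linspace(-1, 1, shape[1])
    X, Y = np.meshgrid(xx, yy)
    cols = [X**i * Y**j for i in range(order + 1) for j in range(order + 1 - i)]
    return np.stack([c.ravel() for c in cols], axis=1)


def correct_illumination(frame: np.ndarray, poly_order: int = 2, n_iter: int = 3):
    """Flatten uneven illumination and subtract the background.

    A low-order 2-D polynomial surface is fitted to the background by an
    iteratively trimmed least squares (pixels darker than the fit — the
    cells — are down-weighted out), the frame is divided by it, and the
    residual background level removed.  The result has background ≈ 0 with
    cells as a positive-going absorption magnitude, so downstream masking
    is invariant to the illumination profile.
    """
    frame = np.asarray(frame, dtype=float)
    if not np.all(np.isfinite(frame)):
        raise ValueError("frame contains non-finite values")
    if frame.std() < 1e-12 * max(abs(frame.mean()), 1.0):
        logger.warning("correct_illumination: constant frame, returning zeros")
        return np.zeros_like(frame)
    design = _poly_design(frame.shape, poly_order)
    z = frame.ravel()
    weight = np.ones_like(z, dtype=bool)
    fit = None
    for _ in range(n_iter):
        coef, *_ = np.linalg.lstsq(design[weight], z[weight], rcond=None)
        fit = design @ coef
        resid = z - fit
        sigma = 1.4826 * np.median(np.abs(resid - np.median(resid))) or resid.std() or 1.0
        weight = resid > -2.0 * sigma  # trim dark (cell) pixels only
        if weight.sum() < design.shape[1] * 3:
            break
    surface = fit.reshape(frame.shape)
    surface = np.where(surface > 1e-9, surface, 1e-9)
    flattened = frame / surface
    background = np.median(flattened)
    return background - flattened  # cells positive-going, background ≈ 0


def _theta_signed_from_orientation(orientation_rad: float) -> float:
    """skimage moments orientation → signed angle to the +x (flow) axis."""
    theta = 90.0 - math.degrees(orientation_rad)
    if theta > 90.0:
        theta -= 180.0
    return theta


def segment_frame(
    frame: np.ndarray,
    params: SegmentationParams,
    pixel_size_um: float,
    frame_index: int = 0,
) -> list[CellObservation]:
    """Segment one illumination-corrected frame into cell observations.

    Applies, in order: constant-offset subtraction (clamped at zero), two
    median-filter passes, marker-controlled watershed (markers are the
    extended maxima of the smoothed Euclidean distance transform, so a
    straight rod seeds one marker along its ridge while touching rods seed
    one per ridge), then the area/aspect/solidity gates.  An empty
    foreground is a valid result.
    """
    params.validate()
    img = np.clip(np.asarray(frame, dtype=float) - params.intensity_offset, 0.0, None)
    fp = morphology.disk(params.median_radius)
    img = ndimage.median_filter(img, footprint=fp)
    img = ndimage.median_filter(img, footprint=fp)
    mask = img > 0
    min_area_px = params.min_area_um2 / pixel_size_um**2
    mask = morphology.remove_small_objects(mask, max_size=max(int(min_area_px // 4), 4) - 1)
    if not mask.any():
        return []
    dist = ndimage.distance_transform_edt(mask)
    if params.marker_smooth_px > 0:
        dist_s = ndimage.gaussian_filter(dist, params.marker_smooth_px)
    else:
        dist_s = dist
    # markers: extended maxima of the distance map, taken per connected
    # component as everything above a fraction of that component's ridge
    # height — a straight rod seeds one marker along its whole ridge, while
    # a neck between touching rods falls below the threshold and splits them
    comp, n_comp = ndimage.label(mask)
    comp_max = ndimage.maximum(dist_s, comp, index=np.arange(1, n_comp + 1))
    thresh = np.zeros_like(dist_s)
    thresh[mask] = params.marker_rel_height * comp_max[comp[mask] - 1]
    peaks = mask & (dist_s > thresh)
    markers, n_mark = ndimage.label(peaks)
    if n_mark == 0:
        markers = comp
    labels = sk_seg.watershed(-dist_s, markers, mask=mask)

    out: list[CellObservation] = []
    px = pixel_size_um
    for rp in measure.regionprops(labels, intensity_image=frame):
        area_um2 = rp.area * px**2
        if not (params.min_area_um2 <= area_um2 <= params.max_area_um2):
            continue
        if rp.solidity < params.min_solidity:
            continue
        length_um = rp.feret_diameter_max * px
        # width from the spherocylinder area model A = wL − w²(1 − π/4):
        # unbiased for rods, reduces to w = L for round blobs
        c4 = 1.0 - math.pi / 4.0
        disc = length_um**2 - 4.0 * c4 * area_um2
        if disc >= 0:
            width_um = (length_um - math.sqrt(disc)) / (2.0 * c4)
        else:
            width_um = max(rp.axis_minor_length, 1.0) * px
        width_um = max(min(width_um, length_um), px)
        if length_um < width_um:
            length_um, width_um = width_um, length_um
        if length_um / width_um < params.min_aspect_ratio:
            continue
        theta_signed = _theta_signed_from_orientation(rp.orientation)
        cy, cx = rp.centroid
        out.append(
            CellObservation(
                frame=frame_index,
                label=rp.label,
                x_um=cx * px,
                y_um=cy * px,
                length_um=length_um,
                width_um=width_um,
                theta_deg=abs(theta_signed),
                theta_signed_deg=theta_signed,
                area_um2=area_um2,
                solidity=rp.solidity,
                mean_intensity=float(rp.intensity_mean),
                coords=rp.coords.astype(np.int32),
            )
        )
    return out


def segment_stack(
    stack: MovieStack, params: SegmentationParams, average: bool = True
) -> tuple[dict[int, list[CellObservation]], MovieStack]:
    """Correct and segment a whole movie.

    Returns the per-frame observations and the (possibly block-averaged)
    stack they refer to.
    """
    work = average_frames(stack, params.averaging_block) if average else stack
    obs: dict[int, list[CellObservation]] = {}
    for f in range(work.n_frames):
        corrected = correct_illumination(work.frames[f])
        obs[f] = segment_frame(corrected, params, work.pixel_size_um, frame_index=f)
    return obs, work


def observations_to_frame(obs: dict[int, list[CellObservation]] | Sequence[CellObservation]) -> pd.DataFrame:
    """Flatten observations into the on-disk CSV schema."""
    if isinstance(obs, dict):
        flat = [o for frame in sorted(obs) for o in obs[frame]]
    else:
        flat = list(obs)
    return pd.DataFrame(
        [
            {
                "frame": o.frame,
                "label": o.label,
                "x_um": o.x_um,
                "y_um": o.y_um,
                "length_um": o.length_um,
                "width_um": o.width_um,
                "theta_deg": o.theta_deg,
                "theta_signed_deg": o.theta_signed_deg,
                "area_um2": o.area_um2,
            }
            for o in flat
        ]
    )
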