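"""Movie container and on-disk formats.

A :class:`MovieStack` is the in-memory form of a brightfield time-lapse:
a (t, rows, cols) grayscale array with physical calibration.  On disk it is
a multi-page 16-bit TIFF plus a JSON sidecar carrying the calibration and
provenance (seed, config hash) that TIFF tags do not hold reliably.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

__all__ = ["MovieStack", "write_truth_csv", "read_truth_csv"]

TRUTH_COLUMNS = [
    "cell_id",
    "parent_id",
    "frame",
    "x_um",
    "y_um",
    "length_um",
    "theta_deg",
    "pivot_frac",
    "bound",
]


@dataclass
class MovieStack:
    """Ordered grayscale frames with physical calibration.

    Flow is along +x (image columns) by convention; the pixel grid origin is
    the top-left corner with y increasing downward.
    """

    frames: np.ndarray  # (t, rows, cols), float or integer grayscale
    frame_rate_fps: float
    pixel_size_um: float
    flow_axis: str = "+x"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a 3-D (t, rows, cols) array")
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("frame intensities must be finite")
        if self.frame_rate_fps <= 0 or self.pixel_size_um <= 0:
            raise ValueError("frame_rate_fps and pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def frame_interval_min(self) -> float:
        """Minutes between consecutive frames."""
        return 1.0 / (self.frame_rate_fps * 60.0)

    def times_min(self) -> np.ndarray:
        """Acquisition time of each frame in minutes (frame 0 at t=0)."""
        return np.arange(self.n_frames) * self.frame_interval_min

    def save(self, path: str | Path) -> None:
        """Write a multi-page 16-bit TIFF plus a ``<stem>.json`` sidecar."""
        path = Path(path)
        data = self.frames.astype(np.float64)
        lo, hi = float(data.min()), float(data.max())
        scale = (hi - lo) or 1.0
        u16 = np.round((data - lo) / scale * 65535.0).astype(np.uint16)
        tifffile.imwrite(path, u16, photometric="minisblack")
        sidecar = {
            "frame_rate_fps": self.frame_rate_fps,
            "pixel_size_um": self.pixel_size_um,
            "flow_axis": self.flow_axis,
            "intensity_lo": lo,
            "intensity_hi": hi,
            **self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "MovieStack":
        path = Path(path)
        u16 = tifffile.imread(path)
        if u16.ndim == 2:
            u16 = u16[None]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        lo = sidecar.pop("intensity_lo", 0.0)
        hi = sidecar.pop("intensity_hi", 65535.0)
        frames = u16.astype(np.float64) / 65535.0 * ((hi - lo) or 1.0) + lo
        return cls(
            frames=frames,
            frame_rate_fps=sidecar.pop("frame_rate_fps"),
            pixel_size_um=sidecar.pop("pixel_size_um"),
            flow_axis=sidecar.pop("flow_axis", "+x"),
            meta=sidecar,
        )


def write_truth_csv(truth: pd.DataFrame, path: str | Path) -> None:
    truth.to_csv(path, index=False, columns=TRUTH_COLUMNS)


def read_truth_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRUTH_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"truth CSV missing columns: {sorted(missing)}")
    return df
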