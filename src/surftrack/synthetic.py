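"""Agent-based simulator of bacterial surface colonization under flow.

The scene emulates what a brightfield time-lapse of a flow channel floor
records: rod-shaped cells arrive on the surface as a Poisson stream while
the inoculum is injected, elongate following a population growth-rate
schedule (linear early in the cell cycle, near-exponential when approaching
division), divide with optional asymmetry, and detach stochastically with
an exponential residence time of configurable half-life.  Each bound cell
carries an orientation state: a median axis that relaxes from flow-aligned
(θ ≈ 0°) toward flow-normal (θ → 90°) as additional adhesive bonds form,
plus a small mean-reverting angular wiggle ∂θ about a pivot point that may
sit at the cell centre (rocking) or off-centre (twisting).

:func:`simulate` produces the per-frame ground truth; :func:`render` turns
it into a brightfield movie (dark cells on a bright, unevenly illuminated
background, with optical blur, sensor noise, optional focus drift and round
nanoparticle confounders).  Together they provide movies with known answers
for every downstream estimator in this package.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, asdict
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .growth import GompertzParams
from .io import MovieStack

__all__ = [
    "SceneConfig",
    "SceneConfigError",
    "TruthTrack",
    "SimulationResult",
    "simulate",
    "simulate_truth",
    "render",
    "truth_table",
    "rod_mask",
]

logger = logging.getLogger(__name__)

# population GR rises from 0.045 to 0.09 µm/min around t≈45 min: the final
# value gives a duplication time T₂ = (2/3)·4.5/0.09 ≈ 33 min, and the
# initial value is half the final, matching the adaptation-lag kinetics of
# surface-bound E. coli
DEFAULT_GR_SCHEDULE = GompertzParams(y0=0.045, A=0.09, k=0.08, t_i=45.0)


class SceneConfigError(ValueError):
    """Invalid scene configuration; the message names the offending field."""


@dataclass
class SceneConfig:
    """Study conditions for one synthetic colonization movie.

    Defaults mirror a wild-type *E. coli* experiment on a mannose-coated
    channel floor: 2 fps acquisition over 3 h, a 20-min inoculum injection,
    an initial growth rate of 0.01 µm/min rising to 0.025 µm/min with a
    transition near 60 min, division around 4.5 µm, and a surface residence
    half-life of 60 min.
    """

    duration_min: float = 180.0
    frame_rate_fps: float = 2.0
    pixel_size_um: float = 0.1
    image_shape: tuple[int, int] = (512, 512)  # (rows, cols)
    injection_window_min: float = 20.0
    arrival_rate_per_min: float = 1.0
    initial_cells: int = 0  # cells present at t=0, in addition to arrivals
    initial_length_um: tuple[float, float] = (2.2, 0.25)  # (mean, sd), ±2σ truncated
    gr_schedule: GompertzParams = field(default_factory=lambda: DEFAULT_GR_SCHEDULE)
    division_length_um: float = 4.5
    division_asymmetry: float = 0.1
    division_gap_um: float = 0.5  # visible septation gap between daughters
    daughter_detach_prob: float = 0.1
    detach_halflife_min: float = 60.0  # may be inf (no detachment)
    realign_rate_per_min: float = 0.02
    initial_theta_sd_deg: float = 8.0  # spread of binding angles about flow axis
    wiggle_amplitude_deg: float = 3.0  # stationary sd of the OU wiggle
    wiggle_relax_time_s: float = 5.0
    pivot_offset_frac: float = 0.0  # signed fraction of length; 0 = rocking
    min_spacing_um: float | None = None  # arrival excluded-volume radius;
    # default = division_length_um (a cell cannot bind on top of another)
    steric_clearance_frac: float = 1.5  # contact-pushing clearance between
    # centrelines, in cell widths; keeps inter-cell furrows optically visible
    contact_pushing: bool = True  # steric exclusion between cells; disable
    # only for non-rendered statistical ensembles where positions are moot
    cell_width_um: float = 0.9
    cell_contrast: float = 0.35  # fractional absorption depth of a cell
    background_level: float = 1.0
    noise_sd: float = 0.02
    psf_sigma_px: float = 1.0
    focus_drift_amp_px: float = 0.0  # sinusoidal extra blur amplitude
    illumination_coeffs: Sequence[Sequence[float]] | None = None
    nanoparticle_rate_per_min: float = 0.0
    nanoparticle_diameter_um: float = 0.4
    seed: int = 0

    def validate(self) -> None:
        def positive(name):
            v = getattr(self, name)
            if not np.isfinite(v) or v <= 0:
                raise SceneConfigError(f"{name} must be positive and finite, got {v}")

        for name in (
            "duration_min", "frame_rate_fps", "pixel_size_um", "division_length_um",
            "wiggle_relax_time_s", "cell_width_um", "background_level",
        ):
            positive(name)
        for name in (
            "injection_window_min", "arrival_rate_per_min", "realign_rate_per_min",
            "wiggle_amplitude_deg", "noise_sd", "psf_sigma_px",
            "nanoparticle_rate_per_min", "initial_theta_sd_deg",
        ):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise SceneConfigError(f"{name} must be non-negative and finite, got {v}")
        if not (0.0 <= self.division_asymmetry < 0.5):
            raise SceneConfigError(
                f"division_asymmetry must be in [0, 0.5), got {self.division_asymmetry}"
            )
        if not (-0.5 <= self.pivot_offset_frac <= 0.5):
            raise SceneConfigError(
                f"pivot_offset_frac must be in [-0.5, 0.5], got {self.pivot_offset_frac}"
            )
        if not (0.0 <= self.daughter_detach_prob <= 1.0):
            raise SceneConfigError(
                f"daughter_detach_prob must be in [0, 1], got {self.daughter_detach_prob}"
            )
        if self.detach_halflife_min <= 0:  # inf allowed
            raise SceneConfigError(
                f"detach_halflife_min must be positive (inf = none), got {self.detach_halflife_min}"
            )
        mean, sd = self.initial_length_um
        if mean <= 0 or sd < 0:
            raise SceneConfigError(f"initial_length_um (mean, sd) invalid: {(mean, sd)}")
        rows, cols = self.image_shape
        if rows < 16 or cols < 16:
            raise SceneConfigError(f"image_shape too small: {self.image_shape}")
        if self.initial_cells < 0:
            raise SceneConfigError("initial_cells must be ≥ 0")

    @property
    def n_frames(self) -> int:
        return int(self.duration_min * 60.0 * self.frame_rate_fps)

    @property
    def frame_interval_min(self) -> float:
        return 1.0 / (self.frame_rate_fps * 60.0)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gr_schedule"] = {k: getattr(self.gr_schedule, k) for k in ("y0", "A", "k", "t_i")}
        return d


class TruthTrack(NamedTuple):
    """Ground-truth record of one cell in one frame."""

    cell_id: int
    parent_id: int | None
    frame: int
    x_um: float
    y_um: float
    length_um: float
    theta_deg: float
    pivot_frac: float
    bound: bool


@dataclass
class SimulationResult:
    tracks: list
    events: list  # dicts: kind, cell_id, frame, effective_frame, t_min
    config: SceneConfig

    def truth_table(self) -> pd.DataFrame:
        return truth_table(self.tracks)


def truth_table(tracks: Sequence[TruthTrack]) -> pd.DataFrame:
    df = pd.DataFrame(tracks, columns=TruthTrack._fields)
    if df.empty:
        df = pd.DataFrame(columns=TruthTrack._fields)
    return df


# ---------------------------------------------------------------------------
# simulation


class _Cell:
    __slots__ = (
        "cell_id", "parent_id", "anchor", "length", "birth_length", "theta_bind",
        "bind_time_min", "detach_time_min", "dtheta", "pivot_frac", "growth_sign",
    )

    def __init__(self, cell_id, parent_id, anchor, length, theta_bind,
                 bind_time_min, detach_time_min, dtheta, pivot_frac,
                 growth_sign=0.0):
        self.cell_id = cell_id
        self.parent_id = parent_id
        self.anchor = anchor  # pivot point fixed on the surface, µm
        self.length = length
        self.birth_length = length
        self.theta_bind = theta_bind
        self.bind_time_min = bind_time_min
        self.detach_time_min = detach_time_min
        self.dtheta = dtheta
        self.pivot_frac = pivot_frac
        # ±1 for daughters (elongation directed away from the sister, as
        # contact pushing does in a microcolony); 0 = symmetric growth
        self.growth_sign = growth_sign


def _axis_unit(theta_deg: float) -> np.ndarray:
    th = math.radians(theta_deg)
    return np.array([math.cos(th), math.sin(th)])


def _segment_gap(c1, u1, h1, c2, u2, h2):
    """Closest vector between two centreline segments (c ± h·u).

    Returns (distance, unit vector from segment 1 to segment 2).
    """
    # coarse but robust: sample candidate points along both segments
    s = np.linspace(-1.0, 1.0, 9)
    p1 = c1[None, :] + (s * h1)[:, None] * u1[None, :]
    p2 = c2[None, :] + (s * h2)[:, None] * u2[None, :]
    d = p1[:, None, :] - p2[None, :, :]
    dist2 = np.einsum("ijk,ijk->ij", d, d)
    i, j = np.unravel_index(np.argmin(dist2), dist2.shape)
    delta = p2[j] - p1[i]
    dist = math.hypot(*delta)
    if dist < 1e-9:
        return 0.0, np.array([1.0, 0.0])
    return dist, delta / dist


def _resolve_overlaps(cells, config, theta_of, n_iter=3):
    """Contact pushing: translate overlapping capsules apart.

    Rod-shaped cells in a microcolony cannot interpenetrate; growth and
    division push neighbours away.  Each iteration moves every overlapping
    pair symmetrically along their line of closest approach until their
    capsule surfaces clear.  Purely steric — no hydrodynamic coupling.
    """
    if len(cells) < 2:
        return
    dmin = config.steric_clearance_frac * config.cell_width_um
    for _ in range(n_iter):
        geo = []
        for c in cells:
            th = theta_of(c)
            u = _axis_unit(th)
            center = c.anchor - c.pivot_frac * c.length * u
            geo.append((center, u, max(c.length - config.cell_width_um, 0.0) / 2.0))
        moved = False
        for i in range(len(cells)):
            ci, ui, hi = geo[i]
            for j in range(i + 1, len(cells)):
                cj, uj, hj = geo[j]
                reach = hi + hj + dmin
                dc = cj - ci
                if dc[0] * dc[0] + dc[1] * dc[1] > reach * reach:
                    continue
                dist, n = _segment_gap(ci, ui, hi, cj, uj, hj)
                if dist < dmin:
                    push = 0.5 * (dmin - dist)
                    cells[i].anchor -= push * n
                    cells[j].anchor += push * n
                    geo[i] = (ci - push * n, ui, hi)
                    geo[j] = (cj + push * n, uj, hj)
                    moved = True
        if not moved:
            break


def _cell_center(cell: _Cell, theta_total: float) -> np.ndarray:
    # centre sits -p·L along the axis from the surface-fixed pivot point
    return cell.anchor - cell.pivot_frac * cell.length * _axis_unit(theta_total)


def _median_theta(cell: _Cell, t_min: float, rate: float) -> float:
    dt = max(t_min - cell.bind_time_min, 0.0)
    return 90.0 - (90.0 - cell.theta_bind) * math.exp(-rate * dt)


def simulate(config: SceneConfig) -> SimulationResult:
    """Run the event-driven colonization simulation frame by frame.

    All stochastic draws (arrival times/positions, initial lengths and
    angles, detachment clocks, division asymmetry, wiggle noise) come from a
    single seeded generator, so identical config + seed reproduce the truth
    table bit for bit.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    dt_min = config.frame_interval_min
    dt_s = dt_min * 60.0
    n_frames = config.n_frames
    rows_px, cols_px = config.image_shape
    width_um = cols_px * config.pixel_size_um
    height_um = rows_px * config.pixel_size_um
    # keep whole cells inside the frame: half a division length plus a little
    margin = min(0.5 * config.division_length_um + 1.0, 0.2 * min(width_um, height_um))

    detach_rate = (
        math.log(2.0) / config.detach_halflife_min
        if np.isfinite(config.detach_halflife_min)
        else 0.0
    )
    # exact OU step for the wiggle perturbation
    phi = math.exp(-dt_s / config.wiggle_relax_time_s)
    ou_sd = config.wiggle_amplitude_deg * math.sqrt(max(1.0 - phi * phi, 0.0))

    tracks: list[TruthTrack] = []
    events: list[dict] = []
    cells: list[_Cell] = []
    next_id = 0

    def new_cell(parent_id, center, length, theta, t_min, frame, dtheta, kind,
                 growth_sign=0.0):
        nonlocal next_id
        cid = next_id
        next_id += 1
        detach_t = (
            t_min + rng.exponential(1.0 / detach_rate) if detach_rate > 0 else math.inf
        )
        anchor = center + config.pivot_offset_frac * length * _axis_unit(theta)
        c = _Cell(cid, parent_id, anchor, length, theta, t_min, detach_t,
                  dtheta, config.pivot_offset_frac, growth_sign)
        cells.append(c)
        events.append({"kind": kind, "cell_id": cid, "parent_id": parent_id,
                       "frame": frame, "effective_frame": frame, "t_min": t_min,
                       "delta": 1})
        return c

    spacing = (
        config.min_spacing_um
        if config.min_spacing_um is not None
        else config.division_length_um
    )

    def spawn_arrival(t_min, frame):
        center = None
        for _ in range(60):  # rejection-sample an unoccupied spot
            cand = np.array([
                rng.uniform(margin, width_um - margin),
                rng.uniform(margin, height_um - margin),
            ])
            if all(
                np.hypot(*(cand - _cell_center(c, c.theta_bind))) >= spacing
                for c in cells
            ):
                center = cand
                break
        if center is None:
            logger.info("arrival at t=%.1f min placed without free spacing", t_min)
            center = cand
        # ±2σ-truncated normal: log-phase rods, no unphysical fragments
        mean_l, sd_l = config.initial_length_um
        length = float(np.clip(rng.normal(mean_l, sd_l), mean_l - 2 * sd_l, mean_l + 2 * sd_l))
        length = max(length, 0.5)
        theta = abs(rng.normal(0.0, config.initial_theta_sd_deg))
        dtheta = rng.normal(0.0, config.wiggle_amplitude_deg) if config.wiggle_amplitude_deg else 0.0
        new_cell(None, center, length, theta, t_min, frame, dtheta, "arrival")

    for frame in range(n_frames):
        t_min = frame * dt_min
        # --- arrivals (Poisson, injection window only) -------------------
        if frame == 0:
            for _ in range(config.initial_cells):
                spawn_arrival(t_min, frame)
        if t_min < config.injection_window_min and config.arrival_rate_per_min > 0:
            for _ in range(rng.poisson(config.arrival_rate_per_min * dt_min)):
                spawn_arrival(t_min, frame)

        # steric relaxation: neighbours pushed apart by growth and division
        if config.contact_pushing:
            _resolve_overlaps(
                cells, config,
                lambda c: _median_theta(c, t_min, config.realign_rate_per_min),
            )

        current = cells
        cells = []  # new_cell now appends newborns here; they start next frame
        survivors: list[_Cell] = []
        gr_now = float(config.gr_schedule(t_min))
        for cell in current:
            # --- detachment ---------------------------------------------
            if t_min >= cell.detach_time_min:
                events.append({"kind": "detach", "cell_id": cell.cell_id,
                               "parent_id": cell.parent_id, "frame": frame,
                               "effective_frame": frame, "t_min": t_min, "delta": -1})
                continue
            # --- growth: linear for first 2/3 of the cycle, then ~exp ----
            # (no growth on the first bound frame, so a daughter's first
            # recorded length is exactly its share of the mother's)
            if t_min > cell.bind_time_min + 1e-12:
                l_switch = cell.birth_length + (2.0 / 3.0) * (
                    config.division_length_um - cell.birth_length
                )
                rate = gr_now if cell.length < l_switch else gr_now * cell.length / l_switch
                dl = max(rate, 0.0) * dt_min
                cell.length += dl
                if cell.growth_sign:
                    # directed elongation: the septum-side pole stays put
                    cell.anchor += cell.growth_sign * 0.5 * dl * _axis_unit(
                        _median_theta(cell, t_min, config.realign_rate_per_min)
                    )
            # --- orientation --------------------------------------------
            theta_med = _median_theta(cell, t_min, config.realign_rate_per_min)
            if config.wiggle_amplitude_deg > 0:
                cell.dtheta = phi * cell.dtheta + ou_sd * rng.standard_normal()
            theta_total = theta_med + cell.dtheta
            center = _cell_center(cell, theta_total)
            tracks.append(TruthTrack(
                cell.cell_id, cell.parent_id, frame, float(center[0]), float(center[1]),
                float(cell.length), float(theta_total), cell.pivot_frac, True,
            ))
            # --- division ------------------------------------------------
            if cell.length >= config.division_length_um:
                events.append({"kind": "division", "cell_id": cell.cell_id,
                               "parent_id": cell.parent_id, "frame": frame,
                               "effective_frame": frame + 1, "t_min": t_min,
                               "delta": -1})
                f = 0.5 + config.division_asymmetry * rng.uniform(-1.0, 1.0)
                l1, l2 = f * cell.length, (1.0 - f) * cell.length
                u = _axis_unit(theta_total)
                gap = config.division_gap_um / 2.0
                c1 = center + (-cell.length / 2.0 + l1 / 2.0 - gap) * u
                c2 = center + (cell.length / 2.0 - l2 / 2.0 + gap) * u
                for li, ci, sgn in ((l1, c1, -1.0), (l2, c2, 1.0)):
                    if rng.uniform() < config.daughter_detach_prob:
                        events.append({"kind": "daughter_departed",
                                       "cell_id": -1, "parent_id": cell.cell_id,
                                       "frame": frame + 1,
                                       "effective_frame": frame + 1,
                                       "t_min": t_min + dt_min, "delta": 0})
                        continue
                    if frame + 1 < n_frames:
                        new_cell(cell.cell_id, ci, li, theta_med,
                                 t_min + dt_min, frame + 1, cell.dtheta,
                                 "daughter_bound", growth_sign=sgn)
                continue  # mother ends here
            survivors.append(cell)
        cells = survivors + cells

    return SimulationResult(tracks=tracks, events=events, config=config)


def simulate_truth(config: SceneConfig) -> list:
    """Ground-truth tracks only (see :func:`simulate` for the event log)."""
    return simulate(config).tracks


# ---------------------------------------------------------------------------
# rendering


def rod_mask(shape, center_px, length_px, width_px, theta_deg) -> np.ndarray:
    """Boolean footprint of a spherocylinder (capsule) on the pixel grid.

    ``center_px`` is (x, y) = (col, row); ``length_px`` is tip-to-tip.
    """
    occ = np.zeros(shape, dtype=float)
    _paint_rod(occ, center_px, length_px, width_px, theta_deg, aa_px=0.0)
    return occ > 0.5


def _paint_rod(occ, center_px, length_px, width_px, theta_deg, aa_px=1.0):
    """Accumulate soft-edged capsule occupancy into ``occ`` (max-combined)."""
    rows, cols = occ.shape
    cx, cy = center_px
    r = width_px / 2.0
    half = max(length_px / 2.0 - r, 0.0)  # half-length of the core segment
    pad = int(math.ceil(length_px / 2.0 + r + aa_px + 2))
    x0, x1 = int(cx) - pad, int(cx) + pad + 1
    y0, y1 = int(cy) - pad, int(cy) + pad + 1
    x0c, x1c = max(x0, 0), min(x1, cols)
    y0c, y1c = max(y0, 0), min(y1, rows)
    if x0c >= x1c or y0c >= y1c:
        return False
    xs = np.arange(x0c, x1c) - cx
    ys = np.arange(y0c, y1c) - cy
    X, Y = np.meshgrid(xs, ys)
    u = _axis_unit(theta_deg)
    along = X * u[0] + Y * u[1]
    perp = -X * u[1] + Y * u[0]
    t = np.clip(along, -half, half)
    d = np.hypot(along - t, perp)
    if aa_px > 0:
        local = np.clip(0.5 + (r - d) / aa_px, 0.0, 1.0)
    else:
        local = (d <= r).astype(float)
    region = occ[y0c:y1c, x0c:x1c]
    np.maximum(region, local, out=region)
    return (x0 < 0) or (y0 < 0) or (x1 > cols) or (y1 > rows)


def _illumination_field(config: SceneConfig) -> np.ndarray:
    rows, cols = config.image_shape
    if config.illumination_coeffs is None:
        return np.ones((rows, cols))
    c = np.asarray(config.illumination_coeffs, dtype=float)
    yy = np.linspace(-1.0, 1.0, rows)
    xx = np.linspace(-1.0, 1.0, cols)
    X, Y = np.meshgrid(xx, yy)
    f = np.polynomial.polynomial.polyval2d(Y, X, c)
    if np.any(f <= 0):
        raise SceneConfigError("illumination_coeffs produce a non-positive field")
    return f


def render(tracks, config: SceneConfig) -> MovieStack:
    """Render ground-truth tracks as a brightfield movie.

    Bound cells are drawn as dark projected spherocylinders on a bright
    background (multiplicative absorption, so overlaps never go negative),
    modulated by the uneven illumination field, blurred by a Gaussian PSF,
    and topped with additive sensor noise and optional round nanoparticle
    spots.  Rendering draws from its own generator derived from the config
    seed, so ``render(simulate_truth(cfg), cfg)`` is fully reproducible.
    """
    config.validate()
    df = tracks if isinstance(tracks, pd.DataFrame) else truth_table(tracks)
    n_frames = config.n_frames
    if not df.empty and df["frame"].max() >= n_frames:
        raise ValueError("tracks extend beyond the configured frame count")
    rng = np.random.default_rng(np.random.PCG64(config.seed + 987_654_321))
    rows, cols = config.image_shape
    illum = _illumination_field(config)
    px = config.pixel_size_um
    width_px = config.cell_width_um / px

    # nanoparticles: Poisson arrivals over the whole movie, persistent
    nano: list[tuple[int, float, float]] = []
    if config.nanoparticle_rate_per_min > 0:
        n_nano = rng.poisson(config.nanoparticle_rate_per_min * config.duration_min)
        for _ in range(n_nano):
            nano.append((
                int(rng.uniform(0, n_frames)),
                rng.uniform(0, cols),
                rng.uniform(0, rows),
            ))
    nano_r_px = config.nanoparticle_diameter_um / px / 2.0

    by_frame = dict(tuple(df.groupby("frame"))) if not df.empty else {}
    frames = np.empty((n_frames, rows, cols), dtype=np.float64)
    clipped = False
    for f in range(n_frames):
        occ = np.zeros((rows, cols))
        sub = by_frame.get(f)
        if sub is not None:
            for row in sub.itertuples():
                if not row.bound:
                    continue
                hit_edge = _paint_rod(
                    occ,
                    (row.x_um / px, row.y_um / px),
                    row.length_um / px,
                    width_px,
                    row.theta_deg,
                )
                clipped = clipped or hit_edge
        for (f0, nx, ny) in nano:
            if f >= f0:
                _paint_rod(occ, (nx, ny), 2 * nano_r_px, 2 * nano_r_px, 0.0)
        img = config.background_level * (1.0 - config.cell_contrast * occ)
        img *= illum
        sigma = config.psf_sigma_px
        if config.focus_drift_amp_px > 0:
            sigma += config.focus_drift_amp_px * 0.5 * (
                1.0 + math.sin(2.0 * math.pi * f / max(n_frames, 1))
            )
        if sigma > 0:
            img = ndimage.gaussian_filter(img, sigma)
        if config.noise_sd > 0:
            img = img + rng.normal(0.0, config.noise_sd, size=img.shape)
        frames[f] = img
    if clipped:
        logger.warning("some cells extended beyond the image bounds and were clipped")
    return MovieStack(
        frames=frames,
        frame_rate_fps=config.frame_rate_fps,
        pixel_size_um=px,
        meta={"seed": config.seed},
    )
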