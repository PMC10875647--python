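"""Colonization curve N(t) and mean binding time T₁/₂.

The count of segmented bacteria per averaged frame traces three phases:
binding (while the inoculum is injected), a plateau (adaptation lag), and
exponential growth once cells divide.  In the exponential phase the net
rate combines gain by division and loss by detachment:

    N(t) = N0 · exp( ∫_{t0}^{t} [ ln2 / T₂(s)  −  ln2 / T₁/₂ ] ds ),

where t0 — the moment the population starts dividing — is approximated by
the inflection point of the Gompertz growth-rate fit, T₂(s) is the
duplication time from the growth analysis, and T₁/₂ is the surface
residence half-life.  Since T₂ is measured independently, fitting the
curve determines T₁/₂.  The fit is linear in log N: with the division gain
D(t) = ∫ ln2/T₂ known, log N − D(t) regressed on (t − t0) has slope
−ln2/T₁/₂; weights ∝ N stabilise the Poisson counting variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np

from .segmentation import CellObservation

__all__ = ["ColonizationCurve", "BindingFit", "build_curve", "fit_binding_time"]

LN2 = math.log(2.0)


@dataclass
class ColonizationCurve:
    """Count of surface-bound bacteria versus time."""

    t_min: np.ndarray
    counts: np.ndarray
    injection_end_min: float | None = None
    phases: list = field(default_factory=list)  # (name, start_min, end_min)

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.counts = np.asarray(self.counts)
        if np.any(np.diff(self.t_min) <= 0):
            raise ValueError("t_min must be strictly increasing")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")


@dataclass
class BindingFit:
    """Result of the N(t) model fit."""

    N0: float
    t0_min: float
    T_half_min: float  # +inf when detachment is undetectable
    net_rate_per_min: float  # OLS slope of log N over the fitted range
    residual: float
    n_points: int


def _annotate_phases(t: np.ndarray, n: np.ndarray) -> list:
    """Change-point detection of the binding / plateau / exponential phases.

    Each candidate segmentation is scored with its natural per-phase model
    — a line for the binding ramp, a constant for the plateau, an
    exponential for the growth phase — using Poisson-stabilised chi-square
    residuals, and the two breakpoints minimising the total are kept.
    """
    if t.size < 9:
        return []
    n = np.asarray(n, dtype=float)
    # coarse candidate grid to keep the search O(grid²)
    idx = np.unique(np.linspace(3, t.size - 4, min(25, t.size - 6)).astype(int))

    def chi(pred, ns):
        return float(np.sum((pred - ns) ** 2 / np.maximum(ns, 1.0)))

    def seg_line(ts, ns):
        if ts.size < 3:
            return np.inf
        coef = np.polyfit(ts, ns, 1)
        return chi(np.polyval(coef, ts), ns)

    def seg_const(ts, ns):
        if ts.size < 3:
            return np.inf
        return chi(np.full_like(ns, ns.mean()), ns)

    def seg_exp(ts, ns):
        pos = ns > 0
        if pos.sum() < 3:
            return np.inf
        coef = np.polyfit(ts[pos], np.log(ns[pos]), 1)
        return chi(np.exp(np.clip(np.polyval(coef, ts), -50, 50)), ns)

    best, best_val = None, np.inf
    for i in idx:
        for j in idx:
            if j <= i + 2:
                continue
            val = seg_line(t[:i], n[:i]) + seg_const(t[i:j], n[i:j]) + seg_exp(t[j:], n[j:])
            if val < best_val:
                best, best_val = (i, j), val
    if best is None:
        return []
    i, j = best
    return [
        ("binding", float(t[0]), float(t[i])),
        ("plateau", float(t[i]), float(t[j])),
        ("exponential", float(t[j]), float(t[-1])),
    ]


def build_curve(
    obs_by_frame: dict[int, list[CellObservation]],
    frame_interval_min: float,
    injection_end_min: float | None = None,
) -> ColonizationCurve:
    """Per-frame gated-object count with phase annotation."""
    frames = sorted(obs_by_frame)
    if not frames:
        return ColonizationCurve(t_min=np.array([0.0]), counts=np.array([0]))
    t = np.array(frames, dtype=float) * frame_interval_min
    counts = np.array([len(obs_by_frame[f]) for f in frames])
    curve = ColonizationCurve(t_min=t, counts=counts, injection_end_min=injection_end_min)
    curve.phases = _annotate_phases(t, counts.astype(float))
    return curve


def fit_binding_time(
    curve: ColonizationCurve,
    T2_of_t: Callable[[np.ndarray], np.ndarray] | float,
    t0_min: float,
    t_end_min: float | None = None,
    time_varying_T2: bool = True,
) -> BindingFit:
    """Fit the net growth–release exponential to the colonization curve.

    Parameters
    ----------
    curve
        Colonization curve (counts per averaged frame).
    T2_of_t
        Duplication time in minutes: a callable of time or a constant.
        With ``time_varying_T2=False`` a callable is frozen at ``t_end_min``.
    t0_min
        Start of the division phase — by convention the inflection point of
        the population Gompertz GR fit.
    t_end_min
        Optional end of the fitted range (defaults to the last sample).

    Returns
    -------
    BindingFit with the release half-life ``T_half_min`` (``inf`` when the
    fitted release rate is ≤ 0, i.e. detachment is undetectable) and the
    simple net exponential rate of log N.  A detachment-dominated, falling
    N(t) is fitted the same way and simply yields T_half below T₂'s gain.
    """
    t_all = curve.t_min
    n_all = np.asarray(curve.counts, dtype=float)
    t_hi = t_all[-1] if t_end_min is None else t_end_min
    sel = (t_all >= t0_min) & (t_all <= t_hi) & (n_all > 0)
    t = t_all[sel]
    n = n_all[sel]
    if t.size < 6:
        raise ValueError(
            f"need ≥ 6 positive-count points after t0={t0_min:.1f} min, got {t.size}"
        )
    if callable(T2_of_t):
        T2 = np.asarray(T2_of_t(t), dtype=float) if time_varying_T2 else float(
            np.asarray(T2_of_t(t_hi))
        ) * np.ones_like(t)
    else:
        T2 = float(T2_of_t) * np.ones_like(t)
    if np.any(T2 <= 0):
        raise ValueError("T₂ must be positive over the fitted range")
    division_rate = LN2 / T2  # 1/min
    # division gain D(t) = ∫_{t0}^{t} ln2/T₂(s) ds (trapezoid from first sample,
    # plus the stub back to t0 using the first rate)
    gain = np.concatenate(
        [[0.0], np.cumsum(0.5 * (division_rate[1:] + division_rate[:-1]) * np.diff(t))]
    )
    gain += division_rate[0] * (t[0] - t0_min)
    z = np.log(n) - gain
    w = n  # Poisson: var(log N) ≈ 1/N
    x = t - t0_min
    # weighted linear LSQ: z = a − b·x
    W = np.sum(w)
    xb = np.sum(w * x) / W
    zb = np.sum(w * z) / W
    sxx = np.sum(w * (x - xb) ** 2)
    slope = np.sum(w * (x - xb) * (z - zb)) / sxx
    intercept = zb - slope * xb
    release_rate = -slope
    if release_rate <= 0:
        warnings.warn("fitted release rate ≤ 0: T₁/₂ reported as inf")
        T_half = math.inf
    else:
        T_half = LN2 / release_rate
    fitted = intercept + slope * x + gain
    residual = float(np.sqrt(np.sum(w * (fitted - np.log(n)) ** 2) / W))
    # unweighted net exponential rate of the raw counts
    net_rate = float(np.polyfit(t, np.log(n), 1)[0])
    return BindingFit(
        N0=float(np.exp(intercept)),
        t0_min=t0_min,
        T_half_min=float(T_half),
        net_rate_per_min=net_rate,
        residual=residual,
        n_points=int(t.size),
    )
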