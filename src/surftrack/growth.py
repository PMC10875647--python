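"""Single-cell growth-rate kinetics and population Gompertz fits.

The per-cell readout is the momentaneous growth rate GR(t): the slope of a
±5 min ordinary-least-squares fit to the cell-length trace around each time
point.  Per-cell rates are pooled into 20-min bins across the population;
the time evolution of the binned medians — for both GR(t) and length L(t) —
is summarised by a Gompertz sigmoid

    y(t) = y0 + (A − y0) · exp(−exp(−k · (t − t_i)))

whose inflection t_i marks the transition from the post-binding adaptation
lag to the biofilm growth phase.  The duplication time follows as

    T₂(t) = (2/3) · L(t_end) / GR(t),

the factor 2/3 reflecting that a rod must add about two-thirds of the final
cell length to double its number.  Replicate experiments are compared via
per-experiment summary medians (mean ± SE, Welch t-tests).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "GompertzParams",
    "GompertzFit",
    "GompertzFitError",
    "momentaneous_gr",
    "bin_population",
    "fit_gompertz",
    "duplication_time",
    "duplication_time_fn",
    "summarize_replicates",
]

DEFAULT_HALF_WINDOW_MIN = 5.0
DEFAULT_BIN_MIN = 20.0


@dataclass(frozen=True)
class GompertzParams:
    """Parameters of the asymmetric sigmoid y0 + (A−y0)·exp(−exp(−k(t−t_i))).

    ``y0``/``A`` share the units of the fitted quantity (µm/min for GR,
    µm for length); ``k`` is 1/min; the inflection ``t_i`` (min) is the
    transition time.
    """

    y0: float
    A: float
    k: float
    t_i: float

    def __post_init__(self) -> None:
        if not np.isfinite([self.y0, self.A, self.k, self.t_i]).all():
            raise ValueError("Gompertz parameters must be finite")
        if self.k <= 0:
            raise ValueError("Gompertz rate k must be positive")

    def __call__(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        return self.y0 + (self.A - self.y0) * np.exp(-np.exp(-self.k * (t - self.t_i)))

    @property
    def transition_time_min(self) -> float:
        return self.t_i


class GompertzFitError(RuntimeError):
    """Raised when no acceptable Gompertz fit exists (carries best residual)."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass(frozen=True)
class GompertzFit:
    """A fitted Gompertz curve with its covariance and residual norm."""

    params: GompertzParams
    cov: np.ndarray
    residual: float  # RMS residual of the fit

    def __call__(self, t):
        return self.params(t)

    @property
    def t_i(self) -> float:
        return self.params.t_i

    @property
    def transition_time_min(self) -> float:
        return self.params.t_i

    def to_dict(self) -> dict:
        p = self.params
        return {
            "y0": p.y0,
            "A": p.A,
            "k": p.k,
            "t_i": p.t_i,
            "residual": self.residual,
        }


# ---------------------------------------------------------------------------
# momentaneous growth rate


def momentaneous_gr(
    times_min: np.ndarray,
    lengths_um: np.ndarray,
    half_window_min: float = DEFAULT_HALF_WINDOW_MIN,
    eligible_range_min: tuple[float, float] | None = None,
) -> pd.DataFrame:
    """Sliding-window OLS growth rate of one trajectory.

    Parameters
    ----------
    times_min, lengths_um
        The full length trace of one cell (minutes, µm), time-sorted.
    half_window_min
        Half-width of the OLS window; the slope at ``t`` uses all samples
        within ``t ± half_window_min``.
    eligible_range_min
        Restrict slope evaluation to centres inside this interval (used to
        exclude the noise-prone first/last 5 min of a trajectory).  The
        window itself may still draw on the excluded samples.

    Returns
    -------
    DataFrame with columns ``t_min``, ``gr_um_per_min``, ``length_um``,
    ``n_window``.  Centres whose window contains fewer than 3 samples or
    would extend past the trajectory are skipped.
    """
    t = np.asarray(times_min, dtype=float)
    ln = np.asarray(lengths_um, dtype=float)
    if t.size != ln.size:
        raise ValueError("times and lengths must have equal size")
    rows = []
    lo, hi = (t.min(), t.max()) if t.size else (0.0, 0.0)
    for i, ti in enumerate(t):
        if eligible_range_min is not None and not (
            eligible_range_min[0] <= ti <= eligible_range_min[1]
        ):
            continue
        if ti - half_window_min < lo - 1e-9 or ti + half_window_min > hi + 1e-9:
            continue  # window would extend past the trajectory
        sel = np.abs(t - ti) <= half_window_min + 1e-9
        if sel.sum() < 3:
            continue
        slope, _ = np.polyfit(t[sel], ln[sel], 1)
        rows.append((ti, slope, ln[i], int(sel.sum())))
    return pd.DataFrame(rows, columns=["t_min", "gr_um_per_min", "length_um", "n_window"])


def bin_population(
    gr_by_traj: dict[int, pd.DataFrame], bin_min: float = DEFAULT_BIN_MIN
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pool per-trajectory GR series into fixed time bins.

    Returns
    -------
    samples : DataFrame
        One row per (trajectory, bin): ``traj_id``, ``bin_start_min``,
        ``mean_gr_um_per_min``, ``mean_length_um``, ``n_points`` — the
        per-bacterium bin means.
    summary : DataFrame
        One row per bin: median and quartiles of the per-bacterium means
        (the boxplot data), plus ``n_traj``.
    """
    rows = []
    for traj_id, df in gr_by_traj.items():
        if df.empty:
            continue
        b = (df["t_min"] // bin_min).astype(int)
        for bin_idx, grp in df.groupby(b):
            rows.append(
                (
                    traj_id,
                    bin_idx * bin_min,
                    grp["gr_um_per_min"].mean(),
                    grp["length_um"].mean(),
                    len(grp),
                )
            )
    samples = pd.DataFrame(
        rows,
        columns=["traj_id", "bin_start_min", "mean_gr_um_per_min", "mean_length_um", "n_points"],
    )
    if samples.empty:
        return samples, pd.DataFrame(
            columns=["bin_start_min", "t_center_min", "median_gr", "q1_gr", "q3_gr",
                     "median_length", "q1_length", "q3_length", "n_traj"]
        )
    parts = []
    for start, grp in samples.groupby("bin_start_min"):
        gq = grp["mean_gr_um_per_min"].quantile([0.25, 0.5, 0.75])
        lq = grp["mean_length_um"].quantile([0.25, 0.5, 0.75])
        parts.append(
            (start, start + bin_min / 2.0, gq[0.5], gq[0.25], gq[0.75],
             lq[0.5], lq[0.25], lq[0.75], len(grp))
        )
    summary = pd.DataFrame(
        parts,
        columns=["bin_start_min", "t_center_min", "median_gr", "q1_gr", "q3_gr",
                 "median_length", "q1_length", "q3_length", "n_traj"],
    )
    return samples, summary.sort_values("bin_start_min").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Gompertz fitting


def _gompertz(t, y0, A, k, t_i):
    return y0 + (A - y0) * np.exp(-np.exp(-np.clip(k * (t - t_i), -700, 700)))


def fit_gompertz(
    t_min: Sequence[float],
    y: Sequence[float],
    min_relative_range: float = 0.05,
) -> GompertzFit:
    """Least-squares Gompertz fit with multi-start initialisation.

    Initial guesses place y0/A at the data extremes, sweep the inflection
    over a coarse grid of observed times, and seed k from the data span —
    the sigmoid's likelihood surface has local minima in (k, t_i) and a
    single start is unreliable.

    Raises
    ------
    GompertzFitError
        For fewer than 5 points, for degenerate (flat) data where the fitted
        plateau cannot be distinguished from the baseline, or when no start
        converges.
    """
    t = np.asarray(t_min, dtype=float)
    yv = np.asarray(y, dtype=float)
    ok = np.isfinite(t) & np.isfinite(yv)
    t, yv = t[ok], yv[ok]
    if t.size < 5:
        raise GompertzFitError(f"need at least 5 points, got {t.size}")
    span = yv.max() - yv.min()
    scale = max(abs(np.median(yv)), 1e-12)
    if span < min_relative_range * scale:
        raise GompertzFitError(
            "degenerate (near-constant) data: plateau indistinguishable from baseline"
        )
    t_range = t.max() - t.min()
    k0s = np.array([1.0, 3.0, 10.0]) / max(t_range, 1e-9)
    ti_grid = np.quantile(t, [0.15, 0.35, 0.5, 0.65, 0.85])
    best = None
    best_res = np.inf
    for ti0 in ti_grid:
        for k0 in k0s:
            p0 = [yv.min(), yv.max(), k0, ti0]
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    popt, pcov = optimize.curve_fit(
                        _gompertz, t, yv, p0=p0,
                        bounds=(
                            [-np.inf, -np.inf, 1e-6, t.min() - 2 * t_range],
                            [np.inf, np.inf, np.inf, t.max() + 2 * t_range],
                        ),
                        maxfev=20_000,
                    )
            except (RuntimeError, ValueError):
                continue
            res = float(np.sqrt(np.mean((_gompertz(t, *popt) - yv) ** 2)))
            if res < best_res:
                best, best_res = (popt, pcov), res
    if best is None:
        raise GompertzFitError("Gompertz fit failed to converge from any start")
    popt, pcov = best
    if abs(popt[1] - popt[0]) < min_relative_range * scale:
        raise GompertzFitError(
            "degenerate fit: A ≈ y0, inflection undefined", best_residual=best_res
        )
    params = GompertzParams(y0=float(popt[0]), A=float(popt[1]), k=float(popt[2]),
                            t_i=float(popt[3]))
    return GompertzFit(params=params, cov=np.asarray(pcov), residual=best_res)


# ---------------------------------------------------------------------------
# duplication time


def duplication_time(
    length_fit: GompertzFit | GompertzParams,
    gr_fit: GompertzFit | GompertzParams,
    t_min,
    t_end_min: float,
):
    """Duplication time T₂(t) = (2/3) · L(t_end) / GR(t), in minutes.

    ``t_end_min`` is the last analysed time (centre of the last populated
    bin).  Non-positive GR yields +inf with a warning — the population is
    not dividing there.
    """
    L_end = float(np.asarray(length_fit(t_end_min)))
    gr = np.asarray(gr_fit(t_min), dtype=float)
    scalar = gr.ndim == 0
    gr = np.atleast_1d(gr)
    out = np.full(gr.shape, np.inf)
    pos = gr > 0
    if not pos.all():
        warnings.warn("GR ≤ 0 at some times: duplication time reported as inf")
    out[pos] = (2.0 / 3.0) * L_end / gr[pos]
    return float(out[0]) if scalar else out


def duplication_time_fn(
    length_fit: GompertzFit | GompertzParams,
    gr_fit: GompertzFit | GompertzParams,
    t_end_min: float,
) -> Callable[[np.ndarray], np.ndarray]:
    """Return T₂(·) as a callable of time, for the binding-kinetics fitter."""
    return lambda t: duplication_time(length_fit, gr_fit, t, t_end_min)


# ---------------------------------------------------------------------------
# replicate summaries


def summarize_replicates(
    experiments: Iterable[dict],
    alpha: float = 0.05,
) -> dict:
    """Cross-replicate summary of per-experiment GR medians.

    Parameters
    ----------
    experiments
        Iterables of dicts with keys ``condition`` (str), ``summary`` (the
        per-bin median table from :func:`bin_population`), and
        ``transition_time_min`` (the experiment's fitted t_i).  The initial
        (final) GR of an experiment is the median of its bin medians in bins
        strictly before (after) its transition time.

    Returns
    -------
    dict with:
      ``per_experiment`` — initial/final GR per experiment;
      ``by_condition`` — mean ± SE per condition (SE is NaN for n=1);
      ``tests`` — Welch two-sample t-tests between every pair of conditions
      for each metric.
    """
    rows = []
    for i, exp in enumerate(experiments):
        summ = exp["summary"]
        t_i = exp["transition_time_min"]
        before = summ[summ["t_center_min"] < t_i]["median_gr"]
        after = summ[summ["t_center_min"] > t_i]["median_gr"]
        rows.append(
            {
                "experiment": exp.get("name", i),
                "condition": exp["condition"],
                "initial_gr": before.median() if len(before) else np.nan,
                "final_gr": after.median() if len(after) else np.nan,
                "transition_time_min": t_i,
            }
        )
    per_exp = pd.DataFrame(rows)
    metrics = ["initial_gr", "final_gr", "transition_time_min"]
    agg = []
    for cond, grp in per_exp.groupby("condition"):
        for m in metrics:
            vals = grp[m].dropna()
            agg.append(
                {
                    "condition": cond,
                    "metric": m,
                    "mean": vals.mean() if len(vals) else np.nan,
                    "se": vals.std(ddof=1) / np.sqrt(len(vals)) if len(vals) > 1 else np.nan,
                    "n": len(vals),
                }
            )
    by_condition = pd.DataFrame(agg)
    tests = []
    conds = sorted(per_exp["condition"].unique())
    for i, a in enumerate(conds):
        for b in conds[i + 1 :]:
            for m in metrics:
                va = per_exp.loc[per_exp["condition"] == a, m].dropna()
                vb = per_exp.loc[per_exp["condition"] == b, m].dropna()
                if len(va) < 2 or len(vb) < 2:
                    p = np.nan
                    tstat = np.nan
                else:
                    tstat, p = stats.ttest_ind(va, vb, equal_var=False)
                tests.append(
                    {"condition_a": a, "condition_b": b, "metric": m,
                     "t": tstat, "p": p, "significant": bool(p < alpha) if np.isfinite(p) else False}
                )
    return {"per_experiment": per_exp, "by_condition": by_condition,
            "tests": pd.DataFrame(tests)}
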