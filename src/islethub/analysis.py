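"""Islet Ca²⁺ activity quantification and dose-response fitting.

Per-cell Ca²⁺ traces are binarized into a raster: each cell's trace is
normalised to its own baseline-epoch maximum and marked active where the
normalised signal exceeds 40% (an absolute µM threshold is available as an
alternative).  Epoch activity is summarised two ways: *summed* activity is
the time-mean of the active-cell fraction, and *amplitude* is the
peak-to-trough excursion of the islet-mean Ca²⁺ trace, each normalised to
the baseline epoch and reported in percent.  Dose-response curves (activity
vs. % of the islet inhibited) are fit with a decreasing two-parameter
logistic  A(x) = 100 / (1 + exp((x − x0)/k)),  whose midpoint x0 is the
IC50 (in % of all islet cells) and k the slope factor.  Species-level IC50
sets are compared with paired or unpaired t-tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .engine import SimulationResult

__all__ = [
    "RasterData",
    "DoseResponse",
    "binarize_traces",
    "activity_metrics",
    "fit_dose_response",
    "dose_response_from_results",
    "compare_species",
    "ic50_as_percent_of_hubs",
]


@dataclass(frozen=True)
class RasterData:
    """Binary per-cell activity on the trace time grid."""

    active: np.ndarray              # (n_t, n_cells) bool
    time_s: np.ndarray
    norm_fraction: float | None     # relative threshold used (None if abs)
    abs_threshold: float | None     # µM threshold used (None if relative)

    @property
    def n_cells(self) -> int:
        return self.active.shape[1]

    def active_fraction(self) -> np.ndarray:
        """Fraction of cells active at each sample."""
        return self.active.mean(axis=1)

    def intervals(self) -> pd.DataFrame:
        """Sparse (cell, t_on, t_off) representation of the raster."""
        rows = []
        t = self.time_s
        for c in range(self.n_cells):
            x = self.active[:, c].astype(np.int8)
            d = np.diff(np.concatenate([[0], x, [0]]))
            on = np.where(d == 1)[0]
            off = np.where(d == -1)[0]
            for a, b in zip(on, off):
                rows.append((c, t[a], t[min(b, len(t) - 1)]))
        return pd.DataFrame(rows, columns=["cell", "t_on_s", "t_off_s"])


def binarize_traces(ca: np.ndarray, time_s: np.ndarray,
                    baseline_mask: np.ndarray | None = None,
                    norm_fraction: float = 0.4,
                    abs_threshold: float | None = None) -> RasterData:
    """Threshold per-cell Ca²⁺ traces into a binary raster.

    With the default relative rule a cell is active where its trace exceeds
    ``norm_fraction`` of that cell's maximum over the baseline window
    (``baseline_mask``; the whole trace when omitted).  Passing
    ``abs_threshold`` (µM, e.g. 0.2) switches to the absolute rule.  Cells
    whose trace is identically zero are marked inactive with a warning.
    """
    ca = np.asarray(ca, dtype=float)
    if np.any(ca < 0):
        raise ValueError("Ca traces must be non-negative")
    if abs_threshold is not None:
        active = ca > abs_threshold
        return RasterData(active, np.asarray(time_s), None,
                          float(abs_threshold))
    base = ca if baseline_mask is None else ca[baseline_mask]
    ref = base.max(axis=0)
    dead = ref <= 0
    if np.any(dead):
        warnings.warn(f"{int(dead.sum())} cell(s) have an all-zero trace; "
                      "marked inactive", stacklevel=2)
        ref = np.where(dead, 1.0, ref)
    active = (ca / ref) > norm_fraction
    active[:, dead] = False
    return RasterData(active, np.asarray(time_s), float(norm_fraction), None)


def _epoch_amplitude(mean_trace: np.ndarray) -> float:
    return float(mean_trace.max() - mean_trace.min()) if mean_trace.size \
        else 0.0


def activity_metrics(result: SimulationResult, raster: RasterData,
                     epoch: str, baseline_epoch: str = "baseline") -> dict:
    """Summed and amplitude Ca²⁺ activity of an epoch, in % of baseline.

    *summed*: time-mean active-cell fraction during the epoch over the same
    quantity during baseline.  *amplitude*: peak-to-trough excursion of the
    islet-mean Ca²⁺ trace over its baseline value.
    """
    if epoch not in result.epochs:
        raise KeyError(f"epoch {epoch!r} not in result "
                       f"({sorted(result.epochs)})")
    m_ep = result.epoch_mask(epoch)
    m_bl = result.epoch_mask(baseline_epoch)
    frac = raster.active_fraction()
    base_sum = float(frac[m_bl].mean())
    base_amp = _epoch_amplitude(result.mean_ca()[m_bl])
    if base_sum <= 0 or base_amp <= 0:
        raise ZeroDivisionError(
            "baseline epoch has zero activity; cannot normalise")
    return {
        "summed": 100.0 * float(frac[m_ep].mean()) / base_sum,
        "amplitude": 100.0 * _epoch_amplitude(result.mean_ca()[m_ep])
                     / base_amp,
    }


@dataclass(frozen=True)
class DoseResponse:
    """Dose-response points and the fitted decreasing logistic."""

    fractions_pct: np.ndarray        # % of islet inhibited
    activity_pct: np.ndarray         # % of no-inhibition activity
    metric: str                      # {summed, amplitude}
    x0: float                        # IC50, % of islet
    k: float                         # slope factor
    r2: float
    sem: np.ndarray | None = None    # per-point SEM over seeds
    n_seeds: int = 1
    flagged: bool = False            # True when R² ≤ 0.9

    def as_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"fraction_pct": self.fractions_pct,
                           "activity_pct": self.activity_pct})
        if self.sem is not None:
            df["sem"] = self.sem
        return df


def logistic_decreasing(x, x0, k, top=100.0):
    """Two-parameter decreasing logistic anchored at ``top`` percent."""
    z = np.clip((np.asarray(x, dtype=float) - x0) / k, -500.0, 500.0)
    return top / (1.0 + np.exp(z))


def fit_dose_response(fractions_pct, activity_pct, metric: str = "summed",
                      sem=None, n_seeds: int = 1,
                      free_top: bool = False) -> DoseResponse:
    """Least-squares logistic fit of activity vs. inhibited fraction.

    Requires the 0% point and at least four distinct dose levels.  Returns
    the IC50 ``x0`` (% of islet), slope ``k`` and R²; fits with R² ≤ 0.9
    are flagged rather than rejected.  ``free_top=True`` adds a free upper
    asymptote as a third parameter.
    """
    x = np.asarray(fractions_pct, dtype=float)
    y = np.asarray(activity_pct, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("fractions and activities must be 1-D and aligned")
    if np.unique(x).size < 4:
        raise ValueError("need at least 4 distinct dose levels")
    if not np.any(x == 0):
        raise ValueError("the 0% (no inhibition) point is required")

    if np.ptp(y) < 1e-9:
        raise RuntimeError(
            "dose-response is flat; logistic midpoint is unidentifiable")

    # midpoint guess: first crossing of half the dynamic range
    half = y.min() + 0.5 * np.ptp(y)
    below = np.where(y <= half)[0]
    x0_guess = float(x[below[0]]) if below.size else float(x.max())
    p0 = [max(x0_guess, 0.5), max(0.3, 0.1 * np.ptp(x))]
    model = (lambda x, x0, k, top: logistic_decreasing(x, x0, k, top)) \
        if free_top else logistic_decreasing
    bounds = ([0.0, 1e-3] + ([1.0] if free_top else []),
              [10 * max(x.max(), 1.0), 100.0] + ([500.0] if free_top else []))
    if free_top:
        p0 = p0 + [100.0]
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(model, x, y, p0=p0, bounds=bounds,
                                         maxfev=20000)
    except RuntimeError as err:
        raise RuntimeError(f"dose-response fit did not converge: {err}")
    yhat = model(x, *popt)
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return DoseResponse(
        fractions_pct=x, activity_pct=y, metric=metric,
        x0=float(popt[0]), k=float(popt[1]), r2=r2,
        sem=None if sem is None else np.asarray(sem, dtype=float),
        n_seeds=n_seeds, flagged=not (r2 > 0.9))


def _raw_epoch_activity(res, epoch, metric, norm_fraction):
    """Unnormalised epoch activity: active-cell fraction (summed) or the
    islet-mean trace excursion in µM (amplitude)."""
    if metric == "amplitude":
        return _epoch_amplitude(res.mean_ca()[res.epoch_mask(epoch)])
    if metric == "summed":
        raster = binarize_traces(res.ca, res.time_s,
                                 baseline_mask=res.epoch_mask("baseline"),
                                 norm_fraction=norm_fraction)
        return float(raster.active_fraction()[res.epoch_mask(epoch)].mean())
    raise ValueError(f"unknown metric {metric!r}")


def dose_response_from_results(fractions_pct, results_per_seed,
                               metric: str = "amplitude",
                               epoch: str = "inhibition",
                               norm_fraction: float = 0.4) -> DoseResponse:
    """Build and fit a dose-response from simulation results.

    ``results_per_seed`` is a list (one entry per seed) of lists of
    :class:`SimulationResult`, aligned with ``fractions_pct``.  Within each
    seed, activities are normalised to the same epoch of that seed's
    no-inhibition (0%) run, so the 0% point is 100% by construction and
    epoch-sampling noise cancels between dose levels.  Per-fraction
    activities are then averaged across seeds (mean ± SEM) and the
    logistic is fit to the means.
    """
    fractions_pct = np.asarray(fractions_pct, dtype=float)
    zero = np.where(fractions_pct == 0.0)[0]
    if zero.size != 1:
        raise ValueError("exactly one 0% (no inhibition) entry is required")
    per_seed = []
    for results in results_per_seed:
        if len(results) != fractions_pct.size:
            raise ValueError("one result per fraction per seed required")
        raw = [_raw_epoch_activity(res, epoch, metric, norm_fraction)
               for res in results]
        ref = raw[int(zero[0])]
        if ref <= 0:
            raise ZeroDivisionError(
                "no-inhibition run shows zero activity; cannot normalise")
        per_seed.append([100.0 * r / ref for r in raw])
    per_seed = np.asarray(per_seed)          # (n_seeds, n_fractions)
    mean = per_seed.mean(axis=0)
    sem = (per_seed.std(axis=0, ddof=1) / np.sqrt(per_seed.shape[0])
           if per_seed.shape[0] > 1 else np.zeros_like(mean))
    return fit_dose_response(fractions_pct, mean, metric=metric, sem=sem,
                             n_seeds=per_seed.shape[0])


def ic50_as_percent_of_hubs(x0_islet_pct: float,
                            hub_fraction: float = 0.10) -> float:
    """Convert an IC50 in % of all islet cells to % of the hub pool."""
    return x0_islet_pct / (100.0 * hub_fraction) * 100.0


def compare_species(mouse_ic50s, human_ic50s, paired: bool = True) -> dict:
    """t-test comparison of per-islet IC50 sets for two species.

    Returns the t statistic, p value and per-group mean ± SEM.  Degenerate
    paired inputs (zero within-pair variance) are flagged instead of
    reporting an infinite statistic.
    """
    a = np.asarray(mouse_ic50s, dtype=float)
    b = np.asarray(human_ic50s, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need at least two islets per group")
    if paired and a.size != b.size:
        raise ValueError("paired comparison requires equal group sizes")
    degenerate = False
    if paired:
        d = a - b
        if np.allclose(d, d[0]):
            degenerate = True
            if np.allclose(d, 0.0):
                t, p = 0.0, 1.0
            else:
                t, p = float("inf") * np.sign(d[0]), 0.0
        else:
            t, p = stats.ttest_rel(a, b)
    else:
        t, p = stats.ttest_ind(a, b)
    return {
        "t": float(t), "p": float(p), "paired": paired,
        "degenerate": degenerate,
        "mouse_mean": float(a.mean()),
        "mouse_sem": float(a.std(ddof=1) / np.sqrt(a.size)),
        "human_mean": float(b.mean()),
        "human_sem": float(b.std(ddof=1) / np.sqrt(b.size)),
        "n_mouse": int(a.size), "n_human": int(b.size),
    }
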