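"""Ratiometric T7RNAP-activity quantification from plate-reader time series.

The activity statistic is the mean YFP/CFP fluorescence ratio per cell during
exponential growth; because both fluorophores scale with cell count and with
overall gene-expression capacity, the ratio normalizes both away.
Fold-induction is the activity at an inducer level divided by the activity
with no inducer; the headline "maximum fold-induction" is the empirical
maximum of the mean fold over the tested concentrations (not a fitted
asymptote, which a non-monotone dose-response leaves undefined), with the
between-day s.d. computed over replicate-level values.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.signal import savgol_filter
from scipy.optimize import curve_fit

from .circuitsim.wells import PlateTimeSeries

__all__ = [
    "GrowthWindow", "DoseResponseFit", "NoGrowthError",
    "detect_exponential_phase", "relative_promoter_activity",
    "fold_induction", "fit_dose_response", "titration_max_fold",
]


class NoGrowthError(ValueError):
    """Raised when an OD trace shows no usable exponential phase."""


@dataclass(frozen=True)
class GrowthWindow:
    """Contiguous index window [start, end) into the time axis plus the peak
    specific growth rate (1/min) found on the trace."""

    start: int
    end: int
    peak_rate: float

    def __post_init__(self) -> None:
        if self.end - self.start < 5:
            raise ValueError("window must span at least 5 samples")

    @property
    def indices(self) -> np.ndarray:
        return np.arange(self.start, self.end)


@dataclass
class DoseResponseFit:
    max_fold: float                  # empirical maximum of mean fold-induction
    max_fold_sd: float               # between-replicate s.d. of that maximum
    max_fold_conc: float             # concentration where the maximum occurs
    half_max_conc: float             # fitted Hill half-activation constant
    hill_coef: float
    fitted_max_fold: float           # fitted asymptote 1 + (F-1)
    rss: float
    nonmonotone: bool = False        # fitted on the rising limb only
    saturation_flag: bool = False    # fitted K outside the tested range
    concentrations: np.ndarray = field(default_factory=lambda: np.array([]))
    mean_folds: np.ndarray = field(default_factory=lambda: np.array([]))


def detect_exponential_phase(times: np.ndarray, od: np.ndarray, blank: float,
                             floor: float = 0.02, slope_frac: float = 0.7,
                             min_len: int = 5, min_rate: float = 1e-4,
                             smooth: int = 9) -> GrowthWindow:
    """Locate exponential growth on a blank-subtracted OD trace.

    The log-OD slope is a Savitzky-Golay first derivative over ``smooth``
    samples (centered differences when smooth <= 1; read noise otherwise
    fragments the run); the window is the maximal contiguous run where the
    slope is at least ``slope_frac`` of the peak slope and the corrected OD
    is above ``floor``.
    """
    times = np.asarray(times, dtype=float)
    od = np.asarray(od, dtype=float)
    if len(times) < 10:
        raise ValueError("need at least 10 timepoints")
    corr = od - blank
    if np.all(corr <= 0):
        raise NoGrowthError("OD never rises above the blank")
    safe = np.clip(corr, 1e-9, None)
    log_od = np.log(safe)
    dt = np.diff(times)
    if smooth > 1 and np.allclose(dt, dt[0]):
        w = min(smooth | 1, len(log_od))
        slope = savgol_filter(log_od, window_length=w, polyorder=2,
                              deriv=1, delta=float(dt[0]))
    elif smooth > 1:
        w = min(smooth | 1, len(log_od))
        slope = np.gradient(savgol_filter(log_od, w, 2), times)
    else:
        slope = np.gradient(log_od, times)
    usable = corr >= floor
    if not np.any(usable):
        raise NoGrowthError(f"OD never reaches the floor of {floor}")
    peak = float(np.max(slope[usable]))
    if peak < min_rate:
        raise NoGrowthError("no growth: peak log-OD slope below threshold")
    good = (slope >= slope_frac * peak) & usable
    # maximal contiguous run of good samples
    best = (0, 0)
    i = 0
    n = len(good)
    while i < n:
        if good[i]:
            j = i
            while j < n and good[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    if best[1] - best[0] < min_len:
        raise NoGrowthError("exponential phase shorter than the minimum window")
    return GrowthWindow(start=best[0], end=best[1], peak_rate=peak)


def relative_promoter_activity(ts: PlateTimeSeries, well: str | int,
                               window: GrowthWindow) -> float:
    """Mean blank-subtracted YFP/CFP ratio over the window timepoints."""
    idx = window.indices
    if idx[-1] >= len(ts.times):
        raise ValueError("window extends beyond the series")
    y = ts.column("YFP", well)[idx] - ts.blanks.get("YFP", 0.0)
    c = ts.column("CFP", well)[idx] - ts.blanks.get("CFP", 0.0)
    bad = np.nonzero(c <= 0)[0]
    if len(bad):
        t = ts.times[idx[bad[0]]]
        raise ValueError(f"non-positive corrected CFP at t={t:g} min")
    return float(np.mean(y / c))


def fold_induction(activities: Mapping[float, float],
                   reference_level: float) -> dict[float, float]:
    """Divide every activity by the reference activity; the fold at the
    reference level is exactly 1."""
    if reference_level not in activities:
        raise KeyError(f"reference level {reference_level} not present")
    ref = activities[reference_level]
    if not (ref > 0):
        raise ValueError("reference activity must be positive")
    out = {level: act / ref for level, act in activities.items()}
    out[reference_level] = 1.0
    return out


def _hill_fold(c, max_fold, K, n):
    cn = np.power(c, n)
    return 1.0 + (max_fold - 1.0) * cn / (K ** n + cn)


def fit_dose_response(folds: Mapping[float, float | Sequence[float]],
                      ) -> DoseResponseFit:
    """Least-squares Hill fit fold(c) = 1 + (F-1) c^n / (K^n + c^n).

    folds maps concentration -> fold (scalar) or per-replicate folds.  A
    non-monotone curve (empirical maximum at an interior concentration) is
    fitted on the data up to that maximum, with the flag set.  The headline
    max_fold is the empirical maximum of the replicate-mean fold, with the
    between-replicate s.d.
    """
    concs = np.array(sorted(folds.keys()), dtype=float)
    reps = {c: np.atleast_1d(np.asarray(folds[c], dtype=float)) for c in concs}
    means = np.array([reps[c].mean() for c in concs])
    nonzero = concs > 0
    if nonzero.sum() < 5:
        raise ValueError("need at least 5 distinct non-zero concentrations")

    i_max = int(np.argmax(means))
    max_fold = float(means[i_max])
    max_fold_sd = float(np.std(reps[concs[i_max]], ddof=1)) \
        if len(reps[concs[i_max]]) > 1 else 0.0
    nonmonotone = i_max < len(concs) - 1 and \
        max_fold > means[-1] * (1.0 + 1e-9) + 1e-12

    keep = np.ones(len(concs), dtype=bool)
    if nonmonotone:
        keep = np.arange(len(concs)) <= i_max
    c_fit = concs[keep]
    y_fit = means[keep]

    nz = c_fit[c_fit > 0]
    # relative (multiplicative-error) least squares: measurement noise scales
    # with the signal, so residuals are weighted by the observed fold
    sigma = np.maximum(y_fit, 1e-9)
    # log-grid initialization over K
    grid = np.geomspace(nz.min() / 10, nz.max() * 10, 40)
    best = None
    for K0 in grid:
        for n0 in (1.0, 2.0):
            pred = _hill_fold(c_fit, max(max_fold, 1.0 + 1e-6), K0, n0)
            rss = float(np.sum(((pred - y_fit) / sigma) ** 2))
            if best is None or rss < best[0]:
                best = (rss, K0, n0)
    _, K0, n0 = best
    p0 = [max(max_fold, 1.0 + 1e-6), K0, n0]
    try:
        popt, _ = curve_fit(_hill_fold, c_fit, y_fit, p0=p0, sigma=sigma,
                            bounds=([1.0, nz.min() / 1e4, 0.1],
                                    [np.inf, nz.max() * 1e4, 10.0]),
                            maxfev=20000)
        fitted_max, K, n = (float(v) for v in popt)
        rss = float(np.sum((_hill_fold(c_fit, *popt) - y_fit) ** 2))
    except RuntimeError:
        fitted_max, K, n = p0[0], K0, n0
        rss = math.inf
    saturation = not (nz.min() <= K <= nz.max())
    return DoseResponseFit(
        max_fold=max_fold, max_fold_sd=max_fold_sd,
        max_fold_conc=float(concs[i_max]),
        half_max_conc=K, hill_coef=n, fitted_max_fold=fitted_max, rss=rss,
        nonmonotone=bool(nonmonotone), saturation_flag=bool(saturation),
        concentrations=concs, mean_folds=means,
    )


def titration_max_fold(ts: PlateTimeSeries, inducer: str = "arabinose",
                       reference_level: float = 0.0) -> DoseResponseFit:
    """End-to-end pipeline on a simulated/parsed titration plate: detect the
    exponential phase per well, compute the ratiometric activity, fold per
    replicate relative to the no-inducer well of the same replicate, and fit
    the dose-response."""
    by_rep: dict[int, dict[float, float]] = {}
    for j, w in enumerate(ts.wells):
        level = getattr(w.condition, inducer)
        window = detect_exponential_phase(ts.times, ts.values["OD600"][:, j],
                                          ts.blanks.get("OD600", 0.0))
        act = relative_promoter_activity(ts, j, window)
        by_rep.setdefault(w.replicate, {})[level] = act
    folds: dict[float, list[float]] = {}
    for rep, acts in by_rep.items():
        f = fold_induction(acts, reference_level)
        for level, v in f.items():
            folds.setdefault(level, []).append(v)
    return fit_dose_response(folds)
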