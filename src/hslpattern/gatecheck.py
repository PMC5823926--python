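"""Three-color AND-gate characterization from 2D HSL titration grids.

All statistics operate on background-corrected intensities, where background
is the (0, 0) condition (no externally supplied HSLs) — distinct from the
media blank handled upstream.  Negative corrected values are retained so that
suppression statistics stay unbiased.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .circuitsim.params import CHANNELS
from .circuitsim.wells import PlateTimeSeries

__all__ = ["TitrationGrid", "grid_from_tidy", "grid_from_plate",
           "correct_background", "max_corrected", "and_score",
           "crosstalk_index", "channel_suppression", "gate_report"]


@dataclass
class TitrationGrid:
    """Raw channel intensities over a (3OC6HSL x 3OC12HSL) grid.

    values maps channel -> array (n_c6, n_c12, n_replicates).
    """

    c6_levels: np.ndarray
    c12_levels: np.ndarray
    values: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        self.c6_levels = np.asarray(self.c6_levels, dtype=float)
        self.c12_levels = np.asarray(self.c12_levels, dtype=float)
        if 0.0 not in self.c6_levels or 0.0 not in self.c12_levels:
            raise ValueError("the (0, 0) background condition must be present")
        for ch, arr in self.values.items():
            arr = np.asarray(arr, dtype=float)
            if arr.ndim == 2:
                arr = arr[:, :, None]
            if arr.shape[:2] != (len(self.c6_levels), len(self.c12_levels)):
                raise ValueError(f"channel {ch}: grid shape mismatch")
            self.values[ch] = arr

    @property
    def n_replicates(self) -> int:
        return next(iter(self.values.values())).shape[2]

    @property
    def zero_idx(self) -> tuple[int, int]:
        return (int(np.nonzero(self.c6_levels == 0)[0][0]),
                int(np.nonzero(self.c12_levels == 0)[0][0]))

    def corrected(self, channel: str) -> np.ndarray:
        return correct_background(self, channel)

    def corrected_mean(self, channel: str) -> np.ndarray:
        return self.corrected(channel).mean(axis=2)


def grid_from_tidy(df: pd.DataFrame) -> TitrationGrid:
    """Build a grid from tidy rows (c6, c12, replicate, channel, value)."""
    required = {"c6", "c12", "replicate", "channel", "value"}
    if not required.issubset(df.columns):
        raise ValueError(f"tidy grid needs columns {sorted(required)}")
    c6 = np.array(sorted(df["c6"].unique()))
    c12 = np.array(sorted(df["c12"].unique()))
    reps = sorted(df["replicate"].unique())
    values = {}
    for ch, sub in df.groupby("channel"):
        arr = np.full((len(c6), len(c12), len(reps)), np.nan)
        for _, row in sub.iterrows():
            i = int(np.nonzero(c6 == row["c6"])[0][0])
            j = int(np.nonzero(c12 == row["c12"])[0][0])
            k = reps.index(row["replicate"])
            arr[i, j, k] = row["value"]
        if np.any(np.isnan(arr)):
            raise ValueError(f"channel {ch}: incomplete grid")
        values[ch] = arr
    return TitrationGrid(c6_levels=c6, c12_levels=c12, values=values)


def grid_from_plate(ts: PlateTimeSeries, tail: int = 10) -> TitrationGrid:
    """Condense a titration plate into a grid: each well's channel value is
    the mean blank-subtracted intensity over the last ``tail`` cycles."""
    rows = []
    for j, w in enumerate(ts.wells):
        for ch in CHANNELS:
            v = ts.values[ch][-tail:, j].mean() - ts.blanks.get(ch, 0.0)
            rows.append({"c6": w.condition.c6, "c12": w.condition.c12,
                         "replicate": w.replicate, "channel": ch, "value": v})
    return grid_from_tidy(pd.DataFrame(rows))


def correct_background(grid: TitrationGrid, channel: str) -> np.ndarray:
    """Subtract the replicate-matched (0, 0) intensity cell-wise; negative
    results are retained."""
    arr = grid.values[channel]
    i0, j0 = grid.zero_idx
    return arr - arr[i0, j0, :][None, None, :]


def max_corrected(grid: TitrationGrid, channel: str) -> tuple[float, float]:
    """Maximum over conditions of the replicate-mean corrected intensity and
    the s.d. of the replicate values at that condition.  Ties break toward
    the lowest (c6, c12) lexicographically."""
    corr = grid.corrected(channel)
    mean = corr.mean(axis=2)
    if mean.size == 0:
        raise ValueError("empty grid")
    i, j = np.unravel_index(int(np.argmax(mean)), mean.shape)  # first == lowest
    at = corr[i, j, :]
    sd = float(np.std(at, ddof=1)) if len(at) > 1 else 0.0
    return float(mean[i, j]), sd


def _single_input_mask(grid: TitrationGrid) -> np.ndarray:
    """Conditions with at most one HSL present (includes (0, 0))."""
    c6 = grid.c6_levels[:, None]
    c12 = grid.c12_levels[None, :]
    return (c6 == 0) | (c12 == 0)


def and_score(grid: TitrationGrid, eps: float = 0.01) -> tuple[float, dict]:
    """AND-gate dynamic range on the corrected RFP grid.

    (max corrected RFP with both inducers present) / (max corrected RFP with
    at most one inducer).  The denominator is floored at ``eps`` times the
    overall maximum corrected RFP; if no single-input condition is positive
    the score is the +infinity sentinel.
    """
    mean = grid.corrected_mean("RFP")
    single = _single_input_mask(grid)
    both = ~single
    if not np.any(both):
        raise ValueError("grid contains no condition with both inducers present")
    num = float(np.max(mean[both]))
    denom_raw = float(np.max(mean[single]))
    info = {"numerator": num, "denominator": denom_raw, "eps_floored": False}
    if denom_raw <= 0:
        info["eps_floored"] = True
        return math.inf, info
    floor = eps * float(np.max(mean))
    denom = max(denom_raw, floor)
    info["eps_floored"] = denom > denom_raw
    info["denominator"] = denom
    return num / denom, info


#: which HSL cognately drives each output channel
_COGNATE = {"CFP": "c6", "YFP": "c12", "RFP": None}


def crosstalk_index(grid: TitrationGrid,
                    channels: tuple[str, ...] = ("YFP", "RFP")) -> dict:
    """Fractional activation by the off-target single input.

    For each requested channel and each input, the maximum corrected
    intensity over conditions where only that input is present, divided by
    the overall maximum corrected intensity.
    """
    out: dict[str, dict[str, float | None]] = {}
    c6 = grid.c6_levels[:, None]
    c12 = grid.c12_levels[None, :]
    only = {"c6": (c6 > 0) & (c12 == 0), "c12": (c6 == 0) & (c12 > 0)}
    for ch in channels:
        mean = grid.corrected_mean(ch)
        overall = float(np.max(mean))
        res: dict[str, float | None] = {}
        for inp, mask in only.items():
            if inp == _COGNATE.get(ch):
                continue  # cognate axis is not crosstalk
            if overall <= 0:
                res[inp] = None  # undefined, flagged as None
            else:
                res[inp] = float(np.max(mean[mask])) / overall
        out[ch] = res
    return out


def channel_suppression(grid: TitrationGrid,
                        channels: tuple[str, ...] = ("CFP", "YFP")) -> dict:
    """Maximal fractional reduction (percent) of each host-driven channel at
    the condition of maximal corrected RFP, relative to its best single-input
    condition."""
    rfp = grid.corrected_mean("RFP")
    i, j = np.unravel_index(int(np.argmax(rfp)), rfp.shape)
    single = _single_input_mask(grid)
    out = {}
    for ch in channels:
        mean = grid.corrected_mean(ch)
        ref = float(np.max(mean[single]))
        if ref <= 0:
            raise ValueError(f"channel {ch}: non-positive single-input maximum")
        out[ch] = 100.0 * (1.0 - mean[i, j] / ref)
    return out


def gate_report(grid: TitrationGrid, eps: float = 0.01) -> dict:
    """Table-1-style JSON-serializable report for one titration grid."""
    score, score_info = and_score(grid, eps=eps)
    maxima = {ch: dict(zip(("mean", "sd"), max_corrected(grid, ch)))
              for ch in CHANNELS}
    return {
        "max_corrected": maxima,
        "and_score": score,
        "and_score_info": score_info,
        "crosstalk": crosstalk_index(grid),
        "suppression_percent": channel_suppression(grid),
    }
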