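"""Spatial analysis of membrane-grid experiments: quadrant quantification,
background-corrected position profiles, interface-domain detection, and
effective-HSL estimation against standard curves.

Background convention for solid-culture data: the matched no-inducer
(no-arabinose or no-HSL) membrane, not the (0, 0) titration condition used
for suspension grids.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.isotonic import IsotonicRegression

from .circuitsim.membrane import MembraneSeries

__all__ = ["SpatialProfile", "DomainCall", "HslEstimate",
           "quantify_quadrants", "position_profile",
           "detect_interface_domain", "estimate_effective_hsl"]

CHANNELS = ("CFP", "YFP", "RFP")


@dataclass
class SpatialProfile:
    """Per-position mean corrected intensity and replicate s.d. at one
    timepoint.  positions are 1-based quadrant indices."""

    positions: np.ndarray
    mean: dict[str, np.ndarray]
    sd: dict[str, np.ndarray]
    time: float
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions)
        if np.any(np.diff(self.positions) <= 0):
            raise ValueError("positions must be strictly increasing")
        for ch, s in self.sd.items():
            if np.any(np.asarray(s) < 0):
                raise ValueError("s.d. must be non-negative")


@dataclass(frozen=True)
class DomainCall:
    """A contiguous gene-expression domain called on a profile."""

    channel: str
    start: int            # 1-based quadrant indices, inclusive
    end: int
    peak: int
    peak_height: float
    symmetry: float       # 1 - normalized mean |mirror difference|
    found: bool = True

    def __post_init__(self) -> None:
        if self.found and not (self.start <= self.peak <= self.end):
            raise ValueError("peak must lie inside the domain interval")


def quantify_quadrants(image: np.ndarray,
                       rects: Sequence[tuple[slice, slice]]) -> np.ndarray:
    """Mean pixel intensity per quadrant rectangle of a 2D image.

    rects maps quadrants to disjoint (row-slice, col-slice) pixel rectangles.
    If ``image`` is already a 1-D per-quadrant table it is passed through.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim == 1:
        return image.copy()
    if image.ndim != 2:
        raise ValueError("expected a 2-D intensity array or a 1-D table")
    occupancy = np.zeros(image.shape, dtype=int)
    out = np.empty(len(rects))
    for q, (rs, cs) in enumerate(rects):
        patch = image[rs, cs]
        if patch.size == 0:
            raise ValueError(f"quadrant {q}: empty pixel rectangle")
        occupancy[rs, cs] += 1
        out[q] = patch.mean()
    if np.any(occupancy > 1):
        raise ValueError("quadrant rectangles overlap")
    return out


def _series_values(series: MembraneSeries, t: float) -> dict[str, np.ndarray]:
    ti = series.at_time(t)
    return {ch: series.channels[ch][ti] for ch in series.channels}


def position_profile(treatment: MembraneSeries | Sequence[MembraneSeries],
                     control: MembraneSeries | Sequence[MembraneSeries],
                     t: float) -> SpatialProfile:
    """Background-corrected intensity against position at time ``t``.

    Each quadrant's value is the treatment intensity minus the matched
    control (same grid, same timepoint).  Replicate membranes may be passed
    as sequences; the s.d. is computed across the replicate quadrants at
    each position (equidistant from the boundary on every membrane).
    """
    tr = [treatment] if isinstance(treatment, MembraneSeries) else list(treatment)
    ct = [control] if isinstance(control, MembraneSeries) else list(control)
    if len(ct) == 1 and len(tr) > 1:
        ct = ct * len(tr)
    if len(tr) != len(ct):
        raise ValueError("need one control per treatment replicate")
    grid = tr[0].grid
    for s in tr + ct:
        if s.grid.n_quadrants != grid.n_quadrants:
            raise ValueError("treatment and control grids do not match")
    corrected = {ch: [] for ch in CHANNELS}
    for a, b in zip(tr, ct):
        va, vb = _series_values(a, t), _series_values(b, t)
        for ch in CHANNELS:
            corrected[ch].append(va[ch] - vb[ch])
    mean = {ch: np.mean(v, axis=0) for ch, v in corrected.items()}
    sd = {ch: (np.std(v, axis=0, ddof=1) if len(v) > 1
               else np.zeros(grid.n_quadrants))
          for ch, v in corrected.items()}
    ti = tr[0].at_time(t)
    return SpatialProfile(positions=grid.positions, mean=mean, sd=sd,
                          time=float(tr[0].times[ti]),
                          meta={"n_replicates": len(tr),
                                "boundary_index": grid.boundary_index})


def detect_interface_domain(profile: SpatialProfile, channel: str,
                            boundary: int | None = None) -> DomainCall:
    """Call the induced domain on one channel of a profile.

    Peak = leftmost argmax of the corrected intensity; domain = maximal
    contiguous interval around the peak at or above half the peak height;
    symmetry = 1 - mean |mirror-pair difference| about the boundary,
    normalized by the peak height.
    """
    y = np.asarray(profile.mean[channel], dtype=float)
    if len(y) < 5:
        raise ValueError("profile too short (need >= 5 quadrants)")
    pos = np.asarray(profile.positions)
    if boundary is None:
        boundary = int(profile.meta.get("boundary_index", len(y) // 2))
    k = int(np.argmax(y))  # leftmost on ties
    peak_height = float(y[k])
    if peak_height <= 0:
        return DomainCall(channel=channel, start=0, end=0, peak=0,
                          peak_height=peak_height, symmetry=0.0, found=False)
    half = peak_height / 2.0
    lo = k
    while lo > 0 and y[lo - 1] >= half:
        lo -= 1
    hi = k
    while hi < len(y) - 1 and y[hi + 1] >= half:
        hi += 1
    # symmetry about the boundary between quadrants b and b+1
    diffs, norm = [], peak_height
    for i in range(len(y)):
        j = 2 * boundary - 1 - i  # mirror index (0-based) about the boundary
        if 0 <= j < len(y) and j > i:
            diffs.append(abs(y[i] - y[j]))
    symmetry = 1.0 - (float(np.mean(diffs)) / norm if diffs else 0.0)
    return DomainCall(channel=channel, start=int(pos[lo]), end=int(pos[hi]),
                      peak=int(pos[k]), peak_height=peak_height,
                      symmetry=symmetry)


@dataclass(frozen=True)
class HslEstimate:
    """Effective HSL concentration bracketed by standards."""

    point: float | None
    low: float | None     # None -> open interval below the lowest standard
    high: float | None    # None -> open interval above the highest standard

    @property
    def open_below(self) -> bool:
        return self.low is None

    @property
    def open_above(self) -> bool:
        return self.high is None


def estimate_effective_hsl(observed: float,
                           standards: Mapping[float, float]) -> HslEstimate:
    """Invert a standard curve (known concentration -> corrected intensity
    under matched conditions) by piecewise-linear interpolation in
    log-concentration, after isotonic cleanup of the standards.

    Observations below the lowest / above the highest standard are reported
    as open intervals.
    """
    if len(standards) < 3:
        raise ValueError("need at least 3 standards")
    conc = np.array(sorted(standards.keys()), dtype=float)
    if np.any(conc <= 0):
        raise ValueError("standard concentrations must be positive")
    vals = np.array([standards[c] for c in conc], dtype=float)
    iso = IsotonicRegression(increasing=True)
    vals = iso.fit_transform(np.log(conc), vals)
    if observed < vals[0]:
        return HslEstimate(point=None, low=None, high=float(conc[0]))
    if observed > vals[-1]:
        return HslEstimate(point=None, low=float(conc[-1]), high=None)
    i = int(np.searchsorted(vals, observed, side="right") - 1)
    i = min(max(i, 0), len(conc) - 2)
    lo, hi = conc[i], conc[i + 1]
    if vals[i + 1] == vals[i]:
        point = float(np.sqrt(lo * hi))
    else:
        f = (observed - vals[i]) / (vals[i + 1] - vals[i])
        point = float(np.exp(np.log(lo) + f * (np.log(hi) - np.log(lo))))
    return HslEstimate(point=point, low=float(lo), high=float(hi))
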