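"""Rhythm ratios, small-integer-ratio categories and rhythm summaries.

The rhythm ratio of two adjacent intervals is r_k = t_k / (t_k + t_k+1),
a scale-free quantity in (0, 1): 0.5 is isochrony (1:1), 0.25 and 0.75
are the 1:3 and 3:1 categories. Ratios are counted as *on-integer* when
they fall within +/-0.056 of a category center (0.444-0.556 around 1:1)
and *off-integer* in the flanking bands a further 0.044 wide
(0.400-0.444 and 0.556-0.600 around 1:1); the same absolute widths are
translated to the 0.25 and 0.75 centers.

Two scalar summaries characterize a ratio sample: *deviance*
|r_k - 0.5| measures accuracy (proximity to perfect isochrony),
summarized by the location of the peak of its Gaussian kernel density;
*spread*, the interquartile range of r_k, measures precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

#: fixed KDE bandwidth for the deviance density
DEVIANCE_BANDWIDTH = 0.00194663

ISOCHRONY_CENTER = 0.5


def ratios(intervals: np.ndarray) -> np.ndarray:
    """Rhythm ratios r_k = t_k / (t_k + t_{k+1}) of adjacent intervals.

    Scale-invariant and order-preserving; requires at least two strictly
    positive intervals.
    """
    t = np.asarray(intervals, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 intervals to form a ratio")
    if np.any(t <= 0):
        bad = np.nonzero(t <= 0)[0]
        raise ValueError(f"non-positive interval(s) at position(s) {bad.tolist()}")
    return t[:-1] / (t[:-1] + t[1:])


@dataclass(frozen=True)
class CategoryWindows:
    """On/off-integer bands around small-integer-ratio centers.

    Each center c gets an on-integer band [c - on, c + on] and two
    off-integer flanks (c - on - off, c - on) and (c + on, c + on + off).
    Bands of different centers must not overlap.
    """

    centers: tuple[float, ...] = (0.25, 0.5, 0.75)
    on_halfwidth: float = 0.056
    off_bandwidth: float = 0.044

    def __post_init__(self):
        if self.on_halfwidth <= 0 or self.off_bandwidth <= 0:
            raise ValueError("band widths must be positive")
        cs = sorted(self.centers)
        reach = self.on_halfwidth + self.off_bandwidth
        for a, b in zip(cs, cs[1:]):
            if a + reach > b - reach:
                raise ValueError(
                    f"windows of centers {a} and {b} overlap (reach {reach})"
                )

    def label(self, r: float) -> tuple[str, float | None]:
        """Classify one ratio: ('on'|'off'|'unclassified', center)."""
        eps = 1e-12  # boundaries: on-band edges inclusive, outer off edge exclusive
        for c in self.centers:
            d = abs(r - c)
            if d <= self.on_halfwidth + eps:
                return "on", c
            if d < self.on_halfwidth + self.off_bandwidth - eps:
                return "off", c
        return "unclassified", None


def classify(r: np.ndarray, windows: CategoryWindows = CategoryWindows()) -> dict:
    """Count ratios per on/off/unclassified label.

    Returns ``{"on": int, "off": int, "unclassified": int,
    "per_center": {center: {"on": int, "off": int}}, "labels": [...]}``;
    the three top-level counts always partition the sample.
    """
    r = np.asarray(r, dtype=float)
    labels = [windows.label(v) for v in r]
    per_center = {c: {"on": 0, "off": 0} for c in windows.centers}
    counts = {"on": 0, "off": 0, "unclassified": 0}
    for lab, c in labels:
        counts[lab] += 1
        if c is not None:
            per_center[c][lab] += 1
    counts["per_center"] = per_center
    counts["labels"] = labels
    return counts


def deviance(r: np.ndarray, center: float = ISOCHRONY_CENTER) -> np.ndarray:
    """Absolute distance of each ratio from the category center."""
    return np.abs(np.asarray(r, dtype=float) - center)


def kde_mode(
    values: np.ndarray,
    bandwidth: float = DEVIANCE_BANDWIDTH,
    grid_points: int = 4096,
) -> tuple[float, float]:
    """Location and height of the peak of a Gaussian KDE.

    The density is evaluated on a fixed grid of ``grid_points`` spanning
    the data range widened by three bandwidths; ties in the maximum are
    broken toward the smallest abscissa so the mode is reproducible.
    Returns ``(mode_location, peak_density)``.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate a density from an empty sample")
    if bandwidth <= 0:
        raise ValueError("bandwidth must be positive")
    lo = v.min() - 3.0 * bandwidth
    hi = v.max() + 3.0 * bandwidth
    grid = np.linspace(lo, hi, grid_points)
    # direct evaluation; chunked over the sample to bound memory
    dens = np.zeros_like(grid)
    norm = 1.0 / (v.size * bandwidth * np.sqrt(2.0 * np.pi))
    for start in range(0, v.size, 2048):
        chunk = v[start : start + 2048]
        z = (grid[:, None] - chunk[None, :]) / bandwidth
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens *= norm
    i = int(np.argmax(dens))  # argmax returns the first (smallest) abscissa
    return float(grid[i]), float(dens[i])


def density_curve(
    values: np.ndarray,
    bandwidth: float = 0.02,
    lo: float = 0.0,
    hi: float = 1.0,
    grid_points: int = 1024,
) -> tuple[np.ndarray, np.ndarray]:
    """Gaussian KDE of a ratio sample on a fixed grid over [lo, hi]."""
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("cannot estimate a density from an empty sample")
    grid = np.linspace(lo, hi, grid_points)
    dens = np.zeros_like(grid)
    for start in range(0, v.size, 2048):
        chunk = v[start : start + 2048]
        z = (grid[:, None] - chunk[None, :]) / bandwidth
        dens += np.exp(-0.5 * z * z).sum(axis=1)
    dens /= v.size * bandwidth * np.sqrt(2.0 * np.pi)
    return grid, dens


def density_modes(
    values: np.ndarray,
    bandwidth: float = 0.02,
    lo: float = 0.0,
    hi: float = 1.0,
    grid_points: int = 1024,
    min_rel_prominence: float = 0.1,
) -> list[float]:
    """Locations of the local maxima of a ratio-sample KDE.

    Peaks must have a prominence of at least ``min_rel_prominence`` times
    the maximum density, which suppresses sampling ripples; locations are
    returned in increasing abscissa order. Used to characterize the
    interlimb (IHI) ratio densities, which are bimodal for gaits whose
    ipsilateral impacts alternate long/short intervals.
    """
    from scipy.signal import find_peaks

    grid, dens = density_curve(values, bandwidth, lo, hi, grid_points)
    idx, _ = find_peaks(dens, prominence=min_rel_prominence * dens.max())
    if idx.size == 0:  # monotone or single-peak-at-edge density
        idx = np.array([int(np.argmax(dens))])
    return [float(grid[i]) for i in idx]


def spread(r: np.ndarray) -> float:
    """Interquartile range Q3 - Q1 of the ratio sample.

    Quartiles use linear interpolation between order statistics (R's
    default type-7 convention). Fewer than 4 values is flagged as
    unreliable but still computed.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        raise ValueError("cannot compute spread of an empty sample")
    if r.size < 4:
        warnings.warn(
            f"spread computed from only {r.size} values; unreliable",
            stacklevel=2,
        )
    q1, q3 = np.quantile(r, [0.25, 0.75], method="linear")
    return float(q3 - q1)


def relative_phase(intervals) -> np.ndarray:
    """Per-cycle relative phase HFI/FHI of the ipsilateral pair.

    Values must lie in (0, 1); cycles whose lag reaches or exceeds the
    enclosing cycle (phase wrap) are excluded.
    """
    hfi = np.asarray(intervals.hfi_s, dtype=float)
    fhi = np.asarray(intervals.hfi_cycle_s, dtype=float)
    if hfi.size != fhi.size:
        raise ValueError("HFI and paired FHI must have equal length")
    if hfi.size == 0:
        return np.empty(0)
    valid = (hfi > 0) & (hfi < fhi)
    return hfi[valid] / fhi[valid]


@dataclass
class RhythmSummary:
    """Per-unit (horse, gait, saddle, hoof) rhythm summary."""

    horse: str
    gait: str
    saddle: str
    hoof: str
    n_ratios: int
    deviance_mode: float
    deviance_peak_density: float
    spread: float
    on_count: int
    off_count: int
    unclassified_count: int


def summarize_unit(
    r: np.ndarray,
    horse: str,
    gait: str,
    saddle: str,
    hoof: str,
    windows: CategoryWindows | None = None,
    bandwidth: float = DEVIANCE_BANDWIDTH,
) -> RhythmSummary:
    """Summarize one unit's single-limb ratio sample.

    Classification uses the isochrony (1:1) window only, as single-limb
    cycle sequences are tested against isochrony.
    """
    windows = windows or CategoryWindows(centers=(ISOCHRONY_CENTER,))
    counts = classify(r, windows)
    mode, height = kde_mode(deviance(r), bandwidth)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        iqr = spread(r)
    return RhythmSummary(
        horse=horse,
        gait=gait,
        saddle=saddle,
        hoof=hoof,
        n_ratios=int(np.size(r)),
        deviance_mode=mode,
        deviance_peak_density=height,
        spread=iqr,
        on_count=counts["on"],
        off_count=counts["off"],
        unclassified_count=counts["unclassified"],
    )
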