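"""Hoof-impact detection and the four interval sequences.

An impact is a positive peak of the withers-normalized sagittal (x)
displacement of a hoof: the hoof is maximally protracted relative to the
trunk at touch-down, so the peak marks the onset of stance and of a new
motion cycle. From the two ipsilateral impact series come four interval
sequences:

FHI   fore-hoof cycle durations (successive fore impacts)
HHI   hind-hoof cycle durations (successive hind impacts)
IHI   intervals between successive impacts of the merged fore+hind train
HFI   per fore cycle, the lag from the fore impact to the first hind
      impact inside that cycle (the ipsilateral coordination lag)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import TrajectorySet


@dataclass
class ImpactSeries:
    """Ordered impact timestamps for one limb."""

    limb: str  # "fore" | "hind"
    times_s: np.ndarray
    key: tuple = ()

    def __post_init__(self):
        self.times_s = np.asarray(self.times_s, dtype=float)
        if self.times_s.size >= 2 and np.any(np.diff(self.times_s) <= 0):
            raise ValueError("impact times must be strictly increasing")

    def __len__(self) -> int:
        return self.times_s.size


@dataclass
class IntervalSet:
    """The four interval sequences derived from an ipsilateral pair.

    ``hfi_cycle_s`` holds the enclosing FHI for each HFI entry so the
    relative phase HFI/FHI can be formed per cycle. ``n_dropped_cycles``
    counts fore cycles without an interior hind impact and
    ``n_ties`` counts near-simultaneous fore/hind impacts that were
    excluded rather than arbitrarily ordered.
    """

    fhi_s: np.ndarray
    hhi_s: np.ndarray
    ihi_s: np.ndarray
    ihi_labels: list[str]
    hfi_s: np.ndarray
    hfi_cycle_s: np.ndarray
    n_dropped_cycles: int = 0
    n_ties: int = 0
    key: tuple = ()


def _refine_peak_times(t: np.ndarray, y: np.ndarray, idx: np.ndarray) -> np.ndarray:
    """Sub-sample peak refinement by a local quadratic (parabolic) fit.

    The 120 Hz frame period (8.3 ms) is coarse relative to the ratio
    windows, so the discrete argmax is shifted by the vertex of the
    parabola through the three samples around it.
    """
    dt = float(np.median(np.diff(t)))
    times = t[idx].astype(float).copy()
    interior = (idx > 0) & (idx < y.size - 1)
    i = idx[interior]
    denom = y[i - 1] - 2.0 * y[i] + y[i + 1]
    ok = denom < 0
    delta = np.zeros_like(denom)
    delta[ok] = 0.5 * (y[i - 1] - y[i + 1])[ok] / denom[ok]
    times[interior] += np.clip(delta, -0.5, 0.5) * dt
    return times


def detect_impacts(
    time_s: np.ndarray,
    x_norm: np.ndarray,
    limb: str = "fore",
    prominence_frac: float = 0.3,
    min_separation_s: float | None = None,
    min_width_samples: int = 2,
    key: tuple = (),
) -> ImpactSeries:
    """Detect hoof impacts as prominent positive peaks of ``x_norm``.

    A first pass estimates the typical inter-peak spacing; the final
    pass requires peaks separated by ``min_separation_s`` (default: a
    quarter of that spacing), a prominence of ``prominence_frac`` times
    the signal's peak-to-peak range, and a half-prominence width of at
    least ``min_width_samples`` samples — together these reject noise
    spikes, which are tall but one sample wide. Peak times are refined
    by quadratic interpolation.
    """
    from scipy.signal import find_peaks

    t = np.asarray(time_s, dtype=float)
    y = np.asarray(x_norm, dtype=float)
    ptp = float(np.ptp(y))
    if ptp <= 0:
        raise ValueError("insufficient cycles: flat signal, no peaks found")
    prominence = prominence_frac * ptp
    first, _ = find_peaks(y, prominence=prominence, width=min_width_samples)
    if first.size < 3:
        raise ValueError(
            f"insufficient cycles: found {first.size} peaks, need at least 3"
        )
    dt = float(np.median(np.diff(t)))
    if min_separation_s is None:
        min_separation_s = 0.25 * float(np.median(np.diff(t[first])))
    distance = max(1, int(round(min_separation_s / dt)))
    idx, _ = find_peaks(
        y, prominence=prominence, distance=distance, width=min_width_samples
    )
    if idx.size < 3:
        raise ValueError(
            f"insufficient cycles: found {idx.size} peaks after separation filter"
        )
    return ImpactSeries(limb, _refine_peak_times(t, y, idx), key=key)


def impacts_from_trial(traj: TrajectorySet, **kwargs) -> tuple[ImpactSeries, ImpactSeries]:
    """Detect fore and hind impacts from a preprocessed trial."""
    key = traj.key()
    fore = detect_impacts(traj.time_s, traj.axis("fore_hoof", 0), "fore", key=key, **kwargs)
    hind = detect_impacts(traj.time_s, traj.axis("hind_hoof", 0), "hind", key=key, **kwargs)
    return fore, hind


def intervals_from_impacts(
    fore: ImpactSeries,
    hind: ImpactSeries,
    tie_tolerance_s: float = 1.0 / 120.0,
) -> IntervalSet:
    """Derive FHI, HHI, IHI and HFI from the two impact series.

    Fore/hind impacts closer than ``tie_tolerance_s`` are treated as
    simultaneous: the affected IHI entries are excluded (never fabricated
    as zero-length intervals) and counted as ties. Fore cycles with no
    interior hind impact are dropped from HFI and counted.
    """
    f = fore.times_s
    h = hind.times_s
    if f.size == 0 or h.size == 0:
        raise ValueError("both impact series must be non-empty")
    if f[-1] < h[0] or h[-1] < f[0]:
        raise ValueError("fore and hind impact series do not overlap in time")

    fhi = np.diff(f)
    hhi = np.diff(h)

    # merged train with limb labels, time-sorted
    times = np.concatenate([f, h])
    limbs = np.array(["fore"] * f.size + ["hind"] * h.size)
    order = np.argsort(times, kind="stable")
    times, limbs = times[order], limbs[order]

    gaps = np.diff(times)
    tie = (gaps < tie_tolerance_s) & (limbs[:-1] != limbs[1:])
    n_ties = int(np.count_nonzero(tie))
    # an interval adjacent to a tied pair is ill-defined on one side only;
    # exclude exactly the tied (near-zero) gaps
    keep = ~tie
    ihi = gaps[keep]
    ihi_labels = [
        f"{a}->{b}" for a, b, k in zip(limbs[:-1], limbs[1:], keep) if k
    ]

    hfi, hfi_cycle = [], []
    n_dropped = 0
    for k in range(f.size - 1):
        lo, hi = f[k], f[k + 1]
        inside = h[(h > lo + tie_tolerance_s) & (h < hi - tie_tolerance_s)]
        if inside.size == 0:
            n_dropped += 1
            continue
        hfi.append(inside[0] - lo)
        hfi_cycle.append(hi - lo)

    return IntervalSet(
        fhi_s=fhi,
        hhi_s=hhi,
        ihi_s=ihi,
        ihi_labels=ihi_labels,
        hfi_s=np.asarray(hfi, dtype=float),
        hfi_cycle_s=np.asarray(hfi_cycle, dtype=float),
        n_dropped_cycles=n_dropped,
        n_ties=n_ties,
        key=fore.key or hind.key,
    )
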