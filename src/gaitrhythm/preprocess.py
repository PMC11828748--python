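"""Trajectory filtering and the horse-based (withers-origin) frame.

Hoof channels are low-passed at 15 Hz and the withers at 5 Hz, both with
a zero-phase (forward-backward) Butterworth filter so that impact timing
is not lagged; hoof positions are then re-expressed relative to the
withers by per-frame subtraction, which removes the horse's travel
through the capture volume.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .trajectory import TrajectorySet, require_markers

HOOF_MARKERS = ("fore_hoof", "hind_hoof")


@dataclass(frozen=True)
class FilterSpec:
    """Low-pass cutoffs per marker class and the filter's shape.

    Defaults: 4th-order Butterworth applied forward-backward (zero phase,
    effective order 8), 15 Hz for hooves, 5 Hz for the withers.
    """

    hoof_cutoff_hz: float = 15.0
    withers_cutoff_hz: float = 5.0
    order: int = 4
    zero_phase: bool = True

    def cutoff_for(self, marker: str) -> float:
        return self.hoof_cutoff_hz if marker in HOOF_MARKERS else self.withers_cutoff_hz


def _apply_lowpass(x: np.ndarray, cutoff_hz: float, fs: float, spec: FilterSpec) -> np.ndarray:
    nyq = fs / 2.0
    if not 0 < cutoff_hz < nyq:
        raise ValueError(f"cutoff {cutoff_hz} Hz must lie in (0, Nyquist={nyq} Hz)")
    sos = signal.butter(spec.order, cutoff_hz, btype="low", fs=fs, output="sos")
    if spec.zero_phase:
        # odd-reflection padding of one settling length handles the short
        # straight-track passes where edge transients would be material
        padlen = min(3 * (2 * spec.order + 1), x.shape[0] - 1)
        return signal.sosfiltfilt(sos, x, axis=0, padlen=padlen)
    return signal.sosfilt(sos, x, axis=0)


def lowpass(traj: TrajectorySet, spec: FilterSpec = FilterSpec()) -> TrajectorySet:
    """Low-pass every marker channel at its class-specific cutoff.

    Raises if any cutoff reaches the Nyquist frequency or the trial is
    shorter than three filter settling lengths.
    """
    fs = traj.sampling_rate_hz
    min_len = 3 * (3 * (2 * spec.order + 1))
    if traj.n_frames < min_len:
        raise ValueError(
            f"trial of {traj.n_frames} frames is shorter than 3x the filter "
            f"settling length ({min_len} frames)"
        )
    out = {
        name: _apply_lowpass(pos, spec.cutoff_for(name), fs, spec)
        for name, pos in traj.positions.items()
    }
    return traj.with_positions(out, filtered=True)


def normalize_to_withers(traj: TrajectorySet) -> TrajectorySet:
    """Express hoof positions relative to the withers, per frame and axis.

    The withers channel is consumed (dropped from the output); the result
    is translation-invariant, so any common drift of the whole horse
    through the volume cancels.
    """
    require_markers(traj)
    withers = traj.positions["withers"]
    out = {}
    for name in HOOF_MARKERS:
        hoof = traj.positions[name]
        if hoof.shape != withers.shape:
            raise ValueError(f"marker {name!r} length differs from withers")
        out[name] = hoof - withers
    return traj.with_positions(out, normalized=True)


def preprocess_trial(traj: TrajectorySet, spec: FilterSpec = FilterSpec()) -> TrajectorySet:
    """Filter then normalize, the canonical order of the pipeline."""
    return normalize_to_withers(lowpass(traj, spec))


def butterworth_two_pass_gain(f_hz: float, cutoff_hz: float, order: int = 4) -> float:
    """Analytic amplitude response of the forward-backward Butterworth.

    One analog pass has |H(f)|^2 = 1 / (1 + (f/fc)^(2n)); two passes
    square the magnitude. Used as the oracle for filter tests.
    """
    single = 1.0 / np.sqrt(1.0 + (f_hz / cutoff_hz) ** (2 * order))
    return float(single**2)
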