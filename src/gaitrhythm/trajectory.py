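"""Container for marker-trajectory time series.

The analysis frame is fixed: ``x`` is the direction of travel (sagittal
axis), ``z`` is vertical, ``y`` is mediolateral. Positions are metres,
time is seconds, and all markers share one uniform time base.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

#: markers every trial must carry before preprocessing
REQUIRED_MARKERS = ("withers", "fore_hoof", "hind_hoof")


@dataclass
class TrajectorySet:
    """Time-indexed 3-D positions for a named set of markers.

    Parameters
    ----------
    sampling_rate_hz : float
        Uniform sampling rate of every marker channel.
    time_s : ndarray, shape (n_frames,)
        Strictly increasing timestamps in seconds.
    positions : dict of str -> ndarray, shape (n_frames, 3)
        Per-marker (x, y, z) positions in metres.
    metadata : dict
        Trial keys (``horse``, ``gait``, ``saddle``, ``trial``) plus any
        provenance the producer wants to carry along.
    """

    sampling_rate_hz: float
    time_s: np.ndarray
    positions: dict[str, np.ndarray]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        if self.time_s.ndim != 1:
            raise ValueError("time_s must be one-dimensional")
        if np.any(np.diff(self.time_s) <= 0):
            bad = int(np.argmax(np.diff(self.time_s) <= 0)) + 1
            raise ValueError(f"time_s not strictly increasing at frame {bad}")
        n = self.time_s.size
        cleaned: dict[str, np.ndarray] = {}
        for name, pos in self.positions.items():
            arr = np.asarray(pos, dtype=float)
            if arr.shape != (n, 3):
                raise ValueError(
                    f"marker {name!r} has shape {arr.shape}, expected ({n}, 3)"
                )
            cleaned[name] = arr
        self.positions = cleaned

    @property
    def n_frames(self) -> int:
        return self.time_s.size

    @property
    def markers(self) -> tuple[str, ...]:
        return tuple(self.positions)

    @property
    def duration_s(self) -> float:
        return float(self.time_s[-1] - self.time_s[0])

    def key(self) -> tuple:
        """(horse, gait, saddle, trial) tuple used to index all outputs."""
        m = self.metadata
        return (m.get("horse"), m.get("gait"), m.get("saddle"), m.get("trial"))

    def axis(self, marker: str, axis: int) -> np.ndarray:
        return self.positions[marker][:, axis]

    def with_positions(
        self, positions: Mapping[str, np.ndarray], **meta_updates
    ) -> "TrajectorySet":
        """Copy with replaced position channels (metadata carried over)."""
        md = dict(self.metadata)
        md.update(meta_updates)
        return TrajectorySet(
            sampling_rate_hz=self.sampling_rate_hz,
            time_s=self.time_s.copy(),
            positions={k: np.array(v) for k, v in positions.items()},
            metadata=md,
        )


def require_markers(traj: TrajectorySet, names=REQUIRED_MARKERS) -> None:
    missing = [m for m in names if m not in traj.positions]
    if missing:
        raise ValueError(
            f"missing required marker(s) {missing}; found {sorted(traj.positions)}"
        )
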