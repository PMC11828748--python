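"""Reading and writing trajectories and analysis outputs.

The canonical on-disk dialect is long-format CSV — one row per time
frame and marker, columns ``time_s, marker, x_m, y_m, z_m`` — with a
JSON sidecar (``<name>.meta.json``) carrying the sampling rate, the
length unit and the trial keys. Long format keeps fixtures unambiguous
and diff-able. C3D interchange is supported when the optional ``ezc3d``
library is installed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .trajectory import REQUIRED_MARKERS, TrajectorySet

#: declared length unit -> metres
_UNIT_TO_M = {"m": 1.0, "mm": 1e-3, "cm": 1e-2}

#: missing samples are bridged by linear interpolation up to this many
#: consecutive frames; longer gaps reject the trial (peak timing must not
#: be invented across long occlusions)
MAX_GAP_FRAMES = 5


@dataclass
class TrialRecord:
    """A trajectory plus its provenance and declared unit."""

    trajectory: TrajectorySet
    provenance: str
    units: str = "m"


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory_csv(traj: TrajectorySet, path) -> Path:
    """Write one trial in the canonical long CSV dialect + JSON sidecar."""
    path = Path(path)
    frames = []
    for marker in sorted(traj.positions):  # canonical marker order
        pos = traj.positions[marker]
        frames.append(
            pd.DataFrame(
                {
                    "time_s": traj.time_s,
                    "marker": marker,
                    "x_m": pos[:, 0],
                    "y_m": pos[:, 1],
                    "z_m": pos[:, 2],
                }
            )
        )
    df = pd.concat(frames, ignore_index=True)
    df.to_csv(path, index=False, float_format="%.9g")
    meta = {
        "sampling_rate_hz": traj.sampling_rate_hz,
        "units": "m",
        "metadata": _jsonable(traj.metadata),
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1, sort_keys=True))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _interpolate_gaps(values: np.ndarray, marker: str) -> np.ndarray:
    """Linearly bridge NaN runs of at most MAX_GAP_FRAMES frames."""
    out = values.copy()
    for ax in range(out.shape[1]):
        col = out[:, ax]
        isnan = np.isnan(col)
        if not isnan.any():
            continue
        # find runs of consecutive NaNs
        edges = np.flatnonzero(np.diff(np.concatenate([[0], isnan.view(np.int8), [0]])))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start > MAX_GAP_FRAMES:
                raise ValueError(
                    f"marker {marker!r} has a gap of {stop - start} frames "
                    f"(> {MAX_GAP_FRAMES}); trial rejected"
                )
        idx = np.arange(col.size)
        out[:, ax] = np.interp(idx, idx[~isnan], col[~isnan])
    return out


def read_trajectory_csv(path, unit: str | None = None) -> TrialRecord:
    """Read a long-format CSV trial.

    The time base must be strictly increasing and uniform (median
    frame-interval deviation below 1e-6 s); positions declared in mm or
    cm are converted to metres. The three required markers must all be
    present.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if unit is None:
        unit = meta.get("units", "m")
    if unit not in _UNIT_TO_M:
        raise ValueError(f"unknown length unit {unit!r}; expected one of {sorted(_UNIT_TO_M)}")
    scale = _UNIT_TO_M[unit]

    df = pd.read_csv(path)
    required_cols = {"time_s", "marker", "x_m", "y_m", "z_m"}
    if not required_cols.issubset(df.columns):
        raise ValueError(f"CSV must have columns {sorted(required_cols)}")

    markers = sorted(df["marker"].unique())
    missing = [m for m in REQUIRED_MARKERS if m not in markers]
    if missing:
        raise ValueError(f"missing required marker(s) {missing}; found {markers}")

    positions = {}
    time_ref = None
    for marker, sub in df.groupby("marker", sort=True):
        t = sub["time_s"].to_numpy(float)
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(sub.index[np.argmax(dt <= 0) + 1])
            raise ValueError(
                f"time not strictly increasing for marker {marker!r} at CSV row {row}"
            )
        if time_ref is None:
            time_ref = t
        elif t.size != time_ref.size or not np.allclose(t, time_ref, atol=1e-9):
            raise ValueError(f"marker {marker!r} uses a different time base")
        pos = sub[["x_m", "y_m", "z_m"]].to_numpy(float) * scale
        positions[marker] = _interpolate_gaps(pos, marker)

    med_dt = float(np.median(np.diff(time_ref)))
    if np.max(np.abs(np.diff(time_ref) - med_dt)) > 1e-6:
        raise ValueError("non-uniform sampling: frame intervals deviate by more than 1e-6 s")
    fs = meta.get("sampling_rate_hz", 1.0 / med_dt)
    if abs(fs - 1.0 / med_dt) > 1e-3 * fs:
        raise ValueError(
            f"declared sampling rate {fs} Hz disagrees with median frame interval {med_dt} s"
        )
    traj = TrajectorySet(fs, time_ref, positions, dict(meta.get("metadata", {})))
    return TrialRecord(trajectory=traj, provenance=str(path), units="m")


DEFAULT_C3D_ALIASES = {
    "withers": "withers",
    "fore_hoof": "fore_hoof",
    "hind_hoof": "hind_hoof",
}


def read_trajectory_c3d(path, alias_table: dict[str, str] | None = None) -> TrialRecord:
    """Read a C3D motion-capture file (requires the optional ezc3d).

    ``alias_table`` maps C3D point labels to the canonical marker names
    (e.g. ``{"T6": "withers"}``). Samples whose residual marks them
    occluded become NaN and pass through the same gap-interpolation
    policy as the CSV reader. C3D stores positions in millimetres by
    convention unless the file declares otherwise.
    """
    try:
        import ezc3d
    except ImportError as err:
        raise ImportError(
            "reading C3D files requires the optional dependency 'ezc3d' "
            "(pip install ezc3d); the canonical CSV dialect needs no extras"
        ) from err
    path = Path(path)
    c3d = ezc3d.c3d(str(path))
    labels = [s.strip() for s in c3d["parameters"]["POINT"]["LABELS"]["value"]]
    rate = float(c3d["parameters"]["POINT"]["RATE"]["value"][0])
    pts = c3d["data"]["points"]  # (4, n_markers, n_frames)
    residuals = c3d["data"]["meta_points"]["residuals"]
    n_frames = pts.shape[2]
    if n_frames == 0:
        raise ValueError("C3D file contains no frames")
    unit_par = c3d["parameters"]["POINT"].get("UNITS", {}).get("value", ["mm"])
    scale = _UNIT_TO_M.get(str(unit_par[0]).strip().lower(), 1e-3)

    alias = dict(DEFAULT_C3D_ALIASES)
    for src, dst in (alias_table or {}).items():
        alias[src] = dst
    name_of = {}
    for i, lab in enumerate(labels):
        if lab in alias:
            name_of[alias[lab]] = i
    missing = [m for m in REQUIRED_MARKERS if m not in name_of]
    if missing:
        raise ValueError(
            f"unmapped required marker(s) {missing}; C3D labels: {labels}"
        )
    time_s = np.arange(n_frames) / rate
    positions = {}
    for name, i in name_of.items():
        xyz = pts[:3, i, :].T * scale
        occluded = residuals[0, i, :] < 0
        xyz[occluded] = np.nan
        positions[name] = _interpolate_gaps(xyz, name)
    traj = TrajectorySet(rate, time_s, positions, {"source": str(path)})
    return TrialRecord(trajectory=traj, provenance=str(path), units="m")


def write_trajectory_c3d(traj: TrajectorySet, path) -> Path:
    """Write a minimal C3D file (requires the optional ezc3d)."""
    try:
        import ezc3d
    except ImportError as err:
        raise ImportError("writing C3D files requires the optional dependency 'ezc3d'") from err
    c3d = ezc3d.c3d()
    markers = list(traj.positions)
    c3d["parameters"]["POINT"]["RATE"]["value"] = [traj.sampling_rate_hz]
    c3d["parameters"]["POINT"]["LABELS"]["value"] = markers
    c3d["parameters"]["POINT"]["UNITS"]["value"] = ["m"]
    data = np.zeros((4, len(markers), traj.n_frames))
    for i, m in enumerate(markers):
        data[:3, i, :] = traj.positions[m].T
        data[3, i, :] = 1.0
    c3d["data"]["points"] = data
    c3d.write(str(path))
    return Path(path)


def write_results(tables: dict[str, pd.DataFrame], outdir, manifest: dict) -> dict[str, Path]:
    """Write tidy result tables as CSV plus a JSON run manifest.

    One file per table name; the manifest records the configuration,
    seeds and software version so any table can be regenerated.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = {}
    for name, df in tables.items():
        p = outdir / f"{name}.csv"
        df.to_csv(p, index=False, float_format="%.10g")
        written[name] = p
    from . import __version__

    manifest = dict(manifest)
    manifest.setdefault("software", {})["gaitrhythm"] = __version__
    mp = outdir / "manifest.json"
    mp.write_text(json.dumps(_jsonable(manifest), indent=1, sort_keys=True))
    written["manifest"] = mp
    return written


def read_manifest(outdir) -> dict:
    return json.loads((Path(outdir) / "manifest.json").read_text())
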