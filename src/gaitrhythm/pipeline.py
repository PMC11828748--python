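"""End-to-end orchestration: simulate -> preprocess -> events -> rhythm -> stats.

One configuration object and one seed determine every output table:
impact times, interval sequences, rhythm ratios with category labels,
per-unit summaries, density curves and test results, plus a JSON
manifest that suffices to reproduce the run. Per-trial counters (peaks
found, cycles dropped, ties excluded) are carried into the tables so
every exclusion is auditable.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import events as ev
from . import io as gio
from . import rhythm as ry
from . import stats as st
from .preprocess import FilterSpec, preprocess_trial
from .simulate import GAITS, SimParams, simulate_cohort
from .trajectory import TrajectorySet


@dataclass
class RunConfig:
    """Serializable configuration of a full pipeline run."""

    n_horses: int = 13
    gaits: tuple[str, ...] = GAITS
    saddles: tuple[str, ...] = ("english", "side")
    trials_per_cell: int = 4
    n_cycles: int = 5
    jitter_cv: float = 0.02
    noise_sd_m: float = 0.005
    sampling_rate_hz: float = 120.0
    horse_tempo_sd: float = 0.05
    horse_phase_sd: float = 0.005
    phase_overrides: dict = field(default_factory=dict)
    filter: FilterSpec = field(default_factory=FilterSpec)
    prominence_frac: float = 0.3
    min_separation_s: float | None = None
    windows: ry.CategoryWindows = field(default_factory=ry.CategoryWindows)
    deviance_bandwidth: float = ry.DEVIANCE_BANDWIDTH
    fit_models: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_horses < 1:
            raise ValueError("n_horses must be >= 1")
        if not self.gaits or not self.saddles:
            raise ValueError("gaits and saddles must be non-empty")
        if self.n_cycles < 3:
            raise ValueError("n_cycles must be >= 3")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["filter"] = dataclasses.asdict(self.filter)
        d["windows"] = dataclasses.asdict(self.windows)
        return d

    def sim_params(self) -> SimParams:
        return SimParams(
            n_cycles=self.n_cycles,
            jitter_cv=self.jitter_cv,
            noise_sd_m=self.noise_sd_m,
            sampling_rate_hz=self.sampling_rate_hz,
            seed=self.seed,
        )


_KEYS = ["horse", "gait", "saddle", "trial"]


def _trial_rows(traj: TrajectorySet, config: RunConfig):
    """Process one trial: impacts and intervals (ratios are pooled later)."""
    pre = preprocess_trial(traj, config.filter)
    fore, hind = ev.impacts_from_trial(
        pre,
        prominence_frac=config.prominence_frac,
        min_separation_s=config.min_separation_s,
    )
    tie_tol = 1.0 / traj.sampling_rate_hz
    ivs = ev.intervals_from_impacts(fore, hind, tie_tolerance_s=tie_tol)
    return fore, hind, ivs


def analyze_trials(trials: list[TrajectorySet], config: RunConfig) -> dict[str, pd.DataFrame]:
    """Run preprocessing, event detection and rhythm analysis on trials.

    Returns tidy tables keyed end-to-end by (horse, gait, saddle, trial).
    Rhythm ratios are never formed across trial boundaries; per-unit
    summaries pool the within-trial ratios of all of a unit's trials.
    """
    impact_rows, interval_rows, ratio_rows, relphase_rows = [], [], [], []
    counter_rows = []
    unit_ratios: dict[tuple, dict[str, list]] = {}
    unit_relphase: dict[tuple, list] = {}
    ihi_ratios_by_gait: dict[str, list] = {}

    for traj in trials:
        meta = {k: traj.metadata.get(k) for k in _KEYS}
        try:
            fore, hind, ivs = _trial_rows(traj, config)
        except ValueError as err:
            raise type(err)(f"trial {tuple(meta.values())}: {err}") from err
        for series in (fore, hind):
            for t in series.times_s:
                impact_rows.append({**meta, "limb": series.limb, "time_s": t})
        for kind, vals in (("FHI", ivs.fhi_s), ("HHI", ivs.hhi_s), ("IHI", ivs.ihi_s)):
            for v in vals:
                interval_rows.append({**meta, "kind": kind, "value_s": v})
        for v, c in zip(ivs.hfi_s, ivs.hfi_cycle_s):
            interval_rows.append({**meta, "kind": "HFI", "value_s": v, "cycle_s": c})
        counter_rows.append(
            {
                **meta,
                "n_fore_impacts": len(fore),
                "n_hind_impacts": len(hind),
                "n_dropped_cycles": ivs.n_dropped_cycles,
                "n_ties": ivs.n_ties,
            }
        )

        # within-trial ratios, pooled per unit
        for hoof, vals in (("fore", ivs.fhi_s), ("hind", ivs.hhi_s)):
            if vals.size >= 2:
                r = ry.ratios(vals)
                unit = (meta["horse"], meta["gait"], meta["saddle"], hoof)
                unit_ratios.setdefault(unit, {"r": []})["r"].extend(r)
                for k, rv in enumerate(r):
                    lab, center = config.windows.label(rv)
                    ratio_rows.append(
                        {**meta, "source": hoof, "k": k, "r": rv,
                         "label": lab, "center": center}
                    )
        if ivs.ihi_s.size >= 2:
            r_ihi = ry.ratios(ivs.ihi_s)
            ihi_ratios_by_gait.setdefault(meta["gait"], []).extend(r_ihi)
            for k, rv in enumerate(r_ihi):
                lab, center = config.windows.label(rv)
                ratio_rows.append(
                    {**meta, "source": "IHI", "k": k, "r": rv,
                     "label": lab, "center": center}
                )
        rp = ry.relative_phase(ivs)
        ukey = (meta["horse"], meta["gait"], meta["saddle"])
        unit_relphase.setdefault(ukey, []).extend(rp)
        for k, v in enumerate(rp):
            relphase_rows.append({**meta, "k": k, "relative_phase": v})

    iso_windows = ry.CategoryWindows(
        centers=(ry.ISOCHRONY_CENTER,),
        on_halfwidth=config.windows.on_halfwidth,
        off_bandwidth=config.windows.off_bandwidth,
    )
    summary_rows = []
    for (horse, gait, saddle, hoof), d in sorted(unit_ratios.items()):
        r = np.asarray(d["r"])
        if r.size < 2:
            continue
        s = ry.summarize_unit(
            r, horse, gait, saddle, hoof,
            windows=iso_windows, bandwidth=config.deviance_bandwidth,
        )
        summary_rows.append(dataclasses.asdict(s))

    density_rows = []
    for gait, vals in sorted(ihi_ratios_by_gait.items()):
        v = np.asarray(vals)
        grid = np.linspace(0.0, 1.0, 512)
        bw = 0.02  # display bandwidth for the ratio densities
        z = (grid[:, None] - v[None, :]) / bw
        dens = np.exp(-0.5 * z * z).sum(axis=1) / (v.size * bw * np.sqrt(2 * np.pi))
        for g, dd in zip(grid, dens):
            density_rows.append({"gait": gait, "source": "IHI", "r": g, "density": dd})

    tables = {
        "impacts": pd.DataFrame(impact_rows),
        "intervals": pd.DataFrame(interval_rows),
        "ratios": pd.DataFrame(ratio_rows),
        "relative_phase": pd.DataFrame(relphase_rows),
        "summaries": pd.DataFrame(summary_rows),
        "densities": pd.DataFrame(density_rows),
        "trial_counters": pd.DataFrame(counter_rows),
    }

    counts = tables["summaries"].rename(
        columns={"on_count": "on_count", "off_count": "off_count"}
    )
    if len(counts):
        wres = st.wilcoxon_on_off(counts)
        tables["wilcoxon"] = pd.DataFrame(
            [
                {
                    "cell": r.label, "W": r.statistic, "p": r.p_value,
                    "method": r.method, "n": r.n, "flags": "; ".join(r.flags),
                }
                for r in wres
            ]
        )
    if config.fit_models and len(tables["summaries"]):
        tables.update(_fit_protocol_models(tables, config))
    return tables


def _fit_protocol_models(tables: dict[str, pd.DataFrame], config: RunConfig) -> dict:
    """Beta mixed models for deviance, spread and relative phase + LRTs."""
    from .betamixed import shrink_to_open_unit

    out = {}
    summ = tables["summaries"].copy()
    model_rows, lrt_rows = [], []
    for resp in ("deviance_mode", "spread"):
        df = summ[["horse", "gait", "saddle", "hoof", resp]].copy()
        df["y"] = shrink_to_open_unit(df[resp].to_numpy())
        full = st.fit_beta_mixed_formula(df, "y ~ gait * hoof", "horse")
        null = st.fit_beta_mixed_formula(df, "y ~ 1", "horse")
        lrt = st.lrt_vs_null(full, null)
        for name, estv, sev in zip(full.param_names, full.params, full.se):
            model_rows.append({"model": resp, "term": name, "estimate": estv, "se": sev})
        lrt_rows.append(
            {"model": resp, "chi2": lrt.statistic, "df": lrt.df, "p": lrt.p_value,
             "aic_full": full.aic, "aic_null": null.aic,
             "converged": full.converged}
        )
    rp = tables["relative_phase"].copy()
    if len(rp):
        rp["y"] = shrink_to_open_unit(rp["relative_phase"].to_numpy())
        full = st.fit_beta_mixed_formula(rp, "y ~ gait", "horse")
        null = st.fit_beta_mixed_formula(rp, "y ~ 1", "horse")
        lrt = st.lrt_vs_null(full, null)
        for name, estv, sev in zip(full.param_names, full.params, full.se):
            model_rows.append({"model": "relative_phase", "term": name,
                               "estimate": estv, "se": sev})
        lrt_rows.append(
            {"model": "relative_phase", "chi2": lrt.statistic, "df": lrt.df,
             "p": lrt.p_value, "aic_full": full.aic, "aic_null": null.aic,
             "converged": full.converged}
        )
        contrasts = st.pairwise_contrasts(full, "gait", rp)
        out["contrasts"] = pd.DataFrame(
            [{"model": "relative_phase", "contrast": c.label, "z": c.statistic,
              "p": c.p_value, "p_holm": c.p_adjusted} for c in contrasts]
        )
    out["models"] = pd.DataFrame(model_rows)
    out["lrt"] = pd.DataFrame(lrt_rows)
    return out


def run_pipeline(config: RunConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Simulate a cohort per ``config`` and run the full analysis.

    Deterministic given ``config.seed``; when ``outdir`` is given the
    tables and a manifest (config, seed, version) are written there.
    """
    config.validate()
    trials = simulate_cohort(
        n_horses=config.n_horses,
        gaits=config.gaits,
        saddles=config.saddles,
        trials_per_cell=config.trials_per_cell,
        params=config.sim_params(),
        horse_tempo_sd=config.horse_tempo_sd,
        horse_phase_sd=config.horse_phase_sd,
        phase_overrides=config.phase_overrides or None,
    )
    tables = analyze_trials(trials, config)
    if outdir is not None:
        gio.write_results(tables, outdir, {"config": config.to_dict(), "seed": config.seed})
    return tables


def run_on_recorded(data_dir, config: RunConfig, outdir=None) -> dict[str, pd.DataFrame]:
    """Run the identical analysis on a directory of recorded trials.

    CSV trials (canonical dialect) and C3D files are accepted; unreadable
    trials are skipped with the reason recorded in the manifest.
    """
    from pathlib import Path

    data_dir = Path(data_dir)
    paths = sorted(data_dir.glob("*.csv")) + sorted(data_dir.glob("*.c3d"))
    paths = [p for p in paths if not p.name.endswith(".meta.json")]
    if not paths:
        raise ValueError(f"no trial files (*.csv, *.c3d) found in {data_dir}")
    trials, skipped = [], []
    for p in paths:
        try:
            if p.suffix == ".csv":
                rec = gio.read_trajectory_csv(p)
            else:
                rec = gio.read_trajectory_c3d(p)
            trials.append(rec.trajectory)
        except Exception as err:  # noqa: BLE001 - reason is logged, not hidden
            skipped.append({"path": str(p), "reason": str(err)})
    if not trials:
        raise ValueError(f"no readable trials in {data_dir}; skipped: {skipped}")
    tables = analyze_trials(trials, config)
    if outdir is not None:
        gio.write_results(
            tables, outdir,
            {"config": config.to_dict(), "data_dir": str(data_dir), "skipped": skipped},
        )
    return tables
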