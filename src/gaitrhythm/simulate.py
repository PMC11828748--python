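"""Synthetic motion-capture generator for quadruped gait trials.

Emulates short straight-track passes of a ridden horse recorded at
120 Hz with three sagittal-plane markers: the withers (trunk reference)
and the right fore and right hind hooves. Only footfall *timing* is
modelled faithfully — each hoof's sagittal position relative to the
withers is a smooth periodic waveform whose unique per-cycle maximum
falls exactly at the scheduled impact, which is the event the analysis
consumes. Cycle-to-cycle tempo jitter is multiplicative (log-normal) and
marker noise is additive white Gaussian.

Gait templates encode the classical footfall structure of the three
natural gaits: walk (four-beat, ipsilateral hind at 3/4 of the fore
cycle), trot (two-beat diagonal, ipsilateral hind in antiphase) and
canter (three-beat with suspension, ipsilateral hind at 3/4 of the
leading-fore cycle).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .trajectory import TrajectorySet

GAITS = ("walk", "trot", "canter")

#: realistic per-gait tempo and stride defaults for a ridden horse at
#: preferred speed: (mean cycle duration s, stride length m)
GAIT_DEFAULTS = {
    "walk": (1.10, 1.8),
    "trot": (0.70, 2.5),
    "canter": (0.60, 3.5),
}


@dataclass(frozen=True)
class GaitSpec:
    """Footfall phase structure of one gait, per unit cycle.

    ``fore_phase``/``hind_phase`` are fractions of the fore-hoof cycle at
    which the right fore / right hind hoof impacts; the fore impact
    defines phase 0.
    """

    gait: str
    beats_per_cycle: int
    fore_phase: float
    hind_phase: float
    duty_factor_fore: float
    duty_factor_hind: float
    has_suspension: bool

    def __post_init__(self):
        if not (0.0 <= self.fore_phase < 1.0 and 0.0 <= self.hind_phase < 1.0):
            raise ValueError("phases must lie in [0, 1)")
        if self.fore_phase == self.hind_phase:
            raise ValueError("fore and hind impacts cannot coincide")
        for df in (self.duty_factor_fore, self.duty_factor_hind):
            if not 0.0 < df < 1.0:
                raise ValueError("duty factors must lie in (0, 1)")


_TEMPLATES = {
    # walk: four independent beats; ipsilateral pair separated by 3/4 cycle
    "walk": GaitSpec("walk", 4, 0.0, 0.75, 0.62, 0.62, False),
    # trot: two-beat diagonal gait, ipsilateral limbs in antiphase
    "trot": GaitSpec("trot", 2, 0.0, 0.5, 0.42, 0.42, True),
    # canter: three beats + suspension; right (leading) hind at 3/4 cycle
    "canter": GaitSpec("canter", 3, 0.0, 0.75, 0.38, 0.42, True),
}


def make_gait_template(gait: str) -> GaitSpec:
    """Return the idealized footfall template for ``gait``.

    Raises
    ------
    ValueError
        If ``gait`` is not one of ``walk``, ``trot``, ``canter``.
    """
    try:
        return _TEMPLATES[gait]
    except KeyError:
        raise ValueError(
            f"unknown gait {gait!r}; expected one of {sorted(_TEMPLATES)}"
        ) from None


@dataclass(frozen=True)
class SimParams:
    """Trial-level generator parameters.

    ``jitter_cv`` is the coefficient of variation of cycle durations
    (multiplicative log-normal jitter); ``noise_sd_m`` is the SD of the
    additive Gaussian noise applied to every marker coordinate.
    """

    n_cycles: int = 5
    mean_cycle_s: float = 1.10
    jitter_cv: float = 0.02
    noise_sd_m: float = 0.005
    sampling_rate_hz: float = 120.0
    stride_length_m: float = 1.8
    seed: int = 0

    def __post_init__(self):
        if self.jitter_cv < 0:
            raise ValueError("jitter_cv must be >= 0")
        if self.noise_sd_m < 0:
            raise ValueError("noise_sd_m must be >= 0")
        if self.mean_cycle_s <= 0 or self.stride_length_m <= 0:
            raise ValueError("mean_cycle_s and stride_length_m must be positive")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")


def _cycle_durations(rng: np.random.Generator, params: SimParams) -> np.ndarray:
    """Log-normal cycle durations with mean ``mean_cycle_s`` and CV ``jitter_cv``."""
    if params.jitter_cv == 0:
        return np.full(params.n_cycles, params.mean_cycle_s)
    sigma = np.sqrt(np.log1p(params.jitter_cv**2))
    draws = np.exp(rng.normal(-0.5 * sigma**2, sigma, size=params.n_cycles))
    return params.mean_cycle_s * draws


def _warp(p: np.ndarray, duty: float) -> np.ndarray:
    # monotone time-warp g with g(0)=0, g(1)=1 and g' continuous across the
    # impact (p=0/1), so the waveform peak stays locally symmetric and
    # sub-sample peak refinement is unbiased; |alpha| < 1/(2 pi) keeps g' > 0
    alpha = float(np.clip(0.5 * (0.5 - duty), -0.14, 0.14))
    return p + alpha * np.sin(2.0 * np.pi * p)


def _limb_phase(t: np.ndarray, impacts: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cycle phase in [0,1) at each time, extrapolating edge cycles."""
    s = np.asarray(impacts, dtype=float)
    lead = s[0] - (s[1] - s[0])
    trail = s[-1] + (s[-1] - s[-2])
    ext = np.concatenate([[lead], s, [trail]])
    idx = np.clip(np.searchsorted(ext, t, side="right") - 1, 0, ext.size - 2)
    p = (t - ext[idx]) / (ext[idx + 1] - ext[idx])
    return np.clip(p, 0.0, 1.0), idx


def _hoof_channels(
    t: np.ndarray,
    impacts: np.ndarray,
    duty: float,
    amplitude_m: float,
    lift_m: float = 0.06,
) -> tuple[np.ndarray, np.ndarray]:
    """Withers-relative sagittal position and vertical lift of one hoof."""
    p, _ = _limb_phase(t, impacts)
    g = _warp(p, duty)
    x_rel = amplitude_m * np.cos(2.0 * np.pi * g)
    z = lift_m * 0.5 * (1.0 - np.cos(2.0 * np.pi * g))
    return x_rel, z


def simulate_trial(spec: GaitSpec, params: SimParams) -> TrajectorySet:
    """Simulate one straight-track pass for the ipsilateral right pair.

    The withers advances at constant mean speed with a small two-per-cycle
    vertical oscillation; each hoof's withers-relative sagittal waveform
    peaks exactly at its scheduled impact. Identical parameters and seed
    give bit-identical output.
    """
    if params.n_cycles < 3:
        raise ValueError(
            "n_cycles must be >= 3: fewer cycles yield no rhythm ratio downstream"
        )
    rng = np.random.default_rng(params.seed)
    d = _cycle_durations(rng, params)

    fore = np.concatenate([[0.0], np.cumsum(d)])  # n_cycles + 1 impacts
    hind = fore[:-1] + (spec.hind_phase - spec.fore_phase) % 1.0 * d

    dt = 1.0 / params.sampling_rate_hz
    t0 = fore[0] - 0.45 * d[0]
    t1 = fore[-1] + 0.45 * d[-1]
    t = t0 + dt * np.arange(int(np.floor((t1 - t0) / dt)) + 1)

    speed = params.stride_length_m / params.mean_cycle_s
    amp = 0.5 * params.stride_length_m
    withers_x = speed * t
    withers_z = 1.35 + 0.03 * np.cos(4.0 * np.pi * t / params.mean_cycle_s)

    fore_rel, fore_z = _hoof_channels(t, fore, spec.duty_factor_fore, amp)
    hind_rel, hind_z = _hoof_channels(t, hind, spec.duty_factor_hind, amp)

    zeros = np.zeros_like(t)
    positions = {
        "withers": np.column_stack([withers_x, zeros, withers_z]),
        "fore_hoof": np.column_stack([withers_x + 0.85 + fore_rel, zeros, 0.02 + fore_z]),
        "hind_hoof": np.column_stack([withers_x - 0.85 + hind_rel, zeros, 0.02 + hind_z]),
    }
    if params.noise_sd_m > 0:
        for name in ("withers", "fore_hoof", "hind_hoof"):
            positions[name] = positions[name] + rng.normal(
                0.0, params.noise_sd_m, size=positions[name].shape
            )

    meta = {
        "gait": spec.gait,
        "params": dataclasses.asdict(params),
        "truth": {
            "fore_impacts_s": fore.tolist(),
            "hind_impacts_s": hind.tolist(),
            "cycle_durations_s": d.tolist(),
            "hind_phase": spec.hind_phase,
        },
    }
    return TrajectorySet(params.sampling_rate_hz, t, positions, meta)


def simulate_cohort(
    n_horses: int,
    gaits=GAITS,
    saddles=("english", "side"),
    trials_per_cell: int = 1,
    params: SimParams = SimParams(),
    horse_tempo_sd: float = 0.05,
    horse_phase_sd: float = 0.005,
    phase_overrides: dict[str, float] | None = None,
    gait_defaults: dict[str, tuple[float, float]] | None = None,
) -> list[TrajectorySet]:
    """Simulate a full factorial cohort (horses x gaits x saddles x trials).

    Each horse receives a tempo multiplier (log-normal, SD
    ``horse_tempo_sd``) and an ipsilateral phase perturbation (Gaussian,
    SD ``horse_phase_sd``), drawn once and shared across that horse's
    trials. ``phase_overrides`` replaces the template hind phase per gait
    (e.g. to emulate measured rather than idealized coordination).
    Saddle is a pure metadata label with no simulated effect. The whole
    cohort is reproducible from ``params.seed``.
    """
    if n_horses < 1:
        raise ValueError("n_horses must be >= 1")
    gaits = tuple(gaits)
    saddles = tuple(saddles)
    if not gaits or not saddles:
        raise ValueError("gaits and saddles must be non-empty")
    defaults = dict(GAIT_DEFAULTS)
    if gait_defaults:
        defaults.update(gait_defaults)
    overrides = phase_overrides or {}

    master = np.random.default_rng(params.seed)
    tempo_mult = np.exp(master.normal(0.0, horse_tempo_sd, size=n_horses))
    phase_shift = master.normal(0.0, horse_phase_sd, size=n_horses)

    trials: list[TrajectorySet] = []
    for h in range(n_horses):
        horse_id = f"H{h + 1:02d}"
        for gait in gaits:
            template = make_gait_template(gait)
            mean_cycle, stride = defaults[gait]
            hind_phase = overrides.get(gait, template.hind_phase) + phase_shift[h]
            hind_phase = float(np.clip(hind_phase, 0.02, 0.98))
            spec = dataclasses.replace(template, hind_phase=hind_phase)
            for saddle in saddles:
                for k in range(trials_per_cell):
                    trial_seed = int(master.integers(0, 2**31 - 1))
                    p = dataclasses.replace(
                        params,
                        mean_cycle_s=mean_cycle * float(tempo_mult[h]),
                        stride_length_m=stride,
                        seed=trial_seed,
                    )
                    traj = simulate_trial(spec, p)
                    traj.metadata.update(
                        horse=horse_id, gait=gait, saddle=saddle, trial=k
                    )
                    trials.append(traj)
    return trials
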