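import numpy as np
import pytest

import gaitrhythm as gr


@pytest.fixture(scope="session")
def noiseless_trials():
    """One noiseless, jitter-free trial per gait (ground truth exact)."""
    out = {}
    for gait in ("walk", "trot", "canter"):
        spec = gr.make_gait_template(gait)
        params = gr.SimParams(
            n_cycles=6, mean_cycle_s=0.9, jitter_cv=0.0, noise_sd_m=0.0, seed=7
        )
        out[gait] = gr.simulate_trial(spec, params)
    return out


@pytest.fixture(scope="session")
def small_cohort_tables():
    """Analysis tables for a small (4-horse) noisy cohort, shared across tests."""
    cfg = gr.RunConfig(n_horses=4, trials_per_cell=2, seed=11)
    return gr.run_pipeline(cfg)


def brute_force_kde(values, bandwidth, n_grid=100_000):
    """Independent KDE-mode oracle: dense-grid evaluation of the Gaussian
    kernel density, tie broken toward the smallest abscissa."""
    v = np.asarray(values, float)
    grid = np.linspace(v.min() - 3 * bandwidth, v.max() + 3 * bandwidth, n_grid)
    dens = np.zeros_like(grid)
    for x in v:
        dens += np.exp(-0.5 * ((grid - x) / bandwidth) ** 2)
    dens /= v.size * bandwidth * np.sqrt(2 * np.pi)
    return grid[np.argmax(dens)]
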