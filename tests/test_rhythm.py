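"""Rhythm ratios, category windows, KDE mode, spread, relative phase."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import gaitrhythm as gr
from tests.conftest import brute_force_kde

finite_intervals = hst.lists(
    hst.floats(0.05, 50.0, allow_nan=False), min_size=2, max_size=20
)


class TestRatios:
    @pytest.mark.parametrize(
        "intervals, expected",
        [
            ([2.0, 2.0], [0.5]),
            ([1.0, 3.0], [0.25]),
            ([3.0, 1.0], [0.75]),
            ([1, 3, 1, 3], [0.25, 0.75, 0.25]),
        ],
    )
    def test_worked_examples(self, intervals, expected):
        assert np.allclose(gr.ratios(intervals), expected)

    @given(t=finite_intervals, lam=hst.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_scale_invariance(self, t, lam):
        assert np.allclose(gr.ratios(t), gr.ratios(np.asarray(t) * lam))

    @given(t=finite_intervals)
    @settings(max_examples=50, deadline=None)
    def test_complement_symmetry_under_reversal(self, t):
        """Ratios of the reversed sequence are 1 - reversed ratios."""
        r = gr.ratios(t)
        r_rev = gr.ratios(np.asarray(t)[::-1])
        assert np.allclose(r_rev, 1.0 - r[::-1])

    def test_non_positive_interval_rejected(self):
        with pytest.raises(ValueError, match="non-positive"):
            gr.ratios([1.0, 0.0, 2.0])

    def test_single_interval_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            gr.ratios([1.0])


class TestClassification:
    @pytest.mark.parametrize(
        "r, label, center",
        [
            (0.50, "on", 0.5),
            (0.444, "on", 0.5),
            (0.556, "on", 0.5),
            (0.42, "off", 0.5),
            (0.58, "off", 0.5),
            (0.35, "unclassified", None),
            (0.25, "on", 0.25),
            (0.75, "on", 0.75),
        ],
    )
    def test_window_labels(self, r, label, center):
        got_label, got_center = gr.CategoryWindows().label(r)
        assert (got_label, got_center) == (label, center)

    @given(rs=hst.lists(hst.floats(0.001, 0.999), min_size=1, max_size=50))
    @settings(max_examples=50, deadline=None)
    def test_counts_partition_the_sample(self, rs):
        counts = gr.classify(np.array(rs))
        assert counts["on"] + counts["off"] + counts["unclassified"] == len(rs)

    def test_overlapping_windows_rejected_at_construction(self):
        with pytest.raises(ValueError, match="overlap"):
            gr.CategoryWindows(centers=(0.45, 0.5))

    @pytest.mark.parametrize("gait", ["walk", "trot", "canter"])
    def test_noiseless_single_limb_ratios_all_on_integer(self, gait, noiseless_trials):
        """Noiseless single-limb cycle sequences are perfectly isochronous:
        every ratio falls in the on-integer 1:1 band, for all gaits."""
        pre = gr.preprocess_trial(noiseless_trials[gait])
        fore, hind = gr.impacts_from_trial(pre)
        for s in (fore, hind):
            r = gr.ratios(np.diff(s.times_s))
            counts = gr.classify(r, gr.CategoryWindows(centers=(0.5,)))
            assert counts["on"] == r.size


class TestKdeMode:
    def test_point_mass(self):
        mode, height = gr.kde_mode(np.full(10, 0.02))
        assert mode == pytest.approx(0.02, abs=1e-5)
        assert height > 0

    def test_bimodal_sample_against_brute_force_oracle(self):
        rng = np.random.default_rng(3)
        sample = np.concatenate([
            0.01 + 0.002 * rng.normal(size=50),
            0.05 + 0.002 * rng.normal(size=10),
        ])
        bw = 0.003
        mode, _ = gr.kde_mode(sample, bandwidth=bw)
        oracle = brute_force_kde(sample, bw)
        assert mode == pytest.approx(oracle, abs=2e-4)
        assert mode == pytest.approx(0.01, abs=0.003)

    def test_mode_invariant_under_sample_duplication(self):
        rng = np.random.default_rng(4)
        v = rng.beta(2, 5, size=40) * 0.1
        m1, _ = gr.kde_mode(v, bandwidth=0.005)
        m2, _ = gr.kde_mode(np.concatenate([v, v]), bandwidth=0.005)
        assert m1 == pytest.approx(m2, abs=1e-9)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            gr.kde_mode(np.array([]))

    def test_default_bandwidth_mode_on_deviance_scale(self):
        """At the fixed narrow bandwidth the mode lands on the densest
        deviance cluster, matching the brute-force oracle."""
        rng = np.random.default_rng(8)
        dev = np.abs(rng.normal(0, 0.004, size=120))
        mode, _ = gr.kde_mode(dev)
        assert mode == pytest.approx(brute_force_kde(dev, gr.rhythm.DEVIANCE_BANDWIDTH),
                                     abs=3e-4)


class TestSpreadAndPhase:
    def test_constant_sequence_zero_iqr(self):
        assert gr.spread(np.full(8, 0.5)) == 0.0

    def test_linear_interpolation_quartiles(self):
        """{1,2,3,4}: Q1 = 1.75, Q3 = 3.25 under the linear (type-7)
        convention, so IQR = 1.5 (brute-force arithmetic)."""
        assert gr.spread(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.5)

    @given(shift=hst.floats(-10, 10, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_iqr_translation_invariance(self, shift):
        v = np.array([0.1, 0.4, 0.45, 0.52, 0.61, 0.9])
        assert gr.spread(v + shift) == pytest.approx(gr.spread(v), abs=1e-12)

    def test_short_sample_warns_but_computes(self):
        with pytest.warns(UserWarning, match="unreliable"):
            got = gr.spread(np.array([0.1, 0.2, 0.3]))
        assert got == pytest.approx(0.1)

    def test_relative_phase_worked_examples(self):
        from gaitrhythm.events import ImpactSeries, intervals_from_impacts

        walk = intervals_from_impacts(ImpactSeries("fore", [0.0, 4.0]),
                                      ImpactSeries("hind", [3.0]))
        assert np.allclose(gr.relative_phase(walk), [0.75])

    def test_noiseless_canter_relative_phase_equals_template(self, noiseless_trials):
        pre = gr.preprocess_trial(noiseless_trials["canter"])
        fore, hind = gr.impacts_from_trial(pre)
        ivs = gr.intervals_from_impacts(fore, hind)
        spec = gr.make_gait_template("canter")
        assert np.allclose(gr.relative_phase(ivs), spec.hind_phase, atol=2e-3)


class TestDensityModes:
    def test_bimodal_ihi_density(self):
        rng = np.random.default_rng(5)
        v = np.concatenate([0.25 + 0.01 * rng.normal(size=200),
                            0.75 + 0.01 * rng.normal(size=200)])
        modes = gr.density_modes(v)
        assert len(modes) == 2
        assert modes[0] == pytest.approx(0.25, abs=0.01)
        assert modes[1] == pytest.approx(0.75, abs=0.01)


def test_deviance_median_monotone_in_jitter():
    """Median single-limb deviance is non-decreasing in the generator's
    cycle jitter (10 seeds per level)."""
    levels = [0.0, 0.01, 0.02, 0.05]
    medians = []
    for cv in levels:
        pooled = []
        for seed in range(10):
            params = gr.SimParams(n_cycles=20, jitter_cv=cv, noise_sd_m=0.003,
                                  seed=1000 + seed)
            traj = gr.simulate_trial(gr.make_gait_template("trot"), params)
            fore, hind = gr.impacts_from_trial(gr.preprocess_trial(traj))
            for s in (fore, hind):
                pooled.extend(gr.deviance(gr.ratios(np.diff(s.times_s))))
        medians.append(float(np.median(pooled)))
    assert all(a <= b + 1e-12 for a, b in zip(medians, medians[1:])), medians
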