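"""Impact detection and interval derivation contracts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as hst

import gaitrhythm as gr
from gaitrhythm.events import ImpactSeries, detect_impacts, intervals_from_impacts


class TestDetectImpacts:
    @pytest.mark.parametrize("gait", ["walk", "trot", "canter"])
    def test_noiseless_trial_recovers_schedule_within_one_sample(self, gait, noiseless_trials):
        traj = noiseless_trials[gait]
        pre = gr.preprocess_trial(traj)
        fore, hind = gr.impacts_from_trial(pre)
        truth = traj.metadata["truth"]
        assert np.allclose(fore.times_s, truth["fore_impacts_s"], atol=1 / 120)
        assert np.allclose(hind.times_s, truth["hind_impacts_s"], atol=1 / 120)

    def test_pure_sine_peaks_spaced_one_period(self):
        fs, period = 120.0, 0.8
        t = np.arange(int(6 * period * fs)) / fs
        y = np.cos(2 * np.pi * t / period)
        s = detect_impacts(t, y)
        assert np.allclose(np.diff(s.times_s), period, atol=1 / fs)

    def test_one_sample_spike_rejected(self):
        """A tall single-sample spike between true peaks is rejected by
        the width rule (spikes are one sample wide at half prominence)."""
        fs, period = 120.0, 1.0
        t = np.arange(int(5 * period * fs)) / fs
        y = np.cos(2 * np.pi * t / period)
        spiky = y.copy()
        i = np.argmin(np.abs(t - 1.45))  # near a trough, 0.45 s from a peak
        spiky[i] += 2.5
        clean = detect_impacts(t, y)
        got = detect_impacts(t, spiky)
        assert len(got) == len(clean)
        assert np.allclose(got.times_s, clean.times_s, atol=2 / fs)

    def test_flat_signal_rejected(self):
        t = np.arange(100) / 120.0
        with pytest.raises(ValueError, match="insufficient cycles"):
            detect_impacts(t, np.ones_like(t))

    def test_too_few_peaks_rejected(self):
        t = np.arange(240) / 120.0
        y = np.cos(2 * np.pi * t / 1.5)  # ~1.3 cycles
        with pytest.raises(ValueError, match="insufficient cycles"):
            detect_impacts(t, y)


class TestIntervals:
    def test_four_beat_worked_example(self):
        """Fore at {0,4,8}, hind at {3,7}: the idealized four-beat cycle
        gives alternating inter-hoof intervals of 3 and 1 units."""
        fore = ImpactSeries("fore", [0.0, 4.0, 8.0])
        hind = ImpactSeries("hind", [3.0, 7.0])
        ivs = intervals_from_impacts(fore, hind)
        assert np.allclose(ivs.fhi_s, [4.0, 4.0])
        assert np.allclose(ivs.hhi_s, [4.0])
        assert np.allclose(ivs.ihi_s, [3.0, 1.0, 3.0, 1.0])
        assert np.allclose(ivs.hfi_s, [3.0, 3.0])
        assert np.allclose(gr.relative_phase(ivs), [0.75, 0.75])

    def test_ideal_trot_cycle(self):
        ivs = intervals_from_impacts(ImpactSeries("fore", [0.0, 2.0]),
                                     ImpactSeries("hind", [1.0]))
        assert np.allclose(ivs.ihi_s, [1.0, 1.0])
        assert np.allclose(ivs.hfi_s, [1.0])
        assert np.allclose(gr.relative_phase(ivs), [0.5])

    def test_single_limb_reused_as_both_gives_empty_hfi(self):
        s = ImpactSeries("fore", [0.0, 1.0, 2.0, 3.0])
        ivs = intervals_from_impacts(s, ImpactSeries("hind", s.times_s))
        assert ivs.hfi_s.size == 0
        assert ivs.n_ties == 4

    def test_zero_overlap_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            intervals_from_impacts(ImpactSeries("fore", [0.0, 1.0]),
                                   ImpactSeries("hind", [5.0, 6.0]))

    def test_near_simultaneous_impacts_excluded_as_ties(self):
        fore = ImpactSeries("fore", [0.0, 4.0, 8.0])
        hind = ImpactSeries("hind", [4.003, 7.0])  # within 1/120 s of a fore
        ivs = intervals_from_impacts(fore, hind)
        assert ivs.n_ties == 1
        assert not np.any(ivs.ihi_s < 1 / 120)

    @given(shift=hst.floats(-100.0, 100.0, allow_nan=False))
    @settings(max_examples=30, deadline=None)
    def test_time_shift_invariance(self, shift):
        """Adding a constant to all impact times changes no interval."""
        fore = np.array([0.0, 1.1, 2.1, 3.3])
        hind = np.array([0.8, 1.9, 2.9])
        a = intervals_from_impacts(ImpactSeries("fore", fore),
                                   ImpactSeries("hind", hind))
        b = intervals_from_impacts(ImpactSeries("fore", fore + shift),
                                   ImpactSeries("hind", hind + shift))
        assert np.allclose(a.fhi_s, b.fhi_s)
        assert np.allclose(a.ihi_s, b.ihi_s)
        assert np.allclose(a.hfi_s, b.hfi_s)

    def test_ihi_sums_to_fhi_within_each_cycle(self, noiseless_trials):
        """The merged-train intervals inside one fore cycle sum to that FHI."""
        pre = gr.preprocess_trial(noiseless_trials["walk"])
        fore, hind = gr.impacts_from_trial(pre)
        ivs = intervals_from_impacts(fore, hind)
        f = fore.times_s
        for k in range(f.size - 1):
            inside = (hind.times_s > f[k]) & (hind.times_s < f[k + 1])
            pieces = np.diff(np.sort(np.concatenate(
                [[f[k]], hind.times_s[inside], [f[k + 1]]])))
            assert np.sum(pieces) == pytest.approx(ivs.fhi_s[k], abs=1e-12)

    def test_interval_cv_tracks_generator_jitter(self):
        """Detected FHI coefficient of variation reproduces jitter_cv."""
        params = gr.SimParams(n_cycles=60, jitter_cv=0.03, noise_sd_m=0.0, seed=21)
        traj = gr.simulate_trial(gr.make_gait_template("trot"), params)
        fore, _ = gr.impacts_from_trial(gr.preprocess_trial(traj))
        fhi = np.diff(fore.times_s)
        cv = fhi.std(ddof=1) / fhi.mean()
        assert cv == pytest.approx(0.03, abs=0.01)
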