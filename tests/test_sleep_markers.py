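"""Nap hypnograms, sleep-EEG spectra and the physiological markers."""

import numpy as np
import pytest
from scipy.signal import periodogram

import circabold as cb
from circabold.markers import (artifact_mask, circadian_strength,
                               delta_rebound, flag_low_outliers,
                               nrem_delta_power, rem_sleepiness_correlation)
from circabold.sleep import (DELTA_BAND, EEG_FS, EPOCH_S, NAP_EPOCHS,
                             HypnoCoeffs, Hypnogram, SleepEEGSpectra,
                             simulate_hypnograms, simulate_sleep_eeg)


def _make_hypno(nap_index, stages, window=(0, 4 / 3)):
    return Hypnogram(subject_id="s", nap_index=nap_index, window_h=window,
                     stages=np.asarray(stages, dtype=str))


def _spectra_from_signal(x_epochs, stages):
    freqs, psd = periodogram(np.asarray(x_epochs), fs=EEG_FS, window="hann",
                             detrend="constant", axis=-1)
    return SleepEEGSpectra(subject_id="s", night="baseline", freqs=freqs,
                           psd=psd, stages=np.asarray(stages, dtype=str))


class TestHypnograms:
    def test_sd_schedule_rejected(self, default_params, sd_sched):
        with pytest.raises(ValueError):
            simulate_hypnograms(default_params, sd_sched, 1)

    def test_structure(self, default_params, np_sched):
        hyps = simulate_hypnograms(default_params, np_sched, 1)
        assert len(hyps) == 10
        for h in hyps:
            assert h.stages.shape == (NAP_EPOCHS,)
            assert set(h.stages) <= {"wake", "N1", "N2", "N3", "N4", "REM"}

    def test_no_circadian_modulation_flattens_rem(self, np_sched):
        p = cb.SubjectParams(subject_id="s", circ_amp=0.0)
        co = HypnoCoeffs(rem_sleepiness_gain=0.0, rem_noise_sd=0.0,
                         wake_s_gain=0.0, wake_time_gain=0.0)
        fracs = np.zeros(10)
        for seed in range(40):
            hyps = simulate_hypnograms(p, np_sched, seed, coeffs=co)
            fracs += [h.fraction("REM") for h in hyps]
        fracs /= 40
        assert fracs.max() - fracs.min() < 0.06

    def test_rem_propensity_peaks_in_late_night_naps(self, default_params,
                                                     np_sched):
        """The circadian REM bump, evaluated on the nap grid, is maximal for
        a nap starting between 20 and 29 h elapsed."""
        from circabold.sleep import _bump
        co = HypnoCoeffs()
        mids = np.array([0.5 * (a + b) for a, b in np_sched.nap_windows])
        idx = int(np.argmax(_bump(mids, co.rem_center_h, co.rem_kappa)))
        assert 20 <= np_sched.nap_windows[idx][0] <= 29

    def test_empirical_rem_peak_and_evening_wake(self, np_sched):
        rem = np.zeros(10)
        wake = np.zeros(10)
        p = cb.SubjectParams(subject_id="s")
        for seed in range(30):
            hyps = simulate_hypnograms(p, np_sched, seed)
            rem += [h.fraction("REM") for h in hyps]
            wake += [h.wake_percent() for h in hyps]
        assert 20 <= np_sched.nap_windows[int(np.argmax(rem))][0] <= 29
        assert int(np.argmax(wake)) == np_sched.evening_nap_index()


class TestCompositeScore:
    def test_no_rem_fully_slept_evening_is_zero(self, np_sched):
        hyps = [_make_hypno(i, ["N2"] * NAP_EPOCHS) for i in range(10)]
        assert circadian_strength(hyps, np_sched) == 0.0

    def test_rem_peak_plus_evening_wake(self, np_sched):
        hyps = []
        ev = np_sched.evening_nap_index()
        for i in range(10):
            if i == ev:
                stages = ["wake"] * 80 + ["N2"] * 80       # 50% wake
            elif i == 5:
                stages = ["REM"] * 40 + ["N2"] * 120       # REM 25% of sleep
            else:
                stages = ["N2"] * NAP_EPOCHS
            hyps.append(_make_hypno(i, stages))
        assert circadian_strength(hyps, np_sched) == pytest.approx(75.0)

    def test_invariant_to_non_evening_nap_order(self, np_sched):
        ev = np_sched.evening_nap_index()
        stages = {i: ["N2"] * NAP_EPOCHS for i in range(10)}
        stages[5] = ["REM"] * 30 + ["N2"] * 130
        stages[7] = ["REM"] * 20 + ["N2"] * 140
        hyps = [_make_hypno(i, s) for i, s in stages.items()]
        score1 = circadian_strength(hyps, np_sched)
        score2 = circadian_strength(list(reversed(hyps)), np_sched)
        assert score1 == score2

    def test_missing_evening_nap_errors(self, np_sched):
        ev = np_sched.evening_nap_index()
        hyps = [_make_hypno(i, ["N2"] * NAP_EPOCHS)
                for i in range(10) if i != ev]
        with pytest.raises(ValueError):
            circadian_strength(hyps, np_sched)


class TestDeltaPower:
    def test_single_tone_matches_closed_form(self):
        t = np.arange(int(EPOCH_S * EEG_FS)) / EEG_FS
        a = 17.0
        x = a * np.cos(2 * np.pi * 2.0 * t + 1.1)
        sp = _spectra_from_signal([x], ["N2"])
        assert nrem_delta_power(sp) == pytest.approx(a ** 2 / 2, rel=1e-10)

    def test_power_scales_quadratically(self):
        t = np.arange(int(EPOCH_S * EEG_FS)) / EEG_FS
        x = np.cos(2 * np.pi * 1.5 * t)
        p1 = nrem_delta_power(_spectra_from_signal([x], ["N3"]))
        p3 = nrem_delta_power(_spectra_from_signal([3 * x], ["N3"]))
        assert p3 == pytest.approx(9 * p1, rel=1e-10)

    def test_epoch_order_invariance(self, rng):
        xs = rng.normal(size=(6, int(EPOCH_S * EEG_FS)))
        stages = ["N1", "N2", "N3", "N2", "N4", "N2"]
        p1 = nrem_delta_power(_spectra_from_signal(xs, stages))
        p2 = nrem_delta_power(_spectra_from_signal(xs[::-1], stages[::-1]))
        assert p1 == pytest.approx(p2)

    def test_all_rem_errors(self, rng):
        xs = rng.normal(size=(4, int(EPOCH_S * EEG_FS)))
        with pytest.raises(ValueError):
            nrem_delta_power(_spectra_from_signal(xs, ["REM"] * 4))

    def test_white_noise_band_share(self, rng):
        xs = rng.normal(0, 30, size=(300, int(EPOCH_S * EEG_FS)))
        sp = _spectra_from_signal(xs, ["N2"] * 300)
        band = nrem_delta_power(sp)
        total = sp.epoch_total_power().mean()
        bw = DELTA_BAND[1] - DELTA_BAND[0] + 1 / EPOCH_S
        assert band / total == pytest.approx(bw / (EEG_FS / 2), rel=0.05)


class TestRebound:
    def test_difference(self):
        assert delta_rebound(100.0, 160.0) == 60.0
        assert delta_rebound(95.5, 95.5) == 0.0

    def test_zero_planted_rebound_recovers_zero(self, default_params):
        p = cb.SubjectParams(subject_id="s", delta_rebound_true=0.0)
        b = nrem_delta_power(simulate_sleep_eeg(p, "baseline", 3))
        r = nrem_delta_power(simulate_sleep_eeg(p, "recovery", 4))
        assert abs(delta_rebound(b, r)) < 12.0

    def test_unknown_night_rejected(self, default_params):
        with pytest.raises(ValueError):
            simulate_sleep_eeg(default_params, "nap", 1)

    def test_artifact_epochs_flagged(self, default_params):
        sp = simulate_sleep_eeg(default_params, "baseline", 8)
        frac = artifact_mask(sp).mean()
        assert 0.005 < frac < 0.04


class TestOutlierRule:
    def test_worked_example(self):
        flags = flag_low_outliers([1.0, 1.1, 1.2, 1.3, -5.0])
        assert list(flags) == [False, False, False, False, True]

    def test_identical_values_none_flagged(self):
        assert not flag_low_outliers([2.0] * 6).any()

    def test_minimum_sample_size(self):
        with pytest.raises(ValueError):
            flag_low_outliers([1, 2, 3, 4])


class TestSpearman:
    def test_perfectly_monotone(self):
        r, p = rem_sleepiness_correlation([1, 2, 3, 4, 5], [2, 4, 5, 7, 9])
        assert r == pytest.approx(1.0)

    def test_anti_monotone(self):
        r, _ = rem_sleepiness_correlation([1, 2, 3, 4, 5], [9, 7, 5, 4, 2])
        assert r == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            rem_sleepiness_correlation([1, 1, 1, 1, 1], [1, 2, 3, 4, 5])
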