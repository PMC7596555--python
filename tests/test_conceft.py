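"""Hermite windows, synchrosqueezing, ConceFT and the 28 band features."""

import numpy as np
import pytest
from scipy import signal as sps

from pursuitspect.conceft import (
    BAND_EDGES,
    average_trials,
    band_power_fraction,
    conceft_transform,
    default_freq_grid,
    extract_features,
    hermite_windows,
    relative_power_spectrum,
    sst,
)
from pursuitspect.errors import (
    DegenerateSignalError,
    EmptySignalError,
    InvalidParameterError,
)


def tone(freq, fs=60.0, seconds=15.0, amp=1.0):
    t = np.arange(int(seconds * fs)) / fs
    return amp * np.sin(2 * np.pi * freq * t)


def periodogram_fraction(x, fs, lo=1.5, hi=2.5, total=(0.1, 8.0)):
    f, P = sps.periodogram(x, fs=fs)
    band = P[(f >= lo) & (f < hi)].sum()
    tot = P[(f >= total[0]) & (f <= total[1])].sum()
    return band / tot


class TestHermiteWindows:
    def test_family_is_orthonormal(self):
        W, _ = hermite_windows(4, 301)
        gram = W.T @ W
        assert np.abs(gram - np.eye(4)).max() < 1e-8

    def test_first_window_is_symmetric_unimodal(self):
        W, _ = hermite_windows(1, 201)
        w = W[:, 0]
        assert np.allclose(w, w[::-1], atol=1e-12)
        assert np.argmax(w) == 100
        assert (np.diff(w[:101]) >= -1e-12).all()

    def test_second_window_is_odd(self):
        W, _ = hermite_windows(2, 201)
        w = W[:, 1]
        assert np.allclose(w, -w[::-1], atol=1e-10)

    def test_invalid_parameters(self):
        with pytest.raises(InvalidParameterError):
            hermite_windows(5, 3)
        with pytest.raises(InvalidParameterError):
            hermite_windows(1, 200)  # even length


class TestSST:
    def test_tone_ridge_tracks_instantaneous_frequency(self):
        x = tone(2.2, fs=240.0)
        tfr = sst(x, 240.0, hop=10)
        ridge = tfr.freq_bins_hz[np.argmax(tfr.power, axis=0)]
        interior = (tfr.frame_times_s > 2) & (tfr.frame_times_s < 13)
        hit = (ridge[interior] >= 2.1) & (ridge[interior] <= 2.3)
        assert hit.mean() > 0.95

    def test_two_tones_give_two_ridges(self):
        x = tone(2.0) + tone(5.0)
        tfr = sst(x, 60.0, hop=5)
        spectrum = tfr.power.sum(axis=1)
        peaks = []
        for lo, hi in [(1.5, 2.5), (4.5, 5.5)]:
            sel = (tfr.freq_bins_hz >= lo) & (tfr.freq_bins_hz < hi)
            peaks.append(tfr.freq_bins_hz[sel][np.argmax(spectrum[sel])])
        assert abs(peaks[0] - 2.0) < 0.15 and abs(peaks[1] - 5.0) < 0.15
        # both ridges persist across interior frames
        for lo, hi in [(1.8, 2.2), (4.8, 5.2)]:
            sel = (tfr.freq_bins_hz >= lo) & (tfr.freq_bins_hz <= hi)
            frames = tfr.power[sel].sum(axis=0)
            assert (frames[20:-20] > 0).mean() > 0.95

    def test_zero_signal_gives_zero_power(self):
        tfr = sst(np.zeros(600), 60.0, hop=5)
        assert tfr.power.sum() == 0.0

    def test_grid_beyond_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            sst(np.ones(600), 12.0, freq_grid=default_freq_grid())


class TestConceFT:
    def test_single_projection_single_window_degenerates_to_sst(self):
        x = tone(2.2)
        W, dW = hermite_windows(1, 121)
        ref = sst(x, 60.0, window=W[:, 0], dwindow=dW[:, 0], hop=5)
        got = conceft_transform(
            x, 60.0, n_windows=1, n_projections=1, seed=9, window_s=2.0, hop=5
        )
        assert np.abs(ref.power - got.power).max() < 1e-9 * ref.power.max()

    def test_ridge_location_matches_sst(self):
        x = tone(2.2)
        tfr = conceft_transform(x, 60.0, n_projections=30, seed=0, hop=5)
        ridge = tfr.freq_bins_hz[np.argmax(tfr.power, axis=0)]
        interior = slice(20, -20)
        assert ((ridge[interior] >= 2.1) & (ridge[interior] <= 2.3)).mean() > 0.95

    def test_features_stable_across_seeds(self):
        x = tone(2.2)
        fa = extract_features(conceft_transform(x, 60.0, n_projections=50, seed=1, hop=5))
        fb = extract_features(conceft_transform(x, 60.0, n_projections=50, seed=2, hop=5))
        rel = np.abs(fa.vector() - fb.vector()).sum() / np.abs(fa.vector()).sum()
        assert rel < 0.02

    def test_deterministic_given_seed(self):
        x = tone(3.3)
        a = conceft_transform(x, 60.0, seed=7, hop=5)
        b = conceft_transform(x, 60.0, seed=7, hop=5)
        assert np.array_equal(a.power, b.power)


class TestExtractFeatures:
    def test_band_edges_are_14_half_hz_segments(self):
        assert len(BAND_EDGES) == 14
        assert BAND_EDGES[0] == (1.0, 1.5)
        assert BAND_EDGES[-1] == (7.5, 8.0)
        widths = {round(hi - lo, 9) for lo, hi in BAND_EDGES}
        assert widths == {0.5}

    def test_normalizations_sum_to_one(self):
        tfr = conceft_transform(tone(2.2) + 0.3 * tone(5.0), 60.0, seed=0, hop=5)
        f = extract_features(tfr)
        assert f.sum_norm.sum() == pytest.approx(1.0, abs=1e-9)
        assert f.var_norm.sum() == pytest.approx(1.0, abs=1e-9)
        assert (f.sum_norm >= 0).all() and (f.var_norm >= 0).all()

    def test_tone_lands_in_its_band(self):
        tfr = conceft_transform(tone(2.2), 60.0, seed=0, hop=5)
        f = extract_features(tfr)
        assert np.argmax(f.sum_norm) == 2  # the 2-2.5 Hz band

    def test_amplitude_invariance(self):
        x = tone(2.2) + 0.2 * tone(4.4)
        fa = extract_features(conceft_transform(x, 60.0, seed=3, hop=5))
        fb = extract_features(conceft_transform(7.7 * x, 60.0, seed=3, hop=5))
        np.testing.assert_allclose(fa.vector(), fb.vector(), atol=1e-9)

    def test_masked_frames_are_truly_ignored(self):
        x = tone(2.2)
        mask = np.zeros(len(x), np.int8)
        mask[300:400] = 2  # blink-interpolated run
        ref = conceft_transform(x, 60.0, seed=0, hop=5, sample_mask=mask)
        x_amp = x.copy()
        x_amp[300:400] *= 10.0
        got = conceft_transform(x_amp, 60.0, seed=0, hop=5, sample_mask=mask)
        fa, fb = extract_features(ref).vector(), extract_features(got).vector()
        assert np.abs(fa - fb).sum() / np.abs(fa).sum() < 0.01

    def test_all_frames_masked_raises(self):
        x = tone(2.2)
        with pytest.raises(EmptySignalError):
            extract_features(
                conceft_transform(x, 60.0, seed=0, hop=5, sample_mask=np.ones(len(x), np.int8))
            )

    def test_zero_power_raises(self):
        tfr = conceft_transform(np.zeros(600), 60.0, seed=0, hop=5)
        with pytest.raises(DegenerateSignalError):
            extract_features(tfr)


class TestAverageTrials:
    def test_identical_trials_average_to_themselves(self):
        tfr = conceft_transform(tone(2.2), 60.0, seed=0, hop=5)
        f = extract_features(tfr, "T1")
        g = extract_features(tfr, "T2")
        avg = average_trials(f, g)
        np.testing.assert_allclose(avg.vector(), f.vector())
        assert avg.trial_id == "T1+T2"

    def test_disjoint_mass_splits_evenly(self):
        from pursuitspect.conceft import ConceFTFeatures

        a = np.zeros(14)
        a[3] = 1.0
        b = np.zeros(14)
        b[4] = 1.0
        avg = average_trials(ConceFTFeatures(a, a, "T1"), ConceFTFeatures(b, b, "T2"))
        assert avg.sum_norm[3] == avg.sum_norm[4] == 0.5
        assert avg.sum_norm.sum() == pytest.approx(1.0)


class TestBandPowerFraction:
    def test_tone_in_band_dominates(self):
        tfr = conceft_transform(tone(2.0), 60.0, seed=0, hop=5)
        assert band_power_fraction(tfr, 1.5, 2.5) > 0.8

    def test_tone_outside_band_is_small(self):
        tfr = conceft_transform(tone(5.0), 60.0, seed=0, hop=5)
        assert band_power_fraction(tfr, 1.5, 2.5) < 0.1

    def test_whole_range_fraction_is_one(self):
        tfr = conceft_transform(tone(3.0), 60.0, seed=0, hop=5)
        assert band_power_fraction(tfr, 0.1, 8.0) == pytest.approx(1.0)

    def test_matches_periodogram_oracle(self):
        x = tone(2.2)
        tfr = conceft_transform(x, 60.0, seed=0, hop=5)
        ours = band_power_fraction(tfr, 1.5, 2.5)
        oracle = periodogram_fraction(x, 60.0)
        assert abs(ours - oracle) < 0.05

    def test_relative_power_spectrum_sums_to_one(self):
        tfr = conceft_transform(tone(2.2), 60.0, seed=0, hop=5)
        p = relative_power_spectrum(tfr)
        assert p.sum() == pytest.approx(1.0)
        assert len(p) == len(tfr.freq_bins_hz)
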