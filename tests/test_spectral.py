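"""Filtering, Morlet band power, ROI summary and window conventions."""

import numpy as np
import pytest

from thetalink.dataio import DEFAULT_BANDS, ROIDefinition, ConfigError
from thetalink.spectral import (
    bandpass_filter,
    fir_bandpass,
    extract_phase,
    morlet_band_power,
    roi_timecourse_pca_flip,
    lateralize,
    mean_window_power,
    window_mask,
    check_edge_margin,
)

SRATE = 512.0
T = np.arange(round(3.5 * SRATE) + 1) / SRATE - 1.0  # -1.0 .. 2.5 s


def _tone(freq, amp=1.0):
    return amp * np.cos(2 * np.pi * freq * (T + 1.0))


class TestFIRBandpass:
    def test_passband_tone_preserved(self):
        y = bandpass_filter(_tone(5.0)[None], 3, 7, SRATE)[0]
        c = T.size // 2
        assert np.abs(y[c - 256:c + 256]).max() == pytest.approx(1.0, abs=0.05)

    def test_stopband_tone_attenuated(self):
        y = bandpass_filter(_tone(20.0)[None], 3, 7, SRATE)[0]
        c = T.size // 2
        assert np.abs(y[c - 256:c + 256]).max() < 0.05

    def test_zeros_in_zeros_out(self):
        y = bandpass_filter(np.zeros((2, T.size)), 3, 7, SRATE)
        assert np.all(y == 0)

    def test_epoch_shorter_than_filter_rejected(self):
        with pytest.raises(ConfigError, match="padding"):
            bandpass_filter(np.zeros((1, 100)), 3, 7, SRATE)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigError):
            fir_bandpass(3, 7, srate=16.0)

    def test_hilbert_phase_advances_at_carrier_rate(self):
        """Filter + Hilbert phase of cos(2 pi f t) has slope 2 pi f (1%)."""
        ph = extract_phase(bandpass_filter(_tone(5.0)[None], 3, 7, SRATE))[0]
        c = T.size // 2
        sl = np.unwrap(ph[c - 128:c + 128])
        slope = np.polyfit(T[c - 128:c + 128], sl, 1)[0]
        assert slope == pytest.approx(2 * np.pi * 5.0, rel=0.01)


class TestMorletBandPower:
    def test_amplitude_doubling_quadruples_power(self):
        band = DEFAULT_BANDS["theta"]
        sig = np.stack([_tone(5.0, 1.0), _tone(5.0, 2.0)])
        bp = morlet_band_power(sig, SRATE, band, tmin=-1.0, out_srate=128.0)
        c = bp.values.shape[1] // 2
        assert bp.values[1, c] / bp.values[0, c] == pytest.approx(4.0,
                                                                  rel=0.02)

    def test_zero_signal_zero_power(self):
        band = DEFAULT_BANDS["alpha"]
        bp = morlet_band_power(np.zeros((2, T.size)), SRATE, band, -1.0)
        assert np.allclose(bp.values, 0.0)

    def test_power_nonnegative_on_noise(self, rng):
        band = DEFAULT_BANDS["beta"]
        bp = morlet_band_power(rng.standard_normal((3, T.size)), SRATE, band,
                               -1.0, out_srate=128.0)
        assert (bp.values >= 0).all()

    def test_translation_covariance(self, rng):
        """Shifting the input in time shifts the power trace identically
        (checked away from the edges, on the undecimated grid)."""
        band = DEFAULT_BANDS["theta"]
        srate = 128.0
        n = round(3.5 * srate) + 1
        x = np.zeros((1, n))
        burst = np.cos(2 * np.pi * 5 * np.arange(int(srate)) / srate)
        burst *= np.hanning(burst.size)
        x[0, 150:150 + burst.size] = burst
        shift = 16
        x2 = np.roll(x, shift, axis=1)
        p1 = morlet_band_power(x, srate, band, -1.0, out_srate=srate).values[0]
        p2 = morlet_band_power(x2, srate, band, -1.0, out_srate=srate).values[0]
        sl = slice(100, 350)
        assert np.allclose(p2[sl.start + shift:sl.stop + shift], p1[sl],
                           rtol=1e-6, atol=1e-9)

    def test_decimation_preserves_band_limited_power(self):
        """128 Hz grid samples agree with the undecimated trace for a
        smooth band-limited power time course."""
        band = DEFAULT_BANDS["theta"]
        sig = _tone(5.0)[None] * (1.0 + 0.3 * np.sin(2 * np.pi * 0.5 * T))[None]
        full = morlet_band_power(sig, SRATE, band, -1.0, out_srate=SRATE)
        dec = morlet_band_power(sig, SRATE, band, -1.0, out_srate=128.0)
        sl = slice(40, dec.values.shape[1] - 40)
        assert np.allclose(dec.values[0, sl], full.values[0, ::4][sl],
                           rtol=0.02)

    def test_epoch_shorter_than_wavelet_rejected(self):
        band = DEFAULT_BANDS["theta"]
        with pytest.raises(ConfigError):
            morlet_band_power(np.zeros((1, 100)), 128.0, band, 0.0)

    def test_edge_margin_guard(self):
        band = DEFAULT_BANDS["theta"]  # half-length 0.5 s
        check_edge_margin(-1.0, 2.5, band, (0.0, 1.8))
        with pytest.raises(ConfigError):
            check_edge_margin(-0.2, 2.5, band, (0.0, 1.8))


class TestPcaFlip:
    def test_identical_sources_recover_signal(self):
        s = np.sin(2 * np.pi * 3 * T)[:512]
        data = np.tile(s, (1, 3, 1))
        roi = ROIDefinition("r", [0, 1, 2], [1, 1, 1], "left")
        tc = roi_timecourse_pca_flip(data, roi)[0]
        r = np.corrcoef(tc, s)[0, 1]
        assert r == pytest.approx(1.0, abs=1e-10)
        assert np.sqrt((tc**2).mean()) == pytest.approx(
            np.sqrt((s**2).mean()), rel=1e-9)

    def test_orientation_signs_fix_polarity(self):
        s = np.sin(2 * np.pi * 3 * T)[:512]
        data = np.stack([s, -s])[None]
        roi = ROIDefinition("r", [0, 1], [1, -1], "left")
        tc = roi_timecourse_pca_flip(data, roi)[0]
        assert np.corrcoef(tc, s)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_common_signal_recovered_from_noise(self, rng):
        s = np.sin(2 * np.pi * 4 * np.arange(1024) / 256.0)
        data = (s[None, None, :]
                + rng.standard_normal((1, 20, 1024)))  # SNR ~ 1 per source
        roi = ROIDefinition("r", list(range(20)), [1] * 20, "left")
        tc = roi_timecourse_pca_flip(data, roi)[0]
        assert np.corrcoef(tc, s)[0, 1] > 0.9

    def test_all_zero_trial_warns_and_zeroes(self):
        roi = ROIDefinition("r", [0, 1], [1, 1], "left")
        with pytest.warns(RuntimeWarning):
            tc = roi_timecourse_pca_flip(np.zeros((1, 2, 64)), roi)
        assert np.all(tc == 0)

    def test_single_source_rejected(self):
        roi = ROIDefinition("r", [0], [1], "left")
        with pytest.raises(ConfigError):
            roi_timecourse_pca_flip(np.zeros((1, 1, 64)), roi)


class TestLateralize:
    def test_left_cue_maps_right_roi_contralateral(self, rng):
        left = rng.standard_normal((4, 10))
        right = rng.standard_normal((4, 10))
        sides = np.array(["left", "right", "left", "right"])
        contra, ipsi = lateralize(left, right, sides)
        assert np.array_equal(contra[0], right[0])
        assert np.array_equal(ipsi[1], right[1])

    def test_identical_hemispheres_cancel(self, rng):
        x = rng.standard_normal((3, 8))
        contra, ipsi = lateralize(x, x, np.array(["left"] * 3))
        assert np.array_equal(contra, ipsi)

    def test_swapping_labels_exchanges_outputs(self, rng):
        left = rng.standard_normal((4, 10))
        right = rng.standard_normal((4, 10))
        sides = np.array(["left", "right", "right", "left"])
        flipped = np.where(sides == "left", "right", "left")
        c1, i1 = lateralize(left, right, sides)
        c2, i2 = lateralize(left, right, flipped)
        assert np.array_equal(c1, i2) and np.array_equal(i1, c2)

    def test_missing_label_rejected(self, rng):
        with pytest.raises(ValueError):
            lateralize(np.zeros((2, 4)), np.zeros((2, 4)),
                       np.array(["left", "??"]))


class TestWindows:
    def test_constant_power_mean(self):
        times = np.arange(100) / 100.0
        vals = np.full((3, 100), 2.5)
        out = mean_window_power(vals, times, (0.2, 0.4))
        assert np.allclose(out, 2.5)

    def test_window_sample_count_on_power_grid(self):
        """[0.355, 0.985] on the 128 Hz grid starting at -1.0 s holds 81
        samples under the closed-interval convention."""
        times = -1.0 + np.arange(449) / 128.0
        assert window_mask(times, (0.355, 0.985)).sum() == 81

    def test_linear_ramp_gives_midpoint(self):
        times = np.arange(101) / 100.0
        vals = times[None, :].repeat(2, axis=0)
        out = mean_window_power(vals, times, (0.2, 0.6))
        assert np.allclose(out, 0.4)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            mean_window_power(np.zeros((1, 10)), np.arange(10.0), (20.0, 21.0))
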