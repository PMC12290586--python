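"""Waveform -> RV/HR/PWA extraction: windowing, filtering, beat detection."""

import numpy as np
import pytest

from vigilcov import (bandpass_ppg, detect_peaks, extract_autonomic, hr_per_tr,
                      ibi_clean, lowpass_015, windowed_std)
from vigilcov.errors import BoundaryError, ParameterError, QualityError
from vigilcov.physio import MIN_PEAK_SPACING_S
from vigilcov.synthetic import PhysioRecording, _ppg_pulse_kernel


# ------------------------------------------------------------- windowed std

class TestWindowedStd:
    def test_constant_signal_gives_zero(self):
        t = np.arange(0, 100, 0.01)
        out = windowed_std(np.full(t.size, 3.7), t, np.array([10.0, 50.0]))
        assert np.allclose(out, 0.0)

    def test_sine_gives_amplitude_over_sqrt2(self):
        # 1-Hz unit sine: each 6-s window spans whole cycles -> std = 1/sqrt(2)
        t = np.arange(0, 60, 0.001)
        sig = np.sin(2 * np.pi * t)
        out = windowed_std(sig, t, np.array([10.0, 30.0, 50.0]))
        assert np.allclose(out, 1 / np.sqrt(2), atol=0.01)

    def test_two_point_window_population_std(self):
        t = np.array([-1.0, 0.0, 1.0, 2.0])
        sig = np.array([5.0, 0.0, 2.0, 5.0])
        out = windowed_std(sig, t, np.array([0.5]), half_width_s=0.7)
        assert out[0] == pytest.approx(1.0)     # population std of {0, 2}

    def test_out_of_bounds_window_raises(self):
        t = np.arange(0, 10, 0.01)
        with pytest.raises(BoundaryError, match="TR 0"):
            windowed_std(np.zeros(t.size), t, np.array([1.0]))

    def test_scale_linearity(self, rng):
        t = np.arange(0, 30, 0.01)
        sig = rng.standard_normal(t.size)
        centers = np.array([5.0, 15.0, 25.0])
        assert np.allclose(windowed_std(3 * sig, t, centers),
                           3 * windowed_std(sig, t, centers), rtol=1e-12)


# ---------------------------------------------------------------- filtering

class TestFilters:
    def test_lowpass_preserves_dc(self):
        out = lowpass_015(np.full(200, 5.0), fs=2.0)
        assert np.allclose(out, 5.0, atol=1e-9)

    @pytest.mark.parametrize("freq,bound,side", [(0.01, 0.95, "ge"),
                                                 (0.30, 0.20, "le")])
    def test_lowpass_frequency_response(self, freq, bound, side):
        fs = 2.0
        t = np.arange(0, 400, 1 / fs)
        out = lowpass_015(np.sin(2 * np.pi * freq * t), fs=fs)
        amp = out[200:600].std() * np.sqrt(2)
        if side == "ge":
            assert amp >= bound
        else:
            assert amp <= bound

    def test_lowpass_rejects_short_series(self):
        with pytest.raises(ParameterError):
            lowpass_015(np.zeros(5), fs=2.0)

    def test_bandpass_passes_1hz(self):
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        out = bandpass_ppg(np.sin(2 * np.pi * 1.0 * t), fs)
        amp = out[2000:10000].std() * np.sqrt(2)
        assert amp == pytest.approx(1.0, abs=0.1)

    def test_bandpass_rejects_slow_drift(self):
        fs = 100.0
        t = np.arange(0, 120, 1 / fs)
        out = bandpass_ppg(np.sin(2 * np.pi * 0.05 * t), fs)
        assert np.abs(out).max() < 0.1

    def test_bandpass_zero_in_zero_out(self):
        assert np.allclose(bandpass_ppg(np.zeros(1000), 100.0), 0.0)

    def test_bandpass_requires_adequate_rate(self):
        with pytest.raises(ParameterError):
            bandpass_ppg(np.zeros(100), rate_hz=3.0)


# ------------------------------------------------------------ beat detection

def _pulse_train(period_s, duration_s, fs=100.0, amp=1.0):
    t = np.arange(0, duration_s, 1 / fs)
    x = np.zeros(t.size)
    beats = np.arange(0.5, duration_s - 0.5, period_s)
    x[np.round(beats * fs).astype(int)] = amp
    kernel = _ppg_pulse_kernel(fs)
    return t, np.convolve(x, kernel)[: t.size], beats


class TestDetectPeaks:
    def test_regular_train_recovered(self):
        t, ppg, beats = _pulse_train(1.0, 60.0)
        peaks = detect_peaks(ppg, 100.0)
        assert abs(peaks.size - beats.size) <= 1
        assert np.allclose(np.diff(peaks), 1.0, atol=0.02)

    def test_minimum_distance_suppresses_close_peaks(self):
        fs = 100.0
        x = np.zeros(500)
        x[100] = x[140] = 1.0                      # 0.4 s apart: below 0.55 s
        peaks = detect_peaks(x, fs)
        assert peaks.size == 1

    def test_spacing_floor_equals_10909_bpm(self):
        # the 0.55-s minimum spacing is exactly a 109.09-bpm ceiling
        assert 60.0 / MIN_PEAK_SPACING_S == pytest.approx(109.09, abs=0.01)

    def test_flat_signal_raises(self):
        with pytest.raises(QualityError):
            detect_peaks(np.zeros(1000), 100.0)


class TestIbiClean:
    def test_clean_series_untouched(self):
        peaks = np.arange(0, 60, 1.0)
        ibi, frac = ibi_clean(peaks)
        assert frac == 0.0
        assert np.allclose(ibi, 1.0)

    def test_single_gap_interpolated(self):
        # a missed beat makes one 3-s IBI in a 1-s train; interpolation ~1 s
        peaks = np.concatenate([np.arange(0, 20, 1.0), np.arange(22, 40, 1.0)])
        ibi, frac = ibi_clean(peaks)
        assert frac == pytest.approx(1 / 37, abs=1e-9)
        assert np.allclose(ibi, 1.0, atol=0.01)

    def test_all_too_fast_raises(self):
        with pytest.raises(QualityError):
            ibi_clean(np.arange(0, 10, 0.25))


class TestHrPerTr:
    def test_constant_1s_ibi_gives_60bpm(self):
        peaks = np.arange(0, 100, 1.0)
        hr = hr_per_tr(np.diff(peaks), peaks, np.array([10.0, 50.0, 90.0]))
        assert np.allclose(hr, 60.0)

    def test_median_by_hand(self):
        peaks = np.array([10.0, 10.5, 11.0, 11.6])
        hr = hr_per_tr(np.diff(peaks), peaks, np.array([11.0]))
        assert hr[0] == pytest.approx(120.0)       # median{0.5, 0.5, 0.6} = 0.5

    def test_055s_ibi_gives_10909bpm(self):
        peaks = np.arange(0, 50, 0.55)
        hr = hr_per_tr(np.diff(peaks), peaks, np.array([25.0]))
        assert hr[0] == pytest.approx(109.09, abs=0.01)


# ----------------------------------------------------------- full extraction

class TestExtraction:
    def test_hr_recovery_within_1bpm(self):
        """Artifact-free PPG with drifting IBI: HR within 1 bpm everywhere."""
        fs, duration, tr = 100.0, 210.0, 2.1
        n_vols = int(duration / tr)
        t = np.arange(-3 * fs, (duration + 3) * fs) / fs
        ibi_fn = lambda tt: 0.8 + 0.2 * np.sin(2 * np.pi * tt / 150.0)  # noqa: E731
        beats = [t[0]]
        while beats[-1] < t[-1]:
            beats.append(beats[-1] + ibi_fn(beats[-1]))
        beats = np.asarray(beats[:-1])
        x = np.zeros(t.size)
        np.add.at(x, np.round((beats - t[0]) * fs).astype(int), 1.0)
        ppg = np.convolve(x, _ppg_pulse_kernel(fs))[: t.size]
        resp = np.sin(2 * np.pi * 0.25 * t)
        rec = PhysioRecording(time_s=t, resp=resp, ppg=ppg, rate_hz=fs)
        auto = extract_autonomic(rec, tr, n_vols)

        centers = (np.arange(n_vols) + 0.5) * tr
        ibi = np.diff(beats)
        mids = 0.5 * (beats[:-1] + beats[1:])
        truth = np.array([
            60.0 / np.median(ibi[(mids >= c - 3) & (mids <= c + 3)])
            for c in centers
        ])
        assert np.max(np.abs(auto.hr - truth)) < 1.0

    def test_output_length_matches_volume_count(self, session, default_config):
        for n_vols in (50, 200, default_config.n_tr):
            auto = extract_autonomic(session.physio, default_config.tr_s, n_vols)
            assert auto.rv.size == auto.hr.size == auto.pwa.size == n_vols

    def test_amplitude_linearity_of_rv_pwa(self, session, default_config):
        rec = session.physio
        scaled = PhysioRecording(time_s=rec.time_s, resp=2.5 * rec.resp,
                                 ppg=2.5 * rec.ppg, rate_hz=rec.rate_hz)
        a1 = extract_autonomic(rec, default_config.tr_s, 100)
        a2 = extract_autonomic(scaled, default_config.tr_s, 100)
        assert np.allclose(a2.rv, 2.5 * a1.rv, atol=1e-6 * np.abs(a1.rv).max())
        assert np.allclose(a2.pwa, 2.5 * a1.pwa, atol=1e-6 * np.abs(a1.pwa).max())
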