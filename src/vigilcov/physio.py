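"""Per-TR autonomic measures from raw respiration and PPG waveforms.

Three measures are computed in sliding 6-s windows centered on each fMRI
volume's acquisition midpoint:

* **RV** (respiratory volume): standard deviation of the respiration-belt
  signal in the window, then low-pass filtered at 0.15 Hz across TRs;
* **PWA** (pulse wave amplitude): standard deviation of the raw PPG in the
  window, low-passed the same way;
* **HR** (heart rate): the PPG is band-pass filtered 0.5-2 Hz (2nd-order
  Butterworth, zero-phase), pulse peaks detected with a minimum height of 5%
  of the signal's interquartile range and a minimum spacing of 0.55 s
  (equivalently a 109.09-bpm ceiling), inter-beat intervals cleaned of
  artifacts by interpolation, and HR taken as 60 over the median IBI whose
  midpoint falls inside the window.

Standard deviations are population (ddof=0) standard deviations: the value
is a signal-amplitude summary, not a sample estimate. All filtering is
zero-phase (forward-backward) so downstream lag analyses see no systematic
phase distortion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import BoundaryError, ParameterError, QualityError
from .synthetic import PhysioRecording

logger = logging.getLogger(__name__)

HALF_WIDTH_S = 3.0
MIN_PEAK_SPACING_S = 0.55          # == 109.09 bpm ceiling
PEAK_HEIGHT_IQR_FRAC = 0.05
IBI_BOUNDS_S = (0.33, 2.0)
IBI_MAD_FACTOR = 3.0
MAX_INTERP_FRACTION = 0.25


@dataclass
class AutonomicSeries:
    """RV/HR/PWA sampled on the TR grid."""

    tr_index: np.ndarray
    rv: np.ndarray
    hr: np.ndarray
    pwa: np.ndarray
    ibi_interpolated_fraction: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tr_index": self.tr_index, "rv": self.rv,
                             "hr": self.hr, "pwa": self.pwa})


# ------------------------------------------------------------------ windows

def windowed_std(
    sig: np.ndarray,
    time_s: np.ndarray,
    center_times: np.ndarray,
    half_width_s: float = HALF_WIDTH_S,
) -> np.ndarray:
    """Population std of ``sig`` within |t - center| <= half_width, per center.

    Implemented with cumulative sums so the cost is independent of the window
    width. Raises :class:`BoundaryError` (naming the first offending TR) if
    any window extends past the recording.
    """
    sig = np.asarray(sig, dtype=float)
    time_s = np.asarray(time_s, dtype=float)
    centers = np.asarray(center_times, dtype=float)
    lo_t, hi_t = centers - half_width_s, centers + half_width_s
    bad = np.nonzero((lo_t < time_s[0] - 1e-9) | (hi_t > time_s[-1] + 1e-9))[0]
    if bad.size:
        raise BoundaryError(
            f"6-s window around TR {bad[0]} (center {centers[bad[0]]:.2f} s) "
            f"extends past the recording [{time_s[0]:.2f}, {time_s[-1]:.2f}] s"
        )
    lo = np.searchsorted(time_s, lo_t, side="left")
    hi = np.searchsorted(time_s, hi_t, side="right")
    sig = sig - sig.mean()        # offset-invariant; tames cumsum cancellation
    c1 = np.concatenate([[0.0], np.cumsum(sig)])
    c2 = np.concatenate([[0.0], np.cumsum(sig**2)])
    n = (hi - lo).astype(float)
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    var = np.maximum(s2 / n - (s1 / n) ** 2, 0.0)
    return np.sqrt(var)


# ---------------------------------------------------------------- filtering

def lowpass_015(series: np.ndarray, fs: float, cutoff_hz: float = 0.15,
                order: int = 4) -> np.ndarray:
    """Zero-phase Butterworth low-pass at 0.15 Hz (DC gain 1)."""
    series = np.asarray(series, dtype=float)
    if not np.all(np.isfinite(series)):
        raise ParameterError("series contains non-finite values")
    if cutoff_hz >= fs / 2:
        raise ParameterError(f"cutoff {cutoff_hz} Hz at or above Nyquist ({fs / 2} Hz)")
    sos = sps.butter(order, cutoff_hz, btype="low", fs=fs, output="sos")
    if series.size < 3 * (2 * order + 1):
        raise ParameterError("series too short for stable zero-phase filtering")
    return sps.sosfiltfilt(sos, series)


def bandpass_ppg(ppg: np.ndarray, rate_hz: float,
                 band_hz: tuple[float, float] = (0.5, 2.0)) -> np.ndarray:
    """Zero-phase 2nd-order Butterworth band-pass, 0.5-2 Hz corners."""
    if rate_hz <= 2 * band_hz[1]:
        raise ParameterError(
            f"sampling rate {rate_hz} Hz too low for a {band_hz[1]} Hz band edge"
        )
    sos = sps.butter(2, band_hz, btype="bandpass", fs=rate_hz, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(ppg, dtype=float))


# ------------------------------------------------------------ beat detection

def detect_peaks(filtered_ppg: np.ndarray, rate_hz: float,
                 time_s: np.ndarray | None = None) -> np.ndarray:
    """Pulse peak times: height >= 5% of the IQR, spacing >= 0.55 s.

    The IQR is computed over the whole scan. When two candidates fall within
    the minimum spacing the taller survives. Returns times in seconds (on
    ``time_s`` if given, else sample index / rate).
    """
    x = np.asarray(filtered_ppg, dtype=float)
    q75, q25 = np.percentile(x, [75, 25])
    height = PEAK_HEIGHT_IQR_FRAC * (q75 - q25)
    idx, _ = sps.find_peaks(x, height=height,
                            distance=max(int(round(MIN_PEAK_SPACING_S * rate_hz)), 1))
    if idx.size == 0:
        raise QualityError(
            f"no pulse peaks found (IQR {q75 - q25:.3g}, height threshold {height:.3g})"
        )
    if time_s is not None:
        return np.asarray(time_s, dtype=float)[idx]
    return idx / rate_hz


def ibi_clean(peak_times: np.ndarray,
              bounds_s: tuple[float, float] = IBI_BOUNDS_S,
              mad_factor: float = IBI_MAD_FACTOR,
              running_window: int = 11,
              min_dev_s: float = 0.1) -> tuple[np.ndarray, float]:
    """Flag and interpolate artifactual inter-beat intervals.

    IBIs outside ``bounds_s``, or deviating from a running median (centered,
    ``running_window`` beats) by more than ``mad_factor`` median absolute
    deviations *and* at least ``min_dev_s``, are replaced by linear
    interpolation over beat index. The absolute floor keeps the rule aimed at
    genuine detector artifacts (missed or doubled beats shift an IBI by
    hundreds of ms) rather than smooth physiological rate drift, where the
    MAD of a slowly varying series can be vanishingly small. Returns the
    cleaned series and the fraction interpolated; more than 25% flagged
    raises :class:`QualityError`.
    """
    peak_times = np.asarray(peak_times, dtype=float)
    if peak_times.size < 3:
        raise ParameterError("need at least 3 peaks to form an IBI series")
    ibi = np.diff(peak_times)
    run_med = _running_median(ibi, running_window)
    mad = np.median(np.abs(ibi - run_med))
    bad = (ibi < bounds_s[0]) | (ibi > bounds_s[1])
    if mad > 0:
        dev = np.abs(ibi - run_med)
        bad |= (dev > mad_factor * mad) & (dev > min_dev_s)
    frac = float(bad.mean())
    if frac > MAX_INTERP_FRACTION:
        raise QualityError(
            f"{100 * frac:.1f}% of IBIs flagged as artifacts; signal unusable"
        )
    if bad.any():
        logger.info("interpolating %d/%d IBIs (%.2f%%)", bad.sum(), bad.size, 100 * frac)
        good = ~bad
        if not good.any():
            raise QualityError("every IBI flagged; signal unusable")
        ibi = ibi.copy()
        ibi[bad] = np.interp(np.nonzero(bad)[0], np.nonzero(good)[0], ibi[good])
    return ibi, frac


def _running_median(x: np.ndarray, window: int) -> np.ndarray:
    if x.size <= window:
        return np.full_like(x, np.median(x))
    return sps.medfilt(x, kernel_size=window if window % 2 else window + 1)


def hr_per_tr(ibi: np.ndarray, peak_times: np.ndarray,
              center_times: np.ndarray,
              half_width_s: float = HALF_WIDTH_S) -> np.ndarray:
    """HR per TR: 60 / median IBI with midpoint inside the 6-s window (bpm).

    A window containing no IBI midpoints carries the nearest window's value
    (with a logged warning).
    """
    ibi = np.asarray(ibi, dtype=float)
    peak_times = np.asarray(peak_times, dtype=float)
    if ibi.size != peak_times.size - 1:
        raise ParameterError("ibi must have one fewer element than peak_times")
    mid = 0.5 * (peak_times[:-1] + peak_times[1:])
    centers = np.asarray(center_times, dtype=float)
    lo = np.searchsorted(mid, centers - half_width_s, side="left")
    hi = np.searchsorted(mid, centers + half_width_s, side="right")
    hr = np.full(centers.size, np.nan)
    for i in range(centers.size):
        if hi[i] > lo[i]:
            hr[i] = 60.0 / float(np.median(ibi[lo[i]:hi[i]]))
    empty = np.isnan(hr)
    if empty.all():
        raise QualityError("no window contains any inter-beat interval")
    if empty.any():
        logger.warning("%d empty HR windows; carrying nearest valid value",
                       int(empty.sum()))
        valid_idx = np.nonzero(~empty)[0]
        for i in np.nonzero(empty)[0]:
            hr[i] = hr[valid_idx[np.argmin(np.abs(valid_idx - i))]]
    return hr


# ------------------------------------------------------------------ pipeline

def extract_autonomic(
    recording: PhysioRecording,
    tr_s: float,
    n_vols: int,
    lowpass: bool = True,
) -> AutonomicSeries:
    """Full waveform -> per-TR RV/HR/PWA extraction for one scan.

    Window centers are each volume's acquisition midpoint,
    ``trigger + (i + 0.5) * TR``. RV and PWA are low-pass filtered at 0.15 Hz
    across TRs; HR is not (matching the published procedure).
    """
    centers = recording.trigger_onset_s + (np.arange(n_vols) + 0.5) * tr_s
    rv = windowed_std(recording.resp, recording.time_s, centers)
    pwa = windowed_std(recording.ppg, recording.time_s, centers)
    if lowpass:
        rv = lowpass_015(rv, fs=1.0 / tr_s)
        pwa = lowpass_015(pwa, fs=1.0 / tr_s)
    filtered = bandpass_ppg(recording.ppg, recording.rate_hz)
    peaks = detect_peaks(filtered, recording.rate_hz, time_s=recording.time_s)
    ibi, frac = ibi_clean(peaks)
    hr = hr_per_tr(ibi, peaks, centers)
    return AutonomicSeries(tr_index=np.arange(n_vols), rv=rv, hr=hr, pwa=pwa,
                           ibi_interpolated_fraction=frac)
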