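"""Session segmentation, per-analysis high-pass filtering, and tertile staging.

Sessions are tiled into non-overlapping windows of a fixed TR count (60 TRs =
126 s for global/network analyses, 115 TRs = 241.5 s for voxelwise ones; any
length from 30-120 TRs is accepted for robustness checks). Signals entering a
windowed analysis are first high-pass filtered at 1/window-length Hz so that
fluctuations slower than one window cannot masquerade as within-window
variance. Windows are staged into pooled low/middle/high baseline-vigilance
tertiles by the 33.3%/66.7% empirical quantiles of the pooled distribution;
ties at a cut point go to the extreme stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

DEFAULT_WINDOW_TRS = 60
VOXELWISE_WINDOW_TRS = 115


@dataclass
class WindowSet:
    """Non-overlapping, ordered, equal-length window boundaries (half-open TRs)."""

    window_len_tr: int
    boundaries: list[tuple[int, int]]
    labels: list[str] = field(default_factory=list)          # condition per window
    stage: list[str] = field(default_factory=list)           # low / mid / high

    def __len__(self) -> int:
        return len(self.boundaries)

    def slices(self):
        for s, e in self.boundaries:
            yield slice(s, e)


def segment(n_tr: int, window_len_tr: int = DEFAULT_WINDOW_TRS) -> WindowSet:
    """Tile ``n_tr`` retained volumes into floor(n_tr / len) windows.

    Indexing is 0-based and half-open; the incomplete tail is discarded.
    A 693-TR session (24.5 min at TR 2.1 s minus 7 discarded volumes) gives
    11 windows of 60 TRs or 6 windows of 115 TRs.
    """
    if window_len_tr < 2:
        raise ParameterError("window length must be at least 2 TRs")
    if n_tr < window_len_tr:
        raise InsufficientDataError(
            f"session has {n_tr} TRs, shorter than one {window_len_tr}-TR window"
        )
    n_win = n_tr // window_len_tr
    bounds = [(i * window_len_tr, (i + 1) * window_len_tr) for i in range(n_win)]
    return WindowSet(window_len_tr=window_len_tr, boundaries=bounds)


def highpass_for_windows(series: np.ndarray, window_len_s: float,
                         fs: float, order: int = 2) -> np.ndarray:
    """Zero-phase Butterworth high-pass at 1/window-length Hz, exact DC removal.

    ``series`` may be 1-D or (n_tr, k); filtering runs along axis 0. The
    residual mean left by end effects is subtracted so the output mean is
    zero to machine precision.
    """
    x = np.asarray(series, dtype=float)
    cutoff = 1.0 / window_len_s
    if cutoff >= fs / 2:
        raise ParameterError("window length too short: cutoff at or above Nyquist")
    sos = sps.butter(order, cutoff, btype="high", fs=fs, output="sos")
    min_len = 3 * (2 * order + 1)
    if x.shape[0] < min_len:
        raise ParameterError(f"series of length {x.shape[0]} too short to filter")
    y = sps.sosfiltfilt(sos, x, axis=0)
    return y - y.mean(axis=0)


def window_variance(series: np.ndarray, windows: WindowSet) -> np.ndarray:
    """Sample variance (ddof=1) of a (high-passed) series in each window.

    Returns (n_windows,) for 1-D input or (n_windows, k) for 2-D.
    """
    x = np.asarray(series, dtype=float)
    out = np.stack([x[sl].var(axis=0, ddof=1) for sl in windows.slices()])
    return out


def stage_tertiles(
    baseline_values_pooled: np.ndarray,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Stage pooled windows into low/mid/high baseline-vigilance tertiles.

    Cut points are the 33.3% and 66.7% linear-interpolation empirical
    quantiles of the pooled distribution; ``low`` is value <= lower cut,
    ``high`` is value >= upper cut, ``mid`` otherwise (ties at a cut point
    land in the extreme stage, matching <= / >= boundary semantics). Stage
    labels depend only on ranks, so they are invariant to any strictly
    monotone transform of the values and to the order sessions are pooled in.
    """
    v = np.asarray(baseline_values_pooled, dtype=float)
    v = v[~np.isnan(v)] if np.isnan(v).any() else v
    if v.size < 3:
        raise InsufficientDataError("need at least 3 pooled windows to form tertiles")
    if np.unique(v).size == 1:
        raise DegenerateInputError("all baseline values identical; tertiles undefined")
    lo_cut = float(np.quantile(v, 1.0 / 3.0))
    hi_cut = float(np.quantile(v, 2.0 / 3.0))
    vals = np.asarray(baseline_values_pooled, dtype=float)
    stage = np.where(vals <= lo_cut, "low",
                     np.where(vals >= hi_cut, "high", "mid"))
    stage = np.where(np.isnan(vals), "nan", stage)
    return stage, (lo_cut, hi_cut)
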