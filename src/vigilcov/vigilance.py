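"""EEG vigilance indexing and its behavioral validation.

The vigilance index is the ratio of EEG alpha-band (8-12 Hz) to theta-band
(3-7 Hz) RMS amplitude per TR, with an alternative form alpha/(delta+theta)
using the 0.5-2 Hz delta band. "Baseline vigilance" is the mean index over a
minutes-long window, optionally after advancing the EEG series by 2 TRs
(4.2 s) relative to the fMRI grid to accommodate hemodynamic delay.

Validation: across windows of a task scan, mean reaction time should rise as
baseline vigilance falls; the association is a Spearman rank correlation with
a two-tailed permutation test (10,000 shuffles of the windowed vigilance
values, add-one corrected so the p-value is never exactly zero).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy import stats

from .errors import (BoundaryError, DegenerateInputError, InsufficientDataError,
                     ParameterError)
from .windows import WindowSet

BANDS_HZ = {"alpha": (8.0, 12.0), "theta": (3.0, 7.0), "delta": (0.5, 2.0)}
DEFAULT_SHIFT_TRS = 2
RT_CUTOFF_S = 4.0


# ------------------------------------------------------------------ band RMS

def band_rms_per_tr(
    eeg: np.ndarray,
    rate_hz: float,
    tr_s: float,
    n_trs: int,
    bands: dict[str, tuple[float, float]] | None = None,
    filter_order: int = 4,
) -> pd.DataFrame:
    """Per-TR band RMS amplitudes averaged over channels.

    ``eeg`` is (n_channels, n_samples) of cleaned EEG. Each channel is
    band-pass filtered (zero-phase Butterworth) per band, the RMS is taken
    over each TR's acquisition interval, and the channel mean is returned:
    one value per band per TR. The order — RMS per channel, then average —
    matters and is fixed.
    """
    eeg = np.atleast_2d(np.asarray(eeg, dtype=float))
    bands = bands if bands is not None else BANDS_HZ
    samples_per_tr = tr_s * rate_hz
    needed = int(np.ceil(n_trs * samples_per_tr))
    if eeg.shape[1] < needed:
        raise BoundaryError(
            f"EEG has {eeg.shape[1]} samples but {needed} are needed for {n_trs} TRs"
        )
    edges = (np.arange(n_trs + 1) * samples_per_tr).round().astype(int)
    out: dict[str, np.ndarray] = {"tr_index": np.arange(n_trs)}
    for name, (lo, hi) in bands.items():
        sos = sps.butter(filter_order, (lo, hi), btype="bandpass", fs=rate_hz,
                         output="sos")
        filtered = sps.sosfiltfilt(sos, eeg, axis=1)
        sq = np.concatenate([np.zeros((eeg.shape[0], 1)),
                             np.cumsum(filtered**2, axis=1)], axis=1)
        n = np.diff(edges)
        rms = np.sqrt((sq[:, edges[1:]] - sq[:, edges[:-1]]) / n)
        out[name] = rms.mean(axis=0)
    return pd.DataFrame(out)


# ---------------------------------------------------------------- the index

def vigilance_index(series: pd.DataFrame, mode: str = "alpha/theta") -> np.ndarray:
    """Per-TR vigilance ratio: ``alpha/theta`` or ``alpha/(delta+theta)``."""
    alpha = series["alpha"].to_numpy(dtype=float)
    theta = series["theta"].to_numpy(dtype=float)
    if mode == "alpha/theta":
        denom = theta
    elif mode == "alpha/(delta+theta)":
        denom = series["delta"].to_numpy(dtype=float) + theta
    else:
        raise ParameterError(f"unknown vigilance index mode {mode!r}")
    if np.any(denom <= 0):
        raise DegenerateInputError(
            "vigilance index undefined: denominator band power is zero at some TR"
        )
    return alpha / denom


def baseline_vigilance(
    ratio: np.ndarray,
    windows: WindowSet,
    shift_trs: int = DEFAULT_SHIFT_TRS,
) -> np.ndarray:
    """Per-window mean of the vigilance ratio after a forward shift.

    The EEG series is advanced by ``shift_trs`` TRs (4.2 s at the default 2)
    relative to the fMRI grid before averaging, approximating the ~5-s peak
    of canonical hemodynamic responses. Windows whose shifted span runs past
    the end of the series get NaN (dropped from downstream pairings).
    """
    ratio = np.asarray(ratio, dtype=float)
    if shift_trs < 0 or shift_trs >= windows.window_len_tr:
        raise ParameterError("shift must be non-negative and smaller than the window")
    out = np.full(len(windows.boundaries), np.nan)
    for i, (s, e) in enumerate(windows.boundaries):
        s2, e2 = s + shift_trs, e + shift_trs
        if e2 <= ratio.size:
            out[i] = ratio[s2:e2].mean()
    return out


# -------------------------------------------------------------- validation

def spearman_permutation(
    x: np.ndarray,
    y: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Spearman rho and two-tailed permutation p (shuffling ``y``).

    Ties get average ranks. The p-value uses the add-one correction
    ``(1 + #{|rho_b| >= |rho|}) / (1 + B)``. Either input constant raises
    :class:`DegenerateInputError` (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("inputs must be the same length")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        raise DegenerateInputError("Spearman correlation undefined for constant input")
    rng = rng if rng is not None else np.random.default_rng()
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    rho = float(rx @ ry / rx.size)
    perm = rng.permuted(np.tile(ry, (n_perm, 1)), axis=1) @ rx / rx.size
    p = (1.0 + np.count_nonzero(np.abs(perm) >= np.abs(rho) - 1e-12)) / (1.0 + n_perm)
    return rho, float(p)


def validate_vigilance(
    baseline: np.ndarray,
    events: pd.DataFrame,
    windows: WindowSet,
    tr_s: float,
    missing_policy: str = "drop",
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Spearman rho (and permutation p) between window-mean RT and baseline vigilance.

    ``missing_policy`` is ``"drop"`` (missing RTs excluded from the window
    mean) or ``"impute_4s"`` (missing RTs scored as a maximal 4-s response).
    Windows with no events (or, under ``drop``, no responded events) are
    excluded; fewer than 5 usable windows raises
    :class:`InsufficientDataError`.
    """
    if missing_policy not in ("drop", "impute_4s"):
        raise ParameterError(f"unknown missing_policy {missing_policy!r}")
    baseline = np.asarray(baseline, dtype=float)
    onsets = events["onset_s"].to_numpy(dtype=float)
    rt = events["rt_s"].to_numpy(dtype=float)
    if missing_policy == "impute_4s":
        rt = np.where(np.isnan(rt), RT_CUTOFF_S, rt)

    mean_rt = np.full(len(windows.boundaries), np.nan)
    for i, (s, e) in enumerate(windows.boundaries):
        in_win = (onsets >= s * tr_s) & (onsets < e * tr_s)
        vals = rt[in_win]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            mean_rt[i] = vals.mean()

    ok = ~np.isnan(mean_rt) & ~np.isnan(baseline)
    if ok.sum() < 5:
        raise InsufficientDataError(
            f"only {int(ok.sum())} windows with RT data; need at least 5"
        )
    return spearman_permutation(mean_rt[ok], baseline[ok], n_perm=n_perm, rng=rng)
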