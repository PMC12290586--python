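"""Model-free lagged cross-correlation of fMRI with autonomic / EEG signals.

The normalized cross-covariance follows the convention of MATLAB's ``xcov``
with ``'normalized'`` scaling: both series are demeaned with their full-window
means, products are summed over the overlapping samples only, and the sum is
divided by ``sqrt(sum((x - xbar)^2) * sum((y - ybar)^2))`` over the full
window. With ``xcov_normalized(fmri, autonomic)``, a *positive* lag pairs the
fMRI sample at ``t + lag`` with the autonomic sample at ``t`` — i.e. the
autonomic signal *leads* the fMRI signal, which is where hemodynamic
responses put their peak. Because the normalizer uses full-window sums while
the numerator only sums the overlap, |r| shrinks toward the extreme lags;
this end effect is inherent to the convention.

The default lag grid spans -5..+15 TRs (-10.5 to +31.5 s at TR 2.1 s).
Per-window cross-correlation curves are averaged within pooled baseline-
vigilance tertile stages, and fMRI signals can first be averaged within
tissue compartments (grey matter, white matter, ventricles).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateInputError, InsufficientDataError, ParameterError

DEFAULT_LAGS_TR = np.arange(-5, 16)


@dataclass
class LagGrid:
    """Signed lags in TRs and seconds (positive = physiology leads fMRI)."""

    lags_tr: np.ndarray
    tr_s: float

    @property
    def lags_s(self) -> np.ndarray:
        return self.lags_tr * self.tr_s


def default_lag_grid(tr_s: float = 2.1) -> LagGrid:
    """-5..+15 TRs: -10.5 to +31.5 s at the study TR, 21 lags."""
    return LagGrid(lags_tr=DEFAULT_LAGS_TR.copy(), tr_s=tr_s)


@dataclass
class StagedXCorr:
    """Per-lag mean and SEM of cross-correlation curves within one stage."""

    target: str
    signal: str
    stage: str
    lags_tr: np.ndarray
    mean_r: np.ndarray
    sem_r: np.ndarray
    n_windows: int


def xcov_normalized(x: np.ndarray, y: np.ndarray,
                    lags_tr: np.ndarray | None = None) -> np.ndarray:
    """Normalized cross-covariance of ``x`` (fMRI) and ``y`` at integer lags.

    ``r[l] = sum_t (x[t + l] - xbar)(y[t] - ybar) / sqrt(Sxx * Syy)`` with
    the sum over the overlap and ``Sxx``/``Syy`` the full-window sums of
    squared deviations. Positive ``l`` therefore means ``y`` leads ``x``.
    Satisfies ``xcov(x, y, l) == xcov(y, x, -l)`` exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ParameterError("series must have equal length within a window")
    lags = np.asarray(lags_tr if lags_tr is not None else DEFAULT_LAGS_TR, dtype=int)
    if np.any(np.abs(lags) >= x.size):
        raise ParameterError("lag magnitude must be smaller than the window length")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = np.sqrt(np.sum(xd**2) * np.sum(yd**2))
    if denom == 0:
        raise DegenerateInputError("zero-variance input to cross-correlation")
    out = np.empty(lags.size)
    for i, ell in enumerate(lags):
        if ell >= 0:
            out[i] = np.dot(xd[ell:], yd[: yd.size - ell]) / denom
        else:
            out[i] = np.dot(xd[: xd.size + ell], yd[-ell:]) / denom
    return out


def windowed_xcov(x: np.ndarray, y: np.ndarray, windows,
                  lags_tr: np.ndarray | None = None) -> np.ndarray:
    """Cross-correlation curve per window: (n_windows, n_lags)."""
    return np.stack([xcov_normalized(x[sl], y[sl], lags_tr)
                     for sl in windows.slices()])


def staged_average(
    xcorrs: np.ndarray,
    stages: np.ndarray,
    lags_tr: np.ndarray | None = None,
    target: str = "global",
    signal: str = "RV",
) -> dict[str, StagedXCorr]:
    """Average per-window curves within each tertile stage (mean and SEM per lag)."""
    xcorrs = np.asarray(xcorrs, dtype=float)
    stages = np.asarray(stages)
    lags = np.asarray(lags_tr if lags_tr is not None else DEFAULT_LAGS_TR)
    out: dict[str, StagedXCorr] = {}
    for stage in ("low", "mid", "high"):
        mask = stages == stage
        n = int(mask.sum())
        if n == 0:
            raise InsufficientDataError(f"no windows in the {stage!r} vigilance stage")
        curves = xcorrs[mask]
        mean = curves.mean(axis=0)
        sem = (curves.std(axis=0, ddof=1) / np.sqrt(n)) if n > 1 else np.zeros(lags.size)
        out[stage] = StagedXCorr(target=target, signal=signal, stage=stage,
                                 lags_tr=lags, mean_r=mean, sem_r=sem, n_windows=n)
    return out


def tissue_average(voxel_series: np.ndarray, voxel_labels: np.ndarray,
                   labels_in_mask) -> np.ndarray:
    """Unweighted mean over in-mask voxels per TR.

    ``voxel_series`` is (n_tr, n_voxels); ``labels_in_mask`` selects the
    atlas labels belonging to the compartment.
    """
    labels = np.asarray(voxel_labels)
    mask = np.isin(labels, np.asarray(labels_in_mask))
    if not mask.any():
        raise ParameterError("tissue mask selects no voxels")
    return np.asarray(voxel_series, dtype=float)[:, mask].mean(axis=1)
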