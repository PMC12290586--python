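"""Hemodynamic-style response kernels and design-matrix assembly.

Three impulse responses map slow physiological fluctuations onto the BOLD
signal:

* the respiratory response function (RRF) of Birn and colleagues, a biphasic
  curve with an early positive lobe and a slower negative lobe,
* the cardiac response function (CRF) of Chang and colleagues, an early
  positive gamma peak followed by a Gaussian trough near 12 s,
* the canonical double-gamma hemodynamic response function (HRF), plus a
  variant re-parameterized for seconds-level EEG power fluctuations (peak
  10 s, undershoot 14 s, dispersions 2, response:undershoot ratio 2).

Each kernel is sampled on the TR grid, truncated at 32 s, and normalized to
unit peak absolute amplitude. Basis sets append finite-difference temporal
derivatives and central-difference dispersion derivatives, each
orthogonalized against the base kernel and scaled to unit norm, giving the
five-column RV/HR bases and three-column HRF bases used throughout.

Design matrices are assembled on the full pre-discard TR grid (convolution
precedes dropping the initial volumes, so lagged responses bleed correctly
into the first analysis window), then truncated and optionally z-scored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CoverageError, ParameterError

logger = logging.getLogger(__name__)

KERNEL_SPAN_S = 32.0


# --------------------------------------------------------------------- kernels

def rrf(t: np.ndarray, dispersion: float = 1.0) -> np.ndarray:
    """Respiratory response function evaluated at lags ``t`` (seconds).

    ``rrf(t) = 0.6 t^2.1 e^{-t/1.6} - 0.0023 t^3.54 e^{-t/4.25}`` with the
    time axis dilated by ``dispersion`` (1 = published shape). Vanishes at 0.
    """
    t = _check_lags(t)
    td = t / float(dispersion)
    return 0.6 * td**2.1 * np.exp(-td / 1.6) - 0.0023 * td**3.54 * np.exp(-td / 4.25)


def crf(t: np.ndarray, dispersion: float = 1.0) -> np.ndarray:
    """Cardiac response function: gamma lobe minus a Gaussian trough at 12 s.

    ``crf(t) = 0.6 t^2.7 e^{-t/1.6} - 16/sqrt(18 pi) e^{-(t-12)^2/18}``.
    The Gaussian term is tiny (but nonzero) at t = 0; it is zeroed there so
    the kernel is exactly causal.
    """
    t = _check_lags(t)
    td = t / float(dispersion)
    peak = 0.6 * td**2.7 * np.exp(-td / 1.6)
    trough = (16.0 / np.sqrt(18.0 * np.pi)) * np.exp(-((td - 12.0) ** 2) / 18.0)
    out = peak - trough
    out[td == 0] = 0.0
    return out


def canonical_hrf(
    t: np.ndarray,
    peak_s: float = 6.0,
    undershoot_s: float = 16.0,
    dispersion: float = 1.0,
    u_dispersion: float = 1.0,
    ratio: float = 6.0,
) -> np.ndarray:
    """Double-gamma HRF: gamma(peak) - gamma(undershoot)/ratio.

    Parameterized by peak/undershoot delays (seconds), dispersion factors and
    the response-to-undershoot ratio; all must be positive.
    """
    for name, v in (("peak_s", peak_s), ("undershoot_s", undershoot_s),
                    ("dispersion", dispersion), ("u_dispersion", u_dispersion),
                    ("ratio", ratio)):
        if v <= 0:
            raise ParameterError(f"{name} must be positive, got {v}")
    t = _check_lags(t)
    main = stats.gamma.pdf(t, peak_s / dispersion, scale=dispersion)
    under = stats.gamma.pdf(t, undershoot_s / u_dispersion, scale=u_dispersion)
    return main - under / ratio


def data_driven_eeg_hrf(t: np.ndarray, dispersion: float = 2.0) -> np.ndarray:
    """HRF variant for seconds-level EEG band power (peak 10 s, undershoot 14 s,
    dispersions 2, response:undershoot ratio 2)."""
    return canonical_hrf(t, peak_s=10.0, undershoot_s=14.0, dispersion=dispersion,
                         u_dispersion=2.0, ratio=2.0)


def _check_lags(t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ParameterError("kernel lags must be non-negative")
    return t


def lag_grid(tr_s: float, span_s: float = KERNEL_SPAN_S) -> np.ndarray:
    """TR-resolution lag grid covering [0, span_s] (at least span_s/TR points)."""
    n = int(np.ceil(span_s / tr_s)) + 1
    return np.arange(n) * tr_s


def _unit_peak(k: np.ndarray) -> np.ndarray:
    m = np.max(np.abs(k))
    if m == 0:
        raise ParameterError("kernel is identically zero on the lag grid")
    return k / m


# ----------------------------------------------------------------- basis sets

@dataclass
class KernelBasis:
    """A named set of kernels sharing one lag grid (TR resolution)."""

    name: str
    lags_s: np.ndarray
    kernels: np.ndarray        # (n_columns, n_lags)
    column_names: list[str] = field(default_factory=list)

    @property
    def n_columns(self) -> int:
        return self.kernels.shape[0]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.kernels.T, columns=self.column_names)
        df.insert(0, "lag_s", self.lags_s)
        return df


def add_derivatives(
    kernel: Callable[..., np.ndarray],
    tr_s: float,
    n_temporal: int = 2,
    n_dispersion: int = 2,
    name: str = "kernel",
    rel_step: float = 0.05,
    base_dispersion: float = 1.0,
) -> KernelBasis:
    """Build a basis of a kernel plus temporal and dispersion derivatives.

    ``kernel(t, dispersion=...)`` is evaluated on the TR lag grid. Temporal
    derivatives are backward finite differences of successive order (a shift
    by ``tr_s`` stays causal); dispersion derivatives are central differences
    with a step of ``rel_step`` times the dispersion value, iterated for the
    second order. Every derivative column is orthogonalized against the base
    kernel and scaled to unit norm; the base kernel keeps unit peak.
    """
    if n_temporal > 2 or n_dispersion > 2 or n_temporal < 0 or n_dispersion < 0:
        raise ParameterError("only 0, 1 or 2 derivatives of each kind are supported")
    lags = lag_grid(tr_s)
    base = _unit_peak(kernel(lags, dispersion=base_dispersion))

    def eval_shifted(shift_s: float, dispersion: float) -> np.ndarray:
        t = lags - shift_s
        out = np.zeros_like(lags)
        ok = t >= 0
        out[ok] = kernel(t[ok], dispersion=dispersion)
        return out / np.max(np.abs(kernel(lags, dispersion=base_dispersion)))

    cols = [base]
    names = [name]

    # temporal: first and second backward differences on a TR shift
    for order in range(1, n_temporal + 1):
        if order == 1:
            d = (eval_shifted(tr_s, base_dispersion) - base) / tr_s
        else:
            d1 = (eval_shifted(tr_s, base_dispersion) - base) / tr_s
            d1_shift = (eval_shifted(2 * tr_s, base_dispersion)
                        - eval_shifted(tr_s, base_dispersion)) / tr_s
            d = (d1_shift - d1) / tr_s
        cols.append(_orth_unit(d, base))
        names.append(f"{name}_t{order}")

    # dispersion: central differences in the dispersion parameter
    h = rel_step * base_dispersion
    if n_dispersion >= 1:
        d1 = (eval_shifted(0.0, base_dispersion + h)
              - eval_shifted(0.0, base_dispersion - h)) / (2 * h)
        cols.append(_orth_unit(d1, base))
        names.append(f"{name}_d1")
    if n_dispersion >= 2:
        d2 = (eval_shifted(0.0, base_dispersion + h)
              - 2 * base
              + eval_shifted(0.0, base_dispersion - h)) / h**2
        cols.append(_orth_unit(d2, base))
        names.append(f"{name}_d2")

    return KernelBasis(name=name, lags_s=lags, kernels=np.vstack(cols),
                       column_names=names)


def _orth_unit(v: np.ndarray, base: np.ndarray) -> np.ndarray:
    """Orthogonalize ``v`` against ``base`` and scale to unit norm."""
    v = v - base * (v @ base) / (base @ base)
    nrm = np.linalg.norm(v)
    if nrm == 0:
        raise ParameterError("derivative column collapsed to zero after orthogonalization")
    return v / nrm


def rrf_basis(tr_s: float) -> KernelBasis:
    """RRF plus two temporal and two dispersion derivatives (5 columns)."""
    return add_derivatives(rrf, tr_s, 2, 2, name="rrf")


def crf_basis(tr_s: float) -> KernelBasis:
    """CRF plus two temporal and two dispersion derivatives (5 columns)."""
    return add_derivatives(crf, tr_s, 2, 2, name="crf")


def hrf_basis(tr_s: float, name: str = "hrf") -> KernelBasis:
    """Canonical HRF plus one temporal and one dispersion derivative (3 columns)."""
    return add_derivatives(canonical_hrf, tr_s, 1, 1, name=name)


def eeg_hrf_basis(tr_s: float, name: str = "eeghrf") -> KernelBasis:
    """Data-driven EEG HRF (peak 10 s) plus its two derivatives (3 columns)."""
    return add_derivatives(data_driven_eeg_hrf, tr_s, 1, 1, name=name,
                           base_dispersion=2.0)


# -------------------------------------------------------------- design matrix

@dataclass
class DesignMatrix:
    """Labeled regressor columns on the TR grid, partitioned into groups."""

    frame: pd.DataFrame
    groups: dict[str, list[str]]
    z_scored: bool = False
    tr_s: float = 2.1

    def group(self, name: str) -> np.ndarray:
        return self.frame[self.groups[name]].to_numpy()

    @property
    def condition_number(self) -> float:
        x = self.frame.to_numpy()
        x = (x - x.mean(0)) / np.where(x.std(0) > 0, x.std(0), 1.0)
        return float(np.linalg.cond(x))


def convolve_tr(signal: np.ndarray, basis: KernelBasis) -> np.ndarray:
    """Convolve a TR-grid signal with each kernel (causal, same length).

    Returns an (n_tr, n_columns) array; the convolution treats kernel samples
    as TR-spaced impulse-response taps.
    """
    signal = np.asarray(signal, dtype=float)
    out = np.empty((signal.size, basis.n_columns))
    for j in range(basis.n_columns):
        out[:, j] = np.convolve(signal, basis.kernels[j])[: signal.size]
    return out


def zscore_columns(x: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Z-score each column; constant columns raise (never silently kept)."""
    x = np.asarray(x, dtype=float)
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    if np.any(sd <= tol * np.maximum(1.0, np.abs(mu))):
        raise ParameterError("cannot z-score a constant column")
    return (x - mu) / sd


def stimulus_covariates(
    events: pd.DataFrame,
    n_tr: int,
    tr_s: float,
    n_discard: int = 0,
    intermediate_rate_hz: float = 1.0,
) -> pd.DataFrame:
    """Stimulus regressors: responded/unresponded tone trains x 3-column HRF basis.

    Binary event trains are built at a 1-Hz intermediate rate over the whole
    pre-discard session, convolved with the canonical HRF basis (HRF +
    temporal + dispersion derivative) sampled at that rate, resampled onto
    the TR grid by linear interpolation, and the first ``n_discard`` TRs
    dropped. A class with no events contributes no columns (logged).
    """
    duration = n_tr * tr_s
    dt = 1.0 / intermediate_rate_hz
    t_fine = np.arange(int(np.ceil(duration / dt))) * dt
    basis = add_derivatives(canonical_hrf, dt, 1, 1, name="stim")

    cols: dict[str, np.ndarray] = {}
    t_tr = np.arange(n_tr) * tr_s
    for label, mask in (
        ("responded", events["responded"].to_numpy(dtype=bool)),
        ("unresponded", ~events["responded"].to_numpy(dtype=bool)),
    ):
        onsets = events.loc[mask, "onset_s"].to_numpy(dtype=float)
        if onsets.size == 0:
            logger.info("no %s events; omitting their stimulus columns", label)
            continue
        train = np.zeros(t_fine.size)
        idx = np.clip(np.round(onsets / dt).astype(int), 0, t_fine.size - 1)
        train[idx] = 1.0
        conv = np.empty((t_fine.size, basis.n_columns))
        for j in range(basis.n_columns):
            conv[:, j] = np.convolve(train, basis.kernels[j])[: t_fine.size]
        for j, kname in enumerate(basis.column_names):
            cols[f"{label}_{kname}"] = np.interp(t_tr, t_fine, conv[:, j])

    frame = pd.DataFrame(cols)
    return frame.iloc[n_discard:].reset_index(drop=True)


def build_design(
    autonomic: pd.DataFrame,
    tr_s: float,
    fast_eeg: pd.DataFrame | None = None,
    events: pd.DataFrame | None = None,
    n_discard: int = 7,
    pwa_advance_trs: int = 2,
    eeg_basis: str = "canonical",
    z_score: bool = False,
) -> DesignMatrix:
    """Assemble the full design matrix on the analysis TR grid.

    ``autonomic`` must carry ``rv``, ``hr``, ``pwa`` columns over the *whole*
    pre-discard session (convolution precedes dropping the first ``n_discard``
    volumes so lagged responses reach the first window). The autonomic group
    is RV * RRF basis (5) + HR * CRF basis (5) + PWA advanced 2 TRs * HRF
    basis (3) = 13 columns. The optional fast-EEG group convolves the alpha,
    delta, and theta per-TR amplitudes with a 3-column HRF basis (canonical
    or the 10-s-peak EEG variant) giving 9 columns; the optional stimulus
    group adds up to 6 columns.

    Columns are returned un-normalized by default; windowed analyses z-score
    within each window (set ``z_score=True`` for whole-span scores).
    """
    required = {"rv", "hr", "pwa"}
    if not required.issubset(autonomic.columns):
        raise CoverageError(f"autonomic table must have columns {sorted(required)}")
    n_full = len(autonomic)
    if n_full <= n_discard:
        raise CoverageError("autonomic series does not cover the pre-discard span")

    cols: dict[str, np.ndarray] = {}
    groups: dict[str, list[str]] = {}

    rv_cols = convolve_tr(autonomic["rv"].to_numpy(), rrf_basis(tr_s))
    hr_cols = convolve_tr(autonomic["hr"].to_numpy(), crf_basis(tr_s))
    pwa = autonomic["pwa"].to_numpy(dtype=float)
    if pwa_advance_trs > 0:          # advance: pwa[t] <- pwa[t + k], edge-padded
        pwa = np.concatenate([pwa[pwa_advance_trs:],
                              np.full(pwa_advance_trs, pwa[-1])])
    pwa_cols = convolve_tr(pwa, hrf_basis(tr_s, name="pwa_hrf"))

    auto_names: list[str] = []
    for arr, basis_names in (
        (rv_cols, [f"rv_{n}" for n in rrf_basis(tr_s).column_names]),
        (hr_cols, [f"hr_{n}" for n in crf_basis(tr_s).column_names]),
        (pwa_cols, [f"pwa_{n}" for n in hrf_basis(tr_s, name="hrf").column_names]),
    ):
        for j, nm in enumerate(basis_names):
            cols[nm] = arr[:, j]
            auto_names.append(nm)
    groups["autonomic"] = auto_names

    if fast_eeg is not None:
        if not {"alpha", "delta", "theta"}.issubset(fast_eeg.columns):
            raise CoverageError("fast_eeg table must have alpha, delta, theta columns")
        if len(fast_eeg) != n_full:
            raise CoverageError("fast_eeg must cover the same pre-discard span")
        basis = (hrf_basis(tr_s, name="hrf") if eeg_basis == "canonical"
                 else eeg_hrf_basis(tr_s))
        eeg_names: list[str] = []
        for band in ("alpha", "delta", "theta"):
            conv = convolve_tr(fast_eeg[band].to_numpy(), basis)
            for j, kname in enumerate(basis.column_names):
                nm = f"{band}_{kname}"
                cols[nm] = conv[:, j]
                eeg_names.append(nm)
        groups["fast_eeg"] = eeg_names

    frame = pd.DataFrame(cols).iloc[n_discard:].reset_index(drop=True)

    if events is not None:
        stim = stimulus_covariates(events, n_full, tr_s, n_discard=n_discard)
        for c in stim.columns:
            frame[c] = stim[c].to_numpy()
        groups["stimulus"] = list(stim.columns)

    if z_score:
        frame = pd.DataFrame(zscore_columns(frame.to_numpy()), columns=frame.columns)

    return DesignMatrix(frame=frame, groups=groups, z_scored=z_score, tr_s=tr_s)
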