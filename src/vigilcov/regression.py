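"""Windowed fMRI-autonomic covariance regression and its inference.

The core statistic: within each window, ordinary least squares of the fMRI
signal on a z-scored regressor group yields the coefficient of determination
R^2 — the percentage of fMRI variance explained by, e.g., the 13 convolved
autonomic regressors. Per-window R^2 values, pooled across sessions within a
condition, are then rank-correlated (Spearman) with the shifted baseline
vigilance of each window; significance comes from a two-tailed permutation
test (10,000 shuffles of the vigilance values, add-one corrected), with
Benjamini-Hochberg FDR control across regions and percentile bootstrap
confidence intervals (2,000 window resamples).

When stimulus covariates are modeled, their explained variance is removed
from the target before the group fit (Frisch-Waugh residualization), so the
reported R^2 attributes only variance the nuisance columns cannot claim.
Comparisons between groups of unequal size (nine fast-EEG vs 13 autonomic
regressors) use adjusted R^2, floored at zero to keep the percent-variance
reading.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DegenerateInputError, InsufficientDataError, ParameterError
from .kernels import zscore_columns
from .vigilance import spearman_permutation
from .windows import WindowSet

logger = logging.getLogger(__name__)


@dataclass
class WindowR2:
    """Variance explained in one window by one regressor group."""

    window_id: int
    region: str
    r2_pct: float
    r2_adj_pct: float
    n_regressors: int
    group: str = "autonomic"


@dataclass
class VigilanceAssociation:
    """Pooled-window Spearman association of R^2 (or FC) with baseline vigilance."""

    region: str
    rho: float
    p_perm: float
    q_fdr: bool | None = None
    ci95: tuple[float, float] | None = None


# ----------------------------------------------------------------------- OLS

def _ols_residual(y: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Residual of ``y`` (1-D or 2-D) on ``[1, x]`` via least squares."""
    n = y.shape[0]
    design = np.column_stack([np.ones(n), x]) if x.size else np.ones((n, 1))
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def _drop_dependent_columns(x: np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Drop linearly dependent columns (rank-revealing QR), with a warning."""
    if x.shape[1] == 0:
        return x
    _, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    if np.all(diag > tol * diag.max()):
        return x
    # greedy forward selection keeps the earliest independent columns
    cols: list[int] = []
    for j in range(x.shape[1]):
        if np.linalg.matrix_rank(x[:, cols + [j]]) == len(cols) + 1:
            cols.append(j)
    logger.warning("dropping %d linearly dependent design columns",
                   x.shape[1] - len(cols))
    return x[:, cols]


def window_r2(
    fmri_window: np.ndarray,
    design_window: np.ndarray,
    adjust: bool = False,
    stimulus_window: np.ndarray | None = None,
    window_id: int = 0,
    region: str = "global",
    group: str = "autonomic",
) -> WindowR2:
    """OLS R^2 (in %) of one window's fMRI signal on a z-scored regressor group.

    The design is z-scored within the window. If ``stimulus_window`` is
    given, both target and design are first residualized on the stimulus
    columns (regressors of no interest), and R^2 is computed on the
    residualized target. ``adjust=True`` applies
    ``1 - (1 - R^2)(n - 1)/(n - p - 1)``, floored at 0.
    """
    y = np.asarray(fmri_window, dtype=float).ravel()
    x = zscore_columns(np.asarray(design_window, dtype=float))
    x = _drop_dependent_columns(x)
    n, p = x.shape
    if n <= p + 2:
        raise InsufficientDataError(
            f"window of {n} TRs cannot support {p} regressors (need n > p + 2)"
        )
    if stimulus_window is not None and stimulus_window.size:
        s = zscore_columns(np.asarray(stimulus_window, dtype=float))
        y = _ols_residual(y, s)
        x = _ols_residual(x, s)
        sd = x.std(axis=0)
        ok = sd > 1e-12
        if not ok.all():
            logger.warning("dropping %d design columns absorbed by stimulus "
                           "covariates", int((~ok).sum()))
            x = x[:, ok]
            p = x.shape[1]

    sst = float(np.sum((y - y.mean()) ** 2))
    if sst <= 0:
        raise DegenerateInputError("fMRI window has zero variance")
    resid = _ols_residual(y, x)
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    r2 = min(max(r2, 0.0), 1.0)
    r2_adj = 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
    if r2_adj < 0:
        logger.debug("adjusted R^2 %.3f floored at 0 (window %d)", r2_adj, window_id)
        r2_adj = 0.0
    return WindowR2(window_id=window_id, region=region, r2_pct=100 * r2,
                    r2_adj_pct=100 * r2_adj, n_regressors=p, group=group)


def windowed_r2_series(
    fmri: np.ndarray,
    design: np.ndarray,
    windows: WindowSet,
    adjust: bool = False,
    stimulus: np.ndarray | None = None,
    region: str = "global",
    group: str = "autonomic",
) -> list[WindowR2]:
    """Apply :func:`window_r2` to every window of a session."""
    out = []
    for i, sl in enumerate(windows.slices()):
        stim = stimulus[sl] if stimulus is not None else None
        out.append(window_r2(fmri[sl], design[sl], adjust=adjust,
                             stimulus_window=stim, window_id=i,
                             region=region, group=group))
    return out


# ------------------------------------------------------------------ inference

def vigilance_association(
    r2_per_window: np.ndarray,
    baseline_vig_shifted: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
    region: str = "global",
) -> VigilanceAssociation:
    """Spearman rho of pooled window R^2 against shifted baseline vigilance.

    Two-tailed permutation p over ``n_perm`` shuffles of the vigilance
    values (seeded stream). Windows with NaN in either variable are dropped;
    fewer than 6 usable windows raises :class:`InsufficientDataError`.
    """
    r2 = np.asarray(r2_per_window, dtype=float)
    vig = np.asarray(baseline_vig_shifted, dtype=float)
    ok = ~np.isnan(r2) & ~np.isnan(vig)
    if ok.sum() < 6:
        raise InsufficientDataError(f"only {int(ok.sum())} windows; need at least 6")
    rho, p = spearman_permutation(r2[ok], vig[ok], n_perm=n_perm, rng=rng)
    return VigilanceAssociation(region=region, rho=rho, p_perm=p)


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at FDR level ``q``."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any(~np.isfinite(p)):
        raise ParameterError("p-values must be finite")
    reject, *_ = multipletests(p, alpha=q, method="fdr_bh")
    return reject


def bootstrap_ci(
    r2: np.ndarray,
    vigilance: np.ndarray,
    n_boot: int = 2_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Percentile 95% CI on Spearman rho from resampling windows with replacement.

    Degenerate resamples (either variable constant) are redrawn; the redraw
    count is logged.
    """
    r2 = np.asarray(r2, dtype=float)
    vig = np.asarray(vigilance, dtype=float)
    ok = ~np.isnan(r2) & ~np.isnan(vig)
    r2, vig = r2[ok], vig[ok]
    n = r2.size
    if n < 3:
        raise InsufficientDataError("need at least 3 windows to bootstrap")
    rng = rng if rng is not None else np.random.default_rng()
    rhos = np.empty(n_boot)
    redraws = 0
    for b in range(n_boot):
        while True:
            idx = rng.integers(0, n, size=n)
            if np.unique(r2[idx]).size > 1 and np.unique(vig[idx]).size > 1:
                break
            redraws += 1
        rhos[b] = stats.spearmanr(r2[idx], vig[idx]).statistic
    if redraws:
        logger.info("redrew %d degenerate bootstrap resamples", redraws)
    return float(np.percentile(rhos, 2.5)), float(np.percentile(rhos, 97.5))


# ----------------------------------------------------------- orthogonalization

def partial_out(target_group: np.ndarray, nuisance_group: np.ndarray) -> np.ndarray:
    """Residualize each target column on the full nuisance group, re-z-scored.

    Columns whose residual collapses (the target lay in the nuisance span)
    are dropped with a warning. Residuals are orthogonal to every nuisance
    column by construction.
    """
    t = np.asarray(target_group, dtype=float)
    nu = np.asarray(nuisance_group, dtype=float)
    if nu.shape[1] + 1 >= t.shape[0]:
        raise ParameterError("nuisance rank must be below the window length")
    resid = _ols_residual(t, nu)
    sd = resid.std(axis=0)
    keep = sd > 1e-10 * max(np.abs(t).max(), 1.0)
    if not keep.all():
        logger.warning("partial_out dropped %d columns fully explained by the "
                       "nuisance group", int((~keep).sum()))
    return zscore_columns(resid[:, keep])


def collinearity_check(
    stimulus_column: np.ndarray,
    autonomic_group: np.ndarray,
    windows: WindowSet,
) -> tuple[float, float, np.ndarray]:
    """Per-window R^2 of the convolved stimulus train on the autonomic group.

    Quantifies how much stimulus-locked variance the autonomic regressors can
    absorb. Returns (mean %, SD %, per-window %).
    """
    vals = np.array([
        window_r2(stimulus_column[sl], autonomic_group[sl], window_id=i,
                  region="stimulus", group="collinearity").r2_pct
        for i, sl in enumerate(windows.slices())
    ])
    return float(vals.mean()), float(vals.std(ddof=1)), vals


def remove_autonomic_from_fmri(fmri: np.ndarray,
                               autonomic_design: np.ndarray) -> np.ndarray:
    """OLS residual of each ROI/voxel series on the z-scored autonomic design."""
    y = np.asarray(fmri, dtype=float)
    x = zscore_columns(np.asarray(autonomic_design, dtype=float))
    return _ols_residual(y, x)


def flag_pwa_outlier_windows(pwa_window_means: np.ndarray,
                             mad_factor: float = 5.0) -> np.ndarray:
    """Automated stand-in for manual outlier-window exclusion.

    Flags windows whose mean PWA lies more than ``mad_factor`` median
    absolute deviations from the pooled median. This rule is this package's
    own; the original exclusions were made by inspection.
    """
    v = np.asarray(pwa_window_means, dtype=float)
    med = np.median(v)
    mad = np.median(np.abs(v - med))
    if mad == 0:
        return np.zeros(v.size, dtype=bool)
    return np.abs(v - med) > mad_factor * mad
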