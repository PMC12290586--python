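"""Windowed functional connectivity and its vigilance association.

FC is the pairwise Pearson correlation of network-mean fMRI time series
within each window, Fisher z-transformed (atanh). With 8 networks (7
cortical + subcortex) the lower triangle gives C(8,2) = 28 unique pairs,
vectorized row-major for pattern comparisons. Per-pair Fisher-z values,
pooled over windows, are rank-correlated with shifted baseline vigilance
(Spearman + permutation p), with Benjamini-Hochberg FDR control across the
28 pairs. Task-vs-rest (or raw-vs-partialled) FC patterns are compared as
Pearson correlations between 28-element vectors with permutation p-values.

A correlation of exactly +/-1 within a window raises an error rather than
being clipped: silently saturating atanh would corrupt permutation nulls.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, ParameterError
from .regression import bh_fdr
from .vigilance import spearman_permutation
from .windows import WindowSet

R_SATURATION_TOL = 1e-12


@dataclass
class FCWindow:
    """Fisher-z connectivity matrix for one window."""

    window_id: int
    z_matrix: np.ndarray
    condition: str = "rest"
    mode: str = "raw"


def pair_labels(names: list[str]) -> list[tuple[str, str]]:
    """Row-major lower-triangle ordering of network pairs."""
    return [(names[i], names[j]) for i in range(len(names)) for j in range(i)]


def lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Row-major lower-triangle vector (length C(n,2))."""
    m = np.asarray(matrix)
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def window_fc(roi_series: np.ndarray, window: slice | tuple[int, int],
              window_id: int = 0, condition: str = "rest",
              mode: str = "raw") -> FCWindow:
    """Pairwise Pearson r within one window, Fisher z-transformed.

    ``roi_series`` is (n_tr, n_networks), already network-averaged,
    high-passed, and (per ``mode``) nuisance-cleaned. Constant series and
    correlations at machine-|1| raise errors.
    """
    sl = window if isinstance(window, slice) else slice(*window)
    x = np.asarray(roi_series, dtype=float)[sl]
    if x.shape[0] < 4:
        raise ParameterError("window too short for a correlation estimate")
    sd = x.std(axis=0)
    if np.any(sd == 0):
        raise DegenerateInputError(
            f"network series constant in window {window_id}; FC undefined"
        )
    r = np.corrcoef(x, rowvar=False)
    off = ~np.eye(r.shape[0], dtype=bool)
    if np.any(np.abs(r[off]) >= 1.0 - R_SATURATION_TOL):
        raise DegenerateInputError(
            f"|r| at machine 1 in window {window_id}; Fisher z undefined "
            "(duplicated network series?)"
        )
    np.fill_diagonal(r, 0.0)      # diagonal is undefined; keep z finite
    z = np.arctanh(r)
    return FCWindow(window_id=window_id, z_matrix=z, condition=condition, mode=mode)


def fc_windows(roi_series: np.ndarray, windows: WindowSet,
               condition: str = "rest", mode: str = "raw") -> list[FCWindow]:
    """FC matrix for every window of a session."""
    return [window_fc(roi_series, sl, window_id=i, condition=condition, mode=mode)
            for i, sl in enumerate(windows.slices())]


def fc_vigilance_association(
    fc_list: list[FCWindow],
    baseline_vig: np.ndarray,
    n_perm: int = 10_000,
    q: float = 0.05,
    rng: np.random.Generator | None = None,
) -> dict[str, np.ndarray]:
    """Per-pair Spearman rho, permutation p, and BH-FDR flags across pairs.

    Windows with NaN baseline vigilance are dropped. Returns arrays of
    length C(n,2) keyed ``rho``, ``p``, ``flag``.
    """
    z = np.stack([lower_triangle(fc.z_matrix) for fc in fc_list])   # (w, pairs)
    vig = np.asarray(baseline_vig, dtype=float)
    ok = ~np.isnan(vig)
    z, vig = z[ok], vig[ok]
    rng = rng if rng is not None else np.random.default_rng()
    n_pairs = z.shape[1]
    rho = np.empty(n_pairs)
    p = np.empty(n_pairs)
    for k in range(n_pairs):
        rho[k], p[k] = spearman_permutation(z[:, k], vig, n_perm=n_perm, rng=rng)
    return {"rho": rho, "p": p, "flag": bh_fdr(p, q=q)}


def pattern_similarity(
    pattern_a: np.ndarray,
    pattern_b: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Pearson r between two FC pattern vectors, permutation p (shuffle one).

    Both patterns must share length and pair ordering.
    """
    a = np.asarray(pattern_a, dtype=float)
    b = np.asarray(pattern_b, dtype=float)
    if a.size != b.size:
        raise ParameterError(f"pattern lengths differ: {a.size} vs {b.size}")
    if a.std() == 0 or b.std() == 0:
        raise DegenerateInputError("constant FC pattern; correlation undefined")
    r = float(stats.pearsonr(a, b).statistic)
    rng = rng if rng is not None else np.random.default_rng()
    az = (a - a.mean()) / a.std()
    bz = (b - b.mean()) / b.std()
    perm = rng.permuted(np.tile(bz, (n_perm, 1)), axis=1) @ az / a.size
    p = (1.0 + np.count_nonzero(np.abs(perm) >= abs(r) - 1e-12)) / (1.0 + n_perm)
    return r, float(p)
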