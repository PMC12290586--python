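"""Windowed R^2, permutation inference, FDR, bootstrap, orthogonalization."""

import numpy as np
import pytest

from vigilcov import (bh_fdr, bootstrap_ci, collinearity_check, partial_out,
                      remove_autonomic_from_fmri, segment, vigilance_association,
                      window_r2, windowed_r2_series)
from vigilcov.errors import DegenerateInputError, InsufficientDataError


def _brute_force_r2(y, x):
    """Normal-equations oracle: R^2 via explicit Gram-matrix solve."""
    x = (x - x.mean(0)) / x.std(0)
    design = np.column_stack([np.ones(y.size), x])
    beta = np.linalg.solve(design.T @ design, design.T @ y)
    resid = y - design @ beta
    sst = np.sum((y - y.mean()) ** 2)
    return 100.0 * (1.0 - np.sum(resid**2) / sst)


class TestWindowR2:
    def test_exact_regressor_gives_100(self, rng):
        x = rng.standard_normal((60, 3))
        y = x[:, 1].copy()
        assert window_r2(y, x).r2_pct == pytest.approx(100.0, abs=1e-8)

    def test_orthogonal_target_gives_zero(self, rng):
        x = rng.standard_normal((60, 3))
        y = rng.standard_normal(60)
        # residualize y on [1, x] so it is exactly orthogonal by construction
        d = np.column_stack([np.ones(60), x])
        y = y - d @ np.linalg.lstsq(d, y, rcond=None)[0]
        assert window_r2(y, x).r2_pct == pytest.approx(0.0, abs=1e-8)

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(100):
            n = int(rng.integers(40, 80))
            p = int(rng.integers(2, 10))
            x = rng.standard_normal((n, p))
            y = rng.standard_normal(n)
            assert window_r2(y, x).r2_pct == pytest.approx(
                _brute_force_r2(y, x), abs=1e-8)

    def test_null_r2_expectation(self, rng):
        """Gaussian target on p random regressors: E[R^2] ~ p/(n-1), adjusted ~ 0."""
        n, p, draws = 60, 5, 1000
        r2 = np.empty(draws)
        adj = np.empty(draws)
        for i in range(draws):
            w = window_r2(rng.standard_normal(n), rng.standard_normal((n, p)),
                          adjust=True)
            r2[i] = w.r2_pct
            adj[i] = w.r2_adj_pct
        assert r2.mean() == pytest.approx(100 * p / (n - 1), abs=1.0)
        # flooring at 0 biases the adjusted mean slightly upward
        assert adj.mean() < 5.0

    def test_too_many_regressors_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            window_r2(rng.standard_normal(20), rng.standard_normal((20, 18)))

    def test_rank_deficient_design_columns_dropped(self, rng):
        x = rng.standard_normal((60, 3))
        x = np.column_stack([x, x[:, 0] * 2.0])
        w = window_r2(rng.standard_normal(60), x)
        assert w.n_regressors == 3

    def test_stimulus_residualization_removes_stim_variance(self, rng):
        stim = rng.standard_normal((60, 2))
        x = rng.standard_normal((60, 3))
        y = 5.0 * stim[:, 0] + x[:, 0]
        with_stim = window_r2(y, x, stimulus_window=stim).r2_pct
        # after removing the stimulus component, x explains nearly everything
        assert with_stim > 99.0

    def test_adjusted_never_exceeds_raw(self, rng):
        for _ in range(20):
            w = window_r2(rng.standard_normal(60), rng.standard_normal((60, 6)),
                          adjust=True)
            assert w.r2_adj_pct <= w.r2_pct + 1e-12


class TestVigilanceAssociation:
    def test_monotone_decreasing_gives_minus_one(self, rng):
        vig = np.arange(10.0)
        r2 = 100.0 - 5.0 * vig
        a = vigilance_association(r2, vig, n_perm=500, rng=rng)
        assert a.rho == pytest.approx(-1.0)
        assert a.p_perm <= 0.02

    def test_monotone_transform_invariance(self, rng):
        r2 = rng.random(15)
        vig = rng.random(15)
        a1 = vigilance_association(r2, vig, n_perm=10,
                                   rng=np.random.default_rng(0))
        a2 = vigilance_association(np.exp(r2), vig**3, n_perm=10,
                                   rng=np.random.default_rng(0))
        assert a1.rho == pytest.approx(a2.rho, abs=1e-12)

    def test_too_few_windows_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            vigilance_association(np.arange(5.0), np.arange(5.0), n_perm=10,
                                  rng=rng)


class TestBhFdr:
    def test_all_ones_no_flags(self):
        assert not bh_fdr(np.ones(10)).any()

    def test_textbook_example(self):
        flags = bh_fdr(np.array([0.001, 0.011, 0.02, 0.8]), q=0.05)
        assert list(flags) == [True, True, True, False]

    def test_matches_exhaustive_threshold_oracle(self, rng):
        def oracle(p, q):
            m = p.size
            order = np.argsort(p)
            ps = p[order]
            k_star = 0
            for k in range(1, m + 1):
                if ps[k - 1] <= k * q / m:
                    k_star = k
            flags = np.zeros(m, dtype=bool)
            if k_star:
                flags[order[:k_star]] = True
            return flags

        for _ in range(1000):
            p = rng.random(int(rng.integers(1, 40)))
            assert np.array_equal(bh_fdr(p, q=0.05), oracle(p, 0.05))

    def test_flags_monotone_in_p(self, rng):
        p = rng.random(30)
        flags = bh_fdr(p)
        if flags.any() and (~flags).any():
            assert p[flags].max() <= p[~flags].min() + 1e-15


class TestBootstrap:
    def test_perfectly_monotone_collapses(self, rng):
        x = np.arange(10.0)
        lo, hi = bootstrap_ci(100 - x, x, n_boot=200, rng=rng)
        assert lo == pytest.approx(-1.0, abs=1e-12)
        assert hi == pytest.approx(-1.0, abs=1e-12)

    def test_interval_contains_point_estimate(self, rng):
        from scipy import stats
        x = rng.random(30)
        y = 0.5 * x + rng.random(30)
        lo, hi = bootstrap_ci(y, x, n_boot=500, rng=rng)
        rho = stats.spearmanr(y, x).statistic
        assert lo <= rho <= hi

    def test_coverage_near_nominal(self):
        """~95% of intervals should cover the true rank correlation."""
        from scipy import stats
        rng = np.random.default_rng(0)
        true_rho_hits = 0
        trials = 100
        n = 60
        # bivariate normal with known Pearson r -> Spearman rho via sin formula
        r = 0.5
        true_rho = 6 / np.pi * np.arcsin(r / 2)
        for _ in range(trials):
            z = rng.multivariate_normal([0, 0], [[1, r], [r, 1]], size=n)
            lo, hi = bootstrap_ci(z[:, 0], z[:, 1], n_boot=300, rng=rng)
            if lo <= true_rho <= hi:
                true_rho_hits += 1
        assert 0.85 <= true_rho_hits / trials <= 1.0


class TestPartialling:
    def test_orthogonal_target_unchanged_up_to_zscore(self, rng):
        nu = rng.standard_normal((100, 3))
        t = rng.standard_normal((100, 2))
        d = np.column_stack([np.ones(100), nu])
        t_orth = t - d @ np.linalg.lstsq(d, t, rcond=None)[0]
        out = partial_out(t_orth, nu)
        tz = (t_orth - t_orth.mean(0)) / t_orth.std(0)
        assert np.allclose(out, tz, atol=1e-8)

    def test_residuals_orthogonal_to_nuisance(self, rng):
        nu = rng.standard_normal((100, 4))
        t = rng.standard_normal((100, 3)) + nu[:, :3]
        out = partial_out(t, nu)
        assert np.abs(out.T @ nu).max() < 1e-8 * 100

    def test_column_in_nuisance_span_dropped(self, rng):
        nu = rng.standard_normal((100, 3))
        t = np.column_stack([nu[:, 0], rng.standard_normal(100)])
        out = partial_out(t, nu)
        assert out.shape[1] == 1


class TestNuisanceRemoval:
    def test_exact_combination_annihilated(self, rng):
        x = rng.standard_normal((100, 4))
        y = x @ np.array([1.0, -2.0, 0.5, 3.0])
        resid = remove_autonomic_from_fmri(y, x)
        assert np.abs(resid).max() < 1e-8

    def test_variance_never_increases(self, rng):
        x = rng.standard_normal((100, 4))
        y = rng.standard_normal((100, 5))
        resid = remove_autonomic_from_fmri(y, x)
        assert np.all(resid.var(axis=0) <= y.var(axis=0) + 1e-12)


class TestCollinearity:
    def test_stimulus_inside_group_gives_100(self, rng):
        x = rng.standard_normal((120, 3))
        ws = segment(120, 60)
        mean, sd, vals = collinearity_check(x[:, 0].copy(), x, ws)
        assert mean == pytest.approx(100.0, abs=1e-8)

    def test_independent_noise_near_null_expectation(self, rng):
        n_win, length, p = 40, 60, 3
        ws = segment(n_win * length, length)
        stim = rng.standard_normal(n_win * length)
        group = rng.standard_normal((n_win * length, p))
        mean, sd, vals = collinearity_check(stim, group, ws)
        assert mean == pytest.approx(100 * p / (length - 1), abs=3.0)


def test_windowed_series_matches_per_window_calls(rng):
    y = rng.standard_normal(180)
    x = rng.standard_normal((180, 4))
    ws = segment(180, 60)
    series = windowed_r2_series(y, x, ws)
    for w, sl in zip(series, ws.slices()):
        assert w.r2_pct == pytest.approx(window_r2(y[sl], x[sl]).r2_pct)
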