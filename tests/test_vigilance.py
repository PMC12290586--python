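"""EEG band RMS, vigilance indices, baseline windows, RT validation."""

import numpy as np
import pandas as pd
import pytest

from vigilcov import (band_rms_per_tr, baseline_vigilance, segment,
                      spearman_permutation, validate_vigilance, vigilance_index)
from vigilcov.errors import (DegenerateInputError, InsufficientDataError,
                             ParameterError)


class TestBandRms:
    def test_zero_eeg_gives_zero_bands_and_undefined_ratio(self):
        eeg = np.zeros((2, 25000))
        out = band_rms_per_tr(eeg, rate_hz=250.0, tr_s=2.1, n_trs=40)
        assert np.allclose(out[["alpha", "theta", "delta"]], 0.0)
        with pytest.raises(DegenerateInputError):
            vigilance_index(out)

    def test_alpha_sine_lands_in_alpha_band(self):
        rate, n_trs = 250.0, 20
        t = np.arange(int(n_trs * 2.1 * rate) + 100) / rate
        eeg = np.sin(2 * np.pi * 10.0 * t)[None, :]
        out = band_rms_per_tr(eeg, rate, 2.1, n_trs)
        inner = out.iloc[2:-2]      # avoid filter edge transients
        assert np.allclose(inner["alpha"], 1 / np.sqrt(2), atol=0.05)
        assert (inner["theta"] <= 0.05).all()

    def test_channel_mean_is_average_of_channel_rms(self):
        rate, n_trs = 250.0, 10
        n = int(n_trs * 2.1 * rate) + 50
        t = np.arange(n) / rate
        base = np.sin(2 * np.pi * 10.0 * t)
        out = band_rms_per_tr(np.vstack([base, 3 * base]), rate, 2.1, n_trs)
        single = band_rms_per_tr(base[None, :], rate, 2.1, n_trs)
        assert np.allclose(out["alpha"], 2 * single["alpha"], rtol=1e-10)

    def test_too_short_recording_raises(self):
        with pytest.raises(Exception):
            band_rms_per_tr(np.zeros((1, 100)), 250.0, 2.1, 40)

    def test_index_invariant_to_common_channel_scaling(self):
        rate, n_trs = 250.0, 10
        n = int(n_trs * 2.1 * rate) + 50
        rng = np.random.default_rng(0)
        eeg = rng.standard_normal((3, n))
        r1 = vigilance_index(band_rms_per_tr(eeg, rate, 2.1, n_trs))
        r2 = vigilance_index(band_rms_per_tr(7.3 * eeg, rate, 2.1, n_trs))
        assert np.allclose(r1, r2, rtol=1e-10)


class TestVigilanceIndex:
    def test_alpha_equals_theta_gives_one(self):
        df = pd.DataFrame({"alpha": [2.0, 3.0], "theta": [2.0, 3.0],
                           "delta": [1.0, 1.0]})
        assert np.allclose(vigilance_index(df), 1.0)

    def test_simple_ratio(self):
        df = pd.DataFrame({"alpha": [2.0], "theta": [1.0], "delta": [5.0]})
        assert vigilance_index(df)[0] == 2.0

    def test_alternative_index(self):
        df = pd.DataFrame({"alpha": [1.0], "theta": [1.0], "delta": [1.0]})
        assert vigilance_index(df, mode="alpha/(delta+theta)")[0] == 0.5

    def test_unknown_mode_rejected(self):
        df = pd.DataFrame({"alpha": [1.0], "theta": [1.0], "delta": [1.0]})
        with pytest.raises(ParameterError):
            vigilance_index(df, mode="beta/theta")


class TestBaselineVigilance:
    def test_constant_ratio_any_shift(self):
        ws = segment(300, 60)
        for shift in (0, 2):
            out = baseline_vigilance(np.full(300, 1.3), ws, shift_trs=shift)
            kept = out[~np.isnan(out)]
            assert np.allclose(kept, 1.3)

    def test_mean_of_first_window_is_295(self):
        ws = segment(300, 60)
        out = baseline_vigilance(np.arange(300, dtype=float), ws, shift_trs=0)
        assert out[0] == pytest.approx(29.5)    # mean of 0..59

    def test_shift_equals_preadvanced_series(self):
        rng = np.random.default_rng(3)
        ratio = rng.random(300)
        ws = segment(240, 60)
        shifted = baseline_vigilance(ratio[:300], ws, shift_trs=2)
        pre = baseline_vigilance(ratio[2:302], ws, shift_trs=0)
        assert np.allclose(shifted, pre, equal_nan=True)

    def test_tail_window_dropped_when_shift_overruns(self):
        ws = segment(120, 60)
        out = baseline_vigilance(np.arange(120, dtype=float), ws, shift_trs=2)
        assert np.isnan(out[-1]) and not np.isnan(out[0])

    def test_excessive_shift_rejected(self):
        ws = segment(120, 60)
        with pytest.raises(ParameterError):
            baseline_vigilance(np.zeros(120), ws, shift_trs=60)


class TestValidation:
    def _events(self, onsets, rts):
        return pd.DataFrame({"onset_s": onsets, "rt_s": rts,
                             "responded": ~np.isnan(rts)})

    def test_monotone_rt_gives_rho_minus_one(self):
        ws = segment(360, 60)
        baseline = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        onsets = np.array([10.0, 140.0, 270.0, 400.0, 530.0, 660.0])
        rts = np.array([0.5, 1.0, 1.5, 2.0, 2.5, 3.0])
        rho, p = validate_vigilance(baseline, self._events(onsets, rts), ws,
                                    tr_s=2.1, n_perm=500,
                                    rng=np.random.default_rng(0))
        assert rho == pytest.approx(-1.0)
        # near the attainable floor: only permutations with |rho| = 1 count
        assert p <= 0.01

    def test_tied_vigilance_rejected(self):
        ws = segment(360, 60)
        onsets = np.array([10.0, 140.0, 270.0, 400.0, 530.0, 660.0])
        rts = np.linspace(0.5, 3.0, 6)
        with pytest.raises(DegenerateInputError):
            validate_vigilance(np.ones(6), self._events(onsets, rts), ws,
                               tr_s=2.1, n_perm=100)

    def test_too_few_windows_with_data(self):
        ws = segment(360, 60)
        onsets = np.array([10.0, 140.0])
        rts = np.array([0.5, 1.0])
        with pytest.raises(InsufficientDataError):
            validate_vigilance(np.arange(6.0), self._events(onsets, rts), ws,
                               tr_s=2.1, n_perm=100)

    def test_impute_policy_uses_missing_events(self):
        ws = segment(360, 60)
        baseline = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        onsets = np.array([10.0, 140.0, 270.0, 400.0, 530.0, 660.0])
        rts = np.array([0.5, 1.0, 1.5, 2.0, 2.5, np.nan])
        rho_d, _ = validate_vigilance(baseline, self._events(onsets, rts), ws,
                                      tr_s=2.1, missing_policy="drop",
                                      n_perm=200, rng=np.random.default_rng(0))
        rho_i, _ = validate_vigilance(baseline, self._events(onsets, rts), ws,
                                      tr_s=2.1, missing_policy="impute_4s",
                                      n_perm=200, rng=np.random.default_rng(0))
        assert rho_d == pytest.approx(-1.0)     # 5 usable windows, monotone
        assert rho_i == pytest.approx(-1.0)     # imputed 4-s RT keeps the order

    def test_simulated_sessions_show_negative_rt_link(self):
        """Monte-Carlo: generator's RT coupling is recovered through the op."""
        import dataclasses
        import vigilcov as vc
        rhos = []
        for seed in range(10):
            cfg = vc.SimulationConfig(seed=seed)
            s = vc.simulate_session(cfg)
            nd = 7
            ratio = vc.vigilance_index(s.eeg_power)[nd:]
            ws = segment(cfg.n_tr - nd, 60)
            base = baseline_vigilance(ratio, ws, shift_trs=0)
            ev = s.events.copy()
            ev["onset_s"] -= nd * cfg.tr_s
            ev = ev[ev["onset_s"] >= 0]
            try:
                rho, _ = validate_vigilance(base, ev, ws, tr_s=cfg.tr_s,
                                            n_perm=200,
                                            rng=np.random.default_rng(seed))
            except InsufficientDataError:
                continue
            rhos.append(rho)
        assert len(rhos) >= 5 and np.median(rhos) < 0


def test_spearman_permutation_matches_scipy():
    from scipy import stats
    rng = np.random.default_rng(8)
    x, y = rng.random(30), rng.random(30)
    rho, _ = spearman_permutation(x, y, n_perm=100, rng=rng)
    assert rho == pytest.approx(stats.spearmanr(x, y).statistic, abs=1e-12)
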