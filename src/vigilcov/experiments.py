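"""Multi-session simulation experiments.

Each function here runs the full pipeline — waveform feature extraction,
design assembly, high-pass, windowed statistics, pooled inference — on
freshly simulated sessions, mirroring how the analysis is applied to a
multi-participant study: windows are pooled across sessions within a
condition before the Spearman step, exactly as the windowed R^2 and
functional-connectivity analyses pool windows across participants.

These are the code paths exercised by the validation suite; they are also
convenient entry points for exploring the method's operating characteristics
(effect recovery, type-I calibration, staging contrasts).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import connectivity, crosscorr, kernels, physio as physio_mod, regression
from . import vigilance as vig_mod, windows as win_mod
from .config import SimulationConfig
from .synthetic import Session, simulate_session

N_DISCARD = 7


@dataclass
class SessionAnalysis:
    """Windowed global-signal analysis of one simulated session."""

    r2_pct: np.ndarray              # per window
    baseline_vigilance: np.ndarray  # per window (shifted)
    windows: win_mod.WindowSet
    session: Session


def analyze_simulated_session(
    config: SimulationConfig,
    window_len_tr: int = 60,
    shift_trs: int = 2,
    use_extraction: bool = True,
) -> SessionAnalysis:
    """Simulate one session and run the windowed global-signal R^2 analysis.

    ``use_extraction=True`` runs the real waveform pipeline (peak detection,
    windowed std, filtering); ``False`` builds the design from the generator's
    per-TR ground-truth autonomic series instead, which isolates the
    regression stage from extraction noise.
    """
    s = simulate_session(config)
    tr = config.tr_s
    if use_extraction:
        auto = physio_mod.extract_autonomic(s.physio, tr, config.n_tr).to_frame()
    else:
        auto = pd.DataFrame({"rv": s.truth.rv_true, "hr": s.truth.hr_true,
                             "pwa": s.truth.pwa_true})
    design = kernels.build_design(auto, tr, n_discard=N_DISCARD)
    ratio = vig_mod.vigilance_index(s.eeg_power)[N_DISCARD:]
    g = s.roi_series[N_DISCARD:].mean(axis=1)

    ws = win_mod.segment(g.size, window_len_tr)
    hp = lambda a: win_mod.highpass_for_windows(  # noqa: E731
        a, window_len_tr * tr, 1.0 / tr)
    r2 = np.array([w.r2_pct for w in regression.windowed_r2_series(
        hp(g), hp(design.group("autonomic")), ws)])
    base = vig_mod.baseline_vigilance(ratio, ws, shift_trs=shift_trs)
    return SessionAnalysis(r2_pct=r2, baseline_vigilance=base, windows=ws, session=s)


def _session_seeds(seed: int, n: int) -> list[int]:
    return [int(x) for x in
            np.random.SeedSequence(seed).generate_state(n) % (2**31 - 1)]


def pooled_recovery(
    config: SimulationConfig | None = None,
    n_sessions: int = 20,
    seed: int = 0,
    n_perm: int = 10_000,
) -> tuple[float, float, int]:
    """Pooled-window Spearman rho of windowed R^2 vs baseline vigilance.

    Simulates ``n_sessions`` sessions (seeds derived from ``seed``), pools
    every window across them within the condition, and returns
    ``(rho, permutation p, n_windows)``. Under the default config (coupling
    gain doubling from high to low vigilance) rho is negative; under the
    null preset it hovers near zero.
    """
    config = config if config is not None else SimulationConfig()
    r2_all, base_all = [], []
    for s in _session_seeds(seed, n_sessions):
        a = analyze_simulated_session(dataclasses.replace(config, seed=s))
        r2_all.append(a.r2_pct)
        base_all.append(a.baseline_vigilance)
    r2 = np.concatenate(r2_all)
    base = np.concatenate(base_all)
    assoc = regression.vigilance_association(
        r2, base, n_perm=n_perm, rng=np.random.default_rng(seed))
    return assoc.rho, assoc.p_perm, int(np.isfinite(base).sum())


def pooled_recovery_median(
    config: SimulationConfig | None = None,
    n_reps: int = 5,
    n_sessions: int = 20,
    seed: int = 0,
    n_perm: int = 10_000,
) -> tuple[float, list[float]]:
    """Median pooled-window rho over independent replicate experiments.

    Each replicate simulates ``n_sessions`` fresh sessions and pools their
    windows; the median over replicates stabilizes the summary against the
    sampling noise of any single pooled correlation.
    """
    reps = []
    for r, s in enumerate(_session_seeds(seed, n_reps)):
        rho, _, _ = pooled_recovery(config=config, n_sessions=n_sessions,
                                    seed=s, n_perm=n_perm)
        reps.append(rho)
    return float(np.median(reps)), reps


def null_rejection_rate(
    n_tests: int = 200,
    seed: int = 0,
    n_perm: int = 10_000,
    alpha: float = 0.05,
) -> tuple[float, np.ndarray]:
    """Type-I calibration of the session-level permutation test.

    Runs ``n_tests`` independent sessions under the null preset (constant
    coupling gain, no vigilance -> autonomic amplitude modulation), performs
    the windowed R^2 vs vigilance permutation test in each, and returns the
    rejection rate at ``alpha`` plus the p-values. With a calibrated test the
    p-values are approximately uniform.
    """
    null_cfg = SimulationConfig().with_null_coupling()
    ps = np.empty(n_tests)
    for i, s in enumerate(_session_seeds(seed, n_tests)):
        a = analyze_simulated_session(dataclasses.replace(null_cfg, seed=s))
        assoc = regression.vigilance_association(
            a.r2_pct, a.baseline_vigilance, n_perm=n_perm,
            rng=np.random.default_rng(s))
        ps[i] = assoc.p_perm
    return float(np.mean(ps <= alpha)), ps


def staged_xcorr_contrast(
    n_sessions: int = 10,
    seed: int = 0,
    window_len_tr: int = win_mod.VOXELWISE_WINDOW_TRS,
) -> dict[str, dict[str, crosscorr.StagedXCorr]]:
    """Cross-correlation curves staged by pooled baseline-vigilance tertiles.

    Simulates sessions under the default (gain-doubling) config, computes
    per-window normalized cross-correlations between the high-passed global
    fMRI signal and each unconvolved autonomic measure over lags -5..+15
    TRs, stages the pooled 241.5-s windows into vigilance tertiles, and
    averages curves within the low/mid/high stages. With stronger coupling
    at low vigilance, the low stage shows the larger peak magnitude.
    """
    cfg = SimulationConfig()
    tr = cfg.tr_s
    curves: dict[str, list[np.ndarray]] = {"RV": [], "HR": [], "PWA": []}
    base_all: list[np.ndarray] = []
    for s in _session_seeds(seed, n_sessions):
        c = dataclasses.replace(cfg, seed=s)
        sess = simulate_session(c)
        auto = physio_mod.extract_autonomic(sess.physio, tr, c.n_tr)
        ratio = vig_mod.vigilance_index(sess.eeg_power)[N_DISCARD:]
        g = sess.roi_series[N_DISCARD:].mean(axis=1)
        ws = win_mod.segment(g.size, window_len_tr)
        hp = lambda a: win_mod.highpass_for_windows(  # noqa: E731
            a, window_len_tr * tr, 1.0 / tr)
        gs = hp(g)
        for name, series in (("RV", auto.rv), ("HR", auto.hr), ("PWA", auto.pwa)):
            sig = hp(np.asarray(series)[N_DISCARD:])
            curves[name].append(crosscorr.windowed_xcov(gs, sig, ws))
        base_all.append(vig_mod.baseline_vigilance(ratio, ws))
    stages, _ = win_mod.stage_tertiles(np.concatenate(base_all))
    return {
        name: crosscorr.staged_average(np.vstack(curveset), stages, signal=name)
        for name, curveset in curves.items()
    }


def fc_partialling_experiment(
    n_sessions: int = 20,
    seed: int = 0,
    n_perm: int = 2_000,
) -> dict[str, np.ndarray]:
    """Effect of autonomic removal on vigilance-FC associations.

    Pools windowed Fisher-z FC across sessions and rank-correlates each of
    the C(n,2) network pairs with baseline vigilance, before and after
    regressing the convolved autonomic design out of the network series.
    Because the simulated networks share a vigilance-gained autonomic
    component, removal should attenuate |rho| for most pairs. Returns
    ``rho_raw``, ``rho_removed``, and the boolean ``attenuated`` per pair.
    """
    cfg = SimulationConfig()
    tr = cfg.tr_s
    z_raw, z_rem, base_all = [], [], []
    for s in _session_seeds(seed, n_sessions):
        c = dataclasses.replace(cfg, seed=s)
        sess = simulate_session(c)
        auto = physio_mod.extract_autonomic(sess.physio, tr, c.n_tr).to_frame()
        design = kernels.build_design(auto, tr, n_discard=N_DISCARD)
        ratio = vig_mod.vigilance_index(sess.eeg_power)[N_DISCARD:]
        rois = sess.roi_series[N_DISCARD:]
        ws = win_mod.segment(rois.shape[0], 60)
        hp = lambda a: win_mod.highpass_for_windows(a, 60 * tr, 1.0 / tr)  # noqa: E731
        rois_hp = hp(rois)
        rois_rem = regression.remove_autonomic_from_fmri(
            rois_hp, hp(design.group("autonomic")))
        base_all.append(vig_mod.baseline_vigilance(ratio, ws))
        z_raw.extend(connectivity.lower_triangle(f.z_matrix)
                     for f in connectivity.fc_windows(rois_hp, ws))
        z_rem.extend(connectivity.lower_triangle(f.z_matrix)
                     for f in connectivity.fc_windows(rois_rem, ws, mode="autonomic_removed"))
    base = np.concatenate(base_all)
    z_raw = np.vstack(z_raw)
    z_rem = np.vstack(z_rem)
    ok = np.isfinite(base)
    rho_raw = np.array([stats.spearmanr(z_raw[ok, k], base[ok]).statistic
                        for k in range(z_raw.shape[1])])
    rho_rem = np.array([stats.spearmanr(z_rem[ok, k], base[ok]).statistic
                        for k in range(z_rem.shape[1])])
    return {"rho_raw": rho_raw, "rho_removed": rho_rem,
            "attenuated": np.abs(rho_rem) <= np.abs(rho_raw)}
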