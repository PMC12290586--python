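"""Synthetic session generator with known ground truth.

A single latent vigilance trajectory (a reflected Ornstein-Uhlenbeck path on
the scale of the EEG alpha/theta ratio) drives everything in one simulated
scan:

* EEG band amplitudes per TR (alpha tracks vigilance, theta/delta rise as it
  falls), so the recovered alpha/theta ratio estimates the latent state;
* autonomic ground truth: the inter-beat interval lengthens, and respiration
  depth and pulse amplitude grow, as vigilance falls;
* raw physiological waveforms: a respiration-belt sinusoid with slowly
  varying rate and depth, and a photoplethysmogram built from asymmetric
  gamma-shaped pulses (width ~0.3 s) placed at the simulated beat times;
* fMRI ROI time series: a vigilance-dependent gain multiplies the sum of the
  convolved autonomic signals (RV * RRF, HR * CRF, PWA * HRF), plus
  canonical-HRF responses to responded task tones and AR(1) noise in percent
  signal change;
* an auditory-task event train with uniform 29-41 s inter-stimulus intervals,
  miss probability rising and reaction time lengthening as vigilance falls
  (reaction times above 4 s are recorded as missing).

Because the coupling gain is a known monotone (affine, clamped) function of
the latent vigilance, every downstream estimate has a recoverable truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import kernels
from .config import SimulationConfig
from .errors import ParameterError

logger = logging.getLogger(__name__)

IBI_HARD_BOUNDS_S = (0.3, 3.0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    vigilance_latent: np.ndarray      # per TR, a.u. (alpha/theta scale)
    coupling_gain: np.ndarray         # per TR, unitless
    ibi_true: np.ndarray              # per beat, seconds
    beat_times_s: np.ndarray          # per beat
    rv_true: np.ndarray               # per TR, a.u. (respiration depth)
    pwa_true: np.ndarray              # per TR, a.u. (pulse amplitude)
    hr_true: np.ndarray               # per TR, bpm (from the IBI curve)
    event_onsets_s: np.ndarray
    responded: np.ndarray             # bool per event


@dataclass
class PhysioRecording:
    """Raw waveforms aligned to the scanner trigger (t = 0 at first volume)."""

    time_s: np.ndarray
    resp: np.ndarray
    ppg: np.ndarray
    rate_hz: float
    trigger_onset_s: float = 0.0


@dataclass
class Session:
    """One full synthetic scan."""

    config: SimulationConfig
    truth: GroundTruth
    physio: PhysioRecording
    eeg_power: pd.DataFrame           # tr_index, alpha, theta, delta
    events: pd.DataFrame              # onset_s, responded, rt_s (NaN = missing)
    roi_series: np.ndarray            # (n_tr, n_rois), % signal change
    voxel_series: np.ndarray | None = None   # (n_tr, n_rois * n_voxels_per_roi)
    voxel_labels: np.ndarray | None = None   # ROI label (1-based) per voxel


# ----------------------------------------------------------------- vigilance

def simulate_vigilance_trajectory(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Reflected Ornstein-Uhlenbeck vigilance path sampled on the TR grid.

    Uses the exact OU transition over each TR step, starting at the
    stationary mean (the midpoint of the bounds), and reflects excursions
    back into ``[v_min, v_max]``. With ``ou_sigma = 0`` the path is constant.
    """
    vm = config.vigilance_model
    if vm.ou_theta <= 0 or vm.ou_sigma < 0:
        raise ParameterError("ou_theta must be > 0 and ou_sigma >= 0")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_tr
    dt = config.tr_s
    mu = 0.5 * (vm.v_min + vm.v_max)
    decay = np.exp(-vm.ou_theta * dt)
    step_sd = vm.ou_sigma * np.sqrt((1 - decay**2) / (2 * vm.ou_theta))
    eps = rng.standard_normal(n - 1)
    v = np.empty(n)
    v[0] = mu
    for t in range(1, n):
        x = mu + (v[t - 1] - mu) * decay + step_sd * eps[t - 1]
        v[t] = _reflect(x, vm.v_min, vm.v_max)
    return v


def _reflect(x: float, lo: float, hi: float) -> float:
    span = hi - lo
    while x < lo or x > hi:
        if x < lo:
            x = 2 * lo - x
        else:
            x = 2 * hi - x
        if span <= 0:  # pragma: no cover - guarded by config validation
            break
    return x


def _drowsiness(vigilance: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """1 - normalized vigilance, in [0, 1] (1 = fully drowsy)."""
    vm = config.vigilance_model
    u = (vigilance - vm.v_min) / (vm.v_max - vm.v_min)
    return 1.0 - np.clip(u, 0.0, 1.0)


def coupling_gain(vigilance: np.ndarray, config: SimulationConfig) -> np.ndarray:
    """Affine-in-vigilance coupling gain, clamped at the endpoint gains.

    Monotonically non-increasing in vigilance: the low-vigilance end of the
    range gets ``gain_low_vig``, the high end ``gain_high_vig``.
    """
    c = config.coupling
    d = _drowsiness(vigilance, config)
    return c.gain_high_vig + (c.gain_low_vig - c.gain_high_vig) * d


# -------------------------------------------------------------------- physio

def _smooth_noise(rng: np.random.Generator, n: int, smooth_trs: float) -> np.ndarray:
    """Unit-SD Gaussian noise smoothed over ~smooth_trs samples (zero mean)."""
    if smooth_trs <= 0:
        x = rng.standard_normal(n)
    else:
        half = int(np.ceil(4 * smooth_trs))
        k = np.exp(-0.5 * (np.arange(-half, half + 1) / smooth_trs) ** 2)
        k /= k.sum()
        x = np.convolve(rng.standard_normal(n + 2 * half), k, mode="valid")[:n]
    x = x - x.mean()
    sd = x.std()
    return x / sd if sd > 0 else x


def _ppg_pulse_kernel(rate_hz: float, width_s: float = 0.3) -> np.ndarray:
    """Asymmetric gamma-shaped pulse, unit peak, ~width_s wide."""
    t = np.arange(int(round(2 * width_s * rate_hz))) / rate_hz
    shape, scale = 2.5, width_s / 4.0
    k = (t / scale) ** (shape - 1) * np.exp(-t / scale)
    return k / k.max()


def simulate_physio(
    vigilance: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[PhysioRecording, GroundTruth]:
    """Generate raw respiration/PPG waveforms plus autonomic ground truth.

    The per-TR truths are: ``ibi`` (mean inter-beat interval, rising with
    drowsiness), ``rv`` (respiration depth) and ``pwa`` (pulse amplitude).
    Beat times integrate the instantaneous IBI curve with small white jitter;
    the PPG is a train of gamma pulses at those times scaled by ``pwa``; the
    respiration belt is a sinusoid with depth ``rv`` and slowly wandering
    rate. Waveforms cover ``[-3 s, duration + 3 s]`` so every centered 6-s
    window around a volume is full.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 1)
    p = config.physio
    fs = config.physio_rate_hz
    duration = config.session_duration_s
    d = _drowsiness(np.asarray(vigilance, dtype=float), config)
    n_tr = d.size
    tr_mid = (np.arange(n_tr) + 0.5) * config.tr_s

    # Slow vigilance-driven component times smooth TR-scale physiological
    # variability (breath-to-breath, beat-to-beat); the latter is what
    # survives the 1/window-length high-pass in windowed analyses.
    fluct = lambda sd, sm: np.exp(sd * _smooth_noise(rng, n_tr, sm))  # noqa: E731
    ibi_sd = p.ibi_fluct * (1.0 + p.ibi_fluct_vig_slope * d)
    ibi_tr = (p.ibi_base_s + p.ibi_vig_slope_s * d) * np.exp(
        ibi_sd * _smooth_noise(rng, n_tr, p.ibi_fluct_smooth_trs))
    rv_tr = (1.0 + p.rv_vig_slope * d) * fluct(p.rv_fluct, p.fluct_smooth_trs)
    pwa_tr = (1.0 + p.pwa_vig_slope * d) * fluct(p.pwa_fluct, p.fluct_smooth_trs)
    hr_tr = 60.0 / ibi_tr

    pad = 3.0
    t = np.arange(int(round((duration + 2 * pad) * fs))) / fs - pad

    # ---- beats: step through the instantaneous IBI curve
    beat_times = []
    ibi_seq = []
    tb = -pad
    while tb < duration + pad:
        ibi_here = float(np.interp(tb, tr_mid, ibi_tr))
        if p.ibi_noise_s > 0:
            ibi_here += p.ibi_noise_s * rng.standard_normal()
        lo, hi = IBI_HARD_BOUNDS_S
        if not lo < ibi_here < hi:
            logger.warning("simulated IBI %.3f s outside (%.1f, %.1f); clipped",
                           ibi_here, lo, hi)
            ibi_here = float(np.clip(ibi_here, lo + 1e-3, hi - 1e-3))
        beat_times.append(tb)
        ibi_seq.append(ibi_here)
        tb += ibi_here
    beat_times = np.asarray(beat_times)
    ibi_seq = np.asarray(ibi_seq)

    # ---- PPG: pulse kernel train with per-beat amplitude
    impulses = np.zeros(t.size)
    idx = np.round((beat_times + pad) * fs).astype(int)
    keep = (idx >= 0) & (idx < t.size)
    amps = np.interp(beat_times, tr_mid, pwa_tr)
    np.add.at(impulses, idx[keep], amps[keep])
    ppg = np.convolve(impulses, _ppg_pulse_kernel(fs))[: t.size]

    # ---- respiration: sinusoid, slowly wandering rate, per-TR depth
    n_ctrl = max(int(duration / 30.0), 2)
    ctrl_t = np.linspace(-pad, duration + pad, n_ctrl)
    ctrl_rate = p.resp_rate_hz * (1 + p.resp_rate_jitter * rng.standard_normal(n_ctrl))
    inst_rate = np.interp(t, ctrl_t, ctrl_rate)
    phase = 2 * np.pi * np.cumsum(inst_rate) / fs
    depth = np.interp(t, tr_mid, rv_tr)
    resp = depth * np.sin(phase)

    recording = PhysioRecording(time_s=t, resp=resp, ppg=ppg, rate_hz=fs)
    truth = GroundTruth(
        vigilance_latent=np.asarray(vigilance, dtype=float),
        coupling_gain=coupling_gain(np.asarray(vigilance, dtype=float), config),
        ibi_true=ibi_seq,
        beat_times_s=beat_times,
        rv_true=rv_tr,
        pwa_true=pwa_tr,
        hr_true=hr_tr,
        event_onsets_s=np.empty(0),
        responded=np.empty(0, dtype=bool),
    )
    return recording, truth


# -------------------------------------------------------------------- events

def simulate_events(
    config: SimulationConfig,
    vigilance: np.ndarray,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Auditory tone train with vigilance-dependent misses and reaction times.

    Inter-stimulus intervals are uniform on ``[isi_min_s, isi_max_s]``. Each
    tone is responded to with probability ``1 - p_miss_low_vig * drowsiness``;
    reaction times lengthen with drowsiness and any RT above 4 s is recorded
    as missing (the event keeps ``responded=False`` in that case).
    """
    task = config.task
    if task.isi_min_s >= task.isi_max_s:
        raise ParameterError("isi_min_s must be below isi_max_s")
    rng = rng if rng is not None else np.random.default_rng(config.seed + 2)
    d = _drowsiness(np.asarray(vigilance, dtype=float), config)
    tr_mid = (np.arange(d.size) + 0.5) * config.tr_s

    onsets = []
    tt = float(rng.uniform(task.isi_min_s, task.isi_max_s))
    while tt < config.session_duration_s - 4.0:
        onsets.append(tt)
        tt += float(rng.uniform(task.isi_min_s, task.isi_max_s))
    onsets = np.asarray(onsets)

    d_at = np.interp(onsets, tr_mid, d)
    responded = rng.random(onsets.size) >= task.p_miss_low_vig * d_at
    rt = 0.25 + 0.9 * d_at + 0.08 * np.abs(rng.standard_normal(onsets.size))
    too_slow = rt > 4.0
    responded &= ~too_slow
    rt = np.where(responded, rt, np.nan)
    return pd.DataFrame({"onset_s": onsets, "responded": responded, "rt_s": rt})


# ---------------------------------------------------------------------- fMRI

def simulate_fmri(
    vigilance: np.ndarray,
    truth: GroundTruth,
    config: SimulationConfig,
    events: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
    with_voxels: bool = False,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray | None]:
    """ROI (and optional voxel) percent-signal-change time series.

    Each ROI series is ``w_r * gain(t) * sum_k conv_k(t)`` plus canonical-HRF
    responses to responded tones plus AR(1) noise, where ``conv_k`` are the
    session-z-scored autonomic truths convolved with their response functions
    (RV * RRF, HR * CRF, PWA * canonical HRF). Voxels add iid Gaussian noise
    around their ROI mean; spatial smoothness is not modeled.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 3)
    tr = config.tr_s
    n_tr = np.asarray(vigilance).size
    gain = coupling_gain(np.asarray(vigilance, dtype=float), config)

    parts = []
    for sig, kern, disp in ((truth.rv_true, kernels.rrf, 1.0),
                            (truth.hr_true, kernels.crf, 1.0),
                            (truth.pwa_true, kernels.canonical_hrf, 1.0)):
        k = kern(kernels.lag_grid(tr), dispersion=disp)
        k = k / np.max(np.abs(k))
        conv = np.convolve(np.asarray(sig, dtype=float), k)[:n_tr]
        # unit-SD so the coupling gain is the signal SD in % signal change
        parts.append(_safe_z(conv))
    shared = gain * np.sum(parts, axis=0)

    stim_sig = np.zeros(n_tr)
    if events is not None and len(events):
        onsets = events.loc[events["responded"].astype(bool), "onset_s"].to_numpy()
        train = np.zeros(n_tr)
        idx = np.clip(np.round(onsets / tr).astype(int), 0, n_tr - 1)
        np.add.at(train, idx, 1.0)
        k = kernels.canonical_hrf(kernels.lag_grid(tr))
        k = k / np.max(np.abs(k))
        stim_sig = config.physio.stim_amp * np.convolve(train, k)[:n_tr]

    weights = (np.asarray(config.roi_weights, dtype=float)
               if config.roi_weights is not None
               else np.linspace(0.8, 1.2, config.n_rois))
    if weights.size != config.n_rois:
        raise ParameterError("roi_weights length must equal n_rois")

    noise = _ar1(rng, (n_tr, config.n_rois), config.noise.ar1_phi, config.noise.sigma)
    background = _ar1(rng, (n_tr, 1), config.noise.ar1_phi,
                      config.noise.shared_sigma)
    roi = (weights[None, :] * shared[:, None] + stim_sig[:, None]
           + background + noise)

    voxel_series = voxel_labels = None
    if with_voxels:
        nv = config.n_voxels_per_roi
        voxel_labels = np.repeat(np.arange(1, config.n_rois + 1), nv)
        voxel_series = (np.repeat(roi, nv, axis=1)
                        + config.noise.voxel_sigma
                        * rng.standard_normal((n_tr, config.n_rois * nv)))
    return roi, voxel_series, voxel_labels


def _safe_z(x: np.ndarray) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


def _ar1(rng: np.random.Generator, shape: tuple[int, int],
         phi: float, sigma: float) -> np.ndarray:
    """Stationary AR(1) noise with marginal standard deviation ``sigma``."""
    n, k = shape
    if sigma == 0:
        return np.zeros((n, k))
    innov_sd = sigma * np.sqrt(max(1 - phi**2, 1e-12))
    out = np.empty((n, k))
    out[0] = sigma * rng.standard_normal(k)
    eps = innov_sd * rng.standard_normal((n - 1, k))
    for t in range(1, n):
        out[t] = phi * out[t - 1] + eps[t - 1]
    return out


# ----------------------------------------------------------------- EEG power

def simulate_eeg_power(
    vigilance: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-TR band RMS amplitudes whose alpha/theta ratio tracks the latent state.

    Theta is a noisy constant, alpha = vigilance x theta (so the ratio equals
    the latent state up to multiplicative noise), and delta rises with
    drowsiness. Band noise is multiplicative log-normal, as band power is
    positive and right-skewed.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 4)
    v = np.asarray(vigilance, dtype=float)
    d = _drowsiness(v, config)
    n = v.size
    lognoise = lambda sd: np.exp(sd * rng.standard_normal(n))  # noqa: E731
    theta = 1.0 * lognoise(0.10)
    alpha = v * theta * lognoise(0.05)
    delta = (1.0 + 0.8 * d) * lognoise(0.10)
    return pd.DataFrame({"tr_index": np.arange(n), "alpha": alpha,
                         "theta": theta, "delta": delta})


# ------------------------------------------------------------------- session

def simulate_session(config: SimulationConfig, with_voxels: bool = False) -> Session:
    """Generate one complete synthetic scan from a config (deterministic in seed)."""
    rng = np.random.default_rng(config.seed)
    child = rng.spawn(5)
    vig = simulate_vigilance_trajectory(config, rng=child[0])
    physio, truth = simulate_physio(vig, config, rng=child[1])
    events = simulate_events(config, vig, rng=child[2])
    truth.event_onsets_s = events["onset_s"].to_numpy()
    truth.responded = events["responded"].to_numpy(dtype=bool)
    roi, vox, labels = simulate_fmri(vig, truth, config, events=events,
                                     rng=child[3], with_voxels=with_voxels)
    eeg = simulate_eeg_power(vig, config, rng=child[4])
    return Session(config=config, truth=truth, physio=physio, eeg_power=eeg,
                   events=events, roi_series=roi, voxel_series=vox,
                   voxel_labels=labels)
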