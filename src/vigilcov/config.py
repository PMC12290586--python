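"""Session and simulation configuration.

:class:`SimulationConfig` collects every knob of the synthetic-session
generator: scan geometry (duration, TR), physiological sampling, the latent
vigilance process, the vigilance-dependent coupling gain between autonomic
signals and the fMRI signal, noise, and the auditory-task event schedule.

Defaults reproduce the study conditions the generator emulates: a 24.5-min
scan at TR = 2.1 s with the first 7 volumes discarded downstream, auditory
tones at 29-41 s inter-stimulus intervals, and a slow vigilance drift whose
low end doubles the fMRI-autonomic coupling gain relative to the high end.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
from typing import Any

import yaml

from .errors import ParameterError


@dataclass
class VigilanceModel:
    """Ornstein-Uhlenbeck parameters for the latent vigilance trajectory.

    The latent state lives on the scale of the EEG alpha/theta ratio; the
    stationary mean is the midpoint of ``(v_min, v_max)`` and excursions are
    reflected back into the bounds.
    """

    ou_theta: float = 1.0 / 300.0   # mean-reversion rate, 1/s (5-min time constant)
    ou_sigma: float = 0.06          # diffusion, a.u./sqrt(s); stationary SD ~0.73
                                    # (reflection at the bounds compresses this)
    v_min: float = 0.3
    v_max: float = 2.0


@dataclass
class Coupling:
    """fMRI-autonomic coupling gain at the vigilance extremes (unitless).

    ``gain_low_vig >= gain_high_vig`` encodes the hypothesized direction:
    drowsiness strengthens the autonomic imprint on the BOLD signal. The gain
    at intermediate vigilance is affine in the latent state, clamped at the
    two endpoint values.
    """

    gain_high_vig: float = 0.5
    gain_low_vig: float = 1.0


@dataclass
class Noise:
    """AR(1) noise added to the ROI time series (% signal).

    ``sigma`` is independent per ROI; ``shared_sigma`` is a single AR(1)
    process common to every ROI, standing in for non-autonomic neural and
    global background that does not average away across regions (without it
    the simulated global mean would be unrealistically clean).
    """

    ar1_phi: float = 0.3
    sigma: float = 1.0
    shared_sigma: float = 1.0
    voxel_sigma: float = 0.5   # extra iid noise per voxel around the ROI mean


@dataclass
class Task:
    """Auditory psychomotor-vigilance task schedule."""

    isi_min_s: float = 29.0
    isi_max_s: float = 41.0
    p_miss_low_vig: float = 0.4   # miss probability at the lowest vigilance


@dataclass
class Physio:
    """Autonomic ground-truth shape parameters.

    ``*_vig_slope`` terms scale how strongly drowsiness (1 - normalized
    vigilance) raises the inter-beat interval, respiration depth, and pulse
    amplitude. Setting the slopes to zero severs every vigilance -> autonomic
    amplitude path, which the null preset uses.
    """

    ibi_base_s: float = 0.75
    ibi_vig_slope_s: float = 0.35
    ibi_noise_s: float = 0.01
    resp_rate_hz: float = 0.25
    resp_rate_jitter: float = 0.03
    rv_vig_slope: float = 0.5
    pwa_vig_slope: float = 0.5
    # TR-scale physiological variability (breath-to-breath depth changes,
    # beat-to-beat heart-rate variability, vascular tone fluctuations),
    # expressed as log-normal SDs of smooth multiplicative noise. These are
    # what couples into the fMRI analysis band after high-pass filtering.
    rv_fluct: float = 0.25
    pwa_fluct: float = 0.25
    ibi_fluct: float = 0.06
    ibi_fluct_vig_slope: float = 1.0   # LF heart-rate variability rises as
                                       # vigilance falls (drowsiness deepens
                                       # autonomic fluctuations)
    fluct_smooth_trs: float = 1.5      # RV/PWA scale (~3 s: breath-to-breath)
    ibi_fluct_smooth_trs: float = 5.0  # HR scale (~10 s: low-frequency HRV);
                                       # slower so the 6-s median window
                                       # resolves it
    stim_amp: float = 0.5          # % signal per responded tone


@dataclass
class SimulationConfig:
    """Complete recipe for one synthetic session."""

    session_duration_s: float = 1470.0
    tr_s: float = 2.1
    physio_rate_hz: float = 100.0
    n_rois: int = 8
    n_voxels_per_roi: int = 4
    vigilance_model: VigilanceModel = field(default_factory=VigilanceModel)
    coupling: Coupling = field(default_factory=Coupling)
    noise: Noise = field(default_factory=Noise)
    task: Task = field(default_factory=Task)
    physio: Physio = field(default_factory=Physio)
    roi_weights: list[float] | None = None   # per-ROI coupling weight, default ~1
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    @property
    def n_tr(self) -> int:
        return int(self.session_duration_s / self.tr_s + 0.5)

    def validate(self) -> None:
        if self.tr_s <= 0 or self.physio_rate_hz <= 0 or self.session_duration_s <= 0:
            raise ParameterError("durations and rates must be positive")
        ratio = self.session_duration_s / self.tr_s
        if abs(ratio - round(ratio)) > 1.0:
            raise ParameterError(
                f"session_duration_s / tr_s = {ratio:.3f} is not within 1 of an integer"
            )
        vm = self.vigilance_model
        if vm.ou_theta <= 0 or vm.ou_sigma < 0:
            raise ParameterError("ou_theta must be > 0 and ou_sigma >= 0")
        if not vm.v_min < vm.v_max:
            raise ParameterError("v_min must be below v_max")
        c = self.coupling
        if not (c.gain_low_vig >= c.gain_high_vig >= 0):
            raise ParameterError(
                "require gain_low_vig >= gain_high_vig >= 0 (drowsiness strengthens coupling)"
            )
        if self.task.isi_min_s >= self.task.isi_max_s:
            raise ParameterError("isi_min_s must be below isi_max_s")
        if self.n_rois < 1 or self.n_voxels_per_roi < 1:
            raise ParameterError("need at least one ROI and one voxel per ROI")

    # ------------------------------------------------------------------ presets

    def with_null_coupling(self) -> "SimulationConfig":
        """Preset with no vigilance-dependent structure in the fMRI-autonomic link.

        Sets the coupling gain constant (mean of the two endpoint gains) and
        zeroes the vigilance -> autonomic amplitude slopes, so any association
        between baseline vigilance and windowed R^2 is pure type-I error.
        """
        g = 0.5 * (self.coupling.gain_low_vig + self.coupling.gain_high_vig)
        return replace(
            self,
            coupling=Coupling(gain_high_vig=g, gain_low_vig=g),
            physio=replace(
                self.physio, ibi_vig_slope_s=0.0, rv_vig_slope=0.0,
                pwa_vig_slope=0.0, ibi_fluct_vig_slope=0.0,
            ),
        )

    # ---------------------------------------------------------------- yaml io

    def to_dict(self) -> dict[str, Any]:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SimulationConfig":
        d = dict(d)
        for key, sub in (
            ("vigilance_model", VigilanceModel),
            ("coupling", Coupling),
            ("noise", Noise),
            ("task", Task),
            ("physio", Physio),
        ):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
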