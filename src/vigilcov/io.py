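"""Session I/O and pipeline orchestration.

A session on disk is a :class:`SessionBundle`: a 4D NIfTI of preprocessed
percent-signal-change fMRI, a matching integer-labeled atlas NIfTI, and TSV
tables for the physiological waveforms (time_s, resp, ppg), the per-TR EEG
band amplitudes (tr_index, alpha, theta, delta), and the task events
(onset_s, rt_s with an empty cell for a missing response). The first
``n_discard`` volumes (default 7, i.e. 14.7 s at TR 2.1 s) are dropped on
load; regressor convolution happens *before* that drop, so the loader keeps
the full-length EEG/physio tables and only truncates the fMRI.

``run_pipeline`` executes the windowed covariance analysis end-to-end on one
or more sessions and writes TSV results plus a JSON provenance record.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import kernels, physio as physio_mod, regression, vigilance as vig_mod, windows as win_mod
from .config import SimulationConfig
from .errors import ParameterError
from .synthetic import PhysioRecording, Session, simulate_session

logger = logging.getLogger(__name__)

DEFAULT_N_DISCARD = 7


@dataclass
class SessionBundle:
    """File paths and scan parameters for one session."""

    fmri_path: Path
    atlas_path: Path
    physio_path: Path
    eeg_path: Path
    events_path: Path
    condition: str = "rest"
    tr_s: float = 2.1
    n_discard: int = DEFAULT_N_DISCARD


@dataclass
class LoadedSession:
    """In-memory session: retained ROI series plus full-span side tables."""

    roi_series: np.ndarray            # (n_retained, n_rois)
    roi_labels: np.ndarray
    voxel_series: np.ndarray          # (n_retained, n_voxels_in_atlas)
    voxel_labels: np.ndarray
    physio: PhysioRecording
    eeg_power: pd.DataFrame           # full pre-discard span
    events: pd.DataFrame
    condition: str
    tr_s: float
    n_discard: int
    n_total_vols: int


# ------------------------------------------------------------------- writing

def save_session(session: Session, outdir: str | Path,
                 condition: str = "rest") -> SessionBundle:
    """Write a synthetic session to disk in the on-disk bundle layout.

    The 4D fMRI image packs voxels as (n_voxels_per_roi, 1, n_rois, n_tr)
    with the atlas labeling each ROI slab 1..n_rois; the TR is recorded in
    the NIfTI header. A JSON ground-truth sidecar stores the latent
    vigilance, coupling gain, and autonomic truths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = session.config
    if session.voxel_series is None:
        raise ParameterError("session was simulated without voxels; "
                             "use simulate_session(..., with_voxels=True)")
    nv, nr = cfg.n_voxels_per_roi, cfg.n_rois
    n_tr = session.roi_series.shape[0]

    # voxel_series columns are ordered (roi 1 voxels..., roi 2 voxels...)
    vol = session.voxel_series.T.reshape(nr, nv, n_tr).transpose(1, 0, 2)
    vol4d = vol[:, None, :, :]                    # grid (nv, 1, nr, t)
    img = nib.Nifti1Image(vol4d.astype(np.float32), affine=np.eye(4))
    img.header.set_zooms((1.0, 1.0, 1.0, cfg.tr_s))
    fmri_path = outdir / "fmri.nii"
    nib.save(img, fmri_path)

    atlas = np.tile(np.arange(1, nr + 1, dtype=np.int16)[None, None, :], (nv, 1, 1))
    atlas_img = nib.Nifti1Image(atlas.astype(np.int16), affine=np.eye(4))
    atlas_path = outdir / "atlas.nii"
    nib.save(atlas_img, atlas_path)

    physio_path = outdir / "physio.tsv"
    pd.DataFrame({"time_s": session.physio.time_s, "resp": session.physio.resp,
                  "ppg": session.physio.ppg}).to_csv(physio_path, sep="\t",
                                                     index=False, float_format="%.6g")
    eeg_path = outdir / "eeg.tsv"
    session.eeg_power.to_csv(eeg_path, sep="\t", index=False, float_format="%.6g")

    events_path = outdir / "events.tsv"
    ev = session.events[["onset_s", "rt_s"]].copy()
    ev.to_csv(events_path, sep="\t", index=False, float_format="%.4f", na_rep="")

    truth = session.truth
    sidecar = {
        "seed": cfg.seed,
        "physio_rate_hz": cfg.physio_rate_hz,
        "vigilance_latent": truth.vigilance_latent.tolist(),
        "coupling_gain": truth.coupling_gain.tolist(),
        "rv_true": truth.rv_true.tolist(),
        "pwa_true": truth.pwa_true.tolist(),
        "hr_true": truth.hr_true.tolist(),
        "event_onsets_s": truth.event_onsets_s.tolist(),
        "responded": truth.responded.astype(int).tolist(),
    }
    (outdir / "ground_truth.json").write_text(json.dumps(sidecar))
    cfg.to_yaml(str(outdir / "config.yaml"))

    return SessionBundle(fmri_path=fmri_path, atlas_path=atlas_path,
                         physio_path=physio_path, eeg_path=eeg_path,
                         events_path=events_path, condition=condition,
                         tr_s=cfg.tr_s)


# ------------------------------------------------------------------- loading

def load_session(bundle: SessionBundle) -> LoadedSession:
    """Load a session bundle, validate geometry and TR, extract ROI means.

    The atlas grid must match the fMRI grid exactly and the header TR must
    agree with the bundle's ``tr_s`` within 1 ms. The first ``n_discard``
    volumes are dropped from the fMRI; EEG/physio/events keep the full span
    (convolution precedes the discard downstream).
    """
    img = nib.load(str(bundle.fmri_path))
    atlas_img = nib.load(str(bundle.atlas_path))
    if img.shape[:3] != atlas_img.shape:
        raise ParameterError(
            f"atlas grid {atlas_img.shape} does not match fMRI grid {img.shape[:3]}"
        )
    header_tr = float(img.header.get_zooms()[3]) if len(img.header.get_zooms()) > 3 else 0.0
    if abs(header_tr - bundle.tr_s) > 1e-3:
        raise ParameterError(
            f"NIfTI header TR {header_tr:.4f} s disagrees with configured "
            f"{bundle.tr_s:.4f} s by more than 1 ms"
        )
    data = np.asarray(img.dataobj, dtype=float)
    atlas = np.asarray(atlas_img.dataobj).astype(int)
    n_total = data.shape[3]
    data = data[..., bundle.n_discard:]

    flat = data.reshape(-1, data.shape[3]).T          # (n_tr, n_voxels)
    labels_flat = atlas.reshape(-1)
    in_brain = labels_flat > 0
    missing = ~np.all(np.isfinite(flat), axis=0)
    if missing.any():
        logger.info("masking %d voxels with missing data", int(missing.sum()))
    keep = in_brain & ~missing
    voxel_series = flat[:, keep]
    voxel_labels = labels_flat[keep]

    roi_labels = np.unique(voxel_labels)
    roi_series = np.column_stack([
        voxel_series[:, voxel_labels == lab].mean(axis=1) for lab in roi_labels
    ])

    physio_df = pd.read_csv(bundle.physio_path, sep="\t")
    for col in ("time_s", "resp", "ppg"):
        if col not in physio_df.columns:
            raise ParameterError(f"physio TSV missing column {col!r}")
    dt = np.diff(physio_df["time_s"].to_numpy())
    rate = 1.0 / np.median(dt)
    recording = PhysioRecording(
        time_s=physio_df["time_s"].to_numpy(dtype=float),
        resp=physio_df["resp"].to_numpy(dtype=float),
        ppg=physio_df["ppg"].to_numpy(dtype=float),
        rate_hz=float(rate),
    )
    eeg = pd.read_csv(bundle.eeg_path, sep="\t")
    events = pd.read_csv(bundle.events_path, sep="\t")
    if "responded" not in events.columns:
        events["responded"] = ~events["rt_s"].isna()

    return LoadedSession(
        roi_series=roi_series, roi_labels=roi_labels,
        voxel_series=voxel_series, voxel_labels=voxel_labels,
        physio=recording, eeg_power=eeg, events=events,
        condition=bundle.condition, tr_s=bundle.tr_s,
        n_discard=bundle.n_discard, n_total_vols=n_total,
    )


# ----------------------------------------------------------------- pipeline

def analyze_session(
    loaded: LoadedSession,
    window_len_tr: int = win_mod.DEFAULT_WINDOW_TRS,
    model_stimuli: bool = False,
    n_perm: int = 10_000,
    seed: int = 0,
) -> dict:
    """Windowed fMRI-autonomic covariance analysis of one loaded session.

    Runs physio feature extraction, vigilance indexing, design assembly,
    per-window R^2 on the global signal and each ROI, and the pooled
    Spearman/permutation association with shifted baseline vigilance.
    Returns a dict of DataFrames and arrays (see keys in the code).
    """
    rng = np.random.default_rng(seed)
    tr = loaded.tr_s
    n_total = loaded.n_total_vols
    n_ret = loaded.roi_series.shape[0]

    auto = physio_mod.extract_autonomic(loaded.physio, tr, n_total)
    design = kernels.build_design(
        auto.to_frame(), tr, fast_eeg=loaded.eeg_power,
        events=loaded.events if model_stimuli else None,
        n_discard=loaded.n_discard,
    )
    ratio = vig_mod.vigilance_index(loaded.eeg_power)[loaded.n_discard:]

    ws = win_mod.segment(n_ret, window_len_tr)
    window_len_s = window_len_tr * tr
    fs = 1.0 / tr
    hp = lambda a: win_mod.highpass_for_windows(a, window_len_s, fs)  # noqa: E731

    global_sig = hp(loaded.roi_series.mean(axis=1))
    rois = hp(loaded.roi_series)
    auto_x = hp(design.group("autonomic"))
    stim_x = (hp(design.group("stimulus"))
              if model_stimuli and "stimulus" in design.groups else None)

    baseline = vig_mod.baseline_vigilance(ratio, ws)

    regions = {"global": global_sig}
    for j, lab in enumerate(loaded.roi_labels):
        regions[f"roi{int(lab)}"] = rois[:, j]

    r2_rows = []
    assoc_rows = []
    for name, sig in regions.items():
        wr2 = regression.windowed_r2_series(sig, auto_x, ws, stimulus=stim_x,
                                            region=name)
        r2 = np.array([w.r2_pct for w in wr2])
        assoc = regression.vigilance_association(r2, baseline, n_perm=n_perm,
                                                 rng=rng, region=name)
        ci = regression.bootstrap_ci(r2, baseline, rng=rng)
        for w, b in zip(wr2, baseline):
            r2_rows.append({"region": name, "window_id": w.window_id,
                            "r2_pct": w.r2_pct, "baseline_vigilance": b})
        assoc_rows.append({"region": name, "rho": assoc.rho, "p_perm": assoc.p_perm,
                           "ci_low": ci[0], "ci_high": ci[1]})

    assoc_df = pd.DataFrame(assoc_rows)
    assoc_df["fdr_flag"] = regression.bh_fdr(assoc_df["p_perm"].to_numpy())
    return {
        "r2": pd.DataFrame(r2_rows),
        "association": assoc_df,
        "baseline_vigilance": baseline,
        "autonomic": auto,
        "design": design,
        "windows": ws,
    }


def run_pipeline(config: SimulationConfig, outdir: str | Path,
                 condition: str = "rest", window_len_tr: int = 60,
                 n_perm: int = 10_000) -> Path:
    """Simulate a session, analyze it, and write all outputs to ``outdir``.

    Writes the session bundle, the per-window R^2 table, the association
    table, and a JSON provenance record (config hash, seed, package
    versions). Deterministic for a fixed config and seed.
    """
    outdir = Path(outdir)
    session = simulate_session(config, with_voxels=True)
    bundle = save_session(session, outdir / "session", condition=condition)
    loaded = load_session(bundle)
    results = analyze_session(loaded, window_len_tr=window_len_tr,
                              model_stimuli=(condition == "task"),
                              n_perm=n_perm, seed=config.seed)
    resdir = outdir / "results"
    resdir.mkdir(parents=True, exist_ok=True)
    results["r2"].to_csv(resdir / "window_r2.tsv", sep="\t", index=False,
                         float_format="%.6f")
    results["association"].to_csv(resdir / "association.tsv", sep="\t",
                                  index=False, float_format="%.6f")

    import vigilcov
    cfg_json = json.dumps(config.to_dict(), sort_keys=True)
    provenance = {
        "config_sha256": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "condition": condition,
        "window_len_tr": window_len_tr,
        "versions": {"vigilcov": vigilcov.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__,
                     "nibabel": nib.__version__},
    }
    (resdir / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return resdir
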