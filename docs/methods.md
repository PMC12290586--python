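# Methods

This note records the models, estimators, and numerical choices behind
`vigilcov`, and what the synthetic-data experiments do and do not establish.

## Signals and measures

**Autonomic measures.** RV and PWA are population standard deviations of the
respiration-belt and PPG waveforms in a 6-s window centered on each volume's
acquisition midpoint, then low-pass filtered at 0.15 Hz across volumes. The
choice of *population* SD (ddof 0) treats the value as a signal-amplitude
summary rather than a sample estimate; at physiological sampling rates the
difference is negligible but tests require one convention. HR is 60 over the
median inter-beat interval whose midpoint falls in the window. Pulse peaks
are detected on a zero-phase 2nd-order Butterworth 0.5–2 Hz band-passed PPG
with a minimum height of 5% of the whole-scan IQR and a minimum spacing of
0.55 s (a 109.09-bpm ceiling). IBIs outside [0.33, 2.0] s, or deviating from
an 11-beat running median by more than 3 MAD *and* more than 100 ms, are
linearly interpolated; above 25% flagged the scan is rejected. The absolute
100-ms floor exists because the MAD of a smoothly drifting heart rhythm can
be vanishingly small, which would turn the rule into a slow-drift detector;
genuine detector artifacts (missed or doubled beats) move an IBI by hundreds
of milliseconds. All filtering in the package is zero-phase
(forward–backward); phase-neutral filtering matters because lagged
cross-correlations downstream would inherit any systematic filter delay.

**Vigilance index.** Per-TR alpha (8–12 Hz), theta (3–7 Hz) and delta
(0.5–2 Hz) RMS amplitudes are computed per channel (4th-order zero-phase
band-pass, RMS over each TR's samples) and then averaged over channels — in
that order; the index is α/θ, with α/(δ+θ) as an alternative. Baseline
vigilance is the window mean after advancing the EEG series 2 TRs (4.2 s)
relative to the fMRI grid, approximating the peak latency of canonical
hemodynamic responses. A zero denominator raises an error rather than
propagating infinities.

**Response models.** The RRF is
`0.6 t^2.1 e^(−t/1.6) − 0.0023 t^3.54 e^(−t/4.25)`; the CRF is
`0.6 t^2.7 e^(−t/1.6) − (16/√(18π)) e^(−(t−12)²/18)` (the Gaussian term is
zeroed at t = 0 so the kernel is exactly causal). The canonical HRF is the
double-gamma `Γ(peak 6, disp 1) − Γ(undershoot 16, disp 1)/6`; the fast-EEG
variant uses peak 10 s, undershoot 14 s, dispersions 2, ratio 2. Kernels are
sampled on the TR grid, truncated at 32 s and unit-peak normalized. Temporal
derivatives are backward finite differences over one TR (a forward shift
would break causality); dispersion derivatives are central differences with
a 5% step in the dispersion parameter, realized for the RRF/CRF as a time
dilation since their closed forms have no separate dispersion parameter.
Each derivative is orthogonalized against its base kernel and unit-norm
scaled. The 5-column RV/HR bases and 3-column HRF bases give the 13-column
autonomic group and, with three EEG bands, the 9-column fast-EEG group.
Convolution happens on the full pre-discard grid; only afterwards are the
first 7 volumes (14.7 s) dropped, so lagged responses reach the first
analysis window. Stimulus trains are built at 1 Hz, convolved, and linearly
resampled to the TR grid (6 columns when both responded and unresponded
tones exist).

## Windowed inference

Sessions are tiled into non-overlapping windows (60 TRs = 126 s by default;
115 TRs = 241.5 s for the noisier voxel-level analyses; 30–120 TRs accepted
for robustness checks). Signals entering a windowed analysis are high-pass
filtered at 1/window-length Hz (2nd-order zero-phase Butterworth, residual
mean subtracted) so variance slower than one window cannot alias into
between-window differences. Within each window the design is z-scored and
R² comes from OLS with intercept; stimulus covariates, when modeled, are
removed from the target first (Frisch–Waugh), so the reported R² counts only
variance the nuisance columns cannot claim. Rank-deficient designs drop
dependent columns greedily with a warning. Adjusted R²
(`1 − (1 − R²)(n−1)/(n−p−1)`) is floored at 0 to preserve the
percent-variance reading when groups of different sizes are compared; the
flooring is logged.

Windows are pooled across sessions within a condition before the Spearman
step — mirroring how a multi-participant analysis pools windows across
participants — and the permutation test shuffles the pooled baseline
vigilance values. The p-value uses the add-one correction
`(1 + #{|ρ_b| ≥ |ρ|})/(1 + B)` with B = 10,000 by default: unbiased under
the null and never exactly zero. BH-FDR flags come from
`statsmodels.stats.multitest` (validated in the test suite against an
exhaustive step-up oracle). Bootstrap CIs are percentile intervals over
2,000 window resamples; degenerate resamples are redrawn and counted. The
pooled permutation treats windows as exchangeable, ignoring within-session
dependence, exactly as the published procedure does; a per-session
stratified permutation would be a straightforward extension.

Cross-correlations follow the normalized cross-covariance convention:
full-window means and sums of squares in the normalizer, overlap-only sums
in the numerator, so |r| shrinks toward extreme lags. With
`xcov_normalized(fmri, physio)`, positive lags mean the physiological signal
leads the fMRI signal — the hemodynamic regime, and the convention under
which a kernel-convolved simulation peaks at the kernel's argmax (verified
to ±1 TR in the tests). Fisher-z connectivity raises an error when |r|
reaches machine 1 instead of clipping; silent clipping would corrupt
permutation nulls built from the z values.

## The synthetic-session generator

The generator emulates a 24.5-min scan at TR 2.1 s with physiological
waveforms at 100 Hz (configurable; 100 Hz resolves the ~0.3-s pulse shape
at desk-scale cost) and auditory tones at 29–41-s inter-stimulus intervals.

**Latent vigilance** is a reflected Ornstein–Uhlenbeck process on the
alpha/theta-ratio scale, bounds [0.3, 2.0], mean-reversion time constant
5 min, stationary SD ≈ 0.7 before reflection. These values make single
sessions traverse a substantial part of the vigilance range, as in scans
where participants drift toward sleep; a faster or tighter process yields
sessions that sit near their mean and carry little between-window contrast
for any staged analysis to find.

**Autonomic ground truth.** Drowsiness (1 − normalized vigilance) raises
the mean IBI (0.75 → 1.10 s, i.e. 80 → 55 bpm), respiration depth, and
pulse amplitude (slopes 0.5). On top of the slow vigilance-driven component,
each measure carries smooth multiplicative log-normal fluctuations — ~3-s
correlation for RV/PWA (breath-to-breath, beat-to-beat variability) and
~10-s for the IBI (low-frequency heart-rate variability, which a 6-s median
window can resolve; faster HRV is largely invisible to that estimator). The
IBI fluctuation SD grows with drowsiness. These TR-scale fluctuations are
what survives the 1/window-length high-pass; a generator with purely slow
autonomic drift would have almost no in-band regressor variance and no
recoverable coupling. The PPG is a train of asymmetric gamma-shaped pulses
(~0.3 s wide) at the integrated beat times; the respiration belt is a
sinusoid with slowly wandering rate and per-TR depth.

**fMRI.** Each ROI series is
`w_r · g(t) · Σ_k conv_k(t) + stimulus responses + AR(1) noise`, where
`conv_k` are the autonomic truths convolved with their response functions
and normalized to unit SD (so the gain is the component SD in % signal),
`g(t)` is affine in vigilance and clamped at the endpoint gains (default
0.5 at the vigilance ceiling, 1.0 at the floor — the hypothesized doubling),
and the noise has an independent per-ROI AR(1) component (SD 1%) plus a
shared AR(1) background (SD 1%) common to all ROIs. The shared background
stands in for non-autonomic neural and global variance; without it the
ROI-mean global signal would be unrealistically clean and windowed R² would
saturate near 100%. Voxels add iid Gaussian noise around their ROI mean;
spatial smoothness is not modeled. Events are answered with probability
falling, and reaction time rising, with drowsiness; RTs above 4 s are
recorded as missing.

**The null preset** (`SimulationConfig.with_null_coupling`) fixes the gain
at the mean of its endpoints *and* zeroes every vigilance → autonomic
amplitude slope. Constant gain alone is not a sharp null: amplitude
modulation changes within-window regressor variance and hence R² even at
fixed gain, so a type-I calibration against constant-gain-only data would
conflate miscalibration with a real (if indirect) vigilance pathway.

**What passing tests show — and don't.** The simulations demonstrate that
the pipeline recovers a planted monotone vigilance–coupling relation
(pooled ρ ≈ −0.35…−0.55 under the default gain doubling), that its
permutation test is calibrated when no such relation exists, and that the
staging and partialling analyses move in the directions the coupling
implies. They do not establish anything about real tissue physiology: the
generator has no spatial structure, no motion or scanner drift, no EEG
artifacts, a single global coupling mechanism, and an affine gain law
chosen as the simplest monotone family — real vigilance–autonomic–BOLD
coupling need not be affine, stationary, or spatially uniform.

## Experiment sizes

The validation experiments run at sizes chosen to make their summary
statistics stable: 20 sessions (220 pooled windows) per recovery replicate
and the median over 5 replicates; 5 × 30 sessions for the null association;
200 single-session permutation tests for the rejection-rate calibration
(exact binomial 95% interval at α = 0.05); 40 sessions (240 pooled 115-TR
windows) for the tertile-staged cross-correlation contrast; 20 sessions for
the FC-partialling direction. At these sizes the full suite and the
acceptance script each run in minutes on a single CPU.

## Known limitations

- ROI/voxel counts are small by neuroimaging standards (8 networks, a few
  voxels per ROI); the code paths are the same at scale but runtimes are
  not characterized here.
- The exchangeability assumption of the pooled permutation ignores
  within-session autocorrelation of windows.
- The "dispersion derivative" for RRF/CRF is a time-dilation derivative,
  a pragmatic reading since those closed forms expose no dispersion
  parameter; the column count, not the exact derivative construction, is
  the binding constraint.
- Automated IBI artifact flagging replaces what is usually a visual
  inspection step; thresholds are configurable and logged.
- EEG gradient/ballistocardiogram cleaning, fMRI preprocessing
  (slice timing, motion, multi-echo ICA, normalization), and
  framewise-displacement controls are upstream of this package and out of
  scope; the pipeline consumes cleaned band powers and preprocessed
  percent-signal-change data.
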