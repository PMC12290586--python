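"""Simulate one synthetic EEG-fMRI-physiology session and inspect its truth.

Builds a 24.5-min scan (TR 2.1 s) in which a slow latent vigilance state
drives EEG band power, heart rhythm, respiration depth, pulse amplitude, and
the gain coupling autonomic signals into the fMRI ROI series.
"""

import numpy as np

from vigilcov import SimulationConfig, simulate_session

cfg = SimulationConfig(seed=1)
session = simulate_session(cfg)
truth = session.truth

print(f"TRs: {cfg.n_tr}, ROIs: {session.roi_series.shape[1]}, "
      f"beats: {truth.beat_times_s.size}, tones: {len(session.events)}")
print(f"latent vigilance range: {truth.vigilance_latent.min():.2f}"
      f" .. {truth.vigilance_latent.max():.2f} (alpha/theta scale)")
print(f"coupling gain range:    {truth.coupling_gain.min():.2f}"
      f" .. {truth.coupling_gain.max():.2f} (% signal per unit regressor)")
print(f"mean IBI: {truth.ibi_true.mean():.3f} s "
      f"(heart rate {60 / truth.ibi_true.mean():.1f} bpm)")
resp_rate = np.mean(~np.isnan(session.events["rt_s"]))
print(f"tones answered: {100 * resp_rate:.0f}% "
      "(misses cluster at low vigilance)")

# The gain is an affine, decreasing function of vigilance: drowsier stretches
# of the scan carry a stronger autonomic imprint on the simulated BOLD signal.
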