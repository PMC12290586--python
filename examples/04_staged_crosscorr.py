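"""Model-free cross-correlation of fMRI with autonomic signals, by vigilance stage.

For 241.5-s (115-TR) windows pooled across sessions, computes normalized
cross-correlations between the high-passed global fMRI signal and each raw
(unconvolved) autonomic measure over lags -10.5 .. +31.5 s, stages windows
into pooled baseline-vigilance tertiles, and averages curves per stage.
Positive lags mean the physiological signal leads the fMRI signal.
"""

import numpy as np

from vigilcov.experiments import staged_xcorr_contrast

out = staged_xcorr_contrast(n_sessions=24, seed=4)
tr = 2.1
for signal in ("RV", "HR", "PWA"):
    low, high = out[signal]["low"], out[signal]["high"]
    lag_lo = low.lags_tr[np.argmax(np.abs(low.mean_r))] * tr
    print(f"{signal}: low-vigilance peak |r| = "
          f"{np.max(np.abs(low.mean_r)):.3f} at {lag_lo:+.1f} s "
          f"({low.n_windows} windows); "
          f"high-vigilance peak |r| = {np.max(np.abs(high.mean_r)):.3f} "
          f"({high.n_windows} windows)")

print("\nWith enough pooled windows the low-vigilance stage shows the "
      "stronger fMRI-autonomic coupling, with peaks at positive lags "
      "(physiology leads, hemodynamics follow).")
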