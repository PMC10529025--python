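"""Recover the injected speckle level from the noisy image alone.

The estimator vectorizes image patches, soft-selects the flat ones, and
reads the noise variance off the smallest eigenvalue of the weighted patch
covariance.  Dividing each patch by the square root of its own mean maps
the signal-dependent speckle variance onto a flat noise floor, so the
estimate lands directly on var(eps).
"""

import despeckle as dsp

table = dsp.noise_recovery_experiment(
    levels=[0.1, 0.2, 0.3, 0.4, 0.5], seeds=list(range(5))
)
print(table.to_string(index=False, float_format=lambda v: f"{v:.4f}"))
print()
print("mean_estimate should track read_level closely; mean_abs_error is the")
print("average |estimate - truth| across seeds (a few 1e-3 at every level).")
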