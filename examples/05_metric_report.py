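"""Compute the full quality-metric report for a (noisy, filtered) pair.

Full-reference metrics need the clean image; no-reference metrics (ENL,
DEI, ABG) judge the filtering from the noisy/filtered pair alone, which is
what is available on real scans.
"""

import numpy as np

import despeckle as dsp

phantom = dsp.generate_shepp_logan(200)
noisy = dsp.add_speckle(phantom, dsp.SpeckleParams(variance=0.1, seed=7))
tau2 = dsp.estimate_speckle_level(noisy) * noisy[noisy > 0.05].mean()
filtered = dsp.restore_image(np.clip(noisy, 0, None), dsp.WindowSpec(noise_variance=tau2))

report = dsp.full_report(np.clip(filtered, 0, 1), noisy, phantom)
fr, nr = report["full_reference"], report["no_reference"]
print("full-reference (vs the clean phantom):")
for name in ("PSNR", "RMSE", "MSSIM", "FOM", "SRS", "CoC", "UQI", "QILV"):
    print(f"  {name:6s} {fr[name]:.4f}")
print("no-reference (from the noisy/filtered pair only):")
for name in ("ENL", "DEI", "ABG"):
    print(f"  {name:6s} {nr[name]:.4f}")
print("  (ENL = inf means the auto-selected homogeneous tile is perfectly")
print("   flat after filtering - the zero background of the phantom)")
print()
print("higher is better for PSNR/MSSIM/FOM/SRS/CoC/UQI/QILV/ENL;")
print("lower is better for RMSE, DEI and the ABG composite.")
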