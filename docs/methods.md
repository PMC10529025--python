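# Methods

## Noise model and synthetic data

The simulator implements the signal-dependent speckle model

    J_noisy = J + J^H · ε,    ε ~ N(0, σ²) i.i.d.,

with `H ∈ {0.5, 1}`.  `H = 0.5` (the default) makes the additive noise
variance proportional to the local intensity, `var = J·σ²`, the standard
B-mode approximation; `H = 1` is fully multiplicative, `J·(1 + ε)`, and is
the regime in which the log transform makes the model exactly additive.
The noise field is drawn from a seeded `numpy` generator, so every
simulation is bit-reproducible; `σ² = 0` returns the input unchanged.
Outputs are **not** clipped to the dynamic range internally — the negative
excursions are genuine samples of the model, and clipping them would bias
every moment the estimator and the metrics rely on.  Clipping to `[0, L]`
happens only when an image is written to file.

The clean truth is the modified (high-contrast) ten-ellipse Shepp–Logan
head phantom, rendered at any size ≥ 64 by additive point-in-ellipse
evaluation at pixel centers on the `[-1, 1]²` plane.  What the phantom
exercises: sharp boundaries at several contrasts, flat regions at
different levels (0, 0.2, 0.3, 1.0), small low-contrast targets.  What it
does not: tissue texture, attenuation/depth dependence, the correlated
(point-spread-function-shaped) speckle of a real scanner, or log-compressed
display scaling.  Passing tests on the phantom therefore demonstrate the
mechanics of the method, not clinical performance.

## Stage 1 — redundant wavelet shrinkage

The transform is the 2-D stationary wavelet transform (SWT): undecimated,
shift-invariant, exactly invertible.  Defaults: `sym4`, 3 levels.
Boundaries are periodic inside the transform (the classic SWT
formulation); images whose sides are not divisible by `2^levels` are
first padded symmetrically and the padding removed on synthesis.
Round-trip error is ~1e-12 relative, verified as a property.

Shrinkage operates in the log domain.  The log offset that guards zero
pixels defaults to 5% of the dynamic range in the pipeline: with heavy
speckle, pixels near zero would otherwise map to `ln(offset)` outliers of
magnitude ~14 that dominate the detail bands and make every threshold
choice bad.  A larger offset bounds that dynamic range at a small cost in
log-linearity; the value is recorded in the run report.

The exponential threshold

    ϑ(c) = 0                                     for |c| < D
    ϑ(c) = sign(c)·(|c| − D·exp(−α(|c|−D)/D))    for |c| ≥ D

is odd and a contraction in every regime.  `α = 0` reproduces the soft
rule exactly; the deviation from the hard rule decays as
`D·exp(−α(|c|−D)/D)`, so hard-rule behavior to 1e-6 at `|c| ≥ 1.1·D`
requires `α ≳ 138 + 10·ln D`.  `D = 0` with the exponential rule has no
decay scale and falls back to the identity (logged).  The approximation
band is never thresholded.

## Noise estimation

Patches of side `K = 8` on a stride-2 grid are vectorized into a
`K² × nₑ` matrix.  Soft selection gives each patch a weight
`C_j = exp(−excess_j / s)`, where `excess_j` is the patch variance above
the flattest patch's floor and `s` the median positive excess — flat
patches dominate, textured ones fade out smoothly.  The noise variance is
the smallest eigenvalue of the weighted, weighted-mean-centered patch
covariance `E_c·diag(C)·E_cᵀ / ΣC`.  Two refinements matter in practice:

* **Finite-sample bias.**  The bottom eigenvalue of a sample covariance is
  biased low by the Marchenko–Pastur factor `(1 − √(d/n_eff))²` with
  `d = K²` and `n_eff = (ΣC)²/ΣC²`; the estimate is divided by it.
* **Speckle mapping.**  For the `H = 0.5` model the additive variance is
  `J·σ²`, so `estimate_speckle_level` divides every patch by the square
  root of its own mean before forming the covariance — the model's
  additive domain — which places the noise floor of every patch at `σ²`
  regardless of the local intensity.  Background patches (mean below 5% of
  the dynamic range) carry no speckle by construction and are excluded.

On the 200×200 phantom this recovers injected levels 0.1–0.5 with mean
absolute error below 0.015 over 20 seeds, monotone in the injected level.

## Stage 2 — fuzzy non-local restoration

For each pixel, all windows (radius 2) within a search radius of 7 are
candidates.  A candidate is graded by the *minimum* of two trapezoidal
memberships — the mean ratio against corners (0.5, 0.8, 1.25, 2.0) and the
variance ratio against (0.25, 0.5, 2.0, 4.0), both roughly symmetric in
log-ratio around 1 — and discarded when membership falls below 0.1.
Survivors are weighted by `membership · exp(−t²/2τ²)`, where `t` is the
RMS window difference (normalizing by pixel count keeps τ² comparable
across window sizes), LLMMSE-smoothed with gain
`k = clip((s² − τ²)/s², 0, 1)`, and combined as a weighted mean (centroid
defuzzification).  The self window always survives with weight 1, so the
output is always defined, and since every contribution is a convex
combination of input values, the result never leaves the input range.
`τ² = 0` short-circuits to the identity.

The pipeline sets `τ² = v̂_residual · mean(informative intensity)`, where
`v̂_residual` is re-estimated from the *shrunk* image: reusing the raw
noise level would over-smooth an input that stage 1 already cleaned
(measured ~2 dB loss on the phantom benchmark).

## Parameter search

The water-wave swarm treats each candidate `(D, α)` as a particle with a
per-dimension wavelength.  Per iteration: propagation
(`x += inertia(t)·wavelength·U(−1,1)`, inertia 0.9 → 0.4 linearly),
wavelength decay ×0.95 for fitter-than-median particles and growth ×1.05
otherwise, a burst of 3 breaking probes around the global best whose
radius (initially 0.25 of the bound span) shrinks ×0.7 whenever a burst
fails — a pattern-search refinement that gives the late-stage precision —
and refraction of particles stagnant for 6 iterations toward the best.
Elitism keeps the best-ever solution, making the trace monotone.  Fitness
is evaluated on a random half of the 64×64 tile cover, a fresh batch per
iteration shared by all particles; the identity candidate `D = 0` is
seeded into the swarm so the tuned result can never score below "do
nothing" under the same objective.  Default search box:
`D ∈ [0, 3·σ̂·√(2 ln N)]` (universal-threshold-scaled, σ̂ from the MAD of
the finest diagonal band), `α ∈ [0, 10]`.

Objectives: full-reference `0.5·min(PSNR, 50)/50 + 0.5·MSSIM` (maximized);
no-reference `ABG + DEI` (minimized).

## Quality metrics

All formulas are pinned in `despeckle.metrics`.  Notable conventions: SSIM
uses the 11×11 Gaussian window (σ = 1.5) with stabilizers `(0.01L)²`,
`(0.03L)²`; Canny runs at σ = 1.4 with hysteresis thresholds 0.1/0.2 of
the dynamic range (the edge map choice materially changes FOM, hence
pinned); FOM uses Pratt's constant 1/9; DEI pairs a 3×3 window with a 9×9
window and takes the minimum narrow-window std over the broad window's
interior, reported as a non-negative ratio with *lower better* — a
"negative DEI" is impossible for a ratio of standard deviations; UQI uses
sliding 8×8 windows, skipping zero-denominator (flat) windows; QILV
applies the UQI structural comparison globally to the two local-variance
maps; ENL auto-selects the minimal-variance 32×32 tile unless a mask is
given.  The ABG composite is
`β|τ_ENL| + (1−β)|τ_θ| + γ` (β = 0.5) on the ratio image noisy/filtered:
`τ_ENL` the inverse ENL of the ratio over the homogeneous tile, `τ_θ` the
standard deviation of the ratio's 9×9 local mean around 1 (structure
leaking into the ratio — an interpretation, as is the SRS combiner),
and γ the correlation of the Laplacian-filtered noisy and ratio images.
`SRS = 100 · mean(SSIM map) · FOM` on a 0–100 scale: it saturates only
when the image is both structurally faithful and keeps edges in place.

Degenerate cases use explicit sentinels: identical images report
`PSNR = inf`; correlation-type metrics on constant images report NaN; an
identity "filter" gives a constant ratio image, `γ = 0` by convention.

Argument-order and invariance notes: NK, SC, NAE, SNR, AD and LMSE are
reference-first; CoC and MSSIM (with shared stabilizers) are symmetric.
MSE/RMSE/PSNR/AD/MD/CoC/LMSE are invariant to adding a common constant to
both images; the normalized/ratio metrics (NK, SC, NAE, UQI, SSIM's
luminance term) are anchored to the intensity scale by construction and
are not.

## Problem sizes and determinism

The shipped benchmarks use the 200×200 phantom (the reference study
size), 20 seeds per noise level for the recovery table, a 20-particle ×
30-iteration tune for the pipeline benchmark, and 100 seeded runs for the
sphere convergence check — sizes chosen so the whole suite and the
acceptance script each run in minutes on a single core while keeping the
Monte-Carlo error well inside the asserted tolerances.  Every stochastic
component takes an explicit seed; pipeline runs embed the resolved
configuration and seed in their report, and re-running a report's config
reproduces its output bit-for-bit.

## Known limitations

* Speckle is simulated as pixelwise-independent Gaussian noise; real
  speckle is spatially correlated by the imaging point-spread function,
  which would lower the patch-covariance estimator's accuracy (its
  smallest-eigenvalue floor absorbs correlated noise into the "signal"
  subspace).
* The `H = 0.5` estimator mapping assumes the exponent used by the
  simulator; blind estimation of `H` itself is out of scope.
* The log-domain shrinkage stage contributes little at high noise on
  piecewise-constant images — the tuner routinely drives `D` toward small
  values and lets the restoration stage do the heavy lifting; on textured
  inputs the balance may differ.
* Grayscale 2-D only; no DICOM, no physically realistic beam simulation.
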