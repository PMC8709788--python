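# Methods

This note documents the models behind `cipkit`, the parameters that
matter, the approximations made by the synthetic-data generators, and the
numerical choices where the design was genuinely open.  It states no
empirical result that the test suite or `scripts/acceptance.py` does not
itself compute.

## Raster-scan simulator

Fluorescent species diffuse by Brownian dynamics in a periodic box: a
square of side ≥ 1.5× the scan field laterally (default exactly 1.5×, so
edge artifacts of the periodic wrap stay outside the PSF reach) and a slab
of ±2 wz axially, with periodic replacement in all three axes so the
particle number is stationary.  The detection volume is a 3D Gaussian with
1/e² waists w0 (default 300 nm) and wz (default 1000 nm), realistic for a
1.2 NA water-immersion objective at 488–561 nm.  With the convention
N = c·(π/2)^(3/2)·w0²·wz, the zero-lag correlation amplitude of the
simulated signal is γ/N with γ = 2^(−3/2), matching the fit model; the
helper `particles_for_focal_number` converts a desired in-focus N into a
box particle count.

*Line-granularity updates.*  Particle positions advance once per scan
line (step σ = √(2 D τ_l) per axis); positions are frozen within a line.
This is accurate because the pixel dwell time (2.05 µs) is three orders
of magnitude shorter than the line time (1.23 ms): the fast-axis
correlation decay contributed by diffusion during τ_p is
4 D τ_p/w0² ≈ 10⁻³ per pixel lag even at D = 25 µm²/s, far below the
scanning-Gaussian term the model captures.  Any residual frame gap
(frame time − rows·line time) adds one extra diffusion step per frame.

*Photon counting.*  Per pixel, each particle contributes
brightness · τ_p · W(r) expected counts (W the Gaussian PSF weight at the
particle position relative to the beam); expected counts are distributed
over the 23 spectral channels by the species' emission spectrum and
Poisson sampled.  Default brightnesses follow typical counts per
molecule: 25 kHz (eGFP-like), 15–20 kHz (YFP-like), 10 kHz
(mCherry-like).  Emission spectra are skew-normal shapes over 23 channels
of 8.9 nm starting at 490 nm, peaking near 505/525/605 nm; the exact
shapes are free parameters.  The PSF is truncated at 2.5 w0 laterally
with a 10⁻⁶ relative amplitude floor — truncation error is far below
shot noise at these brightnesses.

*Heterodimers.*  A species with `bound_fraction` b shares ⌊b·n⌋ of its
particles with the last species in the list: each dimer follows a single
trajectory (diffusing with the slower partner's D) and emits both
partners' spectra.  Dimers consume partner particles, so total copy
numbers per species are preserved.  This is what generates spatial
cross-correlation between unmixed channels, with rel.cc → b for equal
concentrations.

*Not modeled:* triplet/blinking photophysics, detector afterpulsing,
fluorophore maturation or dark states, optics beyond the Gaussian PSF.
Real positive controls sit below rel.cc = 1 because of non-fluorescent
states and imperfect volume overlap; in the simulator the positive
control is ideal, and the control normalization removes the residual
statistical bias of the max-based rel.cc estimator instead.

## Spectral unmixing

Filters are the weighted least-squares construction of fluorescence
lifetime/spectral correlation spectroscopy: F = (MᵀWM)⁻¹MᵀW with
M[k,s] the reference emission probabilities and W = diag(1/⟨I(k)⟩) the
inverse stack-mean channel counts (the Poisson variance proxy).  Filters
are computed per measurement from that stack's own channel means,
mirroring daily reference calibration.  Channels with mean counts below
1e−3 are excluded (their weights would explode); the construction raises
an explicit error when (MᵀWM) is ill-conditioned (condition number
> 1e8) rather than silently pseudo-inverting.  Decomposition is linear
and unbiased in expectation; per-pixel species amplitudes may be
negative.

## ARICS correlation and diffusion fits

The masked correlation uses only pixel pairs with *both* pixels inside
the ROI, normalized per lag by the number of such pairs; it is computed
with zero-padded FFTs and is exactly equal (to 1e−10) to the brute-force
double-loop estimator the tests carry.  δI is taken per frame against
the frame's ROI mean; amplitudes are normalized by the overall ROI means
of both channels.

The fit model is the standard normal-diffusion RICS form (diffusion
factor × scanning-Gaussian factor, γ = 2^(−3/2)), with scan timings and
waists fixed from the configuration and N, D, offset free
(Levenberg–Marquardt via lmfit, xtol = ftol = 1e−12).  "Converged to
meaningful parameters" means: solver success, D within [1e−3, 1e3]
µm²/s, and relative standard errors of N and D below 100%; a fit of a
pure-noise CCF map fails this rule, which is exactly how the pipeline
distinguishes no binding (rel.cc set to 0) from weak binding.

*Zero-lag handling.*  The (0,0) pixel carries the shot-noise spike and
is excluded from ACF fits.  It is excluded from CCF fits of spectrally
decomposed stacks as well: the species stacks are linear combinations of
the *same* detector channels, so the same photon-detection events appear
in both and contribute a shot-noise cross term Σ_k f_i(k) f_j(k) ⟨I(k)⟩
at zero lag.  `fit_diffusion_model(..., exclude_zero_lag=False)` restores
the inclusive behaviour for truly independent detectors.

*High-pass interaction with slow tracers.*  The 4-frame high-pass is
implemented as the average of the two 4-frame windows adjacent to each
frame (symmetric weights 1/8, 1/4, 1/4, 1/4, 1/8, which cancel linear
drifts exactly and trim 4 frames); it scales all correlation amplitudes
by the factor 0.71875, which cancels in rel.cc and binding efficiencies
but inflates fitted N by 1/0.71875.  For species so slow that genuine
correlation survives between frames (D ≈ 1 µm²/s gives an inter-frame
displacement ≈ 1.1 µm, inside the line-lag range) the filter clips that
correlation and biases fitted D low; at the ≥10 µm²/s diffusivities of
cytosolic proteins the inter-frame correlation is < 1% and the filter is
harmless.  The D-recovery validation therefore correlates the stationary
raw stacks, while the binding pipeline keeps the high-pass.

*Binding efficiency.*  BE = (rel.cc_sample − rel.cc_neg) /
(rel.cc_pos − rel.cc_neg) by default; dividing by the positive control
alone is available via `normalize_span=False` (the normalization wording
admits both readings).  Values are clipped below at 0; values above 1
are kept and flagged.  Cells should be screened with
`screen_expression_balance` (reject when any pairwise mean-intensity
ratio reaches 3, strict).

*Default lag ranges* are ±32 pixel lags × ±16 line lags; the published
analysis does not state its ranges.

## Translocation movies and t₀.₇₅

The generator renders an elliptical cell with curvilinear
mitochondria-like blobs (persistent random walks dilated to ~5 px
width, 12–28% of the cell area).  The receiver channel carries a
cell-wide cytosolic component plus a mitochondrial component fed by
exponential recruitment f(t) = 1 − exp(−k t); the amount gained on
mitochondria exactly equals the amount lost by the pool, so whole-frame
intensity is conserved up to bleaching.  The recruited pool is a
fraction β (`depletion`, default 0.05) of the cytosolic signal: real
recruitment does not transfer the entire cytosol, and a full transfer
would make the mito/cytosol ratio diverge rather than follow the
kinetics.  The measured ratio is then analytically

    ratio(t) = (bg + c(t) + m(t)) / (bg + c(t)),
    c(t) = c₀(1 − β f(t)),  m(t) = β f(t) c₀ A_cell / A_mito

and the min–max-normalized trajectory equals f(t) up to a crossing-time
bias of +2.9% at β = 0.05 (solving ρ = 0.75 gives
f* = 0.75/(1 − 0.25β) for long movies) — inside the one-frame-interval
tolerance the recovery targets use.  At β → 0 the normalized trajectory
is exactly 1 − exp(−k t), but frame conservation becomes vacuous.

Defaults: 128×128 px, cytosol 200 counts, receptor 300 counts,
background 5 counts, Poisson noise, 1-px optical blur, Gaussian
illumination (σ = 0.8 × image size), receptor-channel misalignment
(0.6, −0.4) px, bleach rates 5e−4 s⁻¹ per channel (≈ 18% decay over a
400 s movie, below the ~25% the acquisitions tolerate), a bead-pair
alignment reference, and a 3 s injection delay (the stated 2–4 s mixing
delay) that also defines the time origin: first post-addition timestamp
minus the delay.

Analysis choices: segmentation uses classical operators rather than a
trainable classifier — a learned model would need manually annotated
training images that a self-validating package cannot ship (cell:
Gaussian blur + Otsu
+ hole fill + largest component on the purely cytosolic pre-addition
receiver image; mitochondria: white top-hat + per-image Otsu on the
receptor channel), with the robustness checks promoted to QC assertions
(mitochondrial area fraction typically 10–40%, hard warning limits
1–60%; receptor-ROI stability).  Because the normalization anchors
absorb any constant cytosol/mito mixing, moderate segmentation error
does not bias t₀.₇₅ — it only adds jitter.  Bleach correction divides
each channel by a mono-exponential fitted to its whole-frame mean
(linear fallback).  t₀.₇₅ is the first upward 0.75 crossing of the raw
normalized trajectory, linearly interpolated between bracketing frames
and anchored at (0, 0); no smoothing.  The end anchor defaults to the
final image pair, with a plateau mean over the last pairs behind
`plateau_mean_pairs`.  Exclusion: receptor mito-ROI coefficient of
variation > 20% after bleach correction; warning: whole-cell receiver
variation > 2%.

## Dose–response

The generator produces DMSO-normalized responses R(c)·(1 + ε),
ε ~ N(0, CV) per replicate well (multiplicative noise, CV default 5%;
the noise model is not specified by the source workflow), DMSO wells at
1, and splits each well's integrated signal into 20 equal readings.  The
fitted model is the printed one-site Hill form with implicit Hill
coefficient 1 and no floor parameter; EC50 is fitted as log₁₀(EC50) for
positivity.  Confidence intervals bootstrap the replicate wells (1000
resamples by default).  A warning is raised when the fitted EC50 exceeds
the largest concentration or the responses never reach 80% of the fitted
plateau (EC50 poorly constrained).  Both pooled and per-experiment
aggregation are possible by passing the corresponding replicate matrix.

## Colocalization

"20-pixel Gaussian" background subtraction is interpreted as σ = 20 px
(configurable), reflective boundaries, applied to the full image before
masking.  Pearson R is computed per z slice inside the (manual) cell
mask — zero-intensity pixels retained — and averaged unweighted over
slices; the tests assert by construction that this is not the same as
pooling voxels.  Paired comparisons across shuttling steps use two-sided
paired t-tests on per-cell values (p = 1 by convention for identical
scores).

## Validation strategy and what it does not show

Every pipeline is validated by recovering generator ground truth:
EC50s seeded at 0.43/30.8 µM, crossing times at 10.1/107.9 s, bound
fractions at 0.77/0.41, plus property suites (brute-force correlation
oracle, filter unbiasedness to 1e−9, rel.cc limits for pure dimers and
independent species, Pearson null, hand-computed t statistics, Welch
type-I error at 10,000 null replicates).  Recovery problem sizes are
desk-scale reductions chosen after pilot runs: 128×128 px / 100-frame
scans with N ≈ 2.5 per species for the binding targets (the original
acquisitions were 256×256 / 300–400 frames), 20 seeds for D recovery,
10 movies per crossing-time target, 50 plates per EC50 target.

Passing these tests shows the estimators are correct and unbiased under
the generative model; it does not certify performance on real data,
whose cells have heterogeneous expression, organelle exclusion zones,
photophysics and drift the generators only partially emulate (the QC
defects — corrupted illumination sequences, focus loss, misalignment,
bleaching — are modeled; the biology is not).

## Known limitations

* The rel.cc estimator (a max of two correlated ratios) is biased
  upward at low statistical power; the control normalization removes
  most but not all of this bias, which is why the binding-efficiency
  targets carry the widest tolerances.
* The diffusion fit weights all lags equally; at very low
  signal-to-noise the offset–D degeneracy inflates the estimator
  variance (visible in the per-seed spread of the D-recovery test).
* The translocation model is two-dimensional; out-of-focus recruitment
  and cell movement are not simulated (movement was negligible in the
  acquisitions this emulates).
* Anomalous diffusion, two-component fits, temporal ICS and
  number-and-brightness analysis are out of scope.
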