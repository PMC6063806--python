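# Methods

`rdpet` studies the behavior of penalized-likelihood PET reconstruction —
BSREM (block sequential regularized expectation maximization) with the
relative difference penalty (RDP) — against the clinical reference of
early-stopped, post-filtered OSEM, on synthetic pelvic phantoms that
emulate a 2-minute ^68Ga-PSMA PET/MR acquisition.

## Forward model

The measured sinogram is modeled per bin as `y_i ~ Poisson([Px]_i + b_i)`
with `x` the activity image in SUV (g/ml) and `b` the expected
randoms+scatter background.  The operator `P` composes, in order: an
isotropic in-plane Gaussian point-spread model (FWHM 5.4 mm, the reported
resolution scale for ^68Ga on TOF PET/MR), slice-by-slice 2D parallel-beam
line integrals (Joseph bilinear interpolation along the ray's dominant
axis), TOF binning (a Gaussian kernel over the along-ray emission
coordinate, FWHM 60 mm ≈ the spatial localization of a <400 ps timing
resolution, 7 bins of width FWHM/2, truncated at ±3σ and renormalized so
TOF bins sum exactly to the non-TOF projection), per-line attenuation
factors `exp(-∫ μ dl)` computed from the phantom's μ-map with the same
projector, user-suppliable normalization factors (identity by default;
decay/dead-time calibrations would enter here), and a global `count_scale`
setting the count level.  The back-projector is the exact sparse-matrix
transpose, so the adjoint identity holds to round-off; every EM-type
update relies on this.

The choice of stacked 2D parallel-beam geometry rather than fully-3D
cylindrical geometry is deliberate: the questions studied here concern the
optimizer and the penalty, not scanner geometry, and a 2D stacked
projector preserves every algorithmic ingredient (Poisson likelihood,
subsets, TOF, PSF, attenuation) at desk scale.

## Phantom and simulation

The default phantom is a 96×96×16 grid at 2.34×2.34×2.78 mm voxels (the
clinical reconstruction pitch, with reduced transaxial extent): an
elliptic soft-tissue body (semi-axes 95×80 mm, background 1.0 g/ml,
μ = 0.096 cm⁻¹, no bone — the MR-based attenuation situation in the
pelvis), a bladder sphere (r = 22 mm, SUV 7.7 g/ml, the
furosemide-reduced bladder level), and one spherical lesion per stratum:
0.5 cm³ / SUV 4 (small & low uptake), 3 cm³ / SUV 7 (medium), 12 cm³ /
SUV 20 (large or high uptake).  Spheres are voxelized by the
center-in-sphere rule.  A 12 mm background ROI sphere sits in uniform
soft tissue away from bladder and lesions.  Cohort variants jitter lesion
radii and SUVs by ±15% and centers by ±3 mm, emulating between-patient
diversity while keeping strata membership stable.

Counts are Poisson draws around `P(activity) + b`, where `b` is a
radially smooth, angle- and TOF-uniform sinogram whose total equals 30%
of the total trues (a typical pelvic randoms+scatter share).  The
reconstructor receives `b` exactly — the scatter/randoms estimation stage
is assumed ideal, isolating the optimizer comparison.  `count_scale`
(0.348 counts per SUV·mm, ≈ 2.6 M counts per acquisition) was calibrated
once, with the helper in `rdpet.calibrate`, so that the reference OSEM
background coefficient of variation is ≈ 0.22 — the noise regime of the
clinical 2-minute frames (background SUVstd ≈ 0.22 at SUVmean ≈ 1).  The
useful range of the penalty strength is count-level dependent, so it is
the noise regime, not an absolute dose, that is matched.

## Reconstruction

*OSEM*: standard ordered-subset EM over an interleaved angular partition
(subsets visited in bit-reversal order), uniform start image, per-subset
sensitivity images.  With one subset it reduces exactly to MLEM, which is
tested.  The clinical reference is 2 iterations / 28 subsets followed by
the post-filter: normalized in-plane Gaussian of FWHM 5.0 mm, then an
axial 1:4:1 three-slice kernel, both with renormalized truncation at the
edges (a constant image is exactly preserved).

*BSREM*: maximizes `loglik(x) − β R(x)` with the RDP
(`γ = 2`, 26-neighborhood, inverse-distance edge weights in voxel units,
optional per-voxel weights `w_j`, default 1).  The RDP is degree-1
homogeneous, giving activity-dependent noise control; its exact gradient
`∂ψ/∂x_j = d·(x_j + 3x_k + γ|d|)/den²` is implemented (numba kernels) and
verified against central finite differences.  Note the exact gradient is
*not* pairwise antisymmetric — the pair denominator depends on
`x_j + x_k`, so the gradient's total sum is `≤ 0` and Euler's identity
`⟨x, ∇R⟩ = R` holds; both are asserted in tests.

The vendor's exact BSREM update is not public; we use a standard relaxed
preconditioned ascent: for subset m,
`x ← clip(x + α_k D(x) [M ∇L_m(x) − β ∇R(x)], [0, U])` with
`D = diag((x+ε)/s)`, `s` the full sensitivity image, `M` the subset
count (subset balancing), `α_k = α₀/(1 + 0.05 k)` decaying over full
iterations, `α₀ = 1`, `ε = 10⁻⁶ U`, `U = 200` SUV (10× the hottest
phantom structure).  With β = 0, one subset, α = 1, ε = 0 the step is
algebraically MLEM, which is tested to 1e-10.  The default staged
schedule is 2 iterations of non-TOF OSEM, 3 of non-TOF BSREM, then 8 of
TOF BSREM, all with 28 subsets; non-TOF stages consume the TOF sinogram
summed over TOF bins (exactly consistent with the projector's TOF mass
preservation).  The full-data penalized objective is monotone over the
TOF-BSREM stage under this relaxation on the default phantom (asserted
per-iteration); monotonicity across stage boundaries is not expected,
since the non-TOF stages optimize a different likelihood.  Objective
tracking is off by default in sweeps (each evaluation costs a full
forward projection) and can be requested per iteration or per
sub-iteration.  BSREM output is never post-filtered.

## Quantification

Background: mean and population SD over the background ROI (SUVstd is the
noise surrogate; the population/sample choice is applied uniformly so
paired comparisons are unaffected).  Lesions: SUVmax = mean of the 5
hottest voxels within the true lesion mask dilated by one voxel (so PSF-
displaced hot voxels are captured; fixed across algorithms).  Contrast
recovery `CR = (SUVmax/SUVmean_bkg − 1)/(SUVmax_ref/SUVmean_bkg_ref − 1)`.
Lesions are stratified on reference-reconstruction values: small&low
(≤ 1 cm³ and ≤ 5 g/ml, boundaries inclusive), large-or-high (> 10 cm³ or
> 10 g/ml), medium otherwise.  Paired conditions are compared with the
two-sided Wilcoxon matched-pairs signed-rank test (zeros dropped; exact
null for ≤ 25 nonzero pairs, normal approximation above), flagging H/L at
p < 0.05 with no multiple-comparison correction (the sweep subsamples one
β axis, where extra tests do not manufacture positives).

## Beta scale

Absolute β values are not comparable across implementations: the balance
point between likelihood and penalty gradients depends on count level,
projector normalization and neighborhood weights.  The conventional
clinical labels 150–1200 are therefore kept as labels, with operative
strength `β = label × 1.53·10⁻⁴`; the scale was calibrated once (helper in
`rdpet.calibrate`) so that the noise-match point — BSREM background SUVstd
equal to the post-filtered reference OSEM's — falls at label 400, its
conventional location for 2-minute acquisitions.  With that single
anchoring, the rest of the behavior (H flags below 400, L flags above,
the 400–550 window, the stronger SUVmax loss of small low-uptake lesions
at high β) emerges from the model rather than from calibration.

## Problem sizes and determinism

Default experiments use 96 projection angles, 112 radial bins (2.34 mm),
7 TOF bins and 28 subsets; cohort analyses use 12 phantoms (enough
resolution for the exact signed-rank null at p < 0.05 with paired
medians).  The acceptance script sweeps 5 beta labels over 12 phantoms;
the test suite uses the full 15-label grid on a single seed for
monotonicity and a 4-label grid for the cohort checks.  All randomness
flows through explicit integer seeds (phantom jitter and Poisson draws
derive per-phantom seeds from one base seed via `SeedSequence`); repeated
runs are bit-identical.

## What the synthetic setting does and does not show

The phantom reproduces the *structure* the clinical analysis relies on —
uniform background with a measurable noise ROI, hot lesions in three
strata near a hot organ, MR-AC-like boneless attenuation, a clinically
plausible count level and scatter fraction — so passing tests demonstrate
properties of the estimators (noise growth vs plateau, monotone β
response, the noise-matched window, stratum-dependent SUVmax loss).  It
does not reproduce patient anatomy, positron-range or depth-of-interaction
blur, scatter estimation error, halo artifacts near the bladder, fully-3D
geometry, or the paper-reported absolute percent changes from 25 clinical
scans; absolute numbers here characterize this artifact, not the scanner.

## Numerical choices and edge cases

Rays are clipped to the grid; voxels outside the elliptic body carry no
activity, so truncation at the grid edge is immaterial.  EM ratios use
`0/0 = 0`; bins with zero expectation and nonzero counts drive the
log-likelihood to −∞ and are flagged.  MLEM/OSEM zero out voxels with
zero sensitivity.  BSREM clipping at `[0, U]` is a plain projection.
RDP pairs with `x_j = x_k = 0` contribute zero to value and gradient.
The post-filter renormalizes truncated kernels at image edges; the PSF
inside `P` deliberately does not (zero-padded symmetric blur keeps the
operator self-adjoint).  SUVmax falls back to all voxels (with a warning)
for masks smaller than 5 voxels.  Interfaces are the importable API plus
the `examples/` scripts; phantoms persist as NIfTI + JSON sidecar,
sinograms as `.npz` + JSON sidecar, sweep reports as CSV + JSON with a
config hash and all seeds.
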