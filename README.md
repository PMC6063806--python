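# rdpet

Penalized-likelihood PET reconstruction at desk scale: simulation of
time-of-flight (TOF) emission sinograms from digital pelvic phantoms, OSEM
and BSREM (relative difference penalty) reconstruction, and the SUV
quantification used to choose the regularization strength β.

## Who this is for

People studying how regularized PET reconstruction behaves — in
particular the trade-off, familiar from clinical ^68Ga-PSMA pelvic
imaging, between background noise and lesion SUVmax as β varies.  Clinical
OSEM must be stopped early (noise grows with iterations) and post-filtered,
which leaves small-lesion contrast unconverged; BSREM runs to effective
convergence while the penalty controls noise, so the question becomes:
which β matches the reference noise while preserving or improving SUVmax?
`rdpet` makes the whole pipeline — phantom, Poisson TOF acquisition,
reconstruction, quantification, paired statistics — reproducible on a
workstation.

## The model

Reconstruction maximizes the penalized Poisson likelihood

    x̂ = argmax_{x ≥ 0}  Σ_i [ y_i log([Px]_i + b_i) − ([Px]_i + b_i) ] − β R(x)

where `P` is the TOF projector with attenuation, normalization and PSF
resolution modeling, `b` the randoms+scatter background, and `R` the
relative difference penalty

    R(x) = Σ_j Σ_{k∈N_j} w_j w_k (x_j − x_k)² / ((x_j + x_k) + γ|x_j − x_k|),  γ = 2,

whose degree-1 homogeneity makes noise control activity-dependent and whose
γ term preserves edges.  The BSREM optimizer cycles through angular
subsets with relaxed, preconditioned, clipped ascent steps; with β = 0 and
one subset it reduces exactly to MLEM.  Quantification follows clinical
practice: background SUVmean/SUVstd in a uniform ROI (SUVstd = noise
surrogate), lesion SUVmax = mean of the 5 hottest voxels, contrast
recovery CR = (SUVmax/SUVmean_bkg − 1) / (same for the reference OSEM),
Wilcoxon matched-pairs signed-rank tests at p < 0.05.  See
`docs/methods.md` for the full account.

## Worked example

`python examples/02_osem_vs_bsrem.py` simulates one 2-minute-like pelvic
acquisition (≈2.6 M counts) and reconstructs it with the clinical
reference (TOF OSEM 2 it / 28 subsets + 5 mm / 1:4:1 post-filter) and with
BSREM at the noise-matched strength (β label 400):

                                  OSEM ref  BSREM b400    true
    background SUVmean (g/ml)        1.052       1.048     1.0
    background SUVstd  (g/ml)        0.234       0.232     0.0
    lesion_small_low SUVmax           2.77        2.85     4.0
    lesion_medium SUVmax              8.55        9.07     7.0
    lesion_large_high SUVmax         23.10       24.54    20.0

At matched background noise (SUVstd 0.232 vs 0.234 g/ml), BSREM recovers
more lesion contrast than the reference in all three strata — the window
the β sweep is designed to locate.  (SUVmax above the true SUV for the
larger lesions is edge overshoot from resolution modeling, present in both
algorithms.)  `examples/03_beta_sweep.py` runs the cohort sweep and prints
the summary table with H/L significance flags per lesion stratum.

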