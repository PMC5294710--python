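# Methods

## Scope and model overview

`shgscatter` quantifies extracellular-matrix collagen organization in thin
tissue sections from two optical measurement families and combines the
resulting metrics in a linear discriminant:

1. **SHG emission directionality and conversion efficiency.** Second
   harmonic generation in collagen is coherent: momentum conservation under
   imperfect phasematching splits the created signal into forward
   (F_SHG) and backward (B_SHG) lobes whose ratio reflects fibril diameter
   and packing relative to the SHG wavelength. The *measured*
   forward/backward ratio at the detectors additionally carries the
   signature of photon scattering between the focal volume and the two
   detectors, so the intrinsic ratio and the relative conversion
   efficiency are recovered by fitting measured depth-resolved responses
   against a Monte Carlo transport model.
2. **Optical scattering spectroscopy.** Collimated on-axis transmission
   through a thin section gives the scattering coefficient μs by
   Beer–Lambert (absorption is negligible in fibrillar tissue, μa ≪ μs);
   with the separately measured anisotropy g this yields the reduced
   scattering coefficient μs′ = μs(1 − g). Its spectrum follows a
   Whittle–Matérn-motivated power law μs′(λ) ∝ λ^(2m−4); the shape factor
   m summarises sub-micron structural order (roughly half the fractal
   dimension; larger m ↔ larger, more ordered structures).

Both families are wavelength-resolved: SHG excitation sweeps 780–1160 nm
(SHG emission 390–580 nm) and scattering is measured at
390, 445, 494, 535, 780, 890, 988, 1070 nm, with the shape-factor fit
restricted to the 390–535 nm band where spectral contrast between tissues
is largest.

## Monte Carlo transport model

The forward model is a weighted-photon random walk in the MCML tradition,
specialised to SHG creation at a scanned focal depth inside a single
homogeneous slab:

- **Source.** Photons are created at the focal depth with total weight
  proportional to the relative conversion efficiency times the ballistic
  focal excitation weight exp(−2 μs,ex z) — excitation reaches the focus
  ballistically and SHG is quadratic in excitation intensity. Launch
  directions are uniform in solid angle within a cone of half-angle
  asin(NA_exc/n_tissue) about +z (forward lobe) or −z (backward lobe).
- **Stratified lobe split.** Exactly round(N·F/(1+F)) photons launch
  forward (F the intrinsic ratio) rather than a Bernoulli draw per photon.
  This removes pure binomial noise from the quantity being inverted and
  makes the transparent-slab limit exact per batch; it is unbiased
  whenever N·F/(1+F) is integral and biased by at most 1/N otherwise.
- **Propagation.** Exponential free paths with μt = μs + μa;
  Henyey–Greenstein deflections with the measured g (the walk tracks only
  (z, u_z); by azimuthal symmetry the marginal update
  u_z′ = u_z cosθ_d + √(1−u_z²) sinθ_d cosφ is statistically exact);
  per-collision weight decay by the single-scattering albedo when μa > 0;
  Russian roulette below weight 10⁻⁴ with survival probability 0.1.
  Roulette kills *and* the matching survival boosts are routed through the
  absorbed tally, so weight conservation is exact per batch (audited to
  10⁻⁶ relative), not merely exact in expectation.
- **Boundaries and detection.** Unpolarized Fresnel reflection/refraction
  at the tissue/water interfaces (n_surround = 1.33 on both faces by
  default); internally reflected photons continue with the unused portion
  of their step. A transmitted photon is *detected* if its refracted exit
  angle lies within the acceptance cone of the face it crossed:
  sinθ_acc = NA/n_immersion with NA 0.9 (condenser, forward) and 0.8
  (objective, backward).
- **Determinism.** Each depth point draws from an RNG stream seeded by
  (seed, depth index); results are bitwise-reproducible and independent of
  how depth points are scheduled across workers.

The engine models a single homogeneous layer. Vibratome sections are thin
uniform slabs, and nothing in the pipeline or tests exercises a layered
geometry, so a multi-layer generalization was left out rather than shipped
untested.

## Inversion

**Intrinsic F/B.** A lookup table simulates the depth response for 33
log-spaced intrinsic-ratio candidates between 0.25 and 16 (all candidates
share one seed policy — common random numbers — so the χ² surface over
candidates is smooth). The best fit minimises

    χ² = Σ_i (FB_meas,i − FB_sim,i)² / σ_i²

with per-depth variance σ_i² = σ_meas,i² + σ_sim,i²: the measurement term
comes from replicate fields of view when available, else Poisson
propagation of the two channel intensities (var(F/B) = (F/B)²(1/F + 1/B));
the simulation term is the same propagation applied to the simulated
channel weights. Without the second term a finite-photon library could
never "accept" a high-count measurement. A fit is flagged accepted when
the χ² p-value (dof = points − 1) is ≥ 0.05; the uncertainty is the
half-width of the contiguous candidate neighborhood within +1 of the
minimum χ². Exact ties report the lower candidate and widen the
uncertainty to cover both. An optional refinement pass re-simulates five
candidates at half the grid step around the coarse minimum.

**Relative conversion efficiency.** With the fitted ratio fixed, one
simulation gives the expected detected forward curve per unit efficiency;
the efficiency is the least-squares scale factor between the measured
absolute forward curve and that per-unit curve, with the normalized-curve
RMS mismatch reported as a shape diagnostic. Detector gains and photon
budget fold into the scale, so only ratios between samples measured under
one configuration are physically meaningful; tables are therefore
normalized to their global maximum before comparison.

**Wavelength sweep.** Optical properties at arbitrary excitation/SHG
wavelengths are interpolated from the measured set: log-linear in λ for
μs (consistent with power-law scattering), linear for g, n, μa.

## Depth profiles and fiber diameters

Per-slice channel totals are sums over the field of view with the forward
channel divided by the bead-calibrated detector gain ratio. Fields of view
are averaged per depth; per-field F/B SEMs feed the inversion χ². The
"average maximum" self-normalization divides the forward curve by the mean
of its k = 3 largest slice values — robust to a single bright outlier
slice. The surface slice is the first exceeding 10% of the stack maximum
(sections sit in mounting medium).

Fiber diameter: binarize at a user threshold, seed line profiles at random
foreground pixels, orient each profile along the local dominant gradient
direction from a Gaussian-smoothed (σ = 3 px) structure tensor (i.e.
across the fiber), and measure the contiguous above-threshold run through
the seed with 0.5-px nearest-neighbour sampling (half-up rounding, which
keeps the width estimate orientation-consistent). Phantom bars are
recovered within ±1 px across orientations.

## Classification and statistics

Canonical discriminant analysis: features are standardized, within- and
between-class scatter matrices formed, and the generalized eigenproblem
S_b v = λ S_w v solved with the within-class scatter shrunk toward its
diagonal (weight 10⁻³) — necessary in the 3–4-samples-per-class regime
and with duplicated features. At most three canonical variables are
retained. Classification is nearest class centroid in canonical space
with equal priors. Pairwise accuracies fit the discriminant per class
pair; leave-one-out cross-validation is the default for cohorts (≥3 per
class), with resubstitution behind a flag. ROC curves come from an
L2-penalized logistic regression on the scores (the ridge keeps perfectly
separated data fittable); AUC is the trapezoid integral and equals the
normalized Mann–Whitney U on the fitted probabilities. Note the refit
makes AUC invariant to a sign flip of the input scores; a raw-score
ranking mode (`fit_model=False`) provides the AUC → 1 − AUC symmetry.
Group comparisons use one-way ANOVA plus *unprotected* Fisher LSD
pairwise t-tests on the pooled within-group variance, whose per-pair
type-I error under the null is the nominal 0.05 (the ANOVA-gated variant
would be conservative per pair).

The power-law fit is linear least squares of ln μs′ on ln λ (exact for
noise-free data); m = (slope + 4)/2, amplitude reported at 390 nm. It is
**unweighted by default**: inverse-variance weights estimated from the
usual three measurement locations are themselves so noisy that they
destabilize the slope (empirically, sd 0.065 weighted vs 0.054 unweighted
at the default noise level). Weighting by supplied standard errors remains
available.

## Synthetic data: what it emulates and what it does not

No per-sample ovarian measurements are publicly deposited, so the package
ships a generator whose defaults define the study conditions:

- **Five tissue presets** (normal, benign, LGS, endometrioid, HGS) with
  shape factors 1.32 / 1.01 / 1.41 / 1.40 / 1.17, scattering anchors
  μs′(390 nm) = 22 / 19 / 16.5 / 11 / 30 cm⁻¹, g = 0.90, n = 1.40,
  100-µm imaging sections and 50-µm scattering sections. Intrinsic F/B
  rises with wavelength for every tissue (at 988 nm:
  benign 8.0 > LGS 6.0 > normal 4.4 > endometrioid 3.1 > HGS 2.2);
  conversion efficiency peaks for HGS (maximum at 890 nm, decreasing with
  wavelength) while the other tissues rise, LGS most steeply. The numeric
  anchors are synthetic package constants chosen once to respect the
  qualitative cross-tissue orderings that motivated the metric design;
  they are not measured data.
- **Transmission spectra**: T = exp(−μs t) per wavelength and location
  with mean-one log-normal multiplicative noise, CV 2% (realistic for
  laser/photodiode transmission readings), three locations per specimen.
- **Image stacks**: per-slice expected channel totals from the Monte
  Carlo forward model (photon_scale 2×10⁵ detected-photon equivalents per
  launched-photon fraction, giving percent-level F/B noise per slice),
  per-pixel Poisson draws around an oriented band-pass-filtered noise
  texture (a lightweight fiber surrogate for intensity-integral and
  phantom purposes, not a biophysical fiber model), forward channel scaled
  by a detector gain ratio of 1.5 recorded in the manifest.
- **Feature cohorts**: class means from preset ground truth,
  multiplicative Gaussian within-class noise (default CV 10%),
  per-class seeded streams.
- **Cohort sizes** mirror the study design: 4/4/4/3/3 specimens for
  normal/benign/LGS/endometrioid/HGS.

Passing tests on these data demonstrate that the inversion and
classification machinery recovers known ground truth under realistic
noise and scattering — they do not validate tissue-specific biophysics
(fibril-level SHG creation physics, spatial heterogeneity within fields,
instrument drift), which synthetic data cannot supply.

## Problem sizes and numerical choices

The library default photon budget is 10⁵ per depth point. Tests and the
acceptance script run at 1.5–8×10³ photons per depth point with 11 depth
points and a 33-candidate (17 in smoke tests) grid; every stochastic
assertion carries its Monte Carlo error band at the stated budget, so
smaller batches trade precision, not correctness. Other numerics:
roulette threshold 10⁻⁴ / survival 0.1 (MCML conventions); detector
acceptance tolerance 10⁻¹² on sin θ to make boundary-equal cones
inclusive; χ² acceptance p-value 0.05; within-scatter shrinkage 10⁻³;
units cm and cm⁻¹ internally, µm and nm at I/O boundaries only.

## Known limitations

- Excitation delivery is ballistic-only; scattered excitation light
  contributing to the focal volume is neglected (standard for focused
  nonlinear excitation, but increasingly approximate in thick or very
  turbid sections).
- The emission lobes are uniform cones with the excitation half-angle;
  real SHG emission patterns are structured by phasematching.
- The anisotropy g enters as a measured input; no goniometric or
  integrating-sphere inversion is provided.
- Absolute conversion efficiencies are not obtainable — only ratios
  within one instrument configuration.
- Single homogeneous layer; no polarization, time resolution, or
  layered media.
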