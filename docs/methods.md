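# Methods

## Spectral variables and classification

All computations assume percent reflectance on the canonical 300–700 nm grid
at 1 nm (401 samples, endpoints inclusive). Sums are plain sums over grid
samples, not trapezoid integrals: luminance of a flat 0.5% spectrum is
401 × 0.5 = 200.5, and the UV chroma of any flat spectrum is 101/401 (101 of
the 401 samples lie at or below 400 nm). This convention keeps the variables
exactly proportional to integral versions on the uniform grid while making
analytic test values integer-countable.

**R_mid** summarises the position of a spectral cut-off: the wavelength at
which reflectance is halfway between its minimum and maximum, H =
(Rmin + Rmax)/2, searched in the 300–450 nm window. Rmin/Rmax are taken
within the window by default; a `minmax="full"` switch uses the global
extrema instead (both readings of the construct are defensible, and the
window-restricted one is the default because the window is where the
construct is defined). The crossing is the *first upward* crossing, located
by linear interpolation between the bracketing samples, giving sub-grid
precision (a unit step at 340 nm yields 339.5 nm). Spectra whose in-window
dynamic range is below 1e-6 reflectance units have no meaningful cut-off and
return undefined.

Classification thresholds are boundary-inclusive: R_mid ≤ 345 nm → UV⁺white,
R_mid ≥ 365 nm → UV⁻white, otherwise (or undefined) ambiguous. Ambiguous
spectra are retained and labelled but excluded from two-class statistics;
their fate in downstream analyses is a user decision, not silently imposed.

File handling is deliberately conservative: reading never resamples (the
instrument-native grid survives until `resample` is called explicitly),
resampling is linear interpolation and never extrapolates, and cleaning —
flooring negative reflectance at zero, optional local quadratic
(Savitzky–Golay) smoothing with a span given as a fraction of the grid — is
off-by-default, non-mutating, and logged in the set's provenance list.

## The visual model

Cone spectral sensitivities are Govardovskii A1 alpha-band templates
parameterised by λmax and peak-normalised. Only the alpha band is modelled;
beta-band absorbance, ocular media and oil droplets are not (an illuminant
or transmission vector can be folded in via the `illuminant` field). The
shipped λmax defaults (365, 460, 495, 560 nm for UVS/SWS/MWS/LWS) are
literature-derived approximations for a lacertid retina and are a
configuration input, not a measurement made by this package: analyses of
real data should supply the λmax values appropriate to their viewer.

Quantum catches use a flat ("ideal") illuminant by default, von
Kries-normalised against the catch of a perfect reflector, so q_i = 1 and
f_i = ln q_i = 0 for R ≡ 1. Because the RNL distance depends only on
*differences* of log catches, the overall scale of reflectance (percent vs
fraction) and of the illuminant cancels exactly.

Channel noise is intensity-independent ("neural" noise appropriate to
bright-light conditions): ω_i = w·√(n_ref/n_i) with abundances n =
(1, 1, 1, 4), Weber fraction w = 0.05 on the LWS reference, hence
ω = (0.1, 0.1, 0.1, 0.05). The chromatic distance is the Vorobyev–Osorio
closed form for four cones; for any other channel count the equivalent
generalised-least-squares form is used — ΔS² is the weighted residual of the
log-catch difference after removing the best-fitting uniform (achromatic)
shift, which is why Δf ∝ (1,1,1,1) costs exactly 0 JND and why shrinking all
ω by a factor c scales every distance by 1/c. The pairwise-matrix path uses
an isometric embedding of that projection, so matrix entries equal the
scalar closed form to rounding error. Achromatic distance is |Δf_LWS|/w.
Spectra with a zero catch in any channel (e.g. an all-zero trace) have no
finite log-catch and are flagged and excluded from matrices with a warning.

## Two-step statistics

**Step 1 (perceptual).** The between-class distance is measured between
centroids formed by the per-cone *geometric mean* of the normalised catches —
equivalently the arithmetic mean of log catches, which is how it is
computed. Uncertainty comes from a percentile bootstrap (default 1000
replicates): specimens are resampled with replacement within each class and
the centroid distance recomputed. Percentile (not BCa) intervals are used;
they are standard for this procedure, and the simulation-based coverage
check in the test suite shows mild undercoverage (~93% at nominal 95% for
groups of 30), which is characteristic of percentile intervals at these
sample sizes rather than an implementation defect. The estimate is read
against the JND bands: > 3 easily discriminable, 1–3 only under good
illumination, < 1 indistinguishable.

**Step 2 (statistical).** One-way PERMANOVA on the pairwise chromatic JND
matrix, partitioning squared interpoint distances:
SS_total = Σ_{i<j} d²_ij / N, SS_within = Σ_g Σ_{i<j∈g} d²_ij / n_g,
pseudo-F = (SS_between/(a−1))/(SS_within/(N−a)). Significance is by label
permutation with the add-one estimator p = (1 + #{F* ≥ F})/(1 + n_perm)
(default 9999 permutations), so p can never be exactly zero and its
resolution is 1/(n_perm+1). For small samples an `exhaustive` mode
enumerates every distinct relabelling and returns the exact permutation
p-value. On Euclidean distances from univariate data the pseudo-F reduces
exactly to the classical one-way ANOVA F, which the tests verify, and an
all-zero distance matrix returns an explicit degenerate result instead of a
division by zero. Multi-factor designs, strata and dispersion (PERMDISP)
tests are out of scope.

In the pipeline, the two-class comparison is restricted to spectra of white
or white-orange individuals: the R_mid thresholds encode the position of a
*near-UV* cut-off and are not meaningful for yellow/orange long-pass
spectra, whose cut-offs sit in the human-visible range.

## The synthetic cohort generator

The generator's purpose is to produce data with the statistical structure
the analysis assumes — not to fit any particular field dataset. Each
spectrum is a logistic long-pass curve
R(λ) = base + amp/(1 + e^−(λ−λ₀)/s), multiplied by per-sample lognormal
noise and perturbed by additive Gaussian noise, clipped at zero. Defaults:

| parameter | default | why |
|---|---|---|
| λ₀ per class | UV⁺white N(330, 5), UV⁻white N(390, 5), yellow N(460, 8), orange N(520, 10) nm | white-class means symmetric about the 345–365 nm threshold gap so that, at default noise, both classes are essentially always unambiguous — tests then measure algorithm error, not generator overlap |
| slope s | 8 nm | a realistic cut-off steepness for structural whites; steep enough that R_mid ≈ λ₀ |
| base, amplitude | 3%, 40% | ventral white patches plateau at a few tens of percent reflectance above a small baseline |
| multiplicative / additive noise SD | 0.05 (log units), 0.5% | spectrometer-like per-sample jitter; shifts R_mid by ≲ 2 nm |
| cohort | 400 specimens, 50:50 UV⁺/UV⁻, throat + belly each, 10% throat/belly class discordance, balanced sexes | the default study conditions for recovery and discriminability tests |

What the generator deliberately does *not* emulate: pigment physics
(carotenoid/pterin absorbance shapes), ontogenetic colour change, spatial
autocorrelation within localities, probe-geometry artefacts, or any
calibration to real per-class R_mid dispersions (which are not available).
Passing tests on simulated cohorts therefore demonstrate that the pipeline
recovers the structure it assumes, under measurement-like noise — not that
any particular field dataset satisfies those assumptions.

All randomness flows through one seeded `numpy` generator; the same config
(seed included) reproduces cohorts, bootstrap intervals and permutation
p-values byte-identically, and the pipeline manifest records the config
hash and per-output content hashes to make this checkable.

## Problem sizes used by the test suite

Simulation-based checks are sized to run in seconds while keeping Monte
Carlo error well inside the asserted tolerances: 1000 random instances for
the closed-form/GLS equivalence, 1000 null replicates (16 points, 199
permutations each) for the PERMANOVA type-I rate, 500 replicates (30 + 30
specimens, 200 bootstrap draws) for CI coverage, and the 400-specimen
default cohort for end-to-end recovery and discriminability.

## Known limitations

- The RNL model covers bright-light chromatic discrimination only; dark
  noise and quantum fluctuations are not modelled.
- Achromatic JNDs use the LWS channel alone (no double-cone channel, which
  lizards lack in the usual formulation used here).
- The threshold classifier is deliberately simple; it will misbehave on
  spectra whose shape violates the long-pass assumption (e.g. sharply
  peaked UV-only reflectance), which is why the pipeline restricts it to
  white-morph spectra.
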