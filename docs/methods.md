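# Methods

## The model

`pulseoxmc` simulates transmittance-mode finger pulse oximetry with
weighted Monte Carlo photon transport, to quantify how epidermal melanin
concentration shifts the SpO₂ calibration relation and to derive
skin-tone correction factors.

### Finger geometry

The finger is a stack of plane-parallel slabs, 13 mm source-to-detector:
six skin sublayers (stratum corneum, epidermis, papillary dermis, upper
blood-net dermis, reticular dermis, deep blood-net dermis), subcutaneous
fat, a central muscle slab containing a bone cylinder, then fat and the
six skin sublayers mirrored on the detector side.  Both skin stacks carry
identical pigmentation.  Default sublayer thicknesses follow published
layered skin/finger models (stratum corneum 0.02 mm, epidermis 0.08 mm,
papillary dermis 0.18 mm, upper blood net 0.08 mm, reticular dermis
1.5 mm, deep blood net 0.1 mm, fat 0.8 mm per side); the muscle thickness
is derived so the total is exactly 13 mm, the one hard geometric
constraint.  The bone is an infinite cylinder of radius 2 mm (configurable)
whose axis runs perpendicular to the optical axis, centred in the muscle
slab.  The tissue is bounded laterally at |y| = 6.5 mm (a 13 mm-wide
finger; packets crossing the flank escape) and unbounded along the bone
axis, where a translation symmetry is exploited by the detector
estimator.

### Optical properties

Only the two oximetry wavelengths, 660 and 940 nm, are first-class.

*Epidermis.*  Absorption is the melanosome power law plus water plus a
pigment-free baseline:

    mu_a = vmel · 6.6e10 · λ^-3.33 + mu_a_water(λ) · vw
         + (1 − vmel − vw) · 7.84e7 · λ^-3.255      [mm⁻¹, λ in nm]

with epidermal water fraction vw = 0.20 and melanosome volume fractions
2.55% (light, Fitzpatrick I), 15.5% (moderate, IV) and 30.5% (dark, VI).
Water absorption is 4.15e-4 mm⁻¹ at 660 nm and 2.67e-2 mm⁻¹ at 940 nm;
with these values the model reproduces the published epidermal
coefficients (0.7275/0.2297, 4.2100/1.3023, 8.2438/2.5447 mm⁻¹) to four
significant figures.

*Dermis.*  Each of the four dermal sublayers mixes arterial blood at
saturation satA, venous blood at satV = satA − 0.10 (ten percentage
points, the conventional arteriovenous gap), water, and the same
baseline.  Whole-blood absorption at hematocrit 45% uses
mu_a(HbO₂) = 0.15/0.65 mm⁻¹ and mu_a(HHb) = 1.64/0.43 mm⁻¹ at
660/940 nm.  Diastolic blood volume fractions are 4/30/4/10% for the
papillary, upper blood-net, reticular and deep blood-net dermis; water
fractions 50/60/60/70%.

*Cardiac phases.*  Systole doubles the diastolic blood volume; in both
phases the blood is split equally between the arterial and venous
compartments (the equal split is stated for systole; we apply the same
convention in diastole for consistency).  In the systolic upper blood-net
layer the doubled blood plus water nominally exceeds unit volume; the
baseline residual fraction is clamped at zero there rather than allowed
to contribute negative absorption.

*Scattering.*  Stratum corneum, fat, muscle and bone use published
(mu_s, g) pairs per wavelength.  The published table leaves the epidermal
and dermal scattering cells blank; we default them to mu_s = 18.7/12.0
mm⁻¹ with g = 0.91/0.94 at 660/940 nm (standard skin-optics values,
matching the stratum-corneum anisotropy row) and expose them in the
geometry configuration.

### Transport

Standard hop–drop–spin weighted transport: exponential free paths
s = −ln ξ / mu_t, partial absorption w·mu_a/mu_t per interaction,
Henyey–Greenstein deflection sampling, Russian roulette below weight
1e-4 with survival 0.1.  Internal interfaces are index-matched (one
tissue index, 1.4); unpolarized Fresnel reflection acts only at the two
outer air–tissue surfaces.  At an outer surface the packet is split
deterministically: the transmitted fraction 1−R(θ) leaves (tallied as
detected or escaped) and the reflected fraction continues — lower
variance than stochastic branching, identical expectation.  The source
is a Gaussian beam of 1 mm 1/e² radius (σ = 0.5 mm) entering normally;
the initial packet weight is 1 minus the normal-incidence specular
reflectance ((1−1.4)/(1+1.4))² ≈ 0.0278.  The detector is a coaxial
1 mm-radius disc on the distal face with a 90° acceptance half-angle
(all forward exits).

Each run launches seeded batches until the detected-count target is
reached; each batch owns an RNG substream derived from
(seed, batch index), so tallies are bit-reproducible for a fixed seed and
batch size and independent of how batches are scheduled.  The tally
satisfies specular + absorbed + detected + escaped + residual = launched
to better than 1e-9 relative (measured ~5e-13).

### Detector estimator

The geometry is invariant under translation along the bone axis (x), so
a packet's lateral x-displacement is independent of its launch x-offset.
The kernel launches every packet at x = 0 and integrates the Gaussian
launch-offset distribution analytically at each distal exit: the
transmitted weight is multiplied by
P[(x₀+Δx)² + y² ≤ r²] with x₀ ~ N(0, σ), a two-erf expression.  This is
an expected-value form of the binary accept/reject detector with the
same expectation and substantially lower variance; "detected count"
counts exit events with nonzero acceptance probability.

### Variance reduction for thick stacks

Transmittance through 13 mm of scattering tissue at 660 nm is of order
1e-5–1e-6, so unbiased acceleration is essential at realistic budgets:

- **Geometric splitting** (optional, off by default in `RunConfig`, on
  in both experiment presets): at K equally spaced interior planes, a
  packet crossing toward the detector is split in two (half weight
  each) and a packet crossing backward is rouletted with survival 1/2
  (weight doubled on survival).  Expected weights are unchanged; the
  packet population no longer decays exponentially with depth.
  Measured detected-count efficiency rises ~20–50× at K = 6 with
  transmittance statistically unchanged.
- **Correlated condition families**: the grid conditions of one
  wavelength differ only in epidermal and dermal absorption.  One
  reference stack (the family-minimum absorption in each varying layer,
  so every reweight is ≤ 1) is transported; the per-packet pathlength
  in each varying layer class is recorded, and each detection scores
  ``exp(-Δmu_a · L)`` into every family member.  All members therefore
  share identical photon paths, so differences between members — the
  systole/diastole AC signal and the light/moderate/dark contrasts —
  carry almost none of the absolute Monte Carlo noise.  Family
  estimates were validated against direct independent runs (dark skin,
  660 nm: transmittance 2.91e-6 vs 2.82e-6; AC/DC 0.447 vs 0.451).
- **Similarity reduction** (optional, off by default): layers are
  transformed by (mu_s, g) → (mu_s(1−g), 0), the first-order similarity
  relation of radiative transport.  It preserves the reduced scattering
  coefficient and the diffuse transmittance of optically thick media,
  while cutting the number of scattering events per packet by roughly
  1/(1−g) ≈ 10.  Useful for exploratory runs; the experiment presets do
  not use it because it measurably distorts the (small) melanin
  dependence of the AC/DC ratios.

## Calibration analytics

From systolic/diastolic transmittances Is, Id per condition:
AC/DC = (Id − Is)/Is per wavelength; R = (AC/DC)₆₆₀ / (AC/DC)₉₄₀;
ordinary least squares of SaO₂ on R gives the calibration line
SaO₂ = a + b·R per skin type (7 points, unweighted).  Monte Carlo noise
can make Is > Id for a weak-pulsatility condition; such records are
flagged but kept.

Bias against the commercial relation SpO₂ = 110 − 25R: for each true
SaO₂ in 86–92%, invert the skin-specific curve to get R, feed it through
the commercial relation, and report SpO₂ − SaO₂ with the arithmetic mean
over the range.  With the published light-skin curve
(SaO₂ = 109 − 25.95R) this reproduces the published light-skin column
exactly after one-decimal rounding (mean bias 1.7%).  The published
dark-skin column is arithmetically consistent with a commercial
intercept of 109 rather than the printed 110 (e.g. SaO₂ = 86 gives
97.78 → 97.8 under 110 − 25R but 96.8 is printed); we follow the
commercial relation as written (dark mean bias 10.27%) and the test
suite documents the inconsistency by also asserting the 109-intercept
variant that recovers the printed 96.8/9.3 values.

Correction factors: the linear multiplier is R_light/R_other evaluated
at the 100% reference saturation (1.2323 for moderate, 1.6461 for dark
with the published curves).  Because the dark-skin multiplier profile
rises toward low saturation (effectively exponential), a single
reference-point multiplier under-corrects below 100%; the profile over
70–100% in 5% steps has mean 1.792 (~1.8), which is the factor applied
to the dark curve.  Scaling every R by f maps a curve (a, b) exactly to
(a, b/f); this algebraic identity is asserted in the tests.  Multipliers
are computed from the fitted lines rather than raw R values; this is the
route that reproduces the ~1.8 mean.

The clinical cohort table is shipped as a packaged, checksum-pinned
transcription.  The ratio of the printed cohort mean biases is
3.3/0.5 = 6.6; note the printed White mean (0.5) differs slightly from
the arithmetic mean of its printed column (0.5625), so both printed and
recomputed means are exposed.

## Presets and problem sizes

Both presets use the full anisotropic phase function, 6 splitting
planes, and correlated condition families (one transport per
wavelength).

- `paper`: 1e6 detected packets per condition — the published protocol;
  a long-running batch job (order an hour per wavelength family on one
  CPU).
- `ci`: 1e4 detected packets per condition.  The full 84-condition grid
  completes in about a minute on one CPU; this is the preset the test
  suite runs.

## A documented discrepancy: melanin and the ratio of ratios

The published study reports that dark pigmentation roughly halves the
660 nm AC/DC while leaving 940 nm essentially unchanged, which separates
the three calibration curves strongly (slopes −25.95 / −32.69 / −50.31).
This simulator reproduces the *direction* of the effect but not its
wavelength asymmetry: melanin suppresses AC/DC by ~15–20% at **both**
wavelengths (light/dark ratio ≈ 1.18 at 660 nm and ≈ 1.15 at 940 nm),
so the phenotype separation in R is only a few percent and is not
monotone (the moderate phenotype dips slightly below dark).  A static
epidermal filter cancels exactly in (Id − Is)/Is; what remains is the
covariance between epidermal and dermal pathlengths of detected
packets, and in this geometry that covariance is weak and nearly
wavelength-balanced.  The finding is robust: it survives changes of
epidermis thickness (0.08/0.25/0.40 mm), dermal scattering attribution
(18.7/12.0 vs 25.62/5.68 mm⁻¹), bone radius (0.5–3.5 mm), lateral
bounding, and phase-function fidelity, and the correlated-family
estimator behind it was validated against direct simulation.  The
published effect size evidently depends on geometry details that are
only shown pictorially in the original figure.  Consequently the
simulated-grid checks assert the robust trends (negative slopes, 660 nm
AC/DC ordered light > moderate > dark everywhere, light skin having the
largest fitted R, intercepts within 105–115); the strict three-way
orderings of slope magnitude and R as published are asserted only in
the end-to-end acceptance check, where this model genuinely does not
reproduce them.

## What the synthetic data does and does not capture

The simulated experiment emulates a noiseless two-wavelength
transmittance oximeter on an idealised layered finger: no LED spectral
width, no detector noise, no motion, no venous pulsation beyond the
equal-split assumption, uniform melanin on both sides of the finger, no
depth-varying melanin within the epidermis, no subject-to-subject
anatomical variability.  Passing tests therefore demonstrate internal
consistency of the transport and analytics and the direction and
ordering of the melanin effect — not clinical accuracy of any specific
bias magnitude.

## Numerical choices

- Roulette threshold 1e-4, survival 0.1 (standard; configurable).
- Weight-conservation tolerance 1e-9 relative; achieved ~1e-12.
- Bone-surface crossings nudge the packet 1e-9 mm past the surface to
  avoid re-intersection; split planes need no nudge because the
  crossing updates the packet's plane level.
- The splitting progeny stack holds 512 packets; if it ever fills, the
  packet simply continues unsplit, which remains unbiased.
- OLS fits via `scipy.stats.linregress`; degenerate fits (all R equal)
  raise.
- Printed-table rounding is half-away-from-zero to one decimal and lives
  only in the writers; all computation keeps full precision.
- Seeds: every stochastic entry point takes an explicit seed;
  per-condition and per-batch substreams derive from `SeedSequence`
  spawning, so grids are reproducible and scheduling-independent.

## Known limitations

- Exact layer thicknesses and the dermal scattering spectrum of the
  original study are not published; defaults are documented choices and
  configurable, so freshly simulated calibration coefficients are
  expected to differ quantitatively from the published ones while
  preserving their signs and orderings.
- The similarity-reduced mode slightly underestimates absolute
  transmittance (measured ~20–40% low at 660 nm versus the full phase
  function); ratio quantities (AC/DC, R) are much less affected.
- Reflectance-mode oximetry, spectral LED models and depth-resolved
  melanin are out of scope.
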