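# Methods

This note records the model, the numerical choices, and what the
synthetic data do and do not establish. It is the package's own account;
all quantitative statements here are ones the test suite or the examples
compute.

## Forward model

The probe records backscattered intensity versus distance from the
source. We model it with the steady-state diffusion approximation for a
semi-infinite homogeneous medium: an isotropic point source at depth
z₀ = 1/(μa + μs′), mirrored across an extrapolated boundary at
z_b = 2AD, with D = 1/(3(μa + μs′)), μ_eff = √(3 μa (μa + μs′)), and the
internal-reflection parameter A computed from the tissue/air refractive
mismatch (n = 1.4) via the standard empirical polynomial. Reflectance is

R(ρ) = (1/4π) [ z₀ (μ_eff + 1/r₁) e^(−μ_eff r₁)/r₁²
              + (z₀ + 2z_b)(μ_eff + 1/r₂) e^(−μ_eff r₂)/r₂² ],

with r₁, r₂ the distances from the real and image sources to the surface
point at ρ. The instrument this emulates uses a proprietary
modified-diffusion forward model; the pipeline's arithmetic only needs a
physically monotone, invertible reflectance–absorption link, which the
standard solution provides: R is strictly decreasing in both ρ and μa
(verified by finite differences over ρ ∈ [1, 30] mm, μa ∈ [0.002, 0.02]
/mm). Reflectance is treated as relative units throughout; every
downstream quantity is either a ratio or a within-run comparison, so the
overall scale cancels.

Heterogeneous tissue is approximated locally: position k's reflectance is
evaluated with the μa at position k. This ignores lateral photon
sampling, which is acceptable for tumor widths (σ ≈ 15 positions
≈ 3.4 mm) comparable to or larger than the transport length.

**Detector coordinates.** Position k (of 128, each a 16-pixel average of
the 2048-pixel, 14 µm-pitch CCD) is placed at the centre of its block:
ρ_k = 15 mm + (k + 0.5)·0.224 mm from the illuminating LED, spanning
15.1–43.6 mm. The two LEDs illuminate from opposite ends, so LED 2 sees
the positions in reverse order.

## Synthetic data

**Phantoms (training).** 640 homogeneous phantoms, μa ~ U(0.003, 0.015)
/mm and μs′ ~ U(0.9, 1.1) /mm at 690 nm — breast-mimicking ranges with a
±10 % scattering tolerance, typical of solid tissue phantoms.
Reflectance gets multiplicative log-normal noise of scale 0.01 (CCD
shot/gain noise is signal-proportional; 1 % is what survives 16-pixel
averaging of a well-exposed line sensor). Optics draws and noise draws
come from separately spawned streams of one seed, so noise can be varied
against fixed ground truth.

**Cohorts.** 15 patients, 12 slices, 7 scan time points (pretreatment
plus six cycles), both breasts, both LEDs, 690 nm. Healthy tissue is
homogeneous (μa = 0.005 /mm, μs′ = 1.0 /mm). The tumor is a separable
Gaussian absorption excess in (slice, position) with pretreatment
amplitude 0.004 /mm — roughly doubling absorption at the tumor centre,
consistent with hemoglobin-rich lesions — whose amplitude decays
geometrically to `response_ratio × amplitude` at the final cycle.
Single-wavelength (690 nm) simulation is the default; the scoring
arithmetic is wavelength-independent.

What this generator does **not** emulate: layered or otherwise
structured breast anatomy, chromophore spectra (HbO₂/Hb/water/fat),
motion and contact-pressure artifacts, nipple hot-spots, inter-side
anatomical asymmetry, and probe repositioning error between cycles.
Passing the recovery tests therefore shows the pipeline's arithmetic is
faithful and stable under realistic noise, not that the instrument
achieves these accuracies on patients.

## Absorption regression

Pooled (reflectance, μa) pairs are formed **per detector position**: one
degree-4 polynomial per position, all 128 trained jointly (vectorized).
This distance-resolved default is a deliberate design choice: reflectance
at a fixed μa varies by orders of magnitude across the 15–44 mm distance
sweep, so a single scalar polynomial over all positions cannot identify
absorption (it explains < 10 % of variance in our conditions), whereas
per-distance inversion reaches R² ≈ 0.95 held-out. A single pooled model
remains available (`TrainingConfig(pooling="pooled")`) for scalar
regression uses and for the oracle tests.

**Conditioning.** Powers of a positive-valued signal are nearly
collinear. Each feature column (reflectance powers 1..4) is z-scored and
the design is then whitened by the inverse Cholesky factor of its Gram
matrix, making the columns orthonormal on the training data. Gradient
descent on the quadratic cost J(w) = ‖Xw − y‖²/(2n) then has unit
curvature in every direction: the default learning rate 0.5 contracts
the error by half per iteration, descent is monotone (asserted to 1-ulp
roundoff), and 10,000 iterations reach the least-squares solution to
machine precision — which the tests pin against `numpy.linalg.lstsq` and,
in function space, against `numpy.polynomial.polyfit`. Without whitening
the leading Gram eigenvalue exceeds the 2/η stability bound at η = 0.5
and descent diverges; divergence (cost rising for more than 10
consecutive iterations) raises a `ConvergenceError` naming the rate.

The iterates are computed through the precomputed sufficient statistics
G = XᵀX/n and b = Xᵀy/n (w ← w − η(Gw − b)); this is algebraically the
full-batch gradient step, evaluated in O(p²) per iteration instead of
O(np).

Cross-validation splits whole phantoms (never positions of one phantom
across folds) into k = 5 shuffled folds; per-fold held-out MSE and R²
are recorded. Scattering values are carried through I/O but not
regressed: this model predicts absorption only.

## Residual disease and oRCB

- **Superposition:** each slice is estimated once per LED; curves are
  produced in source-relative order, LED 2's curve is reversed into
  detector coordinates, and the combined curve is the position-wise mean.
  With a centred tumor and zero noise the combined curve is symmetric
  under source exchange to machine precision.
- **Slice error:** trapezoidal integral (unit spacing in position index)
  of max(unhealthy − healthy, 0). The positive part is taken *before*
  integrating so below-baseline stretches — which occur in real scans —
  cannot cancel genuine excess; the recorded cohort tables are consistent
  with this convention and not with a plain difference of totals. Ratios
  (oRCB) are invariant to the abscissa spacing, so no physical unit is
  imposed on the integral.
- **Baseline:** the healthy side of the same treatment by default; a
  config flag (`reuse_healthy_baseline`) instead reuses the earliest
  treatment's healthy scan as a fixed reference, matching cohorts whose
  recorded healthy totals repeat identically across cycles.
- **oRCB:** 100 × min/max of per-treatment total errors over all usable
  treatments (missing treatments are dropped, not imputed; fewer than two
  usable treatments raises an insufficient-data error). If the largest
  error is ≤ ε = 1e−12 there was no measurable disease at any cycle and
  the value is 0. The statistic is scale-invariant and clamped to
  [0, 100]. Min/max is taken over all treatments rather than strictly
  (final, pretreatment), and the attaining treatments are reported.

## pRCB mapping

Straight-line OLS (statsmodels) of known pRCB on oRCB, requiring ≥ 3
pairs and non-constant oRCB. On the seven graded cohort pairs the fit is
pRCB = 0.018 + 0.0724·oRCB with R² = 0.990 and residual SE 0.167
(5 df) — computed by the example script and checked against hand-coded
normal equations in the tests.

The prediction interval is `raw ± t(1−α/2, n−2) · s_resid`, a **constant
half-width** with no leverage term: the recorded cohort's printed bounds
have identical upper-minus-value differences at every oRCB from 2.67 to
81.34, which a leverage-dependent band cannot produce, and with a
handful of training points a flat honest band is the defensible choice.
Negative point predictions are clamped to 0 (negative disease burden is
meaningless) while the interval continues to bracket the raw prediction;
classification applies the clamped value with RCB-0 reserved for exact
zero and 1.36/3.28 as inclusive upper bounds.

The development cohort's own mapping reportedly used eight training
pairs, one of which is not recoverable from the published summaries; the
seven-pair fit reproduces the published predictions within 0.03 and the
published R²/MSE within one percentage point, and the tests assert
consistency at exactly those tolerances rather than exact equality.

## Problem sizes and determinism

Default problem sizes — 640 training phantoms, 200 held-out phantoms,
single-patient six-slice cohorts for recovery studies — run the full
suite in well under a minute on one core; the 128 simultaneous
10,000-iteration descents take ~1 s via the sufficient-statistic form.
All randomness flows from explicit integer seeds through
`numpy.random.SeedSequence`, and identical (config, seed) inputs produce
byte-identical report bundles.

## Known limitations

- The forward model is homogeneous and semi-infinite; curved breast
  geometry, layered tissue and chromophore spectra are out of scope.
- The oRCB→pRCB map is fit on seven points; its interval reflects
  residual spread only, not model-selection uncertainty.
- Recovered oRCB carries a small systematic offset from the planted
  response ratio (e.g. 35.7 recovered at 40 planted) caused by the
  nonlinear reflectance–absorption inverse interacting with the
  scattering spread marginalized at training time; the rank order and
  correlation (Pearson ≈ 0.999 noise-free) are unaffected.
- Tables recorded from the development cohort are rounded to 0.1 (AUCs)
  or 0.01 (errors, oRCB); internal-consistency checks are asserted only
  at that printed precision.
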