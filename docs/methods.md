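# Methods

This note documents the models, defaults and design choices behind
`ftirscreen`, in the order the pipeline runs.

## Synthetic cohorts

No public urine ATR-FTIR cohort with endometriosis labels exists, so the
package ships a generator whose output has the statistical structure the
analysis assumes, with ground truth known by construction.

**Grid.** Descending (instrument convention) uniform grid, default
4000 → 400 cm⁻¹ in 1,715 points (≈ 2.1 cm⁻¹ digitization of a 4 cm⁻¹
acquisition resolution).

**Signal model.** A replicate spectrum is

```
A(ν̃) = Σ_b band_b(ν̃) + water(ν̃) + patient offset + baseline(ν̃) + ε(ν̃)
```

* *Bands*: Gaussian peaks (Lorentzian available per band) from a fixed
  urine-like set — background bands (CH stretches near 2925/2855, the
  urea/COO⁻ region near 1400, amide shoulder, phosphate, a broad C–O
  envelope) carrying no class information, plus seven diagnostic bands
  at 1660, 1646, 1593, 1462, 1150, 1063 and 1025 cm⁻¹ whose amplitudes
  differ between classes by ±0.004 AU with alternating sign, so the
  group means differ in both the lipid/protein (1700–1550) and
  carbohydrate (1200–1000) regions.
* *Water*: a broad O–H stretch hump (center 3400, σ 260 cm⁻¹, amplitude
  0.45 AU) plus a 1635 cm⁻¹ bending band, identical in both classes —
  this is what truncation must remove.
* *Patient offset*: one N(0, 0.02²) scalar per patient, shared by that
  patient's replicates, so within-patient variance is below
  between-patient variance.
* *Baseline*: a random quadratic per replicate (coefficient sd 0.03 AU)
  emulating slow drift.
* *Noise*: i.i.d. N(0, 0.008²) per point per replicate.

Labels are assigned to exactly `round(n · prevalence)` patients
(default 50/50 of 100), in randomized order; everything is a pure
function of the config plus one integer seed.

**Calibration.** The class-effect amplitude (0.004 AU) and noise sd
(0.008 AU) were chosen together, once, so that the default pipeline
sits in a strong-but-not-trivial regime: test-set accuracy ≥ 0.8 with
full recovery of the planted bands in the selection-frequency profile,
while the zero-effect control is indistinguishable from coin-flipping.

**Questionnaire.** Binary covariates are drawn with *exact* per-group
"Yes" counts at the reference fractions of a 50/50 cohort of 100
(e.g. other gynaecological diseases 44 % vs 12 %; palpable masses 6 %
vs 20 %), with assignment order randomized under the seed; age is
normal per group (42 ± 8.1 vs 39 ± 7.9 years).

**What the generator does not emulate** — real urine biochemistry,
creatinine/dilution variation, instrument drift between sessions,
Mie scattering, atmospheric CO₂ lines. Passing tests demonstrate that
the *algorithmic machinery* behaves correctly on data with this
covariance structure; they are not evidence about the performance of
any assay on real patients.

## Preprocessing

Ordered chain, identical at train and predict time:

1. **Savitzky–Golay** smoothing, window 9 points, polynomial order 2
   (derivative orders 1–2 available; derivatives account for the
   descending grid's sign).
2. **Truncation** to 1800–900 cm⁻¹. This removes the water-dominated
   region entirely rather than modelling it; the fingerprint window is
   where the biomolecular bands live.
3. **Rubberband baseline**: the lower convex hull of (ν̃, A), built by a
   monotone-chain scan that keeps collinear points (so a straight-line
   spectrum yields an identically zero residual), interpolated and
   subtracted. A least-squares polynomial baseline is available.
4. **Unit-vector normalization** (Euclidean norm 1; Amide-I peak
   normalization available). Together with the rubberband step this
   makes the chain scale-invariant: preprocess(c·A) = preprocess(A)
   for c > 0.

Training preprocesses the *mean* of each patient's raw replicates
(`patient_mean`); prediction preprocesses each replicate independently
(`per_replicate`) because the consensus rule needs three independent
votes. The mode is recorded in dataset provenance. Whether test
replicates should instead be averaged is genuinely open; both paths are
config-switchable.

## MC-GA-LDA

* **Split**: stratified 70/30 by patient, round-half-up per class on
  the train side (50+50 → 35+35 / 15+15); test ids are passed to the
  trainer only as a forbidden list and asserted absent.
* **Monte Carlo**: per model, a stratified 80 % calibration / 20 %
  validation re-split of the training patients under a recorded
  sub-seed (spawned from the ensemble seed).
* **GA**: binary masks over the ~430 truncated wavenumbers;
  initialization uniform in mask size k ∈ [5, 30]; tournament selection
  (size 2), one-point crossover (rate 0.6), per-bit mutation (0.01),
  repair to [k_min, k_max] by random add/drop, elitism 2, 50 individuals,
  40 generations by default. Fitness = validation misclassification of
  the calibration-fitted LDA + 0.002·k. Smaller masks win ties through
  the penalty; all randomness flows from one seed per run.
* **LDA**: pooled within-class covariance with unbiased (n−2)
  denominator. Shrinkage rule: γ = 0 while calibration samples > 3k,
  else γ = 0.1 toward the diagonal, plus escalating diagonal loading
  only if the condition number still exceeds 1e8 — small-n spectral
  LDA is otherwise singular. Weights **w** = S⁻¹(μ₁−μ₀); the bias
  places the boundary at the projected class-mean midpoint (equal
  priors).
* Each member model is fitted on **its own iteration's calibration
  subset** (not the full training set) to preserve ensemble diversity;
  refitting on the full training set is a config switch.
* One GA runs per Monte Carlo resample (100 independent GA runs), and
  the ensemble serializes to versioned JSON (indices, means,
  covariances, configs, seeds) for reuse at predict time.

Default GA scale (50 × 40) is for full analyses; the packaged smoke
profile (population 24, 10 generations, k ∈ [5, 25]) is what the test
suite and the acceptance script use — it trains 100 models on a
100-patient cohort in well under a minute and already recovers all
seven planted bands.

## Consensus, ROC, operating points

Replicate vote fraction = share of models with positive score; replicate
call = (fraction ≥ θ); patient call = majority of replicates, with even
counts tying toward positive (a screening test prefers the sensitive
error; logged decision). Under this rule the patient call at θ equals
thresholding the patient's *median* replicate vote fraction, so the
θ-sweep ROC staircase has an exact Mann–Whitney pair-counting AUC
(ties ½) — both facts are asserted in tests. The mean vote fraction is
also reported as a patient score.

Thresholds are tuned on predictions from **5-fold cross-validation
inside the training set** (a fresh ensemble per fold), because
training-fit scores would be optimistically biased; the chosen θ is
frozen before the test set is scored, and test predictions are computed
exactly once. Default complementary-error constraints are 0.45 for both
tuned modes, placing them on opposite shoulders of the ROC; infeasible
constraints return the closest feasible point flagged `feasible=False`.
Tie-breaks go toward the extreme θ of each mode's direction (balanced
mode: larger θ).

## Metrics and screening impact

The metric panel (sensitivity, specificity, accuracy, PPV, NPV, F1) is
computed from the test-set confusion matrix; zero-denominator ratios are
reported as absent, never as 0, and integer percentages use
round-half-up. The impact calculator rounds each expected count
(n·prev·sens etc.) half-up *independently* — this reproduces every
printed number of the 1,000-patient reference workflow exactly — and
reports the ≤ 2-patient residual explicitly. PPV/NPV follow the Bayes
identities from (sensitivity, specificity, prevalence), which the tests
verify against the rounded counts.

## Cohort statistics

2×2 tables: Pearson chi-square **without** continuity correction,
switching to two-sided Fisher's exact when any expected cell count is
below 5. The no-correction choice is validated by the reference table's
printed p = 0.037 for (10,40) vs (3,47) — the Yates-corrected value
(≈ 0.08) would not match. Continuous variables: Shapiro–Wilk gate at
α = 0.05 per group, Welch's t-test if both pass, otherwise Mann–Whitney
U (asymptotic, tie-corrected; constant input takes the rank path with
p = 1). The test actually used is always recorded in the output.

## Pipeline determinism and leakage audit

A single master seed spawns one `SeedSequence` child per stage
(cohort, split, train, tune) at fixed spawn keys; every stage seed is
below 2³¹ and recorded in the report. The report JSON contains no
timestamps (timings go to a side log), so identical config + seed gives
byte-identical reports. The leakage audit lists the patient ids consumed
by the train and tune stages and their (empty) intersection with the
test ids; the trainer additionally raises if a quarantined id reaches
it.

## Problem sizes

The shipped test suite and acceptance script use: 100-patient cohorts
(triplicates, ~1,715-point spectra) with the smoke GA profile for the
ensemble-scale checks, a 40-patient / 5-model profile for determinism
checks, and closed-form or brute-force oracles at 2–5 variables for the
numerical identities. These sizes were chosen so a complete run is a
coffee-break, not an overnight job, while every statistical claim is
still exercised at meaningful n.

## Known limitations

* The generator's patient effect is a scalar offset; real
  between-patient variation is spectrally structured.
* The polynomial baseline option is a single least-squares fit, not an
  iterative peak-excluding fit.
* No EMSC, scatter correction or probability calibration.
* Real-cohort performance figures cannot be validated here; the
  synthetic regime is calibrated to be *plausible*, not to certify any
  clinical claim.
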