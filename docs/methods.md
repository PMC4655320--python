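# Methods

This note documents the models, statistics and design choices behind
`popscreen`: what each stage computes, which knobs matter, what the
synthetic cohort does and does not emulate, and the numerical conventions.

## Fetal growth numerics

**Estimated fetal weight.** EFW is computed from ultrasound biometry with
the Hadlock log10-polynomial equations. The default is the three-parameter
model

    log10 W = 1.326 − 0.00326·AC·FL + 0.0107·HC + 0.0438·AC + 0.158·FL

with HC, AC, FL in cm and W in grams; the BPD-inclusive four-parameter
variant is selectable. Coefficients live in JSON registry files under
`popscreen/standards/` with citation fields; the transcriptions are flagged
for verification against the cited sources, and the test suite exercises
the machinery against toy internally consistent standards so no test
depends on transcription accuracy.

**EFW percentiles.** The default weight-for-GA reference is the Hadlock
in-utero standard: median weight `exp(0.578 + 0.332·GA − 0.00354·GA²)`
grams with an SD equal to 12.7% of the median, percentiles from a normal
model on the natural scale: `P = 100·Φ((EFW − median)/(0.127·median))`.
Any standard exposing `location(GA)` / `scale(GA)` plugs in behind the same
interface (GA domain checks raise a range error naming the domain).

**Birthweight percentiles.** A sex-specific table (GA week × sex →
mean, SD) interpolated linearly in GA. The shipped
`uk_birthweight_reference_synthetic.csv` is a synthetic stand-in with
UK-scale values (term male mean 3560 g, female 3430 g, SD 12.5% of the
mean); it is internally consistent with the cohort generator, which draws
birthweights from the same reference, so gold-standard prevalences are
exact by construction. Substitute a transcribed national reference for
real-data work.

**GA-adjusted Z-scores.** Because scan timing varies, each measurement is
standardised within the cohort: a polynomial (degree 2 by default) of the
measure on GA gives the mean curve; the SD curve is a polynomial fit to
absolute residuals scaled by √(π/2) (half-normal correction). This is
smoother and more stable at cohort size than binned SDs. The fit requires
≥100 observations spanning ≥2 weeks and refuses SD curves that are not
strictly positive on the fit range. Applying a model to its own fit sample
yields mean(Z) within ±0.05 and SD(Z) within [0.9, 1.1] (tested).

**AC growth velocity.** ΔZ = Z(last scan before birth) − Z(20-week scan)
for abdominal circumference. Pregnancies lacking either scan are excluded
from velocity-stratified analyses with a logged count.

**Customised centiles.** A pluggable coefficient file defines a term
optimal weight as a base plus linear offsets for maternal height, booking
weight and ethnicity; a fetal-weight proportion-of-term curve scales it to
the scan GA, and the percentile uses a proportional-SD normal model. The
shipped coefficients are a documented simplified surrogate with
illustrative magnitudes (8 g/cm height, 7.5 g/kg weight), not the
proprietary GROW set; the interface accepts any coefficient file of the
same shape.

## Screening classification

Screen status is classified on the last eligible scan before birth:
clinically indicated scans at ≥26 weeks for the selective policy (no
eligible scan ⇒ screen negative), research 28/36-week scans for the
universal policy (none ⇒ the pregnancy is excluded, mirroring the study's
exclusion of deliveries before the 28-week scan). Screen positive means
EFW percentile strictly below 10; a percentile of exactly 10.0 is
negative. Gold-standard SGA is birthweight below the 10th percentile for
GA and sex (severe: 3rd), strict again.

Composite neonatal morbidity is 5-minute Apgar < 7, metabolic acidosis
(cord pH < 7.1 **and** base deficit > 10 mmol/L, both strict), or
neonatal-unit admission at term (admission < 48 h after birth at ≥37
weeks with discharge ≥48 h after admission). Severe adverse outcome is
stillbirth or a term livebirth with neonatal death, HIE, inotropes,
mechanical ventilation, or severe acidosis (pH < 7.0 and base deficit
> 12). Missing component fields count as criterion-not-met and are
logged; contradictory admission records raise a validation error.

FGR markers are decile flags computed over the whole cohort's
distribution of GA-adjusted Z-scores: highest deciles of HC/AC ratio,
uterine-artery PI (20-week scan) and umbilical-artery PI (last scan);
lowest deciles of AC/FL ratio and AC growth velocity. Cuts use the
standard type-7 empirical quantile with strict inequality beyond the cut,
so ties at the cut are never flagged (consistent with the strict "<10th
percentile" convention; an all-tied vector flags nobody).

## Paired diagnostic accuracy

All comparisons reduce to the 2×2×2 counts of (selective result,
universal result, SGA status), so every statistic is closed-form:

* **Summary metrics** with Wilson score intervals by default (Wald and
  Clopper–Pearson exact available — the published-style tables follow the
  Wald convention; see "Interval conventions" below); likelihood-ratio
  intervals by the log method.
* **Relative sensitivity**: ratio of detections among the shared diseased
  subjects, delta-method log interval with +1 cell offsets
  (Bonett–Price style), McNemar's test on discordant diseased pairs —
  exact binomial below 25 discordants, continuity-corrected χ² above.
* **Predictive values**: the generalized score statistic for paired
  predictive values — the robust score test of the test-indicator
  coefficient in a marginal logistic model fitted under the null common
  PPV (working independence, clustering by subject). This is the simplest
  exactly identified member of the weighted-score family; a seeded paired
  bootstrap (subject resampling) is the cross-check and the fallback when
  one test makes no qualifying calls.
* **Likelihood ratios**: Wald test of log LR equality. log LR⁺ =
  log(sens) − log(FPF); the diseased and healthy contrasts are
  independent, each with the paired-ratio delta variance
  `1/m₁ + 1/m₂ − 2·n₁₁/(m₁m₂)`. The +1-offset variance was measurably
  anticonservative for LR⁻ at n = 500 (empirical size 0.069), so the test
  uses the plain variance (size 0.046–0.055); empirical size of all four
  paired tests is verified in [0.035, 0.065] under a conditionally
  independent null.
* **ROC AUC** by the Mann–Whitney identity with a DeLong interval.

**Interval conventions.** The published summary tables this pipeline
emulates are reproduced exactly (16/16 intervals after integer rounding)
by the normal-approximation interval, while Wilson reproduces 10/16; the
acceptance suite performs this identification explicitly. The library
default remains Wilson — the better-behaved interval for small cells —
with the method selectable per call.

**Rounding.** Report tables round half-up: integers for percentages, one
decimal for ratios. JSON ledgers keep full precision; rounding happens
only at the output layer.

## Stratified risk

Relative risks use the Katz log-method CI and a two-sided Fisher exact p
(sum of hypergeometric probabilities ≤ the observed table's, the scipy
convention, verified against exhaustive enumeration). Zero cells get an
add-0.5 correction in the CI only, never the point estimate, with a flag.
Zero reference events yield an explicit infinite RR.

The interaction ("does the EFW–morbidity association differ between
marker strata?") is a homogeneity test of the risk ratio across the two
strata: χ²₁ on the difference of log RRs with delta-method variances. A
logistic interaction Wald p is computed alongside; the two agree within
two-fold across simulated scenarios and the homogeneity p tracks a
permutation oracle within ±0.05 on small strata (both tested).

The stratified report has four exposure rows — screen positive by the
population standard, by the customised standard, positive with normal AC
growth velocity, positive with lowest-decile velocity — crossed with the
outcome composites, each cell's 2×2 written to a JSON ledger. All RRs are
referent to screen-negative pregnancies under the corresponding standard.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes,
not obstetric physiology. Per subject:

* a latent size Z drives true fetal weight through the registered
  EFW-for-GA standard and birthweight through the registered birthweight
  reference; its mean is calibrated semi-analytically so that
  P(birth percentile < 10) equals the target prevalence (default 9%);
* a latent FGR class (default 4.3%) carries a progressive growth deficit
  drawn from a Gamma with mean |ΔZ| = 1.2 (SD 0.4), ramping from 20 to 36
  weeks, plus a head-sparing redistribution that raises HC/AC and lowers
  AC/FL at roughly constant EFW;
* measured biometry is produced by inverting the Hadlock polynomial: a
  target measured EFW = true EFW × (per-subject equation bias, CV 7%) ×
  (per-scan lognormal error, CV 10% by default) is imposed by scaling a
  GA-appropriate biometry profile (the log10 polynomial is quadratic in
  the scale factor, so the inversion is exact), then a 1.2% per-measure
  jitter is added. Re-analysing the emitted tables therefore reproduces
  the intended signal-to-noise structure;
* birth Z adds a residual (SD 0.45 Z) for growth between the last scan
  and delivery plus non-growth determinants of birthweight; the
  per-subject equation bias affects every scan but not the birthweight;
* clinically indicated scans follow a logistic indication model on
  diabetes, BMI, age extremes, prior miscarriage, smoking and a noisy
  symphyseal-fundal proxy of fetal size, with the intercept solved for
  the target 42% scan rate; clinical EFW carries a 1.15× error multiplier
  and a +5% (log-scale) systematic bias relative to the masked research
  protocol — the combination reproduces the reference margins (≈3.5%
  selective screen positive, ≈20% selective sensitivity, ≈49% of SGA
  pregnancies scanned);
* neonatal morbidity follows a logistic model whose FGR effect grades
  smoothly with how far below the SGA cut the infant falls (floor 0.15 of
  the effect for restricted-but-not-small fetuses); the intercept and FGR
  coefficient are solved so the marginal rate is 6.9% and the rate ratio
  of FGR∧SGA versus non-FGR equals the configured 3.9. Component flags
  (Apgar, cord gases, admission times) are sampled conditional on the
  composite, so the classifier recovers exactly the intended composites.
  Severe adverse outcomes (0.83%) use a separate FGR-loaded model; severe
  acidosis is drawn among severe cases already meeting the morbidity
  composite, keeping the calibrated morbidity model intact.

Randomness comes from one seed expanded into independent field-labelled
substreams drawn in subject order, so enlarging a cohort never perturbs
existing subjects and the whole pipeline is bit-reproducible per seed.
Infeasible parameter combinations (e.g. a relative risk unreachable at
the requested base rate) raise a calibration error naming the constraint.

With defaults at n = 3977, medians across 50 seeds land at ≈9.0% SGA
prevalence, ≈13.3% universal screen positive and ≈57% universal
sensitivity (verified by the acceptance suite). The generator does **not**
emulate: twin pregnancies, stillbirth as an event (it appears only as an
always-false flag), Doppler waveform physiology (PIs are GA-dependent
lognormals with FGR and size offsets), masking violations, or secular/
operator effects. Passing tests therefore show that the analysis machinery
recovers known structure from realistically noisy tables — not that the
generator's biology is faithful.

## Problem sizes used in the automated checks

The acceptance suite runs 50 default-size cohorts (n = 3977) for
calibration medians, 2000 replicates of n = 500 for test size, 10 000
permutations for the interaction oracle, and n = 5000 simulations for
Z-model recovery; the coverage smoke test uses 200 cohorts at a reduced
n = 1000.

## Known limitations

* The shipped birthweight reference and customisation coefficients are
  synthetic/surrogate; real-data use requires transcribed references.
* The generalized score and LR Wald tests are asymptotic; for very sparse
  tables use the paired bootstrap (`bootstrap_paired_p`).
* The homogeneity-of-RR interaction test covers exactly two strata;
  multi-stratum designs need the logistic route.
* Per-seed separation of the velocity-stratified risk gradient is limited
  by the default measurement noise: the lowest-decile-velocity RR exceeds
  the normal-velocity RR in ~90% of seeds individually and sharply in
  seed-pooled tables.
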