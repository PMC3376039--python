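# Methods

This note documents the models implemented in `nephrokit`, the assumptions
behind them, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices made where the
design was genuinely open.

## 1. Stereological nephron-number estimation

### Model

Glomeruli are modelled as spheres of a single in-vivo radius `r` (µm),
homogeneously distributed in the renal cortex, the only compartment that
contains them. A needle-biopsy section is treated as a uniformly random
plane through this medium. A sphere whose centre lies at distance `x` from
the plane shows a circular profile of radius `sqrt(r² − x²)`; profiles
with observed diameter below a detection cut-off `2·r_o` (default 5 µm)
cannot be counted, so a sphere is countable only when `|x| ≤ h`, with
`h = sqrt(r² − r_o²)`. Averaging the profile area over `x` uniform in
`[−h, h]` gives the mean countable-profile area

    A_h = π (2/3 r² + 1/3 r_o²),

which reduces to the classical `(2/3) π r²` mean section area of a sphere
when `r_o = 0`. With `N_s` countable profiles on a cortex area
`A_cortex = L · d_b` (total cortex length between outermost and innermost
glomeruli, times the needle's internal diameter), the profile-area fraction
`N_s · A_h / A_cortex` estimates the glomerular volume fraction of the
cortex by the Delesse principle, and

    N_total = VF · V_cortex / ((4/3) π r³)

converts it to a count using the cortex volume and the single-glomerulus
volume.

### Shrinkage correction

Formalin fixation and paraffin embedding shrink the tissue by about 31% in
volume, and glomeruli by about 43% (they additionally lose arterial
pressure). Isotropic volume shrinkage by fraction `f` scales lengths by
`(1 − f)^(1/3)`: 0.8837 for tissue and 0.8291 for glomerular axes. On-slide
lengths are divided by these factors to return to the in-vivo scale. The
conventional three-decimal constants are 0.883 and 0.829; note that 0.883
truncates (rather than rounds) the exact cube root 0.88366. The factors are
always computed from the volume fractions, never hard-coded.

The detection cut-off is interpreted on the in-vivo scale by default: the
5 µm limit applies after profile radii have been corrected by the
glomerular factor. The convention is configurable (`cutoff_space =
"on_slide"` divides `r_o` by 0.829 first); the two differ by under 0.01%
of `A_h` at `r = 100 µm`, so the choice is documented rather than
consequential.

### Counting and adequacy rules

Sections showing exactly one glomerulus are ignored entirely — both their
count and their cortex length (strict reading; a switch restores their
length). Sections with zero glomeruli keep their cortex length: they carry
information that the sampled cortex is locally glomerulus-free. A specimen
whose sections together show fewer than 8 glomeruli is flagged
`insufficient`; the numeric estimate is still reported with the flag
attached so that downstream filtering is an explicit analysis decision.
Globally sclerotic glomeruli are included in the primary count (the
registry records the *total* glomerular number) and a secondary
non-sclerotic estimate is emitted alongside.

The needle's internal diameter comes from a configurable gauge table; the
shipped defaults are nominal regular-wall hypodermic inner diameters
(14G: 1.60 mm … 21G: 0.51 mm). The cohort constant `r` is the mean of
per-patient mean profile-equivalent radii over a random ~5% subsample of
patients; how the per-patient radius is measured on sections (maximum
profile, equivalent-circle, …) is left to the laboratory protocol — the
routine averages precomputed values and optionally applies the glomerular
shrinkage correction.

### Units

All internal geometry is in µm. Cortex volumes must arrive as explicitly
tagged `Volume` objects (`cm3`, `mm3`, `um3`); there is no silent unit
inference, and an untagged number raises. `N_total` is invariant under a
consistent global change of length units.

## 2. Cortex volumetry

Whole-kidney and cortex volumes are plain slice summations, `Σ area ×
spacing`, with no trapezoidal or end-cap correction — deliberately matching
the acquisition protocol's formula. `spacing` is the reconstruction
interval. Per-kidney volumes are computed separately and summed across
sides for patient totals (patients with severe laterality are excluded at
eligibility, but symmetry is never assumed). Validation enforces
`0 ≤ cortex area ≤ kidney area` per slice.

The sub-cohort estimating equation — predicting the tomographic cortex
volume from ultrasound axes, sex, eGFR, birth weight, body weight, or any
configured feature set — is ordinary least squares with an intercept
(statsmodels under the hood), with no automatic variable selection. Rank
deficiency raises an error naming the collinear columns. Negative
predictions are floored at zero and flagged. Disease-stratified fitting is
supported by fitting per stratum; the protocol leaves the final feature
set open.

An optional reader converts 3-D label masks (0 background / 1 kidney /
2 cortex, voxel sizes from the header) to per-slice areas; CSV area tables
are the canonical input.

## 3. Clinical computations

eGFR uses the Japanese 3-coefficient serum-creatinine equation
`194 · Age^−0.287 · Cre^−1.094 (× 0.739 for females)` (mL/min/1.73 m²).
CKD staging uses the guideline bands (≥90, 60–89, 30–59, 15–29, <15), with
stages 1–2 requiring a kidney-damage marker; the bands are configuration,
since the protocol cites the guideline rather than restating thresholds.
Low birth weight is `< 2500 g` strictly; the interview fallback categories
(`normal`/`low`/`unknown`) pass through.

Event adjudication: myocardial infarction needs at least two of {chest
symptoms, ECG changes, elevated cardiac enzymes}; angina needs ECG
abnormalities AND chest symptoms AND need for catheter/surgical treatment;
cerebro-vascular events need symptoms lasting over 24 h AND a causative
lesion on imaging, with TIA and asymptomatic small infarctions never
counting. Death and renal death (chronic dialysis, transplantation) are
accepted as reported — the composite does not require cause detail.

The composite endpoint is the first of: accepted death / renal death /
cerebro-cardiovascular event, or the first visit at which eGFR has fallen
to half the enrolment value or below. Design choices, each flagged in
output where relevant:

* a single sub-50% measurement triggers the endpoint (no confirmation
  visit required; `require_confirmation=True` demands persistence at the
  next measured visit) — the protocol states the reduction without a
  confirmation rule;
* the baseline for the 50% rule is the enrolment eGFR, which anchors all
  timing;
* follow-up eGFR values are computed at the enrolment age, as the registry
  records age once;
* transplant pre-emptive of dialysis is dated at the reported event date.

Patients without follow-up are censored at time 0 with a flag. Annual
visits within ±3 months of the biopsy anniversary are accepted (flagged
informationally when off by more than two weeks); visits outside the
window are read but flagged distinctly. The annual eGFR decline rate is
the OLS slope of all available eGFR values (baseline plus visits) on years
since biopsy; no mixed-model shrinkage.

## 4. Study design

### Sample size

The design is a two-tailed log-rank comparison of LBW vs normal-birth-
weight patients, alpha 0.05, power 0.80, allocation fixed by the LBW
prevalence 0.095, uniform accrual over R = 2 years, administrative
censoring T = 5 years after study start, assumed group event rates 0.1
(normal) and 0.2 (LBW), 10% withdrawal inflation. For an exponential event
time with hazard λ and entry uniform on [0, R], the probability of an
observed event is

    p(λ) = 1 − (e^{−λ(T−R)} − e^{−λT}) / (λ R),

continuous at λ = 0 and at R = 0.

"Event rate" is ambiguous, so three readings are selectable: yearly hazard
(`annual_hazard`, the standard survival reading and the default), one-year
event probability (`annual_probability`, hazard `−ln(1 − rate)`), and
cumulative probability over the whole study (`cumulative_probability`,
hazard solving `p(λ) = rate`).

Three formula variants are implemented:

* **protocol** (default): Schoenfeld-type required events
  `d = (z_{α/2} + z_β)² / (Q₁ Q₀ (ln HR)²)` with the hazard ratio taken as
  the *ratio of the stated rates* (2.0) and the events→patients conversion
  using annual-probability hazards: `N = d / (Q₀ p(λ₀) + Q₁ p(λ₁))`. This
  is the reading that reproduces the protocol's planned sizes exactly:
  N = 519.3, LBW group `⌈0.095 N⌉ = 50`, normal group
  `round(50 · 0.905/0.095) = 476`, total 526, recruitment target
  `⌈526/0.9⌉ = 585` (which the protocol rounded up to the "simple number"
  600 — a manual override that is reported, not computed).
* **schoenfeld**: the same events formula with the log hazard ratio taken
  from the hazards implied by the configured rate interpretation.
* **lachin_foulkes**: the variance-based exponential-design formula
  combining null and alternative variances `φ(λ) = λ²/p(λ)`.

Rounding is uniform across variants: the smaller (LBW) group is rounded
up, the larger group derived from the allocation ratio and rounded to
nearest, keeping the realized prevalence as close as possible to 0.095.

### Monte-Carlo verification

`simulate_power` draws entry times uniform over the accrual period,
exponential event times with the group hazards from the configured rate
interpretation, censors at study end, and applies the package's own
log-rank test (standard observed-minus-expected form with hypergeometric
variance, tie-capable). Replicates use independent counter-based
substreams spawned from a single seed.

Two facts the simulations establish, worth stating plainly:

* The events-based (Schoenfeld-type) formulas are *conservative* at this
  design's extreme 9.5%/90.5% allocation: simulated log-rank power at the
  protocol sizes 50/476 under yearly hazards 0.1/0.2 is ≈ 0.88–0.89,
  above the 0.80 design target. The normal approximation with
  subject-fraction allocation understates the information actually
  contributed by the unbalanced risk sets.
* The variance-based Lachin–Foulkes variant is internally consistent here:
  at its returned sizes (38/362 under yearly hazards) simulated power is
  ≈ 0.80 within Monte-Carlo error, and the null rejection rate of the
  log-rank implementation is 0.05 within Monte-Carlo error.

## 5. Synthetic cohorts

`generate_cohort` draws, per patient: age uniform 20–75 and sex balanced;
birth weight from a two-component truncated-normal mixture (LBW component
2100 ± 250 g, normal component 3050 ± 350 g, truncated at 0) whose mixing
weight is calibrated in closed form so the realized fraction below 2500 g
equals the configured prevalence (0.095); nephron number linear in birth
weight (default 250 per gram plus 1.5·10⁵ intercept, Gaussian noise,
floored at 5·10⁴) — the literature asserts a positive correlation, the
linear form and slope are modelling choices of plausible magnitude;
exponential event times with group hazards calibrated so the expected
observed-event fractions match the assumed 0.1/0.2 rates
(cumulative-probability reading by default); entry uniform over accrual;
10% loss to follow-up uniform over each patient's follow-up; baseline eGFR
normal 60 ± 15 (floored at 15) declining linearly with a slope tied to
nephron endowment (default −2.5 mL/min/1.73 m²/yr at the cohort mean,
+0.8 per 10⁵ nephrons above it) plus optional measurement noise; serum
creatinine obtained by inverting the eGFR equation so the emitted
registries contain only quantities a site would record. Hard events are
reported with all adjudication criteria satisfied; event types are drawn
with fixed proportions. A truth table with every generating quantity and
the composite-endpoint time computed directly from the latent variables
accompanies every cohort, and generator parameters are embedded as
metadata.

What the generators deliberately do **not** emulate: per-patient
glomerular size variability (constant `r` matches the estimator's
assumption; a variability switch exists for sensitivity work but defaults
off), anatomically realistic kidney geometry or imaging noise, visit-date
jitter, informative censoring, competing risks, and measurement error in
the biopsy lengths and counts. Passing recovery tests therefore show that
the estimators are correct *under their own assumptions* — they do not
validate those assumptions against real tissue.

`sample_biopsy` realizes the stereological model exactly (Poisson centre
field, uniform section, detection cut-off in in-vivo scale, forward
shrinkage onto the slide); the unbounded centre field is equivalent to
buffering the simulated block by at least `r` on all sides, so sampling is
unbiased by construction. `mri_phantom` slices nested ellipsoids at
midpoint positions (the requested spacing is adjusted so an integer number
of slices spans the organ), with closed-form truth
`(4/3)πabc · (1 − (1 − shell)³)` for the shell.

## 6. Problem sizes used in the checks

The shipped verification suite uses: 10⁶ draws per geometry for the mean
profile-area oracle (10 random geometries), 500 simulated biopsies (3
sections each, 16G needle, 10 mm sections) for nephron-number recovery
against the default virtual kidney (r = 100 µm, N_true = 7·10⁵,
V_cortex = 100 cm³), phantom spacings 0.4/0.2/0.1/0.05 cm, and 5000
replicates for the power and type-I-error simulations. These sizes give
Monte-Carlo standard errors comfortably inside the asserted tolerances
(e.g. the recovery mean has SE ≈ 0.6% against a 5% band).

## 7. Known limitations

* The protocol's reference for its sample-size formula is not identifiable;
  the `protocol` variant documents the reading that reproduces the planned
  50/476 (rate-ratio effect size with annual-probability event
  conversion) and reports all intermediates so the reading is auditable.
  The package reports achieved values side by side rather than asserting
  the protocol's arithmetic as normative.
* `r` is a cohort constant by design; individual glomerular-size variation
  biases individual estimates in either direction and is out of scope.
* The composite endpoint assumes visits carry enough creatinine data to
  evaluate the 50% rule; sparse registries censor at the last visit.
* The estimating-equation module is a generic linear predictor; the actual
  sub-cohort coefficients can only come from the study's own data.
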