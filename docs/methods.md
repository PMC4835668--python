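# Methods

## Adherence model

The pipeline treats a patient's daily step record as a binary wear process
plus a count process. A study day (1-based; day 1 is the first monitoring day
after inclusion) is **active** when its recorded total is at least the wear
cutoff, 100 steps/day by default, inclusive. Totals below the cutoff are
treated as the device being moved around but not worn; days with no synced
record at all are stored as unrecorded zeros. The analysis deliberately does
not distinguish "no sync" from "0 steps" — both fall below the cutoff and are
inactive — because daily-total data cannot separate the two.

Use of the counter is considered terminated after the **final day**, defined
as the last day of the last run of at least `min_consecutive_active`
(default 4) calendar-consecutive active days. Runs are broken by any inactive
or unrecorded day; "temporary breaks in use" are the gaps *between* qualifying
runs, which do not end use as long as another qualifying run follows. A
patient with no qualifying run is terminated without qualifying: their
duration is recorded as zero rather than dropping the patient, keeping cohort
denominators explicit.

**Total days** (duration of use) run from the starting day — the first active
day, which may be later than study day 1 if device setup was delayed — to the
final day, inclusive. **Active days** count the active days inside that span,
and the active ratio is their quotient (0 for zero-duration patients).

## Walking-activity metrics

The **grand mean** is the mean of daily steps over the patient's active days
only, with the sample SD alongside; it is undefined (signalled, never
silently zero) when no active day exists. Grand means are classified on the
graduated step index: low < 3000, medium 3000–9999, high ≥ 10,000 steps/day.
The boundaries are half-open: exactly 3000 is medium, exactly 10,000 is high.

**Checkpoint weekly means** are evaluated at study days 7, 30, 90, 180, 270
and 365 over the 7 days ending at (and including) the checkpoint, again over
active days only — consistent with the grand mean's active-days-only
definition; a window with no active day is undefined. A patient past their
final day is a **nonuser** at that checkpoint; their last defined weekly mean
is carried forward (LOCF) so that later checkpoint summaries are not driven
purely by dropout of low-activity patients. A nonuser with no defined weekly
mean before termination contributes nothing (logged).

A patient's summary BMI is the mean of the baseline and 3-month
measurements; patients missing the 3-month value are flagged and fall back to
baseline in cohort tables. Printed percentages use round-half-away-from-zero
(e.g. 139 of 160 days → 87%).

## Cohort statistics

- Continuous baseline variables across the three activity strata: one-way
  ANOVA; when the omnibus p < .05, pairwise equal-variance t-tests with
  Bonferroni correction over the three stratum pairs (the equal-variance
  choice is the convention for small clinical tables; a Welch switch is
  exposed). With two groups the ANOVA is the t-test via F = t².
- Categorical structure: Fisher's exact test — fully exact for 2×2, and a
  Monte-Carlo permutation null (fresh seeded generator, deterministic per
  seed) for larger tables.
- Durations (total and active days), which are right-skewed: Kruskal–Wallis
  with post hoc two-sample Wilcoxon rank-sum tests (exact for small,
  tie-free samples), reported uncorrected as raw stratum-pair p-values.
- Gender-sorted grand means: two-sample t-test.
- Termination vs walking activity: a repeated-measures logistic regression,
  implemented as a population-averaged binomial GEE with an exchangeable
  working correlation over each patient's checkpoints. The response is the
  indicator of having terminated by the checkpoint; the regressor is the
  checkpoint weekly mean (user value or LOCF), scaled to 1000 steps/day.
  The exchangeable structure was chosen because no correlation structure is
  implied by the design; a subject-level random-intercept model is a
  reasonable alternative but the population-averaged slope is the quantity
  of interest. Degenerate panels (no terminations, no users, no variation,
  or unstable fits suggesting separation) are flagged with no estimate.

Significance is fixed at α = 0.05 throughout.

## Synthetic cohort generator

The generator emulates the data structure the pipeline targets, with defaults
encoding the emulated study conditions: 64 patients; stratum probabilities
14/64, 41/64, 9/64 (low/medium/high); stratum step means 1996/6016/11439
steps/day with SDs 716/1784/440; stratum ages 70.7/61.1/58.2 years
(SD 10.7/11.4/8.3); stratum durations of use 109/168/208 days
(SD 56/103/112); 51/64 male; settings 29/64, 23/64, 12/64; diagnoses
33/64, 18/64, 8/64, 5/64.

Key modelling choices:

- **Band-conditional stratum means.** The activity strata are *defined* by
  the observed grand-mean band, so reported stratum means are conditional on
  band membership. Patient-level means are therefore drawn from normals
  truncated to the stratum's own band, and the parent location is
  moment-matched (Brent root-finding on the truncated mean) so the truncated
  mean equals the configured stratum mean exactly. Without matching, the
  medium band's truncation alone would bias its mean by roughly +120
  steps/day. Durations use the same matching on [2 × run-length, horizon];
  targets that cannot fit the horizon are capped with a warning.
- **Overdispersed daily counts.** Daily totals are gamma-mixed Poisson
  (negative binomial) around the patient mean with dispersion 0.1
  (day-level CV ≈ 0.33, a realistic day-to-day spread for free-living step
  counts), keeping counts non-negative without truncation bias. Dispersion 0
  degenerates to Poisson.
- **Termination by construction.** Each patient's true termination day is
  drawn from the stratum duration distribution (shorter in the low stratum,
  producing the dropout–activity coupling); the series is then built so days
  1–4 and the last 4 days before termination are forced active, interior
  days may fall into wear gaps, and later days are unrecorded zeros. The
  last qualifying run thus ends exactly at the true termination day, making
  the detector's target well-defined: recovery tests can demand exact
  equality. A `stray_active_prob` (default 0) can add isolated post-
  termination active days, which never form a qualifying run.
- **Wear gaps.** From day 5 to 4 days before termination, a gap starts with
  probability 0.02/day and lasts uniformly 2–14 days, emulating holiday
  breaks of one to two weeks.
- **Demographics.** Ages are stratum-conditional normals clipped to
  [30, 95]; sex is a single cohort-wide Bernoulli; diagnosis and setting are
  independent multinomials (the generator does not reproduce stratum-by-
  diagnosis interactions such as an absence of high-activity surgical
  patients). Baseline BMI couples weakly and negatively (ρ = −0.2) to the
  standardized patient step mean; this correlation is structural background
  and tests must not assert its significance. The 3-month BMI is the
  baseline minus a small improvement, missing with probability 0.05.
- **No within-year trend.** Patient-level means are stationary; observed
  cohort-level increases over checkpoints arise from differential dropout
  only. Real cohorts may additionally have genuine recovery trends early
  after the event, which this generator does not model.

Minute-level records, when requested, distribute each recorded day's total
multinomially over 1440 minutes with a bimodal waking-hours profile (zero
overnight), so minute→daily aggregation is exactly lossless; a zero record at
midnight preserves the recorded-day mask through the round trip.

What passing tests on this generator do and do not show: they verify the
pipeline's rules, estimators and statistics against known ground truth under
realistic dropout, gap and noise structure; they do not validate device
accuracy, true wear-time behavior (e.g. partial-day wear), seasonal or
recovery trends, or stratum-demographic interactions absent from the
generator.

## Numerical and design notes

- The wear cutoff is inclusive (≥ 100 steps); the low/medium boundary is
  < 3000. Both choices take the explicit protocol definitions over looser
  prose variants.
- The checkpoint window is anchored to *end* at the checkpoint day (the
  first checkpoint, day 7, spans days 1–7); anchoring was otherwise
  unspecified and this choice makes day-7 summaries use exactly the first
  week.
- `find_final_day` is linear-time over maximal runs; tests verify it against
  a brute-force trailing-window scan on random masks.
- Table cells print mean (SD) with one decimal, SD 0 for singleton cells and
  "0 (0)" for empty cells; percentages are integers. Full precision lives in
  the JSON sidecar. Output ordering and formatting are deterministic, so
  re-running on unchanged inputs is byte-identical.
- Monte-Carlo Fisher tests build a fresh seeded generator per call
  (deterministic, default 19,999 resamples).
- Acceptance-style simulation checks use 200 replicated 64-patient cohorts
  for parameter recovery and 100 replicates for the termination-regression
  power check, with a 300-patient panel for the null check — sizes chosen to
  keep Monte-Carlo error well below the 3-SE decision bands.

## Known limitations

- The pipeline implements the daily-total wear rule only; it does not
  implement minute-level non-wear heuristics, step imputation, energy
  expenditure, or survival analysis of termination times.
- LOCF is a crude dropout correction: it freezes a nonuser's last observed
  week and understates post-dropout decline.
- The GEE slope is population-averaged; subject-specific effects will differ
  when between-patient heterogeneity is large.
- Zero-duration patients are retained in adherence outputs but excluded from
  stratified tables (no grand mean exists); their count is logged.
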