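# stepcohort

Step-counter adherence and walking-activity analysis for wearable-monitored
cardiac (tele)rehabilitation cohorts.

## The problem

Cardiac rehabilitation programs increasingly hand patients a consumer step
counter and follow their walking activity for up to a year after a cardiac
event. Two questions dominate the analysis of such cohorts: **how long do
patients actually keep using the device** (adherence), and **how much do they
walk** — overall, over time, and across clinically meaningful activity
strata? Both questions are entangled: less active patients stop wearing the
device sooner, so naive cohort means drift upward over the year purely
through dropout.

`stepcohort` implements this analysis as a reusable pipeline for daily (or
minute-level) step records:

- **Wear detection.** A day is *active* when it records ≥ 100 steps; fewer
  steps indicate the device was moved around but not worn.
- **Termination rule.** Use ends on the *final day*: the last day of the last
  run of ≥ 4 consecutive active days, regardless of temporary breaks. The
  *duration of use* (total days) runs from the first active day to the final
  day inclusive; patients with no qualifying run terminate with zero
  duration.
- **Walking activity.** Each patient's *grand mean* is the mean of daily
  steps over their active days only, classified on the graduated step index:
  low < 3000, medium 3000–9999, high ≥ 10,000 steps/day.
- **Checkpoint weekly means with LOCF.** Weekly means (7-day window ending at
  days 7, 30, 90, 180, 270, 365) are reported separately for *users* and
  *nonusers* — patients past their final day — whose last defined weekly mean
  is carried forward, exposing dropout-driven inflation.
- **Cohort statistics.** One-way ANOVA with Bonferroni post hoc tests across
  strata, Fisher exact tests for categorical structure, Kruskal–Wallis with
  rank-sum post hocs for durations, a t-test for gender-sorted grand means,
  and a repeated-measures (population-averaged, GEE) logistic regression of
  termination on weekly mean steps.

Because raw per-patient step data from such studies are typically not
deposited, the package includes a first-class seeded synthetic-cohort
generator (`stepcohort.simulate`) reproducing the cohort structure — stratum
sizes, band-conditional step distributions, stratum-dependent dropout,
holiday wear gaps — so every pipeline stage is testable end to end.

## Worked example

```python
from stepcohort import StepCountStudy, SimulationParams

study, cohort = StepCountStudy.from_simulation(SimulationParams(seed=42))
results = study.fit()

s = results.table2.stats
gm, td = s["grand_mean"]["all"], s["total_days"]["all"]
print(f"patients: {results.n_patients}")
print(f"strata (low/medium/high): "
      f"{s['stratum_n']['low']}/{s['stratum_n']['medium']}/{s['stratum_n']['high']}")
print(f"grand mean: {gm['mean']:.0f} (SD {gm['sd']:.0f}) steps/day")
print(f"duration of use: {td['mean']:.0f} (SD {td['sd']:.0f}) days")
print(f"active/total days: {results.table2.table.loc['active_total_pct', 'all']}%")
term = results.termination_regression
print(f"termination vs weekly steps: slope {term.slope_per_1000:.3f} per 1000 steps, "
      f"p = {term.pvalue:.3f}")
```

prints

```
patients: 64
strata (low/medium/high): 15/42/7
grand mean: 5762 (SD 2964) steps/day
duration of use: 149 (SD 85) days
active/total days: 88%
termination vs weekly steps: slope -0.110 per 1000 steps, p = 0.000
```

That is: of 64 simulated patients, 15 were low-, 42 medium- and 7 high-active;
the cohort walked a mean 5762 steps/day over active days and used the device
for a mean 149 days, wearing it on 88% of those days. The negative GEE slope
says patients with lower weekly step counts were significantly more likely to
have stopped using the counter — the dropout–activity coupling the generator
builds in (low-activity strata get shorter duration means).

`results.summary()` prints the full text report, including the stratified
baseline-characteristics and duration/steps tables; `results.save(outdir)`
writes `adherence.csv`, `activity_profiles.csv`, `table1.csv`, `table2.csv`
and a full-precision `stats.json`.

## Command line

```bash
stepcohort simulate --out data/ --seed 1            # synthetic cohort CSVs
stepcohort analyze  --in data/ --out analysis/      # fit + tables
stepcohort report   --in analysis/ --out report/    # chart CSVs + PNGs
```

The report step produces per-patient duration bars (total vs active days),
checkpoint user/nonuser weekly means, and per-setting mean daily steps — each
with a machine-readable CSV twin. An optional YAML config (keys matching
`AnalysisConfig` fields) overrides cutoffs, checkpoints and the horizon.

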