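# acutewell

Analytics for wearable and smartphone wellbeing data collected around an
acute civilian crisis — the kind of prospective cohort in which participants
wear a smartwatch, carry a study app with a daily questionnaire, and live
through a short, sharply delimited emergency (the motivating case is a
brief missile-attack war) whose effects on everyday wellbeing one wants to
quantify objectively, in near real time, and per exposure level.

The package is aimed at biostatisticians and digital-epidemiology groups
who need the full chain as tested, reusable code: cleaning and aggregation
rules, geographic exposure classification, an event-triggered physiological
response statistic, and the mixed-model significance testing — plus a
synthetic cohort generator so that every stage can be validated end to end
without access to a real (and sensitive) cohort.

## The analysis

Twelve daily indicators are followed — four *mental* (screen-on time,
reported mood, reported stress, social encounters), four *energy
expenditure* (step count, average heart rate, % time still, sport time) and
four *sleep* (awake time during sleep, sleep start hour, sleep duration,
sleep quality) — over four contiguous periods: baseline **B** (two weeks),
crisis **W**, and two back-to-routine fortnights **R1**, **R2**.

* **Cleaning and aggregation.** Same-day duplicate questionnaires collapse
  to the latest fill. For each participant, indicator and period, daily
  values are averaged separately over work days and free days (weekends and
  national holidays) and combined as `5/7 · work + 2/7 · free`, removing the
  weekly-rhythm bias caused by unequal free-day counts across the short
  periods. A participant enters an indicator's test only with at least one
  work-day and one free-day value in every required period.
* **Exposure groups.** Residence is the modal nighttime (~04:00) GPS grid
  cell during baseline, falling back to the enrollment hometown; the
  great-circle distance to a conflict reference coordinate classifies
  participants as high (< 60 km), medium (60–110 km) or low (> 110 km)
  exposure.
* **Siren response.** For every air-raid siren sounded between 02:00 and
  06:00 in a participant's area (with no sibling siren inside the baseline
  frame), `Δ = max bpm over [t−5, t+15] min − mean bpm over [t−45, t−15) min`;
  participants are summarized by their mean Δ and the cohort by the median
  of those means.
* **Inference.** Per indicator, a split-plot mixed ANOVA

  `indicator ~ period + exposure_group + period × exposure_group`

  with period as the within-subjects factor (df = 3), exposure group
  between subjects (df = 2), the group effect tested against
  subject-within-group and the within effects against the within residual;
  Bonferroni-corrected paired-t post hoc tests (family m = 6) with paired
  Cohen's d (`mean(diff)/SD(diff)`). A second, additive Type-III ANOVA
  explains the individual war-minus-baseline deltas in the affected
  exposure groups:

  `Δindicator ~ exposure_group + age_group + gender + income_level + baseline_level`.

## Worked example

```python
import acutewell as aw
from acutewell import pipeline

cfg = aw.SimulationConfig(n_participants=400, seed=7,
                          group_proportions={"high": 0.25, "medium": 0.5,
                                             "low": 0.25})
cfg.gps.clock_window = (3.0, 5.0)   # nighttime GPS is all inference needs
tables = aw.generate_cohort(cfg)
aw.write_cohort(tables, "demo_cohort", cfg)

bundle = aw.read_cohort("demo_cohort")
res = pipeline.run_study(bundle)
print(res["mixed"]["mood"].table.round(4))
print(res["posthoc"]["mood"].round(4).to_string(index=False))
print(f"siren cohort median: {res['siren']['median_delta_bpm']:.1f} bpm")
```

prints

```
                      SS   df      MS        F       p
group             0.8929    2  0.4465   0.2988  0.7421
subject(group)  227.0862  152  1.4940      NaN     NaN
period           10.5664    3  3.5221  26.9379  0.0000
period:group      6.9072    6  1.1512   8.8046  0.0000
residual         59.6221  456  0.1308      NaN     NaN

  pair   n  mean_diff       t  p_uncorrected  p_bonferroni  cohens_d direction
 B & W 155    -0.3120 -5.8737         0.0000           0.0   -0.4718  decrease
B & R1 155    -0.0394 -1.2489         0.2136           1.0   -0.1003  decrease
B & R2 155     0.0008  0.0226         0.9820           1.0    0.0018  increase

siren cohort median: 16.1 bpm
```

Reading it: mood drops during the crisis (a −0.31-point mean change,
paired d ≈ −0.47, Bonferroni p < 0.001) and returns to baseline in both
recovery fortnights (corrected p = 1); the period × exposure-group
interaction is significant, i.e. the drop differs by distance from the
conflict; and nighttime sirens raise heart rate by a median 16 bpm — the
cohort was generated with a 16 bpm impulse, which the window statistic
recovers. The 155 participants in the post hoc are those passing the
four-period inclusion filter for mood.

The same stages are available as a CLI:

```bash
acutewell simulate --config config.yaml --out cohort/
acutewell classify --gps cohort/gps.csv --profiles cohort/profiles.csv --out exposure.csv
acutewell aggregate --in cohort/ --out aggregates.csv
acutewell siren-stats --hr cohort/heart_rate.csv --sirens cohort/sirens.csv \
    --exposure exposure.csv --out responses.csv
acutewell anova --in cohort/ --out results/
```

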