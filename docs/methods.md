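# Methods

This note documents the models and procedures `acutewell` implements, the
defaults it ships with and why, the numerical conventions, and what the
synthetic cohort does and does not emulate.

## Study design encoded in the defaults

The default configuration describes a 954-participant cohort of adults aged
40+ followed through four contiguous calendar periods around the May 2021
crisis: baseline **B** (2021-04-26 – 05-09), crisis **W** (05-10 – 05-20),
and two back-to-routine fortnights **R1** (05-21 – 06-03) and **R2**
(06-04 – 06-17). Default demographic and exposure-group proportions are the
published cohort composition (7.1% high, 73.8% medium, 19.1% low exposure;
42.5% men; four age bands from 40–49 to 70+; four income levels including
"unspecified"). Free days are Friday–Saturday plus a configurable holiday
list (default: 2021-05-17, which falls inside W); any other weekend
convention can be configured.

## Synthetic cohort generator

Daily indicator values follow

```
y_ikt = b_ik + o_k·free(t) + w_ik·g(period(t)) + e_ikt
```

with person-level baselines `b_ik ~ N(μ_k, σ_between²)`, a free-day offset
`o_k` (the weekly rhythm), day noise `e ~ N(0, σ_day²)`, and a persistent
crisis response `w_ik` active during W (and scaled by a per-indicator
`recovery_fraction`, default 0, in R1/R2).

**Effect sizing.** Configured crisis effects are Cohen's d values *on the
paired B→W period-aggregate delta scale*: that is the quantity the
published analyses report and the quantity the pipeline recovers, so the
generator guarantees `E[delta] = d·s_k` and `SD(delta) ≈ s_k`, where `s_k`
is the indicator's `delta_scale`. Internally, participants in a group with
effect d draw `w ~ N(d·s_k, σ_resp)` with
`σ_resp² = s_k² − v_agg`, where `v_agg` is the exact expected day-noise
variance of the weighted-period-mean difference given the calendar and fill
probabilities (computed with inclusion-conditional `E[1/n | n ≥ 1]` over
binomial fill counts). Groups with d = 0 have no crisis response at all,
which keeps the null cohort an exact null for the period effect.
An alternative sizing — a shift of d standard deviations of the *daily*
noise — was rejected because period aggregation shrinks the delta SD far
below σ_day, which would make the recovered paired d a large multiple of
the configured one.

Default `delta_scale` values are anchored to the published mean-change /
effect-size ratios (e.g. mood 0.33/0.52 ≈ 0.635 scale points; steps
736.9/0.19 ≈ 3878 steps). Baseline means and SDs are plausible placeholders —
no per-indicator baseline table is available to this package — and are
clearly overridable per indicator.

Default per-group effect sizes use the published per-group values for the
six indicators with reported group-specific effects (e.g. mood high −1.21,
medium −0.51) and the population value for both affected groups elsewhere;
the low-exposure group is unaffected except for screen-on time (+0.17).

**Missingness** is drawn per source stream and day: questionnaires fill
with probability 2.5/7 (≈ 2–3 fills/week; a fill answers all six
self-report indicators at once), the watch records with probability 0.9 and
the phone 0.8. With probability 0.05 a filled questionnaire day also gets
an earlier, perturbed duplicate submission, exercising the
keep-the-latest deduplication rule.

**Bounded scales.** Self-report scales are clipped to [−2, 2] after noise
addition and intrinsically nonnegative indicators at 0. Clipping slightly
shrinks the realized delta SD for indicators whose values approach the
bounds, biasing recovered |d| upward by a few percent (observed ≈ 4–7% for
mood at the default placement); this is within the Monte-Carlo tolerances
used throughout and is documented rather than corrected.

**GPS** is sampled every 15 min; night samples (00:00–07:00) sit at the
hometown coordinate with small jitter (default 5·10⁻⁴ deg ≈ 50 m), a 5%
fraction of nights is spent away from home, and 5% of participants have no
GPS at all (exercising the hometown fallback). A clock window can restrict
emitted samples — nighttime samples are all that residence inference uses,
and full-day traces for large cohorts are bulky.

**Heart rate** is a minute-level stream
`bpm = base + diurnal cosine (trough ≈ 04:00) + N(0, σ_noise) + impulses`,
where each siren in the participant's area adds `amp·exp(−Δt/τ)` for
Δt ≥ 0 (amplitude drawn per participant-event, default N(16, 5²) bpm
clipped at 0; τ = 6 min, so the impulse is < 5% of its amplitude 20 min
after onset, matching the observed ~20-minute return to baseline). The
stream is generated inside a configurable clock window (default 00:00–07:00
local) and by default only for crisis-period dates: the nighttime siren
analysis needs nothing else, and a full-day minute series for 954
participants would be ~20M rows with no analytical use here. Sirens are
Poisson per night and area (defaults 3/night high, 1/night medium, 0 low).

All timestamps are generated in one configurable timezone (default
Asia/Jerusalem; the study window has no DST transition). Every stage is
deterministic given (config, seed); independent substreams per stage make
the tables individually reproducible.

**What the generator does not emulate:** epidemic or holiday confounders,
device dropout dynamics, vendor-specific formats, within-day questionnaire
timing effects, spatial correlation of missingness, or autocorrelated day
noise. Passing tests therefore demonstrate the *pipeline's* correctness and
calibration under the design's statistical structure, not robustness to
every artifact of real wearable data.

## Cleaning and aggregation conventions

* Duplicate questionnaires: "same day" is the local calendar day; the
  retained entry has the maximal submission timestamp, ties keep the later
  input row (logged). Deduplication is idempotent.
* Out-of-range values (mood 7, bpm 300) are hard schema errors naming file,
  row and field — never clamped; silent repair would bias means.
* Sleep start hour is signed hours relative to midnight (23:30 → −0.5,
  00:45 → +0.75) so means are meaningful across midnight.
* The weighted period mean is `5/7·mean(work days) + 2/7·mean(free days)`,
  missing when either component is missing. Day-type means are plain
  arithmetic means.
* Inclusion: a participant enters an indicator's test only with both
  day-type components present in *every* required period (four periods for
  the main analysis, two for the delta analysis). This is the stricter of
  the two possible readings of "at least one value in free days and at
  least one in work days during all considered periods"; the looser
  reading (any nonempty weighted mean) would admit participants whose
  period means mix day types inconsistently.
* Non-recovery flagging: a participant is flagged when their B→R1 delta
  lies beyond k (default 2) robust SDs (median ± k·1.4826·MAD) of the
  cohort delta distribution in the indicator's adverse direction. This is a
  concrete instantiation of the qualitative "did not return to baseline"
  screen; k and the adverse directions are configuration. Fewer than 10
  participants: refuse (the scale estimate is unstable).

## Exposure classification

"Around 04:00" is the clock window [03:30, 04:30), configurable. The modal
location is computed on a grid of 3 decimal degrees (~110 m cells) to make
"most frequent coordinate" well-defined for continuous GPS; ties break to
the earliest-observed cell and are logged. The conflict reference point
defaults to the Gaza City centroid (31.5017 N, 34.4668 E) and is
configurable; distances within 5 km of the 60/110 km thresholds are logged
because classification there is sensitive to the reference choice.
Boundary convention: 60 km and 110 km are both medium ("between 60 and
110"); "less than 60" is strict. Distance is the haversine great-circle
distance on a 6371.0 km sphere.

## Siren response statistic

Windows are fixed as baseline [t−45, t−15) (half-open) and affected
[t−5, t+15] (closed); eligibility is local clock time in [02:00, 06:00)
and no sibling siren of the same area strictly inside (t−45, t−15).
Cross-area sirens do not disqualify, and sirens are matched to participants
by residence-area label, not GPS-at-siren-time. Any nonempty window is
accepted; sample counts per window are carried in the output for
inspection. Because the affected value is a maximum and the baseline a
mean, the statistic has a small positive bias on impulse-free noisy series
(≈ +0.3 bpm at 2 bpm noise and minute sampling); this is a property of the
estimator, verified by test, and deliberately not "corrected".

## Split-plot mixed ANOVA

Implemented from first principles as the classical two-stratum
decomposition. With N subjects in g groups and p = 4 periods (complete
cases only):

* between stratum: `SS_between = p·Σ_i (ȳ_i − ȳ)²` splits into
  `SS_group = p·Σ_g n_g (ȳ_g − ȳ)²` and `SS_subject(group)`;
* within stratum: `Σ_{i,t} (y_it − ȳ_i)²` splits into
  `SS_period = N·Σ_t (ȳ_t − ȳ)²`, the interaction
  `Σ_{g,t} n_g (ȳ_gt − ȳ_g − ȳ_t + ȳ)²`, and the residual.

All marginal means are sample-size weighted. Because every subject
contributes every period, the five components are *exactly* additive for
arbitrary group imbalance (verified to 1e-8 relative against a brute-force
nested-least-squares oracle on randomized designs, and exactly equal to
standard package output on balanced designs). F(group) uses
MS_subject(group); F(period) and F(interaction) use the within residual;
df are (g−1, N−g) and (p−1 resp. (g−1)(p−1), (N−g)(p−1)). No sphericity
correction is applied by default (none is assumed in the reference
analysis); a Greenhouse-Geisser epsilon from the pooled within-group
covariance is available behind a flag and adjusts the two within-effect
p values. Degenerate inputs (zero-variance strata) report F and p as
missing with a diagnostic; a group with fewer than two complete cases
aborts the test loudly rather than being dropped.

## Post hoc tests and effect sizes

Period pairs are compared by two-sided paired t tests on the eligible
complete cases. The Bonferroni family size defaults to m = 6 (all pairs of
four levels) with reporting restricted to the three baseline-containing
pairs; m is configurable and the corrected p clamps at 1. Cohen's d is the
paired-differences variant `mean(d)/SD(d)` (n−1 denominator), consistent
with the paired comparisons; pooled-SD variants would differ and are not
used. Zero-variance differences yield missing values with diagnostics. No
multiplicity correction is applied across the 12 indicators (matching the
reference analysis).

## Subgroup delta-ANOVA

The B→W deltas of the affected groups (medium + high) are modelled
additively on five between-subject factors: exposure group, age group
(younger ≤ 59 / older ≥ 60), gender, income level (three levels;
"unspecified" is missing and those participants drop out of this fit only)
and the baseline level (below vs at-or-above the population median of the
indicator's B value; ties count as at-or-above). Sums of squares are
Type III via sum-to-zero coding — each factor's SS is the RSS increase
from deleting its columns from the full design — appropriate for the
unbalanced demographic cells (and equal to sequential SS on balanced
designs, which is tested). Factor-level adjusted means come from the
sum-coded fit. A factor left with one observed level is dropped with a
diagnostic.

## Problem sizes used in verification

The test suite and the acceptance script scale the Monte-Carlo studies to
what the estimators need rather than to the full cohort everywhere: oracle
equivalence on 50 randomized 6–50-subject designs; type-I calibration with
200 replicates of 300-participant null cohorts (99% binomial band around
α = 0.05 is [0.01, 0.10]); effect recovery at n = 700 over 20 seeds
(pooled-mean tolerance ±0.1 around d = 0.52); the siren statistic on
~100-participant cohorts (tolerance ±1.5 bpm around a 16 bpm impulse);
plus one full default-conditions run at n = 954. Calibration and recovery
cohorts use balanced exposure proportions (25/50/25) so every group retains
enough complete cases at these sizes; the default cohort composition keeps
the published 7/74/19 split.

## Known limitations

* Complete-case analysis throughout; no imputation and no mixed-effects
  (REML) alternative — with 2–3 questionnaire fills per week a panel
  regression would be underpowered, and it is explicitly out of scope.
* The exposure rule is the main-text distance rule; finer region-level
  classification schemes are not guessed at.
* Self-report realism is limited to scale bounds and missingness; response
  styles (anchoring, end-aversion) are not modelled.
* The haversine distance assumes a spherical Earth (≤ 0.5% error), which is
  irrelevant at the 60/110 km thresholds' logged sensitivity but worth
  noting for reuse elsewhere.
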