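# Methods

This note records how each daily score is computed, which choices were open
and how they were settled, what the scenario simulator does and does not
emulate, and the numerical conventions the engine follows.

## Event model

All timestamps are timezone-naive local time; scoring works in minute
deviations, so records are kept at (sub)minute resolution and the simulator
rounds everything to whole minutes. Every point event (dose, motor sample,
meal, exercise, questionnaire) belongs to the calendar date containing its
timestamp. Days with no events still appear in the output table as
all-missing rows so the time axis stays continuous; missing is represented
as NaN/empty-cell and is never imputed or collapsed to 0.

Sleep is the exception to day-partitioning, since nights span midnight. Bed
intervals separated by gaps shorter than `night_chain_gap_h` (default 4 h)
are chained into one sleep episode; an episode qualifies as a night when it
starts after 18:00 or before 12:00 (chains starting in the afternoon are
treated as naps and excluded from sleep scoring); and a night is attributed
to the day on which the patient finally left the bed — the wake day. The
attribution convention is not fixed by the underlying protocol; the wake-day
choice keeps "last night's sleep" on the day it affects, and both the gap
and the qualifying window are configurable. If two qualifying episodes land
on one wake day (a short late-evening episode plus a morning one beyond the
chaining gap), the episode with the most cumulative time in bed is scored.

## Medication compliance

Per day, scheduled deliveries are assigned to planned occasions by the
matching that minimizes the total absolute timing deviation, at most one
delivery per occasion. Because both sequences are time-ordered, an optimal
assignment never crosses, so it is found by an O(n·m) dynamic program; ties
resolve toward the earlier delivery, making the matching deterministic. (A
greedy closest-pair rule was considered and rejected: it is suboptimal on
instances as small as 5×5, and the module's oracle-equivalence property —
agreement with exhaustive assignment on small instances — is the stronger
contract.)

Extra doses are classified against the planned schedule: within
`replacement_window_min` (30 min) of a planned time they replace that
occasion if it is otherwise unmatched, and are omitted from all calculations
if the occasion is already covered; outside every window they form an
occasion of their own, credited at 100.

The per-occasion deviation-to-score map is a linear decay clamped at zero:

    score = max(0, 100 · (1 − deviation / D_max)),   D_max = 120 min

The exact published curve is not recoverable from the protocol text, so the
simplest monotone map onto the stated 0–100 range is used, isolated behind
`occasion_score` so a different curve can be dropped in; `D_max` is
configurable. Missed occasions score 0 and count in *n* — otherwise
skipping doses would raise the daily mean. Whether a replacement dose
contributes its own deviation is genuinely ambiguous; by default it does
(`replacement_counts_deviation=True`), and the alternative reading — the
replaced occasion leaves the daily mean entirely — is behind the flag.
The daily score is the arithmetic mean over the scored occasions; a day
with no occasion is missing.

## Sleep

Cumulative hours in bed, the in-bed window (first enter to final leave) and
the number of interruptions (gaps of at least `min_interruption_gap_min`,
default 1 min, a jitter guard for the bed sensor) summarize a night. The
three components follow the PSQI-style rule tables:

| cumulative hours | duration | efficiency ratio | efficiency | interruptions | disturbances |
|---|---|---|---|---|---|
| > 7 | 0 | ≥ 85 | 0 | 0 | 0 |
| 6–7 | 1 | 75–85 | 1 | 1 | 1 |
| 5–6 | 2 | 65–75 | 2 | 2 | 2 |
| < 5 | 3 | < 65 | 3 | ≥ 3 | 3 |

with ratio = 100 · cumulative hours / window hours (the standard habitual
sleep-efficiency form; the ratio is clamped at 100 against float
round-off). The printed rules use strict inequalities, leaving exactly 7, 6
and 5 hours and ratios exactly 75 and 65 undefined; boundaries join the
less-severe bucket (7 h → 0, 75 → 1), a deterministic benefit-of-the-doubt
rule. The final score is the linear complement of the component sum over
its maximum:

    sleep score = 100 · (1 − (duration + efficiency + disturbances) / 9)

which is the simplest monotone map of the three 0–3 components onto the
declared 0 (worst) – 100 (best) scale. A night whose window has zero width
raises a degenerate-night error. Daytime naps never enter cumulative hours
(see the night-qualification rule above).

## Motor function

The wrist sensor is assumed to deliver bradykinesia and dyskinesia already
normalized to 0–100 with higher = better, consistent with every other score
in the daily summary; calibration of raw inertial data is out of scope. The
daily score per channel is the plain arithmetic mean over the day's
samples — all samples, day and night, since no exclusion rule is defined —
and the channels are reported separately (the averaged single "motor"
column exists only as an optional derived output).

## Meal timing

The recommendation windows are `[t − 30 min, t + 60 min]` around each
levodopa intake *t* (delivered doses, including extras). Levodopa competes
with dietary protein for absorption, so the default reading is that meals
should *avoid* these windows: a meal complies when it falls in no window
(`meal_window_mode="avoid"`); the opposite reading is available as
`"require"`. Score = 100 · NWI / n over the day's reported meals; no meals
reported → missing.

## Physical activity

Score = min(100, 100 · Σᵢ modeᵢ · durationᵢ / target), summing over the
day's occasions, where the mode weight is 1 (boxing, dancing, running,
swimming), 2 (bicycling, gym) or 3 (walking) and the target is the
individual patient target in (0, 100]. The sum-then-normalize form follows
the protocol's worked numeric example (two occasions, mode 1 × 10 min and
mode 2 × 25 min, target 80 → 75), which contradicts its prose sketch of
"average then normalize"; the numeric example is the only verifiable
anchor. Values beyond the target clamp at 100.

## Quality of life

Nine daily items: Mobility, Personal care, Daily activities, Pain or
discomfort, Worry or depression (EQ-5D-3L), Concentration difficulties,
Communication difficulties, Painful cramps or spasms (PDQ-8), and the
EQ-5D-3L 0–100 overall-health VAS. The eight level items map level L ∈
{1, 2, 3} to score 3 − L ∈ {2, 1, 0} (0 worst, 2 best). The VAS serves as
the overall day score — it is the only self-contained 0–100 overall
measure in the instrument set; no EQ-5D utility tariff or PDQ-8 summary
index is computed.

## Aggregation

The daily summary has columns `date, medication, sleep, bradykinesia,
dyskinesia, meal, exercise, overall_day, qol_q1..qol_q8`. Rolling summaries
are per-score means over the last `summary_window_days` (14) rows with
missing values excluded per score; a score missing on all days stays
missing. Bands: good > 70 (green), average 30–70 inclusive (gray), bad
< 30 (orange); 30 and 70 fall in the middle band because the stated middle
range is "30 to 70". Correlation between two daily scores uses Pearson
(Spearman by flag) over pairwise-complete days, with an optional lag
shifting y forward by whole days; fewer than 3 complete pairs is an error,
not a coefficient.

## Scenario simulator

The simulator emulates the kind of hand-built patient scenario databases
the monitoring system was developed against, with statistical structure
sufficient to test the scoring engine — not a clinically realistic disease
phenotype (no progression, no wearing-off pharmacology, no circadian
model). Per seeded scenario:

- planned doses: `doses_per_day` (4) equally spaced across waking hours
  08:00–20:00, 100 units each;
- deliveries: planned time + N(0, `adherence_sd_min` = 15 min), rounded to
  the minute and kept inside the day; each planned dose missed with
  `miss_prob` (0.1); extras as Poisson(`extra_rate_per_day` = 0.3) uniform
  over waking hours;
- nights: in-bed time `bed_duration_h` (7.5 h) from ~23:00 (Gaussian
  bedtime jitter, SD 20 min), split by Poisson(`interruption_rate_per_night`
  = 1.5) interruptions with 5–25 min gaps; every chunk is at least 2 min so
  rounding cannot invert an interval;
- motor: one sample per 2 min per channel; baseline
  (`motor_baseline` = 65) plus a raised-cosine bump of width
  `dose_response_width_min` (120 min) and amplitude
  `dose_response_amplitude` (20; dyskinesia responds at 0.6×) after each
  delivered dose, plus N(0, `motor_noise_sd` = 5), clamped to [0, 100] —
  the simplest fluctuation that makes the dose→motor coupling detectable
  by the correlation view;
- meals at ~08:30/12:30/18:30 with 30-min jitter; exercise on
  `exercise_prob_per_day` (0.6) of days with random mode and 15–60 min
  duration; QoL levels drawn 1/2/3 with probabilities 0.5/0.35/0.15 and
  VAS ~ N(65, 15) clamped.

The defaults describe a moderately fluctuating levodopa-treated patient
over a 14-day horizon. All randomness flows from one `SeedSequence`; each
stream uses its own spawned child generator so adding a stream never
perturbs the others, and equal seeds give byte-identical CSV bundles.
Alongside the streams the simulator records a `GroundTruth` object (realized
per-day timing deviations, missed/extra counts, night duration and
interruption counts, empirical per-day motor means, meal times, exercise
raw activity, VAS) for recovery tests.

What passing tests on simulated data do **not** show: robustness to sensor
dropout patterns of real hardware, to clock drift or timezone changes, to
correlated self-report biases, or to motor signals whose distribution
differs from "baseline + dose bump + Gaussian noise".

`stress_config` draws deliberately extreme configurations (timing noise up
to 4 h, miss probability up to 1, nights of 15 min–14 h, up to ~10
interruptions, exercise to 10 h) used by the range-conservation suite.

## Problem sizes and runtime choices

The test suite and the acceptance script use 14–100 day scenarios; the
range-conservation sweep runs 1000 two-day extreme scenarios (a few
seconds), and statistical recovery checks use 100 days (≈400 occasions,
100 nights) against 3-standard-error bands. The dose-coupling correlation
check uses 40 seeded 21-day runs with strengthened coupling
(miss probability 0.3, amplitude 40) so the expected positive sign
dominates sampling noise.

## Known limitations

- The deviation→score curve, efficiency-ratio form and final sleep-score
  equation reconstruct unpublished formulas from their surviving
  constraints; each is isolated behind one function.
- One questionnaire response per day is assumed (duplicates are rejected);
  multi-patient files are out of scope, as is reading Excel directly (CSV
  export assumed).
- Band thresholds are fixed constants of the interface convention, not
  configurable.
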