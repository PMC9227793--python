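# empark

Daily scoring engine for IoT-based home monitoring of Parkinson disease.

People with Parkinson disease fluctuate within the day between good ("on")
and impaired ("off") motor states, and disease management hinges on the
timing of levodopa doses relative to meals, sleep and activity. A home
monitoring setup — an electronic dosing device, a bed sensor, a wrist sensor
emitting bradykinesia/dyskinesia scores every 2 minutes, and a tablet for
self-reports — produces six raw event streams per patient. `empark` turns
those streams into one row per calendar day of 0–100 scores (0 worst, 100
best), the summaries a patient or clinician dashboard would display, and
cross-score correlations. A seeded scenario simulator generates all six
streams with known ground truth, so the whole pipeline is testable without
any real device data.

## The scores

For each calendar day:

- **Medication compliance** — each delivered dose is matched to the planned
  schedule (minimum total timing deviation); an occasion with deviation *d*
  minutes scores `max(0, 100·(1 − d/D_max))` with `D_max = 120`; missed
  occasions score 0; an extra dose within ±30 min of a planned time replaces
  that occasion, while other extras are credited at 100. Daily score = mean
  over the *n* occasions.
- **Sleep** — bed intervals are chained into a night (gaps < 4 h) attributed
  to the wake day. Three PSQI-style components, each 0 (best) to 3 (worst):
  sleep duration (cumulative hours in bed: >7→0, 6–7→1, 5–6→2, <5→3),
  habitual sleep efficiency (ratio = 100·cumulative/in-bed window: ≥85→0,
  75–85→1, 65–75→2, <65→3), and disturbances (interruptions 0/1/2/≥3 →
  0/1/2/3). Sleep score = `100·(1 − (sum of components)/9)`.
- **Bradykinesia / dyskinesia** — per-channel arithmetic mean of the
  2-minute wrist-sensor samples, reported separately.
- **Meal timing** — a meal complies when it avoids the window 30 min before
  to 60 min after every levodopa intake; score = `100·NWI/n`.
- **Physical activity** — `min(100, 100·Σ mode_i·duration_i / target)`,
  with mode 1 (boxing/dancing/running/swimming), 2 (bicycling/gym),
  3 (walking) and an individual patient target. E.g. mode 1 for 10 min plus
  mode 2 for 25 min at target 80 → `100·(10 + 2·25)/80 = 75`.
- **Quality of life** — nine daily items (five EQ-5D-3L dimensions, three
  PDQ-8 items, each re-coded to 0 worst / 2 best, plus the 0–100
  overall-health VAS, which is the overall day score).

Scores band as good (>70, green), average (30–70, gray), bad (<30, orange);
the start-page summary is the 14-day mean per score.

## Worked example

```
empark simulate --out scenario/ --seed 5        # synthetic 14-day patient
empark score scenario/ --out scores.csv
empark summarize scores.csv
empark correlate scores.csv --x medication --y bradykinesia
```

`summarize` prints the 14-day means with their bands, e.g. (seed 5):

```json
{
 "window_days": 14,
 "scores": {
  "medication":   {"mean": 79.55, "band": "good",    "color": "green"},
  "sleep":        {"mean": 84.92, "band": "good",    "color": "green"},
  "bradykinesia": {"mean": 68.07, "band": "average", "color": "gray"},
  "dyskinesia":   {"mean": 66.83, "band": "average", "color": "gray"},
  "meal":         {"mean": 45.24, "band": "average", "color": "gray"},
  "exercise":     {"mean": 79.44, "band": "good",    "color": "green"},
  "overall_day":  {"mean": 70.78, "band": "good",    "color": "green"}
 }
}
```

(means rounded to 2 dp here), so this simulated patient's medication timing
and sleep band green while motor function sits mid-band; `correlate` then
reports the Pearson coefficient between the daily medication and
bradykinesia scores over the pairwise-complete days (here `coefficient
0.910, n 14` — the simulator couples motor state to dose intake, and the
engine recovers that coupling). The same operations are available as
library calls (`empark.score_scenario`, `empark.rolling_summary`,
`empark.correlate_scores`, `empark.simulate_scenario`).

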