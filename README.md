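# endosched

Prediction-driven appointment scheduling for digestive-endoscopy units.

Elective endoscopy backlogs grew sharply after the COVID-19 pandemic, and
the prevailing booking practice — a flat 30-minute slot for every patient —
sits awkwardly on procedures whose room time actually spans 2 to 85
minutes. This package is for health-services / operations-research work on
that problem: it predicts each patient's procedure duration from clinical
features, turns the prediction into a planned appointment (predicted time
plus a 15-minute buffer for consent, preparation and transfer), schedules a
prioritized waiting list, and measures what the schedule would have done
under the *realized* durations.

## The model

**Duration prediction.** Gradient-boosted trees (or linear / random-forest
/ Gaussian-process / MLP alternatives) regress procedure minutes on the
waiting-list features (sex, age band, BMI band, priority, comorbidities,
past failed colonoscopy, procedure type, indication, endoscopist
specialty). Features are chosen by wrapper backward elimination scored with
5-fold cross-validated MAE, capped at four features.

**Scheduling.** Two policies over a horizon of days `D`, endoscopists `E`
with daily working blocks `δ_e^d` (minutes), and patients `p` with planned
appointment `δ_p` and due date `d_p`:

* a greedy heuristic over a globally sorted waiting list (priority ↓, due
  date ↑, appointment length ↓), placing each patient in the earliest
  feasible opening of their designated endoscopist, or of any accepting
  compatible endoscopist;
* an assignment MIP on binaries `x_{pe}^d`:

  maximize `ω₁ Σ x_{pe}^d − ω₂ Σ_{d > d_p} (d − d_p)² x_{pe}^d`
  subject to `x_{pe}^d = 0` for `e ∉ E_p`,
  `Σ_p δ_p x_{pe}^d ≤ δ_e^d` for all `e, d`, and
  `Σ_{e,d} x_{pe}^d ≤ 1` for all `p`,

  with `ω₁ > ω₂ · (max lateness)²` so throughput dominates and the squared
  penalty spreads unavoidable lateness evenly. Solved by HiGHS
  branch-and-bound via `scipy.optimize.milp`; an exhaustive enumerator
  cross-checks the solver on small instances in the test suite.

**Evaluation.** Schedules are built on planned minutes and evaluated on
realized minutes (actual duration + buffer): scheduled counts and lateness
per priority class, plus per-room-day overtime and earliness against a
390-minute daily budget.

Because the real waiting-list data behind this line of work is not public,
a synthetic-cohort generator reproduces the reported case-mix marginals
and duration moments (truncated log-normal, mean 16.2 min, sd 9.85,
support [2, 85], with procedure-type and comorbidity effects). See
`docs/methods.md` for the full model description and its limitations.

## Worked example

`examples/03_schedule_policies.py` builds a contended instance
(150 patients, 2 rooms × 5 days × 390 min), trains a duration model on a
disjoint cohort, and runs all three policies on identical inputs:

```
policy             scheduled  avg late OT/day/room early/day/room
fixed-30                 130      2.55       49.82           8.50
predictive greedy        122      2.51       21.74           9.84
mip                      128      1.59       35.36           4.29
```

Reading it: the flat baseline books 13 slots a day regardless of who the
patients are, so its realized load overruns the budget by ~50 min per room
per day here; the predictive greedy respects realistic appointment lengths
(fewer patients, much less overtime); the MIP recovers most of the
throughput while cutting average lateness from 2.55 to 1.59 days and idle
time to 4.29 min. Other `examples/` scripts cover cohort generation, model
training, and the two packaged experiments; a `endosched` CLI
(`generate` / `train` / `schedule` / `exp1` / `exp2`) wraps the same
library calls for shell use.

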