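# Methods

## Problem

A digestive-endoscopy unit holds a prioritized waiting list of patients, a
bank of endoscopists each providing a daily working block of room time, and
a fixed planning horizon of working days. Current practice books every
patient into a flat 30-minute slot. Procedure room-time actually varies
widely (2–85 minutes here, mean 16.2, sd 9.85), so flat slots either waste
room time or run the day over. The package predicts each patient's
procedure duration from clinical features, converts the prediction into a
planned appointment length by adding a 15-minute buffer (consent,
preparation, transfer in/out), and schedules the waiting list with either a
greedy heuristic or a day-level assignment MIP. Schedules are *built* on
planned minutes and *evaluated* on realized minutes (actual duration +
buffer), which is what makes over- and under-booking measurable.

## Data model and conventions

Days are integers with the horizon starting at day 1. Due dates derive from
the Quebec priority classes (P2, P3, P4, P5, SURV in decreasing urgency;
P1 emergencies are triaged outside elective lists and are out of scope) and
may be negative — a patient can already be overdue when the horizon opens.
Lateness of a scheduled patient is `max(0, scheduled_day − due_date)`;
waiting time, reported alongside, is `scheduled_day − admission_date`. The
two differ by the priority class's due-date offset, and the package reports
both rather than guessing which one an external table of "average late
time" refers to. Unscheduled patients have no scheduled day and are
excluded from lateness averages; they are counted separately.

One "room" is one endoscopist's daily block stream. For each (endoscopist,
day) the evaluation compares realized load against a configurable daily
operational budget (default 390 minutes): overtime is the excess, earliness
the shortfall, and per construction at most one of the two is positive and
`earliness − overtime = budget − realized load` exactly.

## Synthetic cohorts

Real waiting-list data of this kind is not public, so the generator emulates
the reported case mix by its marginals: sex (51.2 % male), age bands
(17.8 / 27 / 47.1 / 8 %), BMI bands including an explicit "missing" level
(42.7 %), procedure mix (colonoscopy 64.2 %, gastroscopy 30.7 %, other
5.1 %), comorbidity scores (54.6 / 22.7 / 14.4 / 6 / 2.3 %), and prior
pelvic surgery in 13.7 % of patients (females only, so the conditional rate
is 0.137 / 0.488). Features are sampled independently because only
marginals are known; the boolean comorbidity rates (respiratory 15 %,
cardiovascular 20 %, diabetes 12 %), the past-failed-colonoscopy rate
(10 %), the failed-reason split, the indication mix, and the priority mix
(P2 2 %, P3 43 %, P4 15 %, P5 14 %, SURV 26 %) are fixed package defaults,
all exposed through `CohortSpec.marginals`.

Durations follow a truncated log-normal with additive log-scale covariate
effects: gastroscopy −0.77 (×0.46 — gastroscopies take roughly half the
room time of colonoscopies), other procedures −0.05, respiratory disease
+0.18, diabetes +0.11, chosen for clinical plausibility and so a trained
model has genuine signal to find. Given these effects and the feature
marginals, the location `mu0` and scale `sigma` are solved numerically
(two-dimensional root find on closed-form truncated-lognormal mixture
moments) so that the population mean and sd equal 16.2 and 9.85 minutes
exactly on the support [2, 85]. The solution is `mu0 ≈ 2.811`,
`sigma ≈ 0.481`, giving cell means of about 18.7 (colonoscopy), 8.7
(gastroscopy) and 17.7 (other) minutes.

Due dates are uniform on the integer window [−7, 14] relative to horizon
start; admission dates follow from per-priority due-date offsets (P2 14,
P3 60, P4 180, P5 365, SURV 365 days — configurable; they affect only the
waiting-time metric, never feasibility). Half the patients (configurable)
carry a designated ("nominative") endoscopist drawn uniformly among
compatible providers. The default roster makes every endoscopist compatible
with every procedure type and accepting of non-nominative patients; both
flags are configurable.

What the generator does **not** emulate: feature covariance (only marginals
are known), arrival processes, no-shows, cancellations, intra-day patient
flow, and weekday structure. Passing tests therefore demonstrate that the
method behaves correctly under the stated case mix and duration moments,
not that its effect sizes transfer to any particular real unit.

## Duration prediction

Cleaning drops rows whose duration label is missing, nonpositive, or
outside [2, 85] minutes. Categorical features are one-hot encoded with
fixed vocabularies (missing BMI is its own level), the comorbidity score
stays numeric.

Feature selection is wrapper backward elimination at the level of feature
*groups* (a categorical feature and all of its one-hot columns move
together): each round refits the regressor on the current set, scores the
set by 5-fold cross-validated MAE on the training split, and removes the
group the fitted model ranks least important. Importance is total loss
reduction (XGBoost `total_gain`) summed over a group's columns — per-split
averages would bias against boolean features and toward wide categorical
groups — with coefficient magnitude or permutation importance as fallbacks
for models exposing no native measure. Ties break toward the feature later
in the schema order, for determinism. The selected set is the best-scoring
one with at most `max_features` groups (default 4, guarding against
overfitting a small dataset). The test split is withheld until final
evaluation; selection never sees its labels.

Five regressor families are supported behind one contract: linear
regression, random forest, gradient-boosted trees (XGBoost; the default),
Gaussian process, and a small multilayer perceptron. The gradient-boosted
default uses conservative small-data settings (150 trees, depth 4,
learning rate 0.1, `gamma=1.0`, `min_child_weight=10`, no row subsampling):
the explicit split-gain threshold and leaf-weight floor keep pure-noise
splits out of the trees, which both prediction stability and gain-based
ranking rely on, and the absence of subsampling makes fits deterministic
given a seed. Predictions are floored at the 2-minute minimum. Evaluation
uses a random 80/20 train/test split; MAE ≤ √MSE holds by Jensen's
inequality and is asserted in the tests.

## Greedy scheduling

The waiting list is sorted by (1) priority, most urgent first; (2) due
date, earliest first; (3) planned appointment length, longest first; then
admission date and patient id for determinism. Patients are placed in list
order: a nominative patient goes to the earliest feasible opening of their
designated endoscopist; a non-nominative patient goes to the earliest
feasible day over accepting, compatible endoscopists, choosing among
same-day candidates the one with the most remaining minutes (roster order
breaks ties). Appointments pack back-to-back within a day rather than on a
30-minute grid — with flat 30-minute appointments the two coincide, so the
grid emerges as a special case of the baseline rather than a separate code
path. A patient who fits nowhere is skipped (the horizon is fixed; there is
no rollover queue) and the scan continues.

## Assignment MIP

Binary `x[p, e, d]` assigns patient `p` to endoscopist `e` on day `d`;
the objective maximizes `w1·(count scheduled) − w2·Σ (d − d_p)₊²` subject
to eligibility (`E_p` is the designated endoscopist alone for nominative
patients, otherwise all accepting compatible providers), per-(e, d) planned
minutes ≤ the working block, and at most one appointment per patient. The
squared overdue penalty spreads unavoidable lateness evenly: for a fixed
total of 4 overdue days, 2 + 2 costs 8·w2 while 0 + 4 costs 16·w2.
Defaults `w1 = 1`, `w2 = 10⁻³` satisfy the dominance condition
`w1 > w2·(max possible lateness)²` for horizons up to 31 overdue days
(e.g. a 10-day horizon with due dates from −7 gives max lateness 17 and
requires `w2 < 1/289`); `build_instance` verifies the condition against
the actual horizon and scales `w2` down with a warning if violated, so
scheduling a patient always beats leaving them unscheduled. Due dates past
the horizon simply incur zero penalty. Morning/afternoon blocks are merged
into a single daily capacity; block structure is a calendar concern.

Solving uses HiGHS branch-and-bound (`scipy.optimize.milp`). With the
default rational weights the objective is scaled to integer values
(×1000), so an absolute gap below 1 certifies exact optimality; `solve`
requests that certificate alongside the relative-gap tolerance. The
day-level packing problem carries an inherent LP integrality gap of
roughly 0.5–1 % at a few thousand binaries — fractional solutions fill
every block exactly while integer packings cannot — so certifying very
tight relative gaps is impractical at experiment scale even though
incumbents within a patient or two of the bound appear quickly. The
package therefore defaults to a relative gap of 10⁻³ and runs
experiment-scale instances under *deterministic* search limits
(branch-and-bound node or improving-incumbent caps rather than wall-clock
time, which would make results machine-dependent and break seeded
reproducibility; a wall-clock limit remains available for interactive
use). Whenever a limit interrupts the search, the returned solution is
floored by deterministic primal candidates — the solver's incumbent and
the greedy warm-start schedule, each run through a completion pass that
packs remaining patients shortest-first into leftover capacity at the
lowest-penalty day, plus the standalone fill heuristic — and the certified
gap is recomputed against the solver's dual bound. Under the weight
dominance condition the completion pass only ever improves the objective,
and it leaves solutions maximal (no further patient fits). Exact
mode (`gap_tol=0`) is used throughout the tests that compare the solver
against `brute_force_oracle`, an independent depth-first enumerator for
instances of at most ~20 binaries. The MIP assigns days, not clock times;
`sequence_within_day` orders each room-day by the waiting-list sort keys
and packs from minute 0.

## Experiments

Both packaged experiments replicate end to end: each replication draws a
fresh evaluation cohort, trains the duration model on a disjoint synthetic
training cohort (n = 1000 by default, selection off for speed since the
fitted model is what matters there), and runs all requested policies on
bit-identical inputs (asserted by hashing). Results are per-replication
rows plus means and standard errors.

* Throughput: 1000 patients, 6 streams × 10 days × 390 minutes. The flat
  baseline saturates at exactly 780 = 6 × 13 × 10 slots.
* Overtime/earliness: 251 patients, 2 rooms × 8 days × 390 minutes, with
  contention (expected demand ≈ 7 800 planned minutes against 6 240).

A consequence of the calibrated duration moments worth stating plainly:
the mean planned appointment is 16.2 + 15 = 31.2 minutes, more than the
30-minute slot, so under these conditions the flat baseline *overbooks* on
average (realized load ≈ 405 minutes against a 390-minute budget; its
earliness is small and its overtime large), and the adaptive policies
schedule slightly fewer patients than the baseline while respecting
realistic durations. Settings whose case mix yields mean appointments
below 30 minutes show the opposite pattern — an underbooked baseline with
large earliness. Which regime a unit sits in is decided entirely by its
duration distribution, not by the scheduling method.

## Numerical choices and degenerate inputs

Calibration uses `scipy.optimize.root` with tolerance 1e-12 and is cached
per parameter set. Zero-dispersion duration parameters degenerate to
point masses at each cell's location (used as a test limit). Empty
cohorts, empty room-days, and zero-capacity calendars are all defined:
empty room-days contribute full-budget earliness; a calendar with no
room-days is rejected as degenerate. All randomness flows from one run
seed through named substreams (cohort, durations, dates, roster,
nominative assignment, model seeds), so modules are independently
reproducible; replication *i* uses `base_seed + i`.

## Known limitations

Feature independence and a 12-cell duration signal make prediction easier
than on real data in some respects (no label noise beyond the lognormal)
and harder in others (no within-cell covariates to exploit); the test
MAEs the examples print (~6 minutes) are therefore not comparable to any
particular unit's. The MIP returns gap-certified incumbents, not certified optima, at
experiment scale. No-shows, cancellations, emergency insertions and
intra-day sequencing constraints are out of scope.
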