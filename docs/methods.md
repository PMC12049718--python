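# Methods

This note documents the models, conventions and numerical choices behind
`cagecog`, in the order data flow through the package.

## Event model and raw dialect

The canonical observation is a `VisitEvent`: one mouse in one corner
chamber, with nested time-sorted nose-poke and lick events that must lie
within the visit window.  Raw input is three tab-separated files
(`Visits.tsv`, `Nosepokes.tsv`, `Licks.tsv`) with ISO-8601 timestamps,
joined on `visit_id`, plus an unblinding file mapping transponder tag to
group.  Commercial cage software exports vary by version; this dialect is
a deliberately minimal clean-room format that any export can be mapped to
with a few lines of pandas.  Writing then reading is the identity on the
canonical model, and loading never reorders a mouse's event stream.

Timestamps are timezone-naive local clock times.  The light cycle is fixed
on the local clock: light 06:00–18:00, dark 18:00–06:00.  A visit that
spans a phase boundary belongs to the phase of its start time — visits
last seconds to minutes, phases last twelve hours, so the rule is
unambiguous in practice.  All intervals in the package are half-open
`[start, end)`.

## The challenge schedule

The bundled 14-day plan encodes three challenges (11 scored task days):

| day | task | rule | active window |
|----|------|------|---------------|
| 1  | habituation | free | 24 h |
| 2  | place learning | one corner per group | dark phase |
| 3  | reversal learning | diagonal corner | dark phase |
| 4  | multiple reversal | 3-h alternation | dark phase |
| 5  | extinction | free | 24 h |
| 6–7 | episodic memory acq./ret. | place corner | 22:00–24:00 |
| 8–9 | episodic reversal acq./ret. | diagonal corner | 20:00–22:00 |
| 10 | extinction | free | 24 h |
| 11–12 | patrolling clockwise | advance cw per correct attempt | dark phase |
| 13–14 | patrolling counterclockwise | advance ccw | dark phase |

Corners are labeled 1–4 in clockwise physical order, so the diagonal pairs
are (1,3)/(2,4) and "clockwise" and "diagonally opposite" are mutually
consistent.  Plans serialize to YAML; group→corner assignments, the
episodic-memory windows and the start date are all configurable.

Conventions where the protocol leaves room:

- **Multiple-reversal start corner.** Blocks are half-open 3-h intervals
  from dark onset; block 0 rewards the reversal corner (continuity with
  the preceding day), alternating thereafter.  `mrl_start="place"` flips
  this.
- **Patrolling anchor.** The state machine starts unanchored; the first
  drinking attempt's corner becomes the rewarded corner (that attempt is
  classified as correct — any corner would have anchored).  A correct
  attempt at the rewarded corner advances one step in the task direction;
  advancement (and anchoring) happen only inside the active window.
  Door-open status is not required for advancement — a drinking attempt at
  the rewarded corner suffices.
- **Clockwise→counterclockwise handover.** The first ccw rewarded corner
  is one ccw step beyond the corner of the animal's last *correct*
  clockwise attempt — the advance-after-each-correct-attempt rule carried
  through the direction switch.  The alternative reading (the last correct
  corner itself) is available via `patrol_handover="same"`.  Animals with
  no correct clockwise attempt start the ccw phase unanchored.

## Metrics

**Visit classification.** Exploratory ⇔ zero pokes.  Repetitive bouts are
maximal runs of ≥ 2 pokes uninterrupted by a lick (pokes and licks merged
in time order); frequency counts visits containing ≥ 1 bout, total counts
Σ(bout length − 1).  This single rule reproduces the canonical worked
example (10 uninterrupted pokes → frequency 1, total 9) and allows several
bouts per visit when the mouse resumes poking after drinking.

**Error rates** are computed per animal × scored day × period from the
annotated attempt stream:

- The *spatial target* for PE is the day's corner rule with the time
  restriction removed: the assigned corner applies all day on static days;
  multiple reversal resolves to the current 3-h block in the dark phase
  and to the block-0 corner outside it; patrolling uses the current state
  corner (all corners while unanchored).  This choice makes PE meaningful
  in the light-phase and 24-h periods, where no water is actually
  available; the time component is scored separately by TE.
- CE is defined only where a unique previously-rewarded corner exists:
  the place corner on reversal day, the currently unrewarded member of the
  alternating pair during multiple reversal, and the first-episodic corner
  on the episodic-reversal days.  Patrolling days have no single previous
  corner (the preceding phase rewards all corners or a rotating one), so
  CE is reported missing there; it carries no weight in those tasks'
  cognition index either way.
- DE (counterclockwise patrolling only): attempts at the corner one
  clockwise step from the corner of the most recent rewarded attempt.
  With last rewarded corner 2, the next correct corner is 1 and the DE
  corner is 3; attempts at 2 or 4 count toward neither DE nor success.
  DE is undefined until the animal has drunk at least once.
- Since the CE and DE corners are never the currently correct corner,
  their attempts are subsets of PE attempts and PE_adj = PE − CE − DE ≥ 0.
- A cell with zero drinking attempts yields missing rates, never zeros —
  a mouse that never attempted is not a perfect scorer.  Missing values
  propagate to group summaries (n counts non-missing animals) and are
  dropped from statistics.

**Cognition index.** The weighted-error sum is subtracted from 1 as a
whole, CI = 1 − Σ wᵢ eᵢ, which is the only reading that keeps CI in [0,1]
with higher = better.  Weights per task (PE_adj/CE/TE/DE): place and
clockwise patrolling 100/–/–/–, reversal and multiple reversal 75/25/–/–,
episodic acquisition/retrieval 75/–/25/–, episodic reversal 50/25/25/–,
counterclockwise patrolling 75/–/–/25.  Error metrics are not computed for
habituation or extinction days (only behavior counts are).

**Welfare.** An animal is flagged for exclusion from the first day
completing a run of ≥ 2 consecutive days with fewer than 100 licks/day
(strict inequality, consecutive days required).

## Learning curves

For each mouse × task, the active-window drinking attempts are ordered in
time and classified correct/incorrect by corner only (time errors do not
affect curve success).  The cumulative success count against the 1-based
attempt index is fit by ordinary least squares; for a Bernoulli(p) outcome
stream the slope is a consistent estimator of p.  The chance reference is
the analytic line with slope exactly 0.25 and intercept 0 — a design
constant, never estimated; injecting synthetic "dummy" observations into
the model would fabricate degrees of freedom.

Group fits pool animals as replicates under a shared slope.  The points of
one animal's curve are a random walk around its trend, so the naive OLS
standard error (which treats every point as independent) understates the
slope uncertainty by an order of magnitude; under a null simulation it
rejects the true slope two thirds of the time.  The package therefore
estimates group-slope uncertainty with a leave-one-animal-out jackknife
(t reference with n_animals − 1 df), and the group-versus-group ANCOVA
(`cum_success ~ attempt_index × group`, interaction test plus pairwise
slope contrasts) uses cluster-robust covariance with the animal as the
cluster.  Measured under the null: chance-contrast CI coverage 0.948 and
type-I 0.052 (10 animals × 80 attempts), group-contrast type-I 0.05
(8 + 8 animals × 100 attempts).  Per-animal fits keep the plain OLS SE and
are retained for plotting only.  Contrast p-values are invariant to
translating the attempt index.  No multiplicity adjustment is applied
across the 11 tasks by default (per-task p-values are reported); Holm is
available via a flag.

## Statistics

Gates: Shapiro–Wilk per group at α = 0.05, parametric only if every group
passes; any group with n < 3 makes normality untestable and falls to the
non-parametric branch with a warning.  Levene's test uses mean centering.
The decision table (deterministic and exhaustive over
n_groups ∈ {2,3,4} × normal × variance-equal) is in the `stats` module
docstring.  Effect sizes: Cohen's d (pooled SD), Hedges' g = d·(1 −
3/(4·df − 1)), Cliff's delta from its counting definition, ω² from the
one-way decomposition, ε² = H/((n²−1)/(n+1)) ≡ H/(n−1).

The asymptotic k-sample Fisher–Pitman statistic is W = (N−1)·SSB/SST,
referred to χ²(k−1) under the permutation null — the raw-value analog of
Kruskal–Wallis.  A seeded vectorized Monte-Carlo variant
((1 + #{W* ≥ W})/(R + 1)) cross-checks it; the χ² approximation is
accurate for moderate skew but turns conservative for extremely skewed
small samples (measured rejection ≈ 0.025 at α = 0.05 for lognormal σ = 1,
n = 24).  Dunn's post hoc is implemented from the tie-corrected rank-sum z
formula with two-sided normal p and no adjustment by default (Holm via
flag); Games–Howell and Welch ANOVA come from pingouin, Tukey HSD from
scipy.  Post hocs for the permutation branch are pairwise mean contrasts
from the pooled linear model with Hedges' g (no omnibus effect size is
reported for that branch).  Longitudinal change uses repeated-measures
ANOVA when normal and Friedman's rank test otherwise, with listwise
exclusion of animals missing days.

## The simulator

The generator emulates exactly the structure the analysis consumes:

- visits from a piecewise-constant Poisson process (per-phase rates;
  defaults 12/h dark, 2.1/h light put ≈ 85% of visits in the dark phase,
  the circadian asymmetry of healthy mice in this apparatus);
- exploratory visits with probability `p_explore` (default 0.2);
- corner policies: uniform, static preference, or a learner whose
  per-attempt success probability follows
  p(t) = p_max − (p_max − 0.25)·e^(−k·t), with t the attempt index within
  the task day (each task is learned anew), p_max default 0.8 and k
  default 0.1 per attempt;
- pokes per attempt geometric (mean 1/0.6 ≈ 1.7, producing repetitive
  bouts), a lick terminating the bout on rewarded attempts (contacts
  1 + Poisson(24)); visit durations log-normal with 20 s median, clipped
  against the next visit;
- the patrolling state machine runs during generation so learner agents
  can target the moving corner.

The chance cohort (uniform corners, equal phase rates so attempt times are
uniform, no exploration) is the simulated analog of the analytic
reference: PE → 3/4, episodic TE → 22/24, learning slope → 1/4.

What the simulator does *not* model: social interaction and corner
occupancy conflicts (one cage, the physical device serializes corner
access), lick microstructure, bottle-side preference, body-weight or
health dynamics, and any drift in motivation across days.  Passing tests
on synthetic data therefore demonstrate correctness of the bookkeeping and
calibration of the statistics under the stated behavioral model — not that
real mice satisfy that model.

## Numerical conventions and degenerate inputs

Half-open intervals everywhere; events assigned to periods by visit start
time; block and window boundaries belong to the later interval's start.
Zero-attempt cells are missing, not zero.  Constant data raise a
degenerate-input error in the decision tree; identical values give p = 1
in the permutation test and Friedman statistic 0.  All randomness flows
through `numpy.random.default_rng` seeded from a single integer (one
spawned child stream per simulated animal), making logs byte-identical
under a fixed seed.

## Problem sizes used in the tests

The suite simulates 8-animal cohorts over the full 14-day design for
pipeline and oracle checks, 1000-replicate null simulations for the
decision-tree calibration bands ([0.03, 0.07] at α = 0.05), a 100,000-draw
Monte-Carlo permutation oracle, ~4000-attempt chance mice for the slope
reference, and 3 learner agents at 360 active-window attempts for
parameter recovery (±0.05).  These sizes were chosen so the whole suite
runs on a laptop in a few minutes while keeping Monte-Carlo error well
inside the asserted tolerances.
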