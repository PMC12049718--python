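# cagecog

Automated cognitive phenotyping from home-cage operant event logs.

Automated home cages with four corner operant chambers record three event
streams per mouse (identified by RFID transponder): **visits** (presence in
a corner), **nose pokes** (operant responses at a door) and **licks**
(water consumption).  `cagecog` turns those raw streams into per-animal
cognitive readouts for a 14-day, three-challenge protocol — spatial
learning with reversal, episodic-like memory (what–where–when), and a
patrolling working-memory task — and runs the group statistics on top.
It is written for behavioral neuroscientists who run such experiments and
want a scriptable, tested analysis instead of spreadsheet extraction.

A seeded simulator generates full synthetic experiments in the same raw
format, so every stage of the pipeline can be exercised (and is tested)
without animal data.

## The measurements

Every visit is either an **exploratory visit** (no nose poke) or a
**drinking attempt** (≥ 1 nose poke).  Uninterrupted runs of ≥ 2 pokes are
repetitive bouts: a visit with 10 uninterrupted pokes contributes a
repetitive-behavior *frequency* of 1 and a *total* of 9 (= bout length − 1);
a lick ends a bout, so one visit can contain several.

Four error rates are computed per animal × task day × evaluation period
(dark phase, light phase, total 24 h, and the task's *active* window), each
a fraction of that cell's drinking attempts:

- **PE** (place error): attempts at a currently incorrect corner;
- **CE** (challenge error): attempts at the corner rewarded in the
  immediately preceding task — perseveration (reversal, multiple-reversal
  and episodic-memory reversal days);
- **TE** (time error): attempts outside the 2-h reward window
  (episodic-like-memory days);
- **DE** (direction error): attempts one *clockwise* step from the last
  rewarded corner during counterclockwise patrolling — continuation of the
  extinguished clockwise rule.

With PE_adj = PE − CE − DE, the **cognition index** summarizes a task day:

    CI = 1 − (w_PE · PE_adj + w_CE · CE + w_TE · TE + w_DE · DE)

with task-specific weights (rows sum to 1; e.g. reversal learning
75%/25% PE/CE, episodic-memory reversal 50%/25%/25% PE/CE/TE).  Higher CI
is better; an error-free day scores 1.

**Learning curves.** Per mouse and task, the ordered drinking attempts in
the active window are classified correct/incorrect by corner; the
cumulative success count against attempt index is fit by linear
regression, so the slope estimates the per-attempt success probability.
The by-chance reference is the analytic line with slope 0.25 (one rewarded
corner of four).  Group slopes pool animals as replicates; uncertainties
are computed with the animal as the experimental unit (leave-one-animal-out
jackknife; cluster-robust covariance for the ANCOVA group contrasts).

**Statistics.** Each measure is compared across 2–4 groups through a
decision tree gated by Shapiro–Wilk (normality in every group) and
Levene's test: t / Welch-t with Cohen's d, Wilcoxon rank-sum with Cliff's
delta, one-way / Welch ANOVA with ω² and Tukey HSD / Games–Howell post
hocs, Kruskal–Wallis with ε² = H/(n−1) and Dunn post hocs, or the
asymptotic k-sample Fisher–Pitman permutation test.  Within-subject change
across days uses repeated-measures ANOVA or Friedman's test.

## Worked example

```sh
python examples/03_learning_curves.py
```

```
chance   place-learning slope 0.282 (SE 0.054), vs chance 0.25: p = 0.66
learner  place-learning slope 0.876 (SE 0.006), vs chance 0.25: p = 1.2e-09
```

Six simulated mice choosing corners uniformly fit a place-learning slope
statistically indistinguishable from the 0.25 chance line, while six
learners approaching 90% accuracy fit a slope near 0.9 and clear the
chance contrast decisively.  The other scripts in `examples/` walk through
simulation, visit classification and error metrics, the statistical
decision tree, and the file-based end-to-end pipeline.

The command-line interface wraps the same library:

```sh
cagecog simulate --n-animals 16 --seed 1 --out logs/
cagecog analyze --visits logs/Visits.tsv --pokes logs/Nosepokes.tsv \
    --licks logs/Licks.tsv --cohort logs/cohort.tsv --out results/
```

`analyze` writes `per_animal_metrics.csv`, `group_summary.csv`,
`stats_summary.csv`, post-hoc and learning-curve tables, quick-inspection
bar graphs and curve panels, and a run log.

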