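"""Learning curves: chance reference versus an above-chance learner group.

Builds cumulative-success curves from a chance cohort and a learner
cohort, fits the pooled group regressions, and tests each group slope
against the analytic by-chance constant 0.25 (one rewarded corner of
four).  Expect the chance group to sit on the dashed line (p large) and
the learners to clear it decisively (p very small).
"""

from cagecog import (
    AgentConfig,
    aggregate,
    chance_cohort,
    compare_to_chance,
    curves_from_attempts,
    default_plan,
    fit_curves,
    simulate_cohort,
)

plan = default_plan()

for label, maker in [
    ("chance", lambda: chance_cohort(6, plan, seed=3)),
    ("learner", lambda: simulate_cohort(
        [AgentConfig(animal_tag=f"L{i}", group="G1", policy="learner",
                     p_max=0.9) for i in range(6)],
        plan, seed=4)),
]:
    visits, cohort, _ = maker()
    tables = aggregate(visits, plan, cohort)
    curves = curves_from_attempts(tables["attempts"])
    fits = fit_curves(curves)
    fit = next(f for f in fits["group"] if f.task_id == "place_learning")
    comp = compare_to_chance(fit)
    print(f"{label:8s} place-learning slope {fit.slope:.3f} "
          f"(SE {fit.slope_se:.3f}), vs chance 0.25: p = {comp.p:.2g}")
# slope estimates the per-attempt success probability; 0.25 is what a
# mouse choosing corners at random achieves
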