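"""Classify visits and compute the error metrics and cognition index.

Runs the metric aggregation on a small learner cohort and prints, per task
day, the group-mean place error and cognition index in the active window.
A learner that approaches 80% correct shows PE well below the 0.75 chance
level and CI rising toward 1 across the challenge days.
"""

from cagecog import AgentConfig, aggregate, classify_visit, default_plan, simulate_cohort

plan = default_plan()
agents = [
    AgentConfig(animal_tag=f"m{i + 1:02d}", group=["G1", "G2", "G3", "G4"][i % 4],
                policy="learner", p_max=0.8)
    for i in range(8)
]
visits, cohort, _ = simulate_cohort(agents, plan, seed=2)

# single-visit classification: ten uninterrupted pokes -> one repetitive
# bout, frequency 1 and total 9
example = next(v for v in visits if v.n_pokes >= 2)
print("example visit:", classify_visit(example))

tables = aggregate(visits, plan, cohort)
pa = tables["per_animal"]
active = pa[pa["period"] == "active"]
summary = active.groupby("task_id", sort=False)[["pe", "ci"]].mean().dropna()
print("\nmean place error / cognition index (active window):")
print(summary.round(3))
# pe < 0.75 means better-than-chance corner choice; ci is the weighted
# inverse of all error types (1 = error-free)
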