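import numpy as np
import pandas as pd
import pytest

from cagecog import AgentConfig, aggregate, chance_cohort, default_plan, simulate_cohort


@pytest.fixture(scope="session")
def plan():
    return default_plan()


@pytest.fixture(scope="session")
def learner_sim(plan):
    """Eight learner mice, two per group, a realistic small cohort."""
    groups = list(plan.group_corners)
    agents = [
        AgentConfig(
            animal_tag=f"m{i + 1:02d}",
            group=groups[i % 4],
            policy="learner",
            p_max=0.9,
            rate_dark=8.0,
            rate_light=2.0,
        )
        for i in range(8)
    ]
    visits, cohort, truth = simulate_cohort(agents, plan, seed=11)
    return {"visits": visits, "cohort": cohort, "truth": truth, "agents": agents}


@pytest.fixture(scope="session")
def learner_tables(learner_sim, plan):
    return aggregate(learner_sim["visits"], plan, learner_sim["cohort"])


@pytest.fixture(scope="session")
def chance_sim(plan):
    """Eight uniform-choice mice at uniform visit times (chance reference)."""
    visits, cohort, truth = chance_cohort(8, plan, seed=13, rate=6.0)
    return {"visits": visits, "cohort": cohort, "truth": truth}


@pytest.fixture(scope="session")
def chance_tables(chance_sim, plan):
    return aggregate(chance_sim["visits"], plan, chance_sim["cohort"])


def make_visit(
    visit_id=1,
    tag="m01",
    corner=1,
    start="2024-01-01 12:00:00",
    n_pokes=0,
    poke_lick_pattern=None,
    duration_s=60,
):
    """Hand-build a visit; ``poke_lick_pattern`` is a string like 'pplppp'."""
    from cagecog import LickEvent, PokeEvent, VisitEvent

    t0 = pd.Timestamp(start)
    pokes, licks = [], []
    pattern = poke_lick_pattern or "p" * n_pokes
    for i, ch in enumerate(pattern):
        t = t0 + pd.Timedelta(seconds=i + 1)
        if ch == "p":
            pokes.append(PokeEvent(time=t))
        else:
            licks.append(LickEvent(time=t, contact_count=5))
    return VisitEvent(
        visit_id=visit_id,
        animal_tag=tag,
        corner=corner,
        start_time=t0,
        end_time=t0 + pd.Timedelta(seconds=max(duration_s, len(pattern) + 1)),
        pokes=pokes,
        licks=licks,
    )
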