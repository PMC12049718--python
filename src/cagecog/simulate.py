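"""Seeded synthetic home-cage data generator.

Emulates the behavioral structure the analysis assumes so that every
pipeline stage is exercisable without real recordings: per-animal visit
streams from a piecewise-constant (light/dark) Poisson process, per-visit
nose-poke/lick microstructure, corner-choice policies (uniform, static
preference, or a learner whose per-attempt success probability rises from
4-corner chance toward an asymptote), exploratory visits, and geometric
repetitive bouts.  The default circadian rates put ~85% of visits in the
dark phase, the asymmetry reported for healthy mice in this apparatus.

Generated logs always satisfy the canonical-model invariants, round-trip
through the raw-file dialect, and are byte-identical under a fixed seed.
Ground truth (configured parameters plus realized success rates) is
recorded alongside.  One cage per simulation; corner-occupancy conflicts
are not modeled (the physical device serializes them).
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .events import CORNERS, CohortTable, LickEvent, PokeEvent, VisitEvent
from .io import write_cohort, write_visit_log
from .schedule import ChallengePlan, PatrolState, patrol_handover_cw_to_ccw, patrol_step

SEC = pd.Timedelta(seconds=1)


@dataclass
class AgentConfig:
    """Behavioral parameters of one simulated mouse."""

    animal_tag: str
    group: str
    rate_dark: float = 12.0   # visits/hour, dark phase
    rate_light: float = 2.1   # visits/hour, light phase (~85% dark visits)
    p_explore: float = 0.2    # probability a visit has zero pokes
    policy: str = "learner"   # uniform | preference | learner
    preferred_corner: int = 1
    p_pref: float = 0.7       # preference policy: P(preferred corner)
    p_max: float = 0.8        # learner asymptotic success probability
    k: float = 0.1            # learner rate per attempt (resets each task day)
    bout_geom_p: float = 0.6  # pokes/attempt ~ Geometric(p), mean 1/p
    licks_mean: float = 25.0  # lickometer contacts per rewarded attempt

    def __post_init__(self) -> None:
        if self.rate_dark < 0 or self.rate_light < 0:
            raise ValueError("visit rates must be non-negative")
        for name in ("p_explore", "p_pref", "p_max", "bout_geom_p"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class SimTruth:
    """Ground truth recorded during generation."""

    agents: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.agents, indent=1, sort_keys=True))
        return path


def learner_success_probability(t: int, p_max: float, k: float) -> float:
    """p(t) = p_max − (p_max − 0.25)·exp(−k·t); t is the 0-based attempt
    index within the task day and 0.25 the 4-corner chance level."""
    return p_max - (p_max - 0.25) * np.exp(-k * t)


def _choose_corner(rng, agent, target: frozenset[int], attempt_idx: int) -> int:
    others = [c for c in CORNERS]
    if agent.policy == "uniform" or len(target) != 1:
        return int(rng.choice(others))
    if agent.policy == "preference":
        if rng.random() < agent.p_pref:
            return agent.preferred_corner
        rest = [c for c in CORNERS if c != agent.preferred_corner]
        return int(rng.choice(rest))
    if agent.policy == "learner":
        (correct,) = target
        p = learner_success_probability(attempt_idx, agent.p_max, agent.k)
        if rng.random() < p:
            return correct
        rest = [c for c in CORNERS if c != correct]
        return int(rng.choice(rest))
    raise ValueError(f"unknown corner policy {agent.policy!r}")


def _simulate_agent(agent: AgentConfig, plan: ChallengePlan, rng) -> tuple[list, dict]:
    visits = []
    truth = {
        "config": {k: v for k, v in asdict(agent).items()},
        "task_success": {},
        "n_visits_dark": 0,
        "n_visits_light": 0,
    }
    cw_state = PatrolState(animal_tag=agent.animal_tag, direction="cw")
    ccw_state: PatrolState | None = None
    succ: dict[str, list[int]] = {}

    for day in plan.days:
        # piecewise-constant Poisson visit process over the two phases
        times = []
        for phase_start, hours, rate in (
            (day.start, 12, agent.rate_light),
            (day.start + pd.Timedelta(hours=12), 12, agent.rate_dark),
        ):
            n = rng.poisson(rate * hours)
            offs = np.sort(rng.uniform(0, hours * 3600, size=n))
            times.extend(phase_start + pd.to_timedelta(np.round(offs, 3), unit="s"))
        times.sort()

        attempt_idx = 0  # learner attempt counter, reset each task day
        for i, t in enumerate(times):
            gap = (times[i + 1] - t).total_seconds() if i + 1 < len(times) else np.inf
            in_dark = (t - day.start) >= pd.Timedelta(hours=12)
            truth["n_visits_dark" if in_dark else "n_visits_light"] += 1

            state = None
            if day.reward_rule == "patrol_cw":
                state = cw_state
            elif day.reward_rule == "patrol_ccw":
                if ccw_state is None:
                    ccw_state = patrol_handover_cw_to_ccw(
                        cw_state, mode=plan.patrol_handover
                    )
                state = ccw_state

            explore = rng.random() < agent.p_explore
            duration = float(np.clip(20.0 * np.exp(rng.normal(0, 0.5)), 2.0, 600.0))
            if explore:
                duration = min(duration, max(gap - 1.0, 1.0))
                visits.append(
                    VisitEvent(
                        visit_id=-1,
                        animal_tag=agent.animal_tag,
                        corner=int(rng.integers(1, 5)),
                        start_time=t,
                        end_time=t + duration * SEC,
                    )
                )
                continue

            in_active = day.in_active_window(t)
            # the learner aims at the time-restricted rule; with no reward
            # available (or several corners correct) it roams uniformly
            rewarded_now = plan.correct_corners(agent.group, t, state)
            corner = _choose_corner(rng, agent, rewarded_now, attempt_idx)
            if agent.policy == "learner" and in_active and len(rewarded_now) == 1:
                attempt_idx += 1

            n_pokes = int(rng.geometric(agent.bout_geom_p))
            max_pokes = max(1, int(min(gap - 2.0, duration)) - 1)
            n_pokes = min(n_pokes, max_pokes)
            rewarded = corner in rewarded_now
            pokes = [
                PokeEvent(time=t + (j + 1) * SEC, door_opened=rewarded and j == 0)
                for j in range(n_pokes)
            ]
            licks = []
            end = t + max(duration, n_pokes + 1.0) * SEC
            if rewarded:
                contacts = 1 + int(rng.poisson(max(agent.licks_mean - 1, 0)))
                licks = [LickEvent(time=pokes[-1].time, contact_count=contacts)]
            if i + 1 < len(times) and end >= times[i + 1]:
                end = times[i + 1] - SEC
                end = max(end, pokes[-1].time)
            visits.append(
                VisitEvent(
                    visit_id=-1,
                    animal_tag=agent.animal_tag,
                    corner=corner,
                    start_time=t,
                    end_time=end,
                    pokes=pokes,
                    licks=licks,
                )
            )
            if day.is_scored and in_active:
                target = plan.spatial_target(agent.group, t, state)
                succ.setdefault(day.task_id, []).append(int(corner in target))
            if state is not None and in_active:
                new = patrol_step(state, corner)
                if day.reward_rule == "patrol_cw":
                    cw_state = new
                else:
                    ccw_state = new

    truth["task_success"] = {
        task: {"n_attempts": len(v), "success_rate": float(np.mean(v))}
        for task, v in succ.items()
    }
    total = truth["n_visits_dark"] + truth["n_visits_light"]
    truth["dark_visit_fraction"] = (
        truth["n_visits_dark"] / total if total else float("nan")
    )
    return visits, truth


def simulate_cohort(
    agents: list[AgentConfig],
    plan: ChallengePlan,
    seed: int,
    out_dir=None,
) -> tuple[list[VisitEvent], CohortTable, SimTruth]:
    """Generate a full synthetic experiment for a list of agents.

    Deterministic under ``seed`` (one independent child stream per agent).
    With ``out_dir`` set, also writes ``Visits.tsv``/``Nosepokes.tsv``/
    ``Licks.tsv``, ``cohort.tsv`` and ``truth.json``.
    """
    if not agents:
        raise ValueError("agent list is empty")
    tags = [a.animal_tag for a in agents]
    if len(set(tags)) != len(tags):
        raise ValueError("duplicate animal tags in agent list")
    streams = np.random.SeedSequence(seed).spawn(len(agents))
    all_visits: list[VisitEvent] = []
    truth = SimTruth()
    for agent, ss in zip(agents, streams):
        rng = np.random.default_rng(ss)
        visits, agent_truth = _simulate_agent(agent, plan, rng)
        all_visits.extend(visits)
        truth.agents[agent.animal_tag] = agent_truth

    all_visits.sort(key=lambda v: (v.start_time, v.animal_tag))
    for i, v in enumerate(all_visits, start=1):
        v.visit_id = i
        v.validate()

    cohort = CohortTable(
        groups={a.animal_tag: a.group for a in agents},
        cages={a.animal_tag: "cage1" for a in agents},
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_visit_log(all_visits, out_dir)
        write_cohort(cohort, out_dir / "cohort.tsv")
        truth.to_json(out_dir / "truth.json")
    return all_visits, cohort, truth


def chance_cohort(
    n_animals: int,
    plan: ChallengePlan,
    seed: int,
    rate: float = 6.0,
    out_dir=None,
) -> tuple[list[VisitEvent], CohortTable, SimTruth]:
    """A cohort choosing corners uniformly at uniformly distributed times.

    The simulated analog of the analytic by-chance reference: expected
    place error 3/4, expected episodic-memory time error 22/24, learning
    slope 1/4.  Used for all chance-calibration checks.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")
    group_names = list(plan.group_corners) or ["G1"]
    agents = [
        AgentConfig(
            animal_tag=f"chance{i + 1:02d}",
            group=group_names[i % len(group_names)],
            rate_dark=rate,
            rate_light=rate,
            p_explore=0.0,
            policy="uniform",
        )
        for i in range(n_animals)
    ]
    return simulate_cohort(agents, plan, seed, out_dir=out_dir)
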