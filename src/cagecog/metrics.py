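"""Behavioral and cognitive metrics per animal × task day × evaluation period.

Nine derived measurements accompany the three raw readouts (visits, nose
pokes, licks):

* **exploratory visits** — visits with zero nose pokes;
* **drinking attempts** — visits with at least one nose poke;
* **repetitive behavior frequency / total** — uninterrupted bouts of ≥ 2
  nose pokes (a lick breaks a bout): frequency counts visits containing at
  least one bout, total counts the surplus pokes, Σ(bout length − 1).  Ten
  uninterrupted pokes in one visit give frequency 1 and total 9.
* **place error (PE)** — fraction of drinking attempts at a currently
  incorrect corner;
* **challenge error (CE)** — fraction at the corner rewarded in the
  immediately preceding task phase (perseveration);
* **time error (TE)** — fraction outside the rewarded time window
  (episodic-like-memory days);
* **direction error (DE)** — during counterclockwise patrolling, fraction
  at the corner one *clockwise* step from the most recently rewarded
  corner (continuation of the extinguished clockwise rule);
* **cognition index (CI)** — 1 minus the task-weighted sum of adjusted
  place error (PE_adj = PE − CE − DE), CE, TE and DE; higher is better.

Every measurement is evaluated in four periods per day: the dark phase
(18:00–06:00), the light phase (06:00–18:00), the total 24 h, and the
challenge-dependent "active" window.  Events are assigned to periods by
visit start time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import CohortTable, VisitEvent
from .schedule import (
    ChallengePlan,
    PatrolState,
    SCORED_TASKS,
    cw_step,
    patrol_handover_cw_to_ccw,
    patrol_step,
)

#: task-specific error weights (w_pe, w_ce, w_te, w_de); rows sum to 1
WEIGHTS: dict[str, tuple[float, float, float, float]] = {
    "place_learning": (1.00, 0.00, 0.00, 0.00),
    "reversal_learning": (0.75, 0.25, 0.00, 0.00),
    "multiple_reversal": (0.75, 0.25, 0.00, 0.00),
    "elm_acq": (0.75, 0.00, 0.25, 0.00),
    "elm_ret": (0.75, 0.00, 0.25, 0.00),
    "elm_rev_acq": (0.50, 0.25, 0.25, 0.00),
    "elm_rev_ret": (0.50, 0.25, 0.25, 0.00),
    "patrol_cw_d1": (1.00, 0.00, 0.00, 0.00),
    "patrol_cw_d2": (1.00, 0.00, 0.00, 0.00),
    "patrol_ccw_d1": (0.75, 0.00, 0.00, 0.25),
    "patrol_ccw_d2": (0.75, 0.00, 0.00, 0.25),
}

CE_TASKS = ("reversal_learning", "multiple_reversal", "elm_rev_acq", "elm_rev_ret")
TE_TASKS = ("elm_acq", "elm_ret", "elm_rev_acq", "elm_rev_ret")
DE_TASKS = ("patrol_ccw_d1", "patrol_ccw_d2")

PERIODS = ("dark", "light", "total24h", "active")

LICK_EXCLUSION_THRESHOLD = 100  # licks/day
LICK_EXCLUSION_RUN = 2  # consecutive days


@dataclass(frozen=True)
class VisitClass:
    visit_id: int
    kind: str  # "exploratory" | "drinking_attempt"
    repetitive_bouts: tuple[int, ...]

    @property
    def repetitive_frequency(self) -> int:
        return 1 if self.repetitive_bouts else 0

    @property
    def repetitive_total(self) -> int:
        return sum(b - 1 for b in self.repetitive_bouts)


def classify_visit(visit: VisitEvent) -> VisitClass:
    """Classify one visit and extract its repetitive-behavior bouts.

    A visit with no nose poke is exploratory.  Within a drinking attempt,
    pokes and licks are merged in time order and maximal runs of ≥ 2 pokes
    uninterrupted by a lick form the repetitive bouts, so a mouse that
    resumes poking after drinking can trigger more than one bout per visit.
    """
    if not visit.pokes:
        return VisitClass(visit.visit_id, "exploratory", ())
    merged = sorted(
        [(p.time, "poke") for p in visit.pokes]
        + [(l.time, "lick") for l in visit.licks],
        key=lambda x: x[0],
    )
    bouts: list[int] = []
    run = 0
    for _, kind in merged:
        if kind == "poke":
            run += 1
        else:
            if run >= 2:
                bouts.append(run)
            run = 0
    if run >= 2:
        bouts.append(run)
    return VisitClass(visit.visit_id, "drinking_attempt", tuple(bouts))


def cognition_index(
    pe_adj: float, ce: float, te: float, de: float, task_id: str
) -> float:
    """CI = 1 − (w_pe·PE_adj + w_ce·CE + w_te·TE + w_de·DE), in [0, 1]."""
    try:
        w_pe, w_ce, w_te, w_de = WEIGHTS[task_id]
    except KeyError:
        raise ValueError(f"no cognition-index weights for task {task_id!r}") from None

    def term(w, e):
        if w == 0.0:
            return 0.0
        if e is None or (isinstance(e, float) and np.isnan(e)):
            return np.nan
        return w * e

    return 1.0 - (term(w_pe, pe_adj) + term(w_ce, ce) + term(w_te, te) + term(w_de, de))


# -- attempt annotation ----------------------------------------------------

def annotate_attempts(
    visits: list[VisitEvent], plan: ChallengePlan, cohort: CohortTable
) -> pd.DataFrame:
    """One row per drinking attempt with its error classification.

    Runs the patrolling state machine per animal (state persists across the
    two days of each direction; the counterclockwise state is seeded from
    the clockwise handover rule).  Columns: ``animal_tag, group, time,
    corner, day_index, task_id, in_active, success, is_pe, is_ce, is_te,
    is_de, target`` — the boolean error columns are NaN where the error
    type is undefined for the task.
    """
    by_animal: dict[str, list[VisitEvent]] = {}
    for v in visits:
        by_animal.setdefault(v.animal_tag, []).append(v)

    rows = []
    for tag, avisits in by_animal.items():
        if tag not in cohort.groups:
            continue  # reported by io.check_tags
        group = cohort.group_of(tag)
        avisits = sorted(avisits, key=lambda v: v.start_time)
        cw_state = PatrolState(animal_tag=tag, direction="cw")
        ccw_state: PatrolState | None = None
        for v in avisits:
            if not v.pokes:
                continue
            t = v.start_time
            try:
                day = plan.day_at(t)
            except Exception:
                continue  # outside the plan (e.g., deprivation gaps)
            task = day.task_id
            state = None
            if day.reward_rule == "patrol_cw":
                state = cw_state
            elif day.reward_rule == "patrol_ccw":
                if ccw_state is None:
                    ccw_state = patrol_handover_cw_to_ccw(
                        cw_state, mode=plan.patrol_handover
                    )
                state = ccw_state

            target = plan.spatial_target(group, t, state)
            success = v.corner in target
            is_pe: float = float(not success)

            is_ce: float = np.nan
            if task in CE_TASKS:
                ce_corner = plan.challenge_error_corner(task, group, t)
                is_ce = float(v.corner == ce_corner)

            is_te: float = np.nan
            if task in TE_TASKS:
                is_te = float(not day.in_active_window(t))

            is_de: float = np.nan
            if task in DE_TASKS:
                last = state.last_correct_corner if state is not None else None
                is_de = float(last is not None and v.corner == cw_step(last))

            rows.append(
                {
                    "animal_tag": tag,
                    "group": group,
                    "time": t,
                    "corner": v.corner,
                    "day_index": day.day_index,
                    "task_id": task,
                    "in_active": day.in_active_window(t),
                    "success": success,
                    "is_pe": is_pe,
                    "is_ce": is_ce,
                    "is_te": is_te,
                    "is_de": is_de,
                    "target": ",".join(map(str, sorted(target))),
                }
            )

            # state advances only on active-window attempts
            if state is not None and day.in_active_window(t):
                new = patrol_step(state, v.corner)
                if day.reward_rule == "patrol_cw":
                    cw_state = new
                else:
                    ccw_state = new
    cols = [
        "animal_tag", "group", "time", "corner", "day_index", "task_id",
        "in_active", "success", "is_pe", "is_ce", "is_te", "is_de", "target",
    ]
    return pd.DataFrame(rows, columns=cols)


def error_rates(
    attempts: pd.DataFrame, plan: ChallengePlan, periods=PERIODS
) -> pd.DataFrame:
    """Error rates per animal × scored task day × evaluation period.

    ``attempts`` is the output of :func:`annotate_attempts`.  A cell with
    zero drinking attempts yields NaN rates (a mouse that never attempted
    carries no information, not a perfect score).  ``pe_adj = pe − ce − de``
    with undefined CE/DE contributing 0.
    """
    out = []
    day_by_index = {d.day_index: d for d in plan.days}
    for (tag, group, day_index), sub in attempts.groupby(
        ["animal_tag", "group", "day_index"], sort=True
    ):
        day = day_by_index[day_index]
        if not day.is_scored:
            continue
        windows = day.periods()
        for period in periods:
            w0, w1 = windows[period]
            cell = sub[(sub["time"] >= w0) & (sub["time"] < w1)]
            n = len(cell)
            row = {
                "animal_tag": tag,
                "group": group,
                "day_index": day_index,
                "task_id": day.task_id,
                "period": period,
                "n_attempts": n,
            }
            if n == 0:
                row.update(pe=np.nan, ce=np.nan, te=np.nan, de=np.nan,
                           pe_adj=np.nan, ci=np.nan)
            else:
                pe = cell["is_pe"].mean()
                ce = cell["is_ce"].mean() if day.task_id in CE_TASKS else np.nan
                te = cell["is_te"].mean() if day.task_id in TE_TASKS else np.nan
                de = cell["is_de"].mean() if day.task_id in DE_TASKS else np.nan
                pe_adj = pe - np.nan_to_num(ce) - np.nan_to_num(de)
                ci = cognition_index(pe_adj, ce, te, de, day.task_id)
                row.update(pe=pe, ce=ce, te=te, de=de, pe_adj=pe_adj, ci=ci)
            out.append(row)
    return pd.DataFrame(
        out,
        columns=["animal_tag", "group", "day_index", "task_id", "period",
                 "n_attempts", "pe", "ce", "te", "de", "pe_adj", "ci"],
    )


# -- behavior summaries ----------------------------------------------------

def behavior_summary(
    visits: list[VisitEvent], plan: ChallengePlan, cohort: CohortTable
) -> pd.DataFrame:
    """Raw-readout counts per animal × day × period.

    Counts visits, exploratory visits, drinking attempts, nose pokes,
    licks and the repetitive-behavior frequency/total.  Exploratory +
    drinking attempts = visits in every cell.
    """
    rows = []
    by_animal: dict[str, list[VisitEvent]] = {}
    for v in visits:
        by_animal.setdefault(v.animal_tag, []).append(v)
    for tag in cohort.tags:
        group = cohort.group_of(tag)
        avisits = by_animal.get(tag, [])
        if not avisits:
            warnings.warn(f"animal {tag!r} has no events; emitting missing rows",
                          stacklevel=2)
        for day in plan.days:
            windows = day.periods()
            dvisits = [v for v in avisits if day.contains(v.start_time)]
            for period in PERIODS:
                w0, w1 = windows[period]
                cell = [v for v in dvisits if w0 <= v.start_time < w1]
                classes = [classify_visit(v) for v in cell]
                n_expl = sum(c.kind == "exploratory" for c in classes)
                rows.append(
                    {
                        "animal_tag": tag,
                        "group": group,
                        "day_index": day.day_index,
                        "task_id": day.task_id,
                        "period": period,
                        "visits": len(cell),
                        "exploratory_visits": n_expl,
                        "drinking_attempts": len(cell) - n_expl,
                        "nosepokes": sum(v.n_pokes for v in cell),
                        "licks": sum(v.n_licks for v in cell),
                        "repetitive_frequency": sum(
                            c.repetitive_frequency for c in classes
                        ),
                        "repetitive_total": sum(c.repetitive_total for c in classes),
                    }
                )
    return pd.DataFrame(rows)


def welfare_flags(daily_licks: pd.DataFrame) -> pd.DataFrame:
    """Exclusion flags: < 100 licks/day on ≥ 2 consecutive days.

    ``daily_licks`` needs columns ``animal_tag, day_index, licks``.  The
    flag is raised on the first day completing such a run.
    """
    out = []
    for tag, sub in daily_licks.groupby("animal_tag"):
        sub = sub.sort_values("day_index")
        run = 0
        flag_day = None
        for day_idx, licks in zip(sub["day_index"], sub["licks"]):
            run = run + 1 if licks < LICK_EXCLUSION_THRESHOLD else 0
            if run >= LICK_EXCLUSION_RUN and flag_day is None:
                flag_day = day_idx
        out.append(
            {"animal_tag": tag, "excluded": flag_day is not None,
             "flag_day": flag_day}
        )
    return pd.DataFrame(out, columns=["animal_tag", "excluded", "flag_day"])


# -- top-level aggregation -------------------------------------------------

METRIC_COLUMNS = [
    "visits", "exploratory_visits", "drinking_attempts", "nosepokes", "licks",
    "repetitive_frequency", "repetitive_total",
    "pe", "ce", "te", "de", "pe_adj", "ci",
]


def aggregate(
    visits: list[VisitEvent], plan: ChallengePlan, cohort: CohortTable
) -> dict[str, pd.DataFrame]:
    """Full long-format metric tables for a loaded experiment.

    Returns ``per_animal`` (one row per animal × day × period with all
    counts, error rates and CI), ``group_summary`` (group × day × period ×
    measure with n, mean, sd), ``attempts`` (the annotated attempt stream)
    and ``welfare`` (exclusion flags from daily lick counts).
    """
    attempts = annotate_attempts(visits, plan, cohort)
    behavior = behavior_summary(visits, plan, cohort)
    rates = error_rates(attempts, plan)
    keys = ["animal_tag", "group", "day_index", "task_id", "period"]
    per_animal = behavior.merge(
        rates.drop(columns=["n_attempts"]), on=keys, how="left"
    )

    long = per_animal.melt(id_vars=keys, value_vars=METRIC_COLUMNS,
                           var_name="measure", value_name="value")
    grp = (
        long.groupby(["group", "day_index", "task_id", "period", "measure"])["value"]
        .agg(n="count", mean="mean", sd="std")
        .reset_index()
    )

    daily = behavior[behavior["period"] == "total24h"][
        ["animal_tag", "day_index", "licks"]
    ]
    return {
        "per_animal": per_animal,
        "group_summary": grp,
        "attempts": attempts,
        "welfare": welfare_flags(daily),
    }
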