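"""Declarative challenge schedule and corner-rule resolution.

The 14-day design holds three cognitive challenges (11 scored task days):

* **Challenge 1 — spatial learning** (d2–d4): place learning at one corner
  per group, reversal at the diagonally opposite corner, then multiple
  reversal where the rewarded corner alternates between the two every 3 h.
* **Challenge 2 — episodic-like memory** (d6–d9): water only in a 2-h
  window (22:00–24:00) at the place corner (acquisition + retrieval), then
  reversal to the diagonal corner with the window shifted to 20:00–22:00.
* **Challenge 3 — working memory / patrolling** (d11–d14): the rewarded
  corner advances one step clockwise after each correct drinking attempt
  for two days, then counterclockwise for two days.

Days 1 (habituation), 5 and 10 (extinction) grant free access to all
corners.  Days run on the local light cycle: light 06:00–18:00, dark
18:00–06:00; each task day spans [06:00, 06:00 + 24 h).

Corners are labeled 1–4 in clockwise physical order, so diagonal pairs are
(1,3) and (2,4) and "clockwise" / "diagonally opposite" are mutually
consistent.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd
import yaml

from .events import CORNERS

DAY = pd.Timedelta(hours=24)
H = pd.Timedelta(hours=1)

#: task days that feed error metrics and learning curves, in plan order
SCORED_TASKS = (
    "place_learning",
    "reversal_learning",
    "multiple_reversal",
    "elm_acq",
    "elm_ret",
    "elm_rev_acq",
    "elm_rev_ret",
    "patrol_cw_d1",
    "patrol_cw_d2",
    "patrol_ccw_d1",
    "patrol_ccw_d2",
)

FREE_TASKS = ("habituation", "extinction")


class ScheduleError(ValueError):
    """A time fell outside the plan, or a rule could not be resolved."""


def cw_step(corner: int) -> int:
    """Next corner clockwise (1→2→3→4→1)."""
    return corner % 4 + 1


def ccw_step(corner: int) -> int:
    """Next corner counterclockwise (1→4→3→2→1)."""
    return (corner - 2) % 4 + 1


def diagonal(corner: int) -> int:
    """Diagonally opposite corner: (1,3) and (2,4) are the diagonal pairs."""
    return (corner + 1) % 4 + 1


@dataclass(frozen=True)
class TaskDay:
    task_id: str
    day_index: int  # 1-based position in the plan
    start: pd.Timestamp
    end: pd.Timestamp
    active_start: pd.Timestamp
    active_end: pd.Timestamp
    reward_rule: str  # free | static | alternating_3h | patrol_cw | patrol_ccw

    def contains(self, time: pd.Timestamp) -> bool:
        return self.start <= time < self.end

    def in_active_window(self, time: pd.Timestamp) -> bool:
        return self.active_start <= time < self.active_end

    @property
    def is_scored(self) -> bool:
        return self.task_id in SCORED_TASKS

    def periods(self) -> dict[str, tuple[pd.Timestamp, pd.Timestamp]]:
        """The four evaluation windows of this day (half-open intervals)."""
        return {
            "light": (self.start, self.start + 12 * H),
            "dark": (self.start + 12 * H, self.end),
            "total24h": (self.start, self.end),
            "active": (self.active_start, self.active_end),
        }


@dataclass(frozen=True)
class PatrolState:
    """Per-animal working-memory task state.

    ``corner`` is the currently rewarded corner (None until the animal's
    first drinking attempt anchors it); ``last_correct_corner`` is the
    corner of the most recent correct (rewarded) drinking attempt and
    drives direction-error classification and the cw→ccw handover.
    """

    animal_tag: str
    direction: str  # "cw" | "ccw"
    corner: int | None = None
    last_correct_corner: int | None = None

    @property
    def unset(self) -> bool:
        return self.corner is None


@dataclass
class ChallengePlan:
    """Ordered task days plus per-group corner assignments."""

    days: list[TaskDay]
    group_corners: dict[str, int]  # group -> place-learning corner
    # cw→ccw handover reading: "step" = one ccw step beyond the last correct
    # cw corner (default); "same" = that corner itself.
    patrol_handover: str = "step"
    # first 3-h block of multiple reversal rewards the reversal corner
    # (continuity with the preceding day); "place" starts at the place corner
    mrl_start: str = "reversal"

    def __post_init__(self) -> None:
        for g, c in self.group_corners.items():
            if c not in CORNERS:
                raise ScheduleError(f"group {g}: place corner {c} not in 1..4")
        starts = [d.start for d in self.days]
        if starts != sorted(starts):
            raise ScheduleError("task days must be ordered by start time")
        for a, b in zip(self.days, self.days[1:]):
            if a.end > b.start:
                raise ScheduleError(f"overlapping task days: {a.task_id}/{b.task_id}")

    # -- lookups ----------------------------------------------------------
    def day_at(self, time: pd.Timestamp) -> TaskDay:
        for d in self.days:
            if d.contains(time):
                return d
        raise ScheduleError(f"time {time} falls outside the plan")

    def day_of(self, task_id: str) -> TaskDay:
        for d in self.days:
            if d.task_id == task_id:
                return d
        raise ScheduleError(f"no task day with id {task_id!r}")

    def place_corner(self, group: str) -> int:
        try:
            return self.group_corners[group]
        except KeyError:
            raise ScheduleError(f"group {group!r} has no corner assignment") from None

    def reversal_corner(self, group: str) -> int:
        return diagonal(self.place_corner(group))

    def static_corner(self, task_id: str, group: str) -> int:
        """The single rewarded corner of a static task day."""
        if task_id in ("place_learning", "elm_acq", "elm_ret"):
            return self.place_corner(group)
        if task_id in ("reversal_learning", "elm_rev_acq", "elm_rev_ret"):
            return self.reversal_corner(group)
        raise ScheduleError(f"{task_id!r} is not a static task")

    # -- previously-correct corner (challenge error) ----------------------
    def challenge_error_corner(
        self, task_id: str, group: str, time: pd.Timestamp | None = None
    ) -> int | None:
        """Corner rewarded in the immediately preceding phase, if unique.

        Defined for the four perseveration-scored tasks: reversal learning
        (the place corner), multiple reversal (the currently unrewarded
        member of the alternating pair) and the two ELM reversal days (the
        first-ELM corner).  None elsewhere.
        """
        if task_id == "reversal_learning":
            return self.place_corner(group)
        if task_id == "multiple_reversal":
            if time is None:
                raise ScheduleError("multiple_reversal CE corner requires a time")
            current = self.alternation_corner(group, time, clip=True)
            pair = {self.place_corner(group), self.reversal_corner(group)}
            return (pair - {current}).pop()
        if task_id in ("elm_rev_acq", "elm_rev_ret"):
            return self.place_corner(group)
        return None

    # -- rule resolution ---------------------------------------------------
    def alternation_corner(
        self, group: str, time: pd.Timestamp, clip: bool = False
    ) -> int:
        """Rewarded corner during the multiple-reversal 3-h alternation.

        Blocks are half-open 3-h intervals from dark onset; blocks 0 and 2
        reward the reversal corner and 1 and 3 the place corner (continuity
        with the preceding reversal day; swapped when ``mrl_start='place'``).
        With ``clip=True``, times outside the dark phase resolve to the
        block-0 corner instead of raising.
        """
        day = self.day_of("multiple_reversal")
        dark_onset = day.active_start
        if not day.in_active_window(time):
            if not clip:
                raise ScheduleError(
                    f"{time} outside the multiple-reversal dark phase"
                )
            block = 0
        else:
            block = int((time - dark_onset) // (3 * H))
        first = (
            self.reversal_corner(group)
            if self.mrl_start == "reversal"
            else self.place_corner(group)
        )
        second = diagonal(first)
        return first if block % 2 == 0 else second

    def correct_corners(
        self,
        group: str,
        time: pd.Timestamp,
        patrol_state: PatrolState | None = None,
    ) -> frozenset[int]:
        """Corner(s) where a nose poke opens the door at ``time``.

        Free days return all four corners; restricted days return the empty
        set outside the active window and a singleton inside it (all four
        on a patrolling day whose state is still unanchored).
        """
        day = self.day_at(time)
        if day.reward_rule == "free":
            return frozenset(CORNERS)
        if not day.in_active_window(time):
            return frozenset()
        if day.reward_rule == "static":
            return frozenset({self.static_corner(day.task_id, group)})
        if day.reward_rule == "alternating_3h":
            return frozenset({self.alternation_corner(group, time)})
        # patrolling: anchored state determines the corner; before anchoring
        # every corner is rewarded (the first attempt starts the protocol)
        if patrol_state is None or patrol_state.unset:
            return frozenset(CORNERS)
        return frozenset({patrol_state.corner})

    def spatial_target(
        self,
        group: str,
        time: pd.Timestamp,
        patrol_state: PatrolState | None = None,
    ) -> frozenset[int]:
        """The day's spatial rule with the time restriction removed.

        Used to classify place errors in evaluation periods outside the
        active window: a static day's corner applies all day; multiple
        reversal resolves to the current block in the dark phase and the
        block-0 corner otherwise; patrolling uses the current state corner.
        """
        day = self.day_at(time)
        if day.reward_rule == "free":
            return frozenset(CORNERS)
        if day.reward_rule == "static":
            return frozenset({self.static_corner(day.task_id, group)})
        if day.reward_rule == "alternating_3h":
            return frozenset({self.alternation_corner(group, time, clip=True)})
        if patrol_state is None or patrol_state.unset:
            return frozenset(CORNERS)
        return frozenset({patrol_state.corner})


# -- patrolling state machine ---------------------------------------------

def patrol_step(state: PatrolState, attempt_corner: int) -> PatrolState:
    """Advance the working-memory state for one drinking attempt.

    An unanchored state adopts the attempt's corner as the rewarded corner
    (the first drinking attempt starts the protocol).  A correct attempt —
    one at the rewarded corner — advances the reward one step in the task
    direction; any other attempt leaves the state unchanged.
    """
    if attempt_corner not in CORNERS:
        raise ScheduleError(f"corner {attempt_corner} not in 1..4")
    if state.unset:
        return replace(state, corner=attempt_corner)
    if attempt_corner != state.corner:
        return state
    step = cw_step if state.direction == "cw" else ccw_step
    return replace(
        state, corner=step(attempt_corner), last_correct_corner=attempt_corner
    )


def patrol_handover_cw_to_ccw(
    last_cw_state: PatrolState, mode: str = "step"
) -> PatrolState:
    """Seed the counterclockwise state from the final clockwise state.

    The first counterclockwise rewarded corner is one ccw step beyond the
    corner of the animal's last correct clockwise attempt (``mode='step'``,
    the default: the advance-after-each-correct-attempt rule continues
    through the direction switch) or that corner itself (``mode='same'``).
    An animal with no correct clockwise attempt starts unanchored.
    """
    anchor = last_cw_state.last_correct_corner
    if anchor is None:
        return PatrolState(animal_tag=last_cw_state.animal_tag, direction="ccw")
    corner = ccw_step(anchor) if mode == "step" else anchor
    return PatrolState(
        animal_tag=last_cw_state.animal_tag,
        direction="ccw",
        corner=corner,
        last_correct_corner=anchor,
    )


# -- the bundled default design -------------------------------------------

_DAY_SPECS = [
    # (task_id, reward_rule, active_start_hour, active_end_hour) — hours are
    # offsets from the 06:00 day start; the dark phase is hours 12–24.
    ("habituation", "free", 0, 24),
    ("place_learning", "static", 12, 24),
    ("reversal_learning", "static", 12, 24),
    ("multiple_reversal", "alternating_3h", 12, 24),
    ("extinction", "free", 0, 24),
    ("elm_acq", "static", 16, 18),       # 22:00–24:00
    ("elm_ret", "static", 16, 18),
    ("elm_rev_acq", "static", 14, 16),   # 20:00–22:00
    ("elm_rev_ret", "static", 14, 16),
    ("extinction", "free", 0, 24),
    ("patrol_cw_d1", "patrol_cw", 12, 24),
    ("patrol_cw_d2", "patrol_cw", 12, 24),
    ("patrol_ccw_d1", "patrol_ccw", 12, 24),
    ("patrol_ccw_d2", "patrol_ccw", 12, 24),
]


def default_plan(
    start: str | pd.Timestamp = "2024-01-01 06:00",
    group_corners: dict[str, int] | None = None,
    patrol_handover: str = "step",
) -> ChallengePlan:
    """The standard 14-day, three-challenge design."""
    start = pd.Timestamp(start)
    if group_corners is None:
        group_corners = {"G1": 1, "G2": 2, "G3": 3, "G4": 4}
    days = []
    for i, (task_id, rule, a0, a1) in enumerate(_DAY_SPECS):
        d0 = start + i * DAY
        days.append(
            TaskDay(
                task_id=task_id,
                day_index=i + 1,
                start=d0,
                end=d0 + DAY,
                active_start=d0 + a0 * H,
                active_end=d0 + a1 * H,
                reward_rule=rule,
            )
        )
    return ChallengePlan(
        days=days, group_corners=group_corners, patrol_handover=patrol_handover
    )


def plan_to_yaml(plan: ChallengePlan, path) -> Path:
    path = Path(path)
    doc = {
        "group_corners": dict(plan.group_corners),
        "patrol_handover": plan.patrol_handover,
        "mrl_start": plan.mrl_start,
        "days": [
            {
                "task_id": d.task_id,
                "day_index": d.day_index,
                "start": d.start.isoformat(),
                "end": d.end.isoformat(),
                "active_start": d.active_start.isoformat(),
                "active_end": d.active_end.isoformat(),
                "reward_rule": d.reward_rule,
            }
            for d in plan.days
        ],
    }
    path.write_text(yaml.safe_dump(doc, sort_keys=False))
    return path


def plan_from_yaml(path) -> ChallengePlan:
    doc = yaml.safe_load(Path(path).read_text())
    days = [
        TaskDay(
            task_id=d["task_id"],
            day_index=int(d["day_index"]),
            start=pd.Timestamp(d["start"]),
            end=pd.Timestamp(d["end"]),
            active_start=pd.Timestamp(d["active_start"]),
            active_end=pd.Timestamp(d["active_end"]),
            reward_rule=d["reward_rule"],
        )
        for d in doc["days"]
    ]
    return ChallengePlan(
        days=days,
        group_corners={str(k): int(v) for k, v in doc["group_corners"].items()},
        patrol_handover=doc.get("patrol_handover", "step"),
        mrl_start=doc.get("mrl_start", "reversal"),
    )
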