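"""Canonical in-memory model of home-cage operant events.

The automated cage records three nested event streams per corner chamber:
*visits* (an RFID antenna detects a mouse inside the corner tube),
*nose pokes* (the mouse breaks a light barrier at a door) and *licks*
(contacts with the lickometer of a drinking nipple).  A :class:`VisitEvent`
is the atomic observation; pokes and licks are nested inside the visit that
contains them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

CORNERS = (1, 2, 3, 4)


@dataclass(frozen=True)
class PokeEvent:
    """A single nose poke within a visit."""

    time: pd.Timestamp
    door_opened: bool = False


@dataclass(frozen=True)
class LickEvent:
    """A lickometer contact episode within a visit."""

    time: pd.Timestamp
    contact_count: int = 1

    def __post_init__(self) -> None:
        if self.contact_count < 1:
            raise ValueError(f"contact_count must be >= 1, got {self.contact_count}")


@dataclass
class VisitEvent:
    """One corner visit with its nested nose-poke and lick events.

    Invariants enforced by :meth:`validate`: ``start_time <= end_time``,
    every nested event lies within the visit window, the corner is one of
    1..4, and nested events are time-sorted.
    """

    visit_id: int
    animal_tag: str
    corner: int
    start_time: pd.Timestamp
    end_time: pd.Timestamp
    pokes: list[PokeEvent] = field(default_factory=list)
    licks: list[LickEvent] = field(default_factory=list)

    @property
    def n_pokes(self) -> int:
        return len(self.pokes)

    @property
    def n_licks(self) -> int:
        return sum(l.contact_count for l in self.licks)

    def validate(self) -> None:
        if self.corner not in CORNERS:
            raise ValueError(
                f"visit {self.visit_id}: corner must be in 1..4, got {self.corner}"
            )
        if self.start_time > self.end_time:
            raise ValueError(
                f"visit {self.visit_id}: start_time after end_time "
                f"({self.start_time} > {self.end_time})"
            )
        for kind, events in (("poke", self.pokes), ("lick", self.licks)):
            times = [e.time for e in events]
            if any(t < self.start_time or t > self.end_time for t in times):
                raise ValueError(
                    f"visit {self.visit_id}: {kind} event outside visit window"
                )
            if times != sorted(times):
                raise ValueError(f"visit {self.visit_id}: {kind} events not time-sorted")


@dataclass
class CohortTable:
    """Unblinding table mapping animal tag -> (group label, cage id)."""

    groups: dict[str, str]
    cages: dict[str, str] = field(default_factory=dict)

    @property
    def tags(self) -> list[str]:
        return list(self.groups)

    @property
    def group_names(self) -> list[str]:
        seen: list[str] = []
        for g in self.groups.values():
            if g not in seen:
                seen.append(g)
        return seen

    def group_of(self, tag: str) -> str:
        return self.groups[tag]

    def unknown_tags(self, tags) -> list[str]:
        """Tags present in an event stream but absent from the table."""
        return sorted(set(tags) - set(self.groups))


def sort_visits(visits: list[VisitEvent]) -> list[VisitEvent]:
    """Stable global time-sort; per-animal streams become non-decreasing."""
    return sorted(visits, key=lambda v: (v.start_time, v.animal_tag, v.visit_id))
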