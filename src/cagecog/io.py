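"""Readers and writers for the raw event-log dialect and the cohort table.

The dialect is three tab-separated files with ISO-8601 timestamps:

* ``Visits.tsv``     — visit_id, animal_tag, corner, start, end
* ``Nosepokes.tsv``  — visit_id, time, door_opened
* ``Licks.tsv``      — visit_id, time, contact_count

plus a cohort/unblinding file (``animal_tag``, ``group``, optional
``cage_id``).  Any real cage export can be converted to this layout with a
few lines of pandas.  Round-trip (write then read) is the identity on the
canonical model.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import pandas as pd

from .events import CohortTable, LickEvent, PokeEvent, VisitEvent, sort_visits

VISIT_COLUMNS = ["visit_id", "animal_tag", "corner", "start", "end"]
POKE_COLUMNS = ["visit_id", "time", "door_opened"]
LICK_COLUMNS = ["visit_id", "time", "contact_count"]


class FormatError(ValueError):
    """Raised when an input file does not conform to the documented dialect."""


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")


def _parse_times(series: pd.Series, path) -> pd.Series:
    parsed = pd.to_datetime(series, format="ISO8601", errors="coerce")
    bad = parsed.isna() & series.notna()
    if bad.any():
        row = int(bad.idxmax())
        raise FormatError(
            f"{path}: unparseable timestamp {series[row]!r} at data row {row + 1}"
        )
    return parsed


def read_visit_log(
    visits_path, pokes_path=None, licks_path=None
) -> list[VisitEvent]:
    """Load the three event tables into time-sorted :class:`VisitEvent` records.

    Nested poke/lick rows are joined on ``visit_id``; row counts are
    conserved.  Orphan pokes/licks (unknown ``visit_id``) raise a
    :class:`FormatError` listing the offending ids.
    """
    vdf = pd.read_csv(visits_path, sep="\t", dtype={"animal_tag": str})
    _require_columns(vdf, VISIT_COLUMNS, visits_path)
    vdf["start"] = _parse_times(vdf["start"], visits_path)
    vdf["end"] = _parse_times(vdf["end"], visits_path)

    def _nested(path, cols):
        if path is None:
            return pd.DataFrame(columns=cols)
        df = pd.read_csv(path, sep="\t")
        _require_columns(df, cols, path)
        if len(df):
            df["time"] = _parse_times(df["time"], path)
        return df

    pdf = _nested(pokes_path, POKE_COLUMNS)
    ldf = _nested(licks_path, LICK_COLUMNS)

    known = set(vdf["visit_id"])
    for name, df in (("poke", pdf), ("lick", ldf)):
        orphans = sorted(set(df["visit_id"]) - known)
        if orphans:
            raise FormatError(
                f"{name} rows reference unknown visit_id(s): {orphans}"
            )

    pokes_by_visit: dict[int, list[PokeEvent]] = {}
    for row in pdf.sort_values("time", kind="stable").itertuples(index=False):
        pokes_by_visit.setdefault(row.visit_id, []).append(
            PokeEvent(time=row.time, door_opened=bool(row.door_opened))
        )
    licks_by_visit: dict[int, list[LickEvent]] = {}
    for row in ldf.sort_values("time", kind="stable").itertuples(index=False):
        licks_by_visit.setdefault(row.visit_id, []).append(
            LickEvent(time=row.time, contact_count=int(row.contact_count))
        )

    visits = []
    for row in vdf.itertuples(index=False):
        v = VisitEvent(
            visit_id=int(row.visit_id),
            animal_tag=str(row.animal_tag),
            corner=int(row.corner),
            start_time=row.start,
            end_time=row.end,
            pokes=pokes_by_visit.get(row.visit_id, []),
            licks=licks_by_visit.get(row.visit_id, []),
        )
        v.validate()
        visits.append(v)
    return sort_visits(visits)


def write_visit_log(visits: list[VisitEvent], out_dir) -> dict[str, Path]:
    """Write the canonical model back to the three-file dialect."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vrows, prows, lrows = [], [], []
    for v in visits:
        vrows.append(
            {
                "visit_id": v.visit_id,
                "animal_tag": v.animal_tag,
                "corner": v.corner,
                "start": v.start_time.isoformat(),
                "end": v.end_time.isoformat(),
            }
        )
        for p in v.pokes:
            prows.append(
                {
                    "visit_id": v.visit_id,
                    "time": p.time.isoformat(),
                    "door_opened": p.door_opened,
                }
            )
        for l in v.licks:
            lrows.append(
                {
                    "visit_id": v.visit_id,
                    "time": l.time.isoformat(),
                    "contact_count": l.contact_count,
                }
            )
    paths = {
        "visits": out_dir / "Visits.tsv",
        "pokes": out_dir / "Nosepokes.tsv",
        "licks": out_dir / "Licks.tsv",
    }
    pd.DataFrame(vrows, columns=VISIT_COLUMNS).to_csv(
        paths["visits"], sep="\t", index=False
    )
    pd.DataFrame(prows, columns=POKE_COLUMNS).to_csv(
        paths["pokes"], sep="\t", index=False
    )
    pd.DataFrame(lrows, columns=LICK_COLUMNS).to_csv(
        paths["licks"], sep="\t", index=False
    )
    return paths


def read_cohort(path) -> CohortTable:
    """Load the unblinding table (tag -> group, optional cage)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    _require_columns(df, ["animal_tag", "group"], path)
    if df.empty:
        raise FormatError(f"{path}: cohort file has no rows")
    dupes = df["animal_tag"][df["animal_tag"].duplicated()].tolist()
    if dupes:
        raise FormatError(f"{path}: duplicated animal_tag(s): {sorted(set(dupes))}")
    groups = dict(zip(df["animal_tag"], df["group"]))
    cages = (
        dict(zip(df["animal_tag"], df["cage_id"])) if "cage_id" in df.columns else {}
    )
    return CohortTable(groups=groups, cages=cages)


def write_cohort(cohort: CohortTable, path) -> Path:
    path = Path(path)
    rows = [
        {"animal_tag": t, "group": g, "cage_id": cohort.cages.get(t, "cage1")}
        for t, g in cohort.groups.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def check_tags(visits: list[VisitEvent], cohort: CohortTable) -> list[str]:
    """Warn about event tags that do not resolve in the cohort table."""
    unknown = cohort.unknown_tags(v.animal_tag for v in visits)
    if unknown:
        warnings.warn(
            f"event stream contains tag(s) absent from the cohort table: {unknown}",
            stacklevel=2,
        )
    return unknown
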