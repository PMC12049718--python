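"""Brute-force recomputation of the error metrics, independent of the
package's annotation code path.

Everything here is written directly from the metric definitions with plain
dict/loop logic: its own corner maps, its own patrol bookkeeping, its own
per-period filtering.  Used to check that the pipeline's PE/CE/TE/DE/CI
agree exactly with a from-scratch manual extraction.
"""

import math

import pandas as pd

DIAG = {1: 3, 2: 4, 3: 1, 4: 2}
CW = {1: 2, 2: 3, 3: 4, 4: 1}
CCW = {2: 1, 3: 2, 4: 3, 1: 4}

ORACLE_WEIGHTS = {
    "place_learning": (1.00, 0, 0, 0),
    "reversal_learning": (0.75, 0.25, 0, 0),
    "multiple_reversal": (0.75, 0.25, 0, 0),
    "elm_acq": (0.75, 0, 0.25, 0),
    "elm_ret": (0.75, 0, 0.25, 0),
    "elm_rev_acq": (0.50, 0.25, 0.25, 0),
    "elm_rev_ret": (0.50, 0.25, 0.25, 0),
    "patrol_cw_d1": (1.00, 0, 0, 0),
    "patrol_cw_d2": (1.00, 0, 0, 0),
    "patrol_ccw_d1": (0.75, 0, 0, 0.25),
    "patrol_ccw_d2": (0.75, 0, 0, 0.25),
}


def oracle_error_rates(visits, plan, cohort):
    """Recompute per animal x scored day x period rates from scratch."""
    day_info = [
        (d.day_index, d.task_id, d.start, d.end, d.active_start, d.active_end)
        for d in plan.days
    ]
    rows = []
    for tag in cohort.tags:
        group = cohort.groups[tag]
        place = plan.group_corners[group]
        rev = DIAG[place]
        av = sorted(
            (v for v in visits if v.animal_tag == tag and len(v.pokes) > 0),
            key=lambda v: v.start_time,
        )
        attempts = [(v.start_time, v.corner) for v in av]

        # patrol bookkeeping: replay every attempt in time order
        annotations = {}  # index -> (target set, de_flag)
        cur = None  # current rewarded corner
        last_drunk = None  # corner of last rewarded attempt
        direction = None
        for i, (t, c) in enumerate(attempts):
            day = next(
                (d for d in day_info if d[2] <= t < d[3]), None
            )
            if day is None:
                continue
            _, task, d0, d1, a0, a1 = day
            if not task.startswith("patrol"):
                continue
            newdir = "cw" if "cw_d" in task and "ccw" not in task else "ccw"
            if direction == "cw" and newdir == "ccw":
                # handover: one ccw step beyond the last rewarded cw corner
                cur = CCW[last_drunk] if last_drunk is not None else None
                if last_drunk is None:
                    cur = None
            direction = newdir
            target = {cur} if cur is not None else {1, 2, 3, 4}
            de = last_drunk is not None and c == CW[last_drunk] and newdir == "ccw"
            annotations[i] = (target, de)
            if a0 <= t < a1:  # advancement inside the active window only
                if cur is None:
                    cur = c
                elif c == cur:
                    last_drunk = c
                    cur = CW[c] if newdir == "cw" else CCW[c]

        for day_index, task, d0, d1, a0, a1 in day_info:
            if task not in ORACLE_WEIGHTS:
                continue
            periods = {
                "light": (d0, d0 + pd.Timedelta(hours=12)),
                "dark": (d0 + pd.Timedelta(hours=12), d1),
                "total24h": (d0, d1),
                "active": (a0, a1),
            }
            for period, (w0, w1) in periods.items():
                idx = [
                    i for i, (t, c) in enumerate(attempts) if w0 <= t < w1
                    and d0 <= t < d1
                ]
                n = len(idx)
                if n == 0:
                    rows.append(
                        dict(animal_tag=tag, day_index=day_index, task_id=task,
                             period=period, n=0, pe=math.nan, ce=math.nan,
                             te=math.nan, de=math.nan, ci=math.nan)
                    )
                    continue
                n_pe = n_ce = n_te = n_de = 0
                for i in idx:
                    t, c = attempts[i]
                    if task == "place_learning":
                        tgt = {place}
                    elif task in ("reversal_learning", "elm_rev_acq", "elm_rev_ret"):
                        tgt = {rev}
                    elif task in ("elm_acq", "elm_ret"):
                        tgt = {place}
                    elif task == "multiple_reversal":
                        if a0 <= t < a1:
                            block = int((t - a0).total_seconds() // 10800)
                        else:
                            block = 0
                        tgt = {rev} if block % 2 == 0 else {place}
                    else:  # patrolling
                        tgt, de_flag = annotations[i]
                        if de_flag and task.startswith("patrol_ccw"):
                            n_de += 1
                    if c not in tgt:
                        n_pe += 1
                    if task == "reversal_learning" and c == place:
                        n_ce += 1
                    if task in ("elm_rev_acq", "elm_rev_ret") and c == place:
                        n_ce += 1
                    if task == "multiple_reversal":
                        if a0 <= t < a1:
                            block = int((t - a0).total_seconds() // 10800)
                        else:
                            block = 0
                        unrewarded = place if block % 2 == 0 else rev
                        if c == unrewarded:
                            n_ce += 1
                    if task.startswith("elm") and not (a0 <= t < a1):
                        n_te += 1
                pe = n_pe / n
                ce = n_ce / n if task in (
                    "reversal_learning", "multiple_reversal",
                    "elm_rev_acq", "elm_rev_ret",
                ) else math.nan
                te = n_te / n if task.startswith("elm") else math.nan
                de = n_de / n if task.startswith("patrol_ccw") else math.nan
                pe_adj = pe
                if not math.isnan(ce):
                    pe_adj -= ce
                if not math.isnan(de):
                    pe_adj -= de
                w_pe, w_ce, w_te, w_de = ORACLE_WEIGHTS[task]
                ci = 1.0 - (
                    w_pe * pe_adj
                    + (w_ce * ce if w_ce else 0.0)
                    + (w_te * te if w_te else 0.0)
                    + (w_de * de if w_de else 0.0)
                )
                rows.append(
                    dict(animal_tag=tag, day_index=day_index, task_id=task,
                         period=period, n=n, pe=pe, ce=ce, te=te, de=de, ci=ci)
                )
    return pd.DataFrame(rows)
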