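import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagecog import (
    CohortTable,
    WEIGHTS,
    annotate_attempts,
    classify_visit,
    cognition_index,
    error_rates,
    welfare_flags,
)
from cagecog.metrics import METRIC_COLUMNS, behavior_summary

from conftest import make_visit


# -- visit classification --------------------------------------------------

def test_zero_pokes_is_exploratory():
    c = classify_visit(make_visit(n_pokes=0))
    assert c.kind == "exploratory"
    assert c.repetitive_frequency == 0 and c.repetitive_total == 0


def test_ten_uninterrupted_pokes_frequency_1_total_9():
    c = classify_visit(make_visit(n_pokes=10))
    assert c.kind == "drinking_attempt"
    assert c.repetitive_frequency == 1
    assert c.repetitive_total == 9


def test_lick_breaks_bout():
    # 2 pokes, lick, 3 pokes -> bouts [2, 3], total (2-1)+(3-1)=3, one visit
    c = classify_visit(make_visit(poke_lick_pattern="pplppp"))
    assert c.repetitive_bouts == (2, 3)
    assert c.repetitive_total == 3
    assert c.repetitive_frequency == 1


def test_single_poke_not_repetitive():
    c = classify_visit(make_visit(n_pokes=1))
    assert c.kind == "drinking_attempt"
    assert c.repetitive_bouts == ()


@given(st.text(alphabet="pl", max_size=30))
@settings(deadline=None)
def test_bout_decomposition_property(pattern):
    """Total always equals sum(bout-1) over maximal poke runs >= 2."""
    if "p" not in pattern:
        return
    c = classify_visit(make_visit(poke_lick_pattern=pattern, duration_s=60))
    runs = [len(r) for r in pattern.split("l") if len(r) >= 2]
    assert list(c.repetitive_bouts) == runs
    assert c.repetitive_total == sum(r - 1 for r in runs)
    assert c.repetitive_frequency == (1 if runs else 0)


# -- cognition index -------------------------------------------------------

def test_weight_rows_sum_to_one_for_all_11_tasks():
    assert len(WEIGHTS) == 11
    for task, w in WEIGHTS.items():
        assert sum(w) == pytest.approx(1.0), task


def test_ci_is_one_when_error_free():
    assert cognition_index(0, 0, 0, 0, "place_learning") == 1.0


def test_ci_elm_reversal_weighting():
    # 50% place-error weight row
    assert cognition_index(1.0, 0.0, 0.0, np.nan, "elm_rev_acq") == pytest.approx(0.5)


def test_ci_reversal_hand_computation():
    # pe=0.4, ce=0.2 -> pe_adj=0.2; 1 - (0.75*0.2 + 0.25*0.2) = 0.8
    assert cognition_index(0.2, 0.2, np.nan, np.nan, "reversal_learning") == (
        pytest.approx(0.8)
    )


def test_ci_unknown_task_raises():
    with pytest.raises(ValueError, match="weights"):
        cognition_index(0, 0, 0, 0, "extinction")


# -- error rates on hand-built streams ------------------------------------

def _cohort():
    return CohortTable(groups={"m01": "G1"})


def _attempt_rates(plan, visits, period="dark"):
    att = annotate_attempts(visits, plan, _cohort())
    rates = error_rates(att, plan)
    return rates[rates["period"] == period]


def test_pe_half_when_two_of_four_attempts_wrong(plan):
    # place learning day, group corner 1; attempts at 1,1,2,3 in the dark
    visits = [
        make_visit(visit_id=i + 1, corner=c, start=f"2024-01-02 {19 + i}:00:00",
                   n_pokes=1)
        for i, c in enumerate([1, 1, 2, 3])
    ]
    row = _attempt_rates(plan, visits)
    row = row[row["task_id"] == "place_learning"].iloc[0]
    assert row["pe"] == pytest.approx(0.5)
    assert row["n_attempts"] == 4
    assert row["ci"] == pytest.approx(0.5)


def test_all_correct_gives_zero_errors(plan):
    visits = [
        make_visit(visit_id=i + 1, corner=3, start=f"2024-01-03 {19 + i}:00:00",
                   n_pokes=1)
        for i in range(4)
    ]  # reversal day, G1 reversal corner is 3
    row = _attempt_rates(plan, visits)
    row = row[row["task_id"] == "reversal_learning"].iloc[0]
    assert row["pe"] == 0 and row["ce"] == 0
    assert row["ci"] == 1.0


def test_reversal_ce_counts_previous_corner(plan):
    # attempts at the old place corner (1) are both PE and CE
    visits = [
        make_visit(visit_id=1, corner=1, start="2024-01-03 19:00:00", n_pokes=1),
        make_visit(visit_id=2, corner=3, start="2024-01-03 20:00:00", n_pokes=1),
        make_visit(visit_id=3, corner=2, start="2024-01-03 21:00:00", n_pokes=1),
        make_visit(visit_id=4, corner=3, start="2024-01-03 22:00:00", n_pokes=1),
    ]
    row = _attempt_rates(plan, visits)
    row = row[row["task_id"] == "reversal_learning"].iloc[0]
    assert row["pe"] == pytest.approx(0.5)
    assert row["ce"] == pytest.approx(0.25)
    assert row["pe_adj"] == pytest.approx(0.25)


def test_direction_error_semantics(plan):
    """With last rewarded corner 2 on a ccw day, attempts at 3 (one cw step)
    are DE; attempts at 2 or 4 are not."""
    day13 = "2024-01-13"
    visits = [
        # anchor at 2, then drink at 2 -> rewarded advances ccw to 1,
        # last rewarded corner = 2
        make_visit(visit_id=1, corner=2, start=f"{day13} 19:00:00", n_pokes=1),
        make_visit(visit_id=2, corner=2, start=f"{day13} 19:30:00", n_pokes=1),
        # now: target 1; DE corner = cw(2) = 3
        make_visit(visit_id=3, corner=3, start=f"{day13} 20:00:00", n_pokes=1),
        make_visit(visit_id=4, corner=4, start=f"{day13} 20:30:00", n_pokes=1),
    ]
    att = annotate_attempts(visits, plan, _cohort())
    d = att[att["task_id"] == "patrol_ccw_d1"]
    assert list(d["is_de"]) == [0.0, 0.0, 1.0, 0.0]
    assert list(d["success"]) == [True, True, False, False]


def test_zero_attempts_flagged_missing(plan):
    visits = [make_visit(visit_id=1, corner=1, start="2024-01-02 19:00:00",
                         n_pokes=1)]
    rates = _attempt_rates(plan, visits, period="light")
    row = rates[rates["task_id"] == "place_learning"].iloc[0]
    assert row["n_attempts"] == 0
    assert np.isnan(row["pe"]) and np.isnan(row["ci"])


# -- welfare ---------------------------------------------------------------

@pytest.mark.parametrize(
    "licks, excluded, flag_day",
    [
        ([99, 99], True, 2),
        ([100, 99], False, None),
        ([99, 150, 99], False, None),
        ([150, 99, 98, 97], True, 3),
    ],
)
def test_welfare_exclusion_rule(licks, excluded, flag_day):
    df = pd.DataFrame(
        {"animal_tag": "m01", "day_index": range(1, len(licks) + 1),
         "licks": licks}
    )
    row = welfare_flags(df).iloc[0]
    assert bool(row["excluded"]) is excluded
    assert row["flag_day"] == flag_day or (flag_day is None and
                                           pd.isna(row["flag_day"]))


# -- aggregate invariants on simulated data -------------------------------

def test_visit_partition_identities(learner_tables):
    pa = learner_tables["per_animal"]
    assert (pa["exploratory_visits"] + pa["drinking_attempts"]
            == pa["visits"]).all()
    wide = pa.pivot_table(index=["animal_tag", "day_index"], columns="period",
                          values="visits", aggfunc="sum")
    assert (wide["dark"] + wide["light"] == wide["total24h"]).all()


def test_pe_adj_nonnegative(learner_tables, chance_tables):
    for tables in (learner_tables, chance_tables):
        pa = tables["per_animal"].dropna(subset=["pe_adj"])
        assert (pa["pe_adj"] >= -1e-12).all()


def test_rates_bounded(chance_tables):
    pa = chance_tables["per_animal"]
    for col in ("pe", "ce", "te", "de", "pe_adj", "ci"):
        v = pa[col].dropna()
        assert ((v >= 0) & (v <= 1)).all(), col


def test_group_summary_matches_brute_force(learner_tables):
    pa = learner_tables["per_animal"]
    gs = learner_tables["group_summary"]
    probe = gs[(gs["measure"] == "pe") & (gs["period"] == "dark")]
    for row in probe.itertuples(index=False):
        cell = pa[(pa["group"] == row.group) & (pa["day_index"] == row.day_index)
                  & (pa["period"] == "dark")]["pe"].dropna()
        if len(cell) == 0:
            continue
        assert row.mean == pytest.approx(float(np.mean(cell)))
        if len(cell) > 1:
            assert row.sd == pytest.approx(float(np.std(cell, ddof=1)))
        assert row.n == len(cell)


def test_missing_animal_warns(plan):
    cohort = CohortTable(groups={"m01": "G1", "ghostly": "G2"})
    visits = [make_visit(visit_id=1, corner=1, start="2024-01-02 19:00:00",
                         n_pokes=1)]
    with pytest.warns(UserWarning, match="ghostly"):
        bs = behavior_summary(visits, plan, cohort)
    assert set(bs["animal_tag"]) == {"m01", "ghostly"}
    ghost = bs[bs["animal_tag"] == "ghostly"]
    assert (ghost["visits"] == 0).all()


def test_all_metric_columns_present(learner_tables):
    assert set(METRIC_COLUMNS) <= set(learner_tables["per_animal"].columns)
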