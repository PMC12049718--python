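import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cagecog import (
    CHANCE_SLOPE,
    build_curve,
    compare_groups,
    compare_to_chance,
    curves_from_attempts,
    fit_curves,
)


def _bernoulli_curves(rng, groups, n_attempts):
    """groups: dict label -> (n_animals, p)."""
    rows = []
    for g, (n_animals, p) in groups.items():
        for a in range(n_animals):
            y = np.cumsum(rng.random(n_attempts) < p)
            rows.extend(
                {"animal_tag": f"{g}-{a}", "group": g, "task_id": "task",
                 "attempt_index": i + 1, "cum_success": int(y[i])}
                for i in range(n_attempts)
            )
    return pd.DataFrame(rows)


def test_build_curve_examples():
    c = build_curve([1, 0, 1, 1])
    assert list(c["cum_success"]) == [1, 1, 2, 3]
    assert list(c["attempt_index"]) == [1, 2, 3, 4]
    assert list(build_curve([0, 0, 0])["cum_success"]) == [0, 0, 0]
    assert build_curve([]).empty


@given(st.lists(st.booleans(), max_size=40))
@settings(deadline=None)
def test_curve_nondecreasing_and_bounded(outcomes):
    c = build_curve(outcomes)
    y = c["cum_success"].to_numpy()
    assert (np.diff(y) >= 0).all() if len(y) > 1 else True
    assert all(y[k] <= k + 1 for k in range(len(y)))


def test_perfect_learner_slope_one():
    rng = np.random.default_rng(0)
    curves = _bernoulli_curves(rng, {"A": (1, 1.0)}, 50)
    fit = fit_curves(curves)["group"][0]
    assert fit.slope == pytest.approx(1.0)


@pytest.mark.parametrize("p, n, tol", [(0.25, 1000, 0.05), (0.8, 500, 0.03)])
def test_slope_estimates_success_probability(p, n, tol):
    rng = np.random.default_rng(1234)
    curves = _bernoulli_curves(rng, {"A": (1, p)}, n)
    fit = fit_curves(curves)["group"][0]
    assert fit.slope == pytest.approx(p, abs=tol)


def test_slope_consistency_across_probabilities():
    rng = np.random.default_rng(99)
    for p in (0.25, 0.5, 0.9):
        curves = _bernoulli_curves(rng, {"A": (4, p)}, 400)
        fit = fit_curves(curves)["group"][0]
        assert fit.slope == pytest.approx(p, abs=0.04)


def test_chance_reference_is_constant():
    assert CHANCE_SLOPE == 0.25


def test_learners_beat_chance():
    rng = np.random.default_rng(5)
    curves = _bernoulli_curves(rng, {"A": (10, 0.9)}, 100)
    fit = fit_curves(curves)["group"][0]
    comp = compare_to_chance(fit)
    assert comp.p < 1e-4
    assert comp.estimate > 0.5


def test_chance_contrast_calibration():
    """Groups simulated exactly at chance: the slope-difference CI covers 0
    in at least 93 of 100 seeded replicates at alpha=0.05."""
    rng = np.random.default_rng(2024)
    covered = 0
    for _ in range(100):
        curves = _bernoulli_curves(rng, {"A": (10, 0.25)}, 80)
        fit = fit_curves(curves)["group"][0]
        comp = compare_to_chance(fit)
        covered += comp.ci_low <= 0 <= comp.ci_high
    assert covered >= 93


def test_zero_variance_at_chance_slope():
    # deterministic pattern with exact slope 0.25 and zero residual noise
    y = [(k + 1) * 0.25 for k in range(40)]
    curves = pd.DataFrame(
        {"animal_tag": "a", "group": "A", "task_id": "t",
         "attempt_index": np.arange(1, 41), "cum_success": y}
    )
    fit = fit_curves(curves)["group"][0]
    comp = compare_to_chance(fit)
    assert comp.estimate == pytest.approx(0.0, abs=1e-12)


def test_group_separation_detected():
    rng = np.random.default_rng(7)
    curves = _bernoulli_curves(rng, {"slow": (8, 0.3), "fast": (8, 0.8)}, 200)
    comps = compare_groups(curves, "task")
    pair = [c for c in comps if "vs" in c.contrast and "chance" not in c.contrast]
    assert pair[0].p < 0.05
    het = [c for c in comps if c.contrast == "slope heterogeneity"][0]
    assert het.p < 0.05


def test_group_label_swap_flips_sign():
    rng = np.random.default_rng(8)
    curves = _bernoulli_curves(rng, {"A": (6, 0.3), "B": (6, 0.7)}, 120)
    swapped = curves.copy()
    swapped["group"] = swapped["group"].map({"A": "B", "B": "A"})
    a = [c for c in compare_groups(curves, "task") if c.contrast == "A vs B"][0]
    b = [c for c in compare_groups(swapped, "task") if c.contrast == "A vs B"][0]
    assert a.estimate == pytest.approx(-b.estimate)
    assert a.p == pytest.approx(b.p)


def test_contrast_invariant_to_index_translation():
    rng = np.random.default_rng(9)
    curves = _bernoulli_curves(rng, {"A": (5, 0.4), "B": (5, 0.6)}, 100)
    shifted = curves.copy()
    shifted["attempt_index"] = shifted["attempt_index"] + 57
    a = [c for c in compare_groups(curves, "task") if c.contrast == "A vs B"][0]
    b = [c for c in compare_groups(shifted, "task") if c.contrast == "A vs B"][0]
    assert a.p == pytest.approx(b.p)
    assert a.estimate == pytest.approx(b.estimate)


def test_identical_groups_type_one_error():
    """Same success probability in both groups: interaction test rejects at
    alpha=0.05 no more than 7% of the time over 200 replicates."""
    rng = np.random.default_rng(11)
    rej = 0
    for _ in range(200):
        curves = _bernoulli_curves(rng, {"A": (8, 0.4), "B": (8, 0.4)}, 60)
        comps = compare_groups(curves, "task")
        pair = [c for c in comps if c.contrast == "A vs B"][0]
        rej += pair.p < 0.05
    assert rej / 200 <= 0.07


def test_compare_groups_requires_two_groups():
    rng = np.random.default_rng(3)
    curves = _bernoulli_curves(rng, {"A": (3, 0.5)}, 30)
    with pytest.raises(ValueError, match="two groups"):
        compare_groups(curves, "task")


def test_curves_from_attempts_uses_active_window(plan, chance_tables):
    curves = curves_from_attempts(chance_tables["attempts"])
    att = chance_tables["attempts"]
    n_active = att[att["in_active"]].groupby(
        ["animal_tag", "task_id"]).size()
    n_curve = curves.groupby(["animal_tag", "task_id"]).size()
    pd.testing.assert_series_equal(n_active.sort_index(), n_curve.sort_index())
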