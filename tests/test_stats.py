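import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from cagecog import (
    cliffs_delta,
    cohens_d,
    decide_and_test,
    epsilon_squared,
    hedges_g,
    longitudinal_test,
    omega_squared,
    permutation_ksample,
)
from cagecog.stats import DegenerateDataError, dunn_posthoc


# -- effect sizes ----------------------------------------------------------

def test_effect_sizes_zero_on_identical_groups():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    assert cohens_d(x, x) == 0.0
    assert cliffs_delta(x, x) == 0.0


def test_hedges_g_smaller_than_cohens_d():
    rng = np.random.default_rng(0)
    x, y = rng.normal(0, 1, 8), rng.normal(1, 1, 8)
    assert abs(hedges_g(x, y)) < abs(cohens_d(x, y))


def test_cliffs_delta_matches_definition_oracle():
    rng = np.random.default_rng(1)
    x, y = rng.exponential(1, 15), rng.exponential(2, 12)
    brute = sum(
        (1 if xi > yi else -1 if xi < yi else 0) for xi in x for yi in y
    ) / (len(x) * len(y))
    assert cliffs_delta(x, y) == pytest.approx(brute)
    assert -1 <= cliffs_delta(x, y) <= 1


def test_epsilon_squared_worked_example():
    assert epsilon_squared(10, 21) == pytest.approx(0.5)
    assert epsilon_squared(0, 10) == 0.0


@given(
    H=st.floats(min_value=0, max_value=100),
    n=st.integers(min_value=2, max_value=500),
)
def test_epsilon_squared_algebraic_identity(H, n):
    assert epsilon_squared(H, n) * (n - 1) == pytest.approx(H, rel=1e-12)


def test_epsilon_squared_invalid_inputs():
    with pytest.raises(ValueError):
        epsilon_squared(1.0, 1)
    with pytest.raises(ValueError):
        epsilon_squared(-1.0, 10)


# -- decision tree branch selection ---------------------------------------

def _run(groups, **kw):
    values = np.concatenate(list(groups.values()))
    labels = np.repeat(list(groups), [len(v) for v in groups.values()])
    return decide_and_test(values, labels, **kw)


def test_t_test_branch_matches_textbook_formula():
    rng = np.random.default_rng(42)
    x, y = rng.normal(0, 1, 20), rng.normal(0.3, 1, 20)
    res = _run({"A": x, "B": y})
    assert res.test_name in ("t-test", "Welch t-test")
    if res.test_name == "t-test":
        sp2 = (19 * x.var(ddof=1) + 19 * y.var(ddof=1)) / 38
        t = (x.mean() - y.mean()) / np.sqrt(sp2 * (1 / 20 + 1 / 20))
    else:
        t = (x.mean() - y.mean()) / np.sqrt(
            x.var(ddof=1) / 20 + y.var(ddof=1) / 20
        )
    assert res.statistic == pytest.approx(t, abs=1e-10)
    assert res.effect_size_name == "Cohen's d"


def test_nonnormal_two_groups_rank_sum_branch():
    rng = np.random.default_rng(3)
    x, y = rng.exponential(1, 25) ** 2, rng.exponential(1, 25) ** 2
    res = _run({"A": x, "B": y})
    assert res.test_name == "Wilcoxon rank-sum"
    assert res.effect_size_name == "Cliff's delta"
    assert -1 <= res.effect_size_value <= 1


def test_three_group_normal_equal_goes_anova_tukey():
    rng = np.random.default_rng(4)
    groups = {g: rng.normal(mu, 1, 15) for g, mu in zip("ABC", (0, 0.5, 1))}
    res = _run(groups)
    assert res.normal and res.variance_equal
    assert res.test_name == "one-way ANOVA"
    assert res.effect_size_name == "omega-squared"
    assert len(res.posthoc) == 3
    assert set(res.posthoc["effect_size_name"]) == {"Cohen's d"}


def test_branch_consistency_with_gates():
    """Whatever the gates decide, the chosen test matches the decision table."""
    rng = np.random.default_rng(5)
    cases = [
        {g: rng.normal(0, 1, 12) for g in "AB"},
        {g: rng.exponential(1, 12) for g in "AB"},
        {"A": rng.normal(0, 1, 12), "B": rng.normal(0, 6, 12),
         "C": rng.normal(0, 1, 12)},
        {"A": rng.exponential(0.2, 12), "B": rng.exponential(5, 12),
         "C": rng.exponential(1, 12)},
        {g: rng.lognormal(0, 1, 12) for g in "ABCD"},
    ]
    table = {
        (2, True, True): "t-test",
        (2, True, False): "Welch t-test",
        (2, False, True): "Wilcoxon rank-sum",
        (2, False, False): "Wilcoxon rank-sum",
        (3, True, True): "one-way ANOVA",
        (3, True, False): "Welch ANOVA",
        (3, False, True): "Kruskal-Wallis",
        (3, False, False): "Fisher-Pitman permutation",
    }
    for groups in cases:
        res = _run(groups)
        k = min(len(groups), 3)
        assert res.test_name == table[(k, res.normal, res.variance_equal)]


def test_small_group_falls_to_nonparametric_with_warning():
    with pytest.warns(UserWarning, match="n < 3"):
        res = _run({"A": np.array([1.0, 2.0]), "B": np.array([3.0, 4.0, 5.0])})
    assert not res.normal
    assert res.test_name == "Wilcoxon rank-sum"


def test_constant_data_degenerate():
    with pytest.raises(DegenerateDataError):
        _run({"A": np.ones(5), "B": np.ones(5)})


def test_unsupported_group_counts():
    rng = np.random.default_rng(6)
    with pytest.raises(ValueError):
        _run({g: rng.normal(0, 1, 5) for g in "ABCDE"})
    with pytest.raises(ValueError):
        decide_and_test(rng.normal(0, 1, 5), np.repeat("A", 5))


# -- permutation test ------------------------------------------------------

def test_permutation_identical_values_p_one():
    res = permutation_ksample([1, 1, 1, 1], ["a", "a", "b", "b"])
    assert res.p == 1.0


def test_permutation_label_symmetry():
    rng = np.random.default_rng(7)
    v = rng.normal(0, 1, 20)
    lab = np.repeat(["a", "b"], 10)
    swapped = np.where(lab == "a", "b", "a")
    assert permutation_ksample(v, lab).p == pytest.approx(
        permutation_ksample(v, swapped).p
    )


def test_permutation_asymptotic_close_to_monte_carlo():
    rng = np.random.default_rng(8)
    v = np.concatenate([rng.lognormal(0, 0.5, 15), rng.lognormal(0.5, 0.5, 15)])
    lab = np.repeat(["a", "b"], 15)
    asym = permutation_ksample(v, lab).p
    mc = permutation_ksample(v, lab, n_perm=100_000, seed=1).p
    assert asym == pytest.approx(mc, abs=0.02)


def test_permutation_reproducible_under_seed():
    rng = np.random.default_rng(9)
    v = rng.normal(0, 1, 24)
    lab = np.repeat(["a", "b", "c"], 8)
    p1 = permutation_ksample(v, lab, n_perm=5000, seed=77).p
    p2 = permutation_ksample(v, lab, n_perm=5000, seed=77).p
    assert p1 == p2


# -- post hocs -------------------------------------------------------------

def test_dunn_detects_separated_group():
    rng = np.random.default_rng(10)
    samples = {"A": rng.exponential(1, 15), "B": rng.exponential(1, 15),
               "C": rng.exponential(1, 15) + 10}
    df = dunn_posthoc(samples)
    pc = df[(df["group2"] == "C") | (df["group1"] == "C")]
    assert (pc["p"] < 0.01).all()
    ab = df[(df["group1"] == "A") & (df["group2"] == "B")]
    assert float(ab["p"].iloc[0]) > 0.05


def test_posthoc_holm_adjustment_monotone():
    rng = np.random.default_rng(11)
    samples = {g: rng.exponential(1, 12) for g in "ABC"}
    raw = dunn_posthoc(samples)
    adj = dunn_posthoc(samples, adjust="holm")
    assert (adj["p"].to_numpy() >= raw["p"].to_numpy() - 1e-15).all()


# -- longitudinal ----------------------------------------------------------

def test_friedman_detects_monotone_improvement():
    rng = np.random.default_rng(12)
    base = rng.normal(0, 0.1, (10, 1))
    m = pd.DataFrame(base + np.arange(4) + rng.normal(0, 0.1, (10, 4)))
    res = longitudinal_test(m, normal=False)
    assert res.test_name == "Friedman"
    assert res.p < 0.01


def test_friedman_identical_columns_null():
    m = pd.DataFrame(np.tile(np.arange(5.0)[:, None], (1, 4)))
    res = longitudinal_test(m, normal=False)
    assert res.statistic == 0.0
    assert res.p == 1.0


def test_rm_anova_matches_sum_of_squares_oracle():
    rng = np.random.default_rng(13)
    n_sub, n_day = 8, 4
    m = pd.DataFrame(rng.normal(0, 1, (n_sub, n_day))
                     + np.array([0, 0.5, 1.0, 1.5]))
    res = longitudinal_test(m, normal=True)
    assert res.test_name == "RM-ANOVA"
    # two-way (subject + day) fixed-effects decomposition
    x = m.to_numpy()
    grand = x.mean()
    ss_day = n_sub * ((x.mean(axis=0) - grand) ** 2).sum()
    ss_sub = n_day * ((x.mean(axis=1) - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_day - ss_sub
    f = (ss_day / (n_day - 1)) / (ss_err / ((n_day - 1) * (n_sub - 1)))
    assert res.statistic == pytest.approx(f, rel=1e-6)
    p = sps.f.sf(f, n_day - 1, (n_day - 1) * (n_sub - 1))
    assert res.p == pytest.approx(p, rel=1e-6)


def test_longitudinal_requires_enough_data():
    with pytest.raises(ValueError):
        longitudinal_test(pd.DataFrame(np.ones((2, 4))), normal=False)


def test_longitudinal_listwise_dropping_warns():
    m = pd.DataFrame(np.random.default_rng(14).normal(0, 1, (6, 3)))
    m.iloc[0, 1] = np.nan
    with pytest.warns(UserWarning, match="dropped"):
        longitudinal_test(m, normal=False)


# -- calibration (fast per-branch null checks live in test_acceptance) ----

def test_omega_squared_null_near_zero():
    rng = np.random.default_rng(15)
    vals = [rng.normal(0, 1, 200) for _ in range(3)]
    assert abs(omega_squared(vals)) < 0.02
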