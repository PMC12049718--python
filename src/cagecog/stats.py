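"""Group comparisons via a distribution-guided decision tree.

Every derived measure is compared across 2–4 groups with the test the data
support: Shapiro–Wilk gates normality (parametric only when every group
passes at α), Levene's test (mean-centered) gates equal variance, and the
(n_groups, normal, variance_equal) cell maps deterministically to exactly
one test:

====================  ============================  =========================
cell                  test                          effect size / post hoc
====================  ============================  =========================
2, normal             Student t (Welch if unequal)  Cohen's d
2, non-normal         Wilcoxon rank-sum             Cliff's delta
3–4, normal, equal    one-way ANOVA                 ω²; Tukey HSD + Cohen's d
3–4, normal, unequal  Welch ANOVA                   ω²; Games–Howell + Cohen's d
3–4, non-n., equal    Kruskal–Wallis                ε²; Dunn + Cliff's delta
3–4, non-n., unequal  Fisher–Pitman permutation     — ; GLH contrasts + Hedges' g
====================  ============================  =========================

ε² = H / ((n² − 1)/(n + 1)) = H/(n − 1) for the Kruskal–Wallis statistic H
and total sample size n.  The asymptotic k-sample Fisher–Pitman statistic is
W = (N − 1)·SSB/SST ~ χ²_{k−1} under the permutation null (the raw-value
analog of Kruskal–Wallis); a seeded Monte-Carlo variant is available for
cross-checking and no effect size is reported for that branch.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
import pingouin as pg
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

ALPHA_GATE = 0.05  # Shapiro and Levene gates


class DegenerateDataError(ValueError):
    """All observations identical — no test is informative."""


@dataclass
class StatResult:
    variable: str
    groups: list[str]
    n_per_group: dict[str, int]
    test_name: str
    statistic: float
    p: float
    effect_size_name: str | None
    effect_size_value: float | None
    normal: bool
    variance_equal: bool
    posthoc: pd.DataFrame | None = None
    notes: list[str] = field(default_factory=list)


# -- effect sizes ----------------------------------------------------------

def cohens_d(x, y) -> float:
    """Standardized mean difference with the pooled SD."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    nx, ny = len(x), len(y)
    sp = np.sqrt(
        ((nx - 1) * np.var(x, ddof=1) + (ny - 1) * np.var(y, ddof=1)) / (nx + ny - 2)
    )
    if sp == 0:
        return 0.0
    return float((np.mean(x) - np.mean(y)) / sp)


def hedges_g(x, y) -> float:
    """Cohen's d with the small-sample bias correction J = 1 − 3/(4·df − 1)."""
    df = len(x) + len(y) - 2
    return cohens_d(x, y) * (1 - 3 / (4 * df - 1))


def cliffs_delta(x, y) -> float:
    """(#{x>y} − #{x<y}) / (n_x·n_y), in [−1, 1]."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    diff = x[:, None] - y[None, :]
    return float((np.sum(diff > 0) - np.sum(diff < 0)) / (len(x) * len(y)))


def omega_squared(values_by_group) -> float:
    """ω² from the one-way decomposition: (SSB − df_b·MSW)/(SST + MSW)."""
    groups = [np.asarray(g, float) for g in values_by_group]
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssb = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
    ssw = sum(((g - g.mean()) ** 2).sum() for g in groups)
    dfb = len(groups) - 1
    dfw = len(allv) - len(groups)
    msw = ssw / dfw
    denom = ssb + ssw + msw
    if denom == 0:
        return 0.0
    return float((ssb - dfb * msw) / denom)


def epsilon_squared(H: float, n: int) -> float:
    """ε² = H / ((n² − 1)/(n + 1)); algebraically H/(n − 1)."""
    if n < 2:
        raise ValueError(f"epsilon-squared needs n >= 2, got {n}")
    if H < 0:
        raise ValueError(f"H must be non-negative, got {H}")
    return float(H / ((n**2 - 1) / (n + 1)))


# -- permutation test ------------------------------------------------------

def _fisher_pitman_stat(values: np.ndarray, labels: np.ndarray) -> float:
    grand = values.mean()
    sst = ((values - grand) ** 2).sum()
    if sst == 0:
        return 0.0
    ssb = 0.0
    for g in np.unique(labels):
        sub = values[labels == g]
        ssb += len(sub) * (sub.mean() - grand) ** 2
    return (len(values) - 1) * ssb / sst


def permutation_ksample(
    values, labels, n_perm: int | None = None, seed: int | None = None,
    variable: str = "value",
) -> StatResult:
    """Asymptotic k-sample Fisher–Pitman permutation test on raw values.

    With ``n_perm`` set, the p-value is instead the seeded Monte-Carlo
    permutation estimate (1 + #{W* ≥ W}) / (n_perm + 1).
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    uniq = np.unique(labels)
    if len(uniq) < 2:
        raise ValueError("need at least two groups")
    notes = []
    if np.ptp(values) == 0:
        notes.append("all values identical; p = 1 by convention")
        w, p = 0.0, 1.0
    else:
        w = _fisher_pitman_stat(values, labels)
        if n_perm is None:
            p = float(sps.chi2.sf(w, len(uniq) - 1))
        else:
            # permuting values over fixed label positions == permuting labels
            rng = np.random.default_rng(seed)
            n = len(values)
            sizes = [int((labels == g).sum()) for g in uniq]
            grand = values.mean()
            sst = ((values - grand) ** 2).sum()
            count = 0
            chunk = 20_000
            done = 0
            while done < n_perm:
                m = min(chunk, n_perm - done)
                idx = np.argsort(rng.random((m, n)), axis=1)
                pv = values[idx]
                ssb = np.zeros(m)
                pos = 0
                for sz in sizes:
                    means = pv[:, pos: pos + sz].mean(axis=1)
                    ssb += sz * (means - grand) ** 2
                    pos += sz
                wperm = (n - 1) * ssb / sst
                count += int((wperm >= w - 1e-12).sum())
                done += m
            p = (1 + count) / (n_perm + 1)
    return StatResult(
        variable=variable,
        groups=list(map(str, uniq)),
        n_per_group={str(g): int((labels == g).sum()) for g in uniq},
        test_name="Fisher-Pitman permutation"
        + ("" if n_perm is None else f" (MC, {n_perm})"),
        statistic=float(w),
        p=float(p),
        effect_size_name=None,
        effect_size_value=None,
        normal=False,
        variance_equal=False,
        notes=notes,
    )


# -- post hocs -------------------------------------------------------------

def _adjust(pvals, method):
    if method is None or method == "none":
        return list(pvals)
    return list(multipletests(pvals, method=method)[1])


def dunn_posthoc(samples: dict[str, np.ndarray], adjust: str | None = None) -> pd.DataFrame:
    """Dunn's rank-sum post hoc after Kruskal–Wallis (tie-corrected).

    z_{ij} = (R̄_i − R̄_j) / sqrt[(N(N+1)/12 − T)·(1/n_i + 1/n_j)] with the
    tie term T = Σ(t³ − t)/(12(N − 1)); two-sided normal p, unadjusted by
    default (Holm via ``adjust='holm'``).
    """
    labels = list(samples)
    allv = np.concatenate([samples[g] for g in labels])
    ranks = sps.rankdata(allv)
    n_total = len(allv)
    mean_ranks, sizes, idx = {}, {}, 0
    for g in labels:
        n = len(samples[g])
        mean_ranks[g] = ranks[idx: idx + n].mean()
        sizes[g] = n
        idx += n
    _, counts = np.unique(allv, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (12 * (n_total - 1))
    base_var = n_total * (n_total + 1) / 12 - tie_term
    rows = []
    for a, b in combinations(labels, 2):
        se = np.sqrt(base_var * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        rows.append(
            {"group1": a, "group2": b, "statistic": float(z),
             "p": float(2 * sps.norm.sf(abs(z))),
             "effect_size_name": "Cliff's delta",
             "effect_size_value": cliffs_delta(samples[a], samples[b])}
        )
    df = pd.DataFrame(rows)
    df["p"] = _adjust(df["p"], adjust)
    return df


def tukey_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Tukey HSD pairwise comparisons with Cohen's d per pair."""
    res = sps.tukey_hsd(*samples.values())
    labels = list(samples)
    rows = []
    for i, j in combinations(range(len(labels)), 2):
        a, b = labels[i], labels[j]
        rows.append(
            {"group1": a, "group2": b,
             "statistic": float(res.statistic[i, j]),
             "p": float(res.pvalue[i, j]),
             "effect_size_name": "Cohen's d",
             "effect_size_value": cohens_d(samples[a], samples[b])}
        )
    return pd.DataFrame(rows)


def games_howell_posthoc(samples: dict[str, np.ndarray]) -> pd.DataFrame:
    """Games–Howell pairwise comparisons (studentized range with
    Welch–Satterthwaite df) with Cohen's d per pair."""
    long = pd.DataFrame(
        {"value": np.concatenate(list(samples.values())),
         "group": np.repeat(list(samples), [len(v) for v in samples.values()])}
    )
    gh = pg.pairwise_gameshowell(data=long, dv="value", between="group")
    rows = []
    for r in gh.itertuples(index=False):
        rows.append(
            {"group1": r.A, "group2": r.B, "statistic": float(r.T),
             "p": float(r.pval),
             "effect_size_name": "Cohen's d",
             "effect_size_value": cohens_d(samples[r.A], samples[r.B])}
        )
    return pd.DataFrame(rows)


def glh_posthoc(samples: dict[str, np.ndarray], adjust: str | None = None) -> pd.DataFrame:
    """Pairwise mean contrasts from the pooled linear model (general-
    linear-hypothesis style) with Hedges' g per pair."""
    allv = np.concatenate(list(samples.values()))
    n = len(allv)
    k = len(samples)
    ssw = sum(((v - v.mean()) ** 2).sum() for v in samples.values())
    mse = ssw / (n - k)
    rows = []
    for a, b in combinations(samples, 2):
        na, nb = len(samples[a]), len(samples[b])
        diff = samples[a].mean() - samples[b].mean()
        se = np.sqrt(mse * (1 / na + 1 / nb))
        t = diff / se if se > 0 else 0.0
        rows.append(
            {"group1": a, "group2": b, "statistic": float(t),
             "p": float(2 * sps.t.sf(abs(t), n - k)),
             "effect_size_name": "Hedges' g",
             "effect_size_value": hedges_g(samples[a], samples[b])}
        )
    df = pd.DataFrame(rows)
    df["p"] = _adjust(df["p"], adjust)
    return df


# -- the decision tree -----------------------------------------------------

def decide_and_test(
    values,
    labels,
    variable: str = "value",
    alpha: float = ALPHA_GATE,
    posthoc_adjust: str | None = None,
    seed: int | None = None,
) -> StatResult:
    """Run the full test-selection decision tree on one variable.

    ``values``/``labels`` are parallel sequences; NaNs are dropped.  The
    chosen test, its statistic and p-value, the gate outcomes, the branch
    effect size and (for 3–4 groups) the post-hoc table are returned in a
    :class:`StatResult`.
    """
    values = np.asarray(values, float)
    labels = np.asarray(labels)
    keep = ~np.isnan(values)
    values, labels = values[keep], labels[keep]
    uniq = [g for g in pd.unique(labels)]
    samples = {str(g): values[labels == g] for g in uniq}
    samples = {g: v for g, v in samples.items() if len(v) > 0}
    k = len(samples)
    if k < 2:
        raise ValueError("need at least two non-empty groups")
    if k > 4:
        raise ValueError("decision tree supports 2-4 groups")
    if np.ptp(values) == 0:
        raise DegenerateDataError(f"{variable}: all observations identical")

    notes: list[str] = []
    normal = True
    for g, v in samples.items():
        if len(v) < 3:
            warnings.warn(
                f"{variable}: group {g} has n < 3; Shapiro-Wilk undefined, "
                "falling to the non-parametric branch",
                stacklevel=2,
            )
            notes.append(f"group {g}: n < 3, normality untestable")
            normal = False
        elif np.ptp(v) == 0 or sps.shapiro(v).pvalue < alpha:
            normal = False
    var_equal = bool(
        sps.levene(*samples.values(), center="mean").pvalue >= alpha
    )

    names = list(samples)
    posthoc = None
    es_name: str | None
    es_value: float | None

    if k == 2:
        a, b = samples[names[0]], samples[names[1]]
        if normal:
            res = sps.ttest_ind(a, b, equal_var=var_equal)
            test_name = "t-test" if var_equal else "Welch t-test"
            stat, p = res.statistic, res.pvalue
            es_name, es_value = "Cohen's d", cohens_d(a, b)
        else:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            test_name = "Wilcoxon rank-sum"
            stat, p = res.statistic, res.pvalue
            es_name, es_value = "Cliff's delta", cliffs_delta(a, b)
            if not var_equal:
                notes.append("unequal variance under rank-sum test")
    else:
        if normal and var_equal:
            res = sps.f_oneway(*samples.values())
            test_name = "one-way ANOVA"
            stat, p = res.statistic, res.pvalue
            es_name, es_value = "omega-squared", omega_squared(samples.values())
            posthoc = tukey_posthoc(samples)
        elif normal:
            long = pd.DataFrame(
                {"value": values, "group": labels.astype(str)}
            )
            wa = pg.welch_anova(data=long, dv="value", between="group")
            test_name = "Welch ANOVA"
            stat, p = float(wa["F"].iloc[0]), float(wa["p_unc"].iloc[0])
            es_name, es_value = "omega-squared", omega_squared(samples.values())
            posthoc = games_howell_posthoc(samples)
        elif var_equal:
            res = sps.kruskal(*samples.values())
            test_name = "Kruskal-Wallis"
            stat, p = res.statistic, res.pvalue
            es_name = "epsilon-squared"
            es_value = epsilon_squared(float(stat), len(values))
            posthoc = dunn_posthoc(samples, adjust=posthoc_adjust)
        else:
            fp = permutation_ksample(values, labels, seed=seed, variable=variable)
            test_name = fp.test_name
            stat, p = fp.statistic, fp.p
            es_name, es_value = None, None
            notes.extend(fp.notes)
            posthoc = glh_posthoc(samples, adjust=posthoc_adjust)

    return StatResult(
        variable=variable,
        groups=names,
        n_per_group={g: len(v) for g, v in samples.items()},
        test_name=test_name,
        statistic=float(stat),
        p=float(p),
        effect_size_name=es_name,
        effect_size_value=None if es_value is None else float(es_value),
        normal=normal,
        variance_equal=var_equal,
        posthoc=posthoc,
        notes=notes,
    )


# -- within-subject longitudinal tests -------------------------------------

def longitudinal_test(
    matrix: pd.DataFrame, normal: bool | None = None, alpha: float = ALPHA_GATE,
    variable: str = "value",
) -> StatResult:
    """Within-subject change across days (animals × days matrix).

    Repeated-measures ANOVA when the data are treated as normal, Friedman's
    rank test otherwise.  ``normal=None`` gates on Shapiro–Wilk applied to
    each day column.  Rows with missing days are dropped listwise.
    """
    m = matrix.dropna(axis=0)
    if m.shape[0] < matrix.shape[0]:
        warnings.warn(
            f"{matrix.shape[0] - m.shape[0]} subject(s) dropped for missing days",
            stacklevel=2,
        )
    n_sub, n_day = m.shape
    if n_day < 2 or n_sub < 3:
        raise ValueError(f"need >= 2 days and >= 3 subjects, got {m.shape}")
    if normal is None:
        normal = all(
            len(m[c]) >= 3 and np.ptp(m[c]) > 0 and sps.shapiro(m[c]).pvalue >= alpha
            for c in m.columns
        )
    if normal:
        long = m.reset_index(names="subject").melt(
            id_vars="subject", var_name="day", value_name="value"
        )
        aov = pg.rm_anova(data=long, dv="value", within="day", subject="subject")
        stat, p, name = float(aov["F"].iloc[0]), float(aov["p_unc"].iloc[0]), "RM-ANOVA"
    else:
        if np.ptp(m.to_numpy()) == 0 or all(
            np.ptp(m.to_numpy()[i]) == 0 for i in range(n_sub)
        ):
            stat, p, name = 0.0, 1.0, "Friedman"
        else:
            res = sps.friedmanchisquare(*[m[c] for c in m.columns])
            stat, p, name = float(res.statistic), float(res.pvalue), "Friedman"
    return StatResult(
        variable=variable,
        groups=[str(c) for c in m.columns],
        n_per_group={str(c): n_sub for c in m.columns},
        test_name=name,
        statistic=stat,
        p=p,
        effect_size_name=None,
        effect_size_value=None,
        normal=bool(normal),
        variance_equal=True,
    )


def results_to_frame(results: list[StatResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        rows.append(
            {"variable": r.variable, "groups": "|".join(r.groups),
             "n": "|".join(str(r.n_per_group[g]) for g in r.groups),
             "test": r.test_name, "statistic": r.statistic, "p": r.p,
             "effect_size": r.effect_size_name or "",
             "effect_size_value": r.effect_size_value,
             "normal": r.normal, "variance_equal": r.variance_equal,
             "notes": "; ".join(r.notes)}
        )
    return pd.DataFrame(rows)
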