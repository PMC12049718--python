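"""Cumulative-success learning curves and slope-based group comparisons.

For each mouse and task day, the ordered sequence of drinking attempts in
the task's active window is classified as a success (attempt at a currently
correct corner) or a place error.  The running count of successes against
the attempt index forms a learning curve whose ordinary-least-squares slope
estimates the per-attempt success probability: a perfect learner approaches
slope 1, and a mouse choosing uniformly among the four corners (one of
which is rewarded) produces slope 1/4.  Group curves pool animals as
replicates under a shared slope; the by-chance reference is the analytic
line with slope exactly 0.25 and intercept 0 — a constant, never estimated,
so the chance contrast tests the estimated group slope against 0.25 without
fabricating degrees of freedom.

Group-versus-group comparisons use the analysis-of-covariance framework:
a pooled linear model of cumulative successes on attempt index × group, a
global slope-heterogeneity (interaction) test, and pairwise slope
contrasts from the fitted covariance (estimated-marginal-means style).
Because the points of one animal's cumulative curve are strongly
autocorrelated, all pooled-model uncertainties use cluster-robust
covariance with the animal as the cluster — the animal, not the attempt,
is the experimental replicate — which keeps the contrast tests calibrated
under the null.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

CHANCE_SLOPE = 0.25  # 1 rewarded corner of 4; fixed by design


@dataclass(frozen=True)
class CurveFit:
    label: str  # group name or animal tag
    task_id: str
    slope: float
    intercept: float
    slope_se: float
    ci_low: float
    ci_high: float
    n_points: int
    n_animals: int
    df: float  # degrees of freedom of the slope uncertainty


@dataclass(frozen=True)
class CurveComparison:
    contrast: str  # "<group> vs chance" | "<a> vs <b>" | "slope heterogeneity"
    task_id: str
    estimate: float  # slope difference
    ci_low: float
    ci_high: float
    statistic: float
    p: float


def build_curve(successes) -> pd.DataFrame:
    """Cumulative successes against 1-based attempt index.

    ``successes`` is an ordered boolean/0-1 sequence; the result is empty
    for zero attempts and non-decreasing with increments in {0, 1}.
    """
    s = np.asarray(list(successes), dtype=float)
    if s.size and not np.isin(s, (0.0, 1.0)).all():
        raise ValueError("successes must be 0/1 valued")
    return pd.DataFrame(
        {"attempt_index": np.arange(1, s.size + 1), "cum_success": np.cumsum(s)}
    )


def curves_from_attempts(attempts: pd.DataFrame) -> pd.DataFrame:
    """Per animal × task curves from an annotated attempt table.

    Uses active-window attempts ordered by time (the challenge window is
    where the task is performable).  Long format: ``animal_tag, group,
    task_id, attempt_index, cum_success``.
    """
    rows = []
    sub = attempts[attempts["in_active"]]
    for (tag, group, task), cell in sub.groupby(
        ["animal_tag", "group", "task_id"], sort=True
    ):
        cell = cell.sort_values("time", kind="stable")
        curve = build_curve(cell["success"].to_numpy())
        curve.insert(0, "task_id", task)
        curve.insert(0, "group", group)
        curve.insert(0, "animal_tag", tag)
        rows.append(curve)
    if not rows:
        return pd.DataFrame(
            columns=["animal_tag", "group", "task_id", "attempt_index", "cum_success"]
        )
    return pd.concat(rows, ignore_index=True)


def _ols_fit(label, task, x, y, clusters=None) -> CurveFit:
    """OLS of cumulative successes on attempt index.

    With ``clusters`` given (animal tags), the slope uncertainty is
    cluster-robust with the animal as the replicate; otherwise plain OLS
    (single-animal fits, kept for plotting only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = sm.add_constant(x)
    res = sm.OLS(y, X).fit()
    slope, intercept = float(res.params[1]), float(res.params[0])
    n_animals = 1
    if clusters is not None:
        clusters = np.asarray(clusters)
        n_animals = len(np.unique(clusters))
    if clusters is not None and n_animals >= 2:
        # leave-one-animal-out jackknife: the animal is the replicate and
        # points within a curve are autocorrelated, so the naive OLS SE
        # (and the few-cluster sandwich) would understate the uncertainty
        uniq = np.unique(clusters)
        loo = []
        for c in uniq:
            keep = clusters != c
            loo.append(float(sm.OLS(y[keep], X[keep]).fit().params[1]))
        loo = np.asarray(loo)
        g = len(uniq)
        se = float(np.sqrt((g - 1) / g * np.sum((loo - loo.mean()) ** 2)))
        df = float(g - 1)
    else:
        se = float(res.bse[1])
        df = float(res.df_resid)
    half = sps.t.ppf(0.975, df) * se if se > 0 else 0.0
    return CurveFit(
        label=label,
        task_id=task,
        slope=slope,
        intercept=intercept,
        slope_se=se,
        ci_low=slope - half,
        ci_high=slope + half,
        n_points=int(res.nobs),
        n_animals=n_animals,
        df=df,
    )


def fit_curves(curves: pd.DataFrame) -> dict[str, list[CurveFit]]:
    """OLS fits per group (animals pooled as replicates) and per animal.

    Groups (or animals) contributing fewer than two points are skipped
    with a warning row omitted from the output.
    """
    group_fits, animal_fits = [], []
    for (group, task), cell in curves.groupby(["group", "task_id"], sort=True):
        if len(cell) < 2:
            continue
        group_fits.append(
            _ols_fit(group, task, cell["attempt_index"], cell["cum_success"],
                     clusters=cell["animal_tag"])
        )
    for (tag, task), cell in curves.groupby(["animal_tag", "task_id"], sort=True):
        if len(cell) < 2:
            continue
        animal_fits.append(
            _ols_fit(tag, task, cell["attempt_index"], cell["cum_success"])
        )
    return {"group": group_fits, "animal": animal_fits}


def compare_to_chance(fit: CurveFit, chance_slope: float = CHANCE_SLOPE) -> CurveComparison:
    """Two-sided test of H0: group slope equals the by-chance constant."""
    if fit.n_points < 3 or not np.isfinite(fit.slope_se) or fit.slope_se == 0:
        if fit.slope == chance_slope:
            return CurveComparison(
                f"{fit.label} vs chance", fit.task_id, 0.0, 0.0, 0.0, 0.0, 1.0
            )
        raise ValueError(f"degenerate fit for {fit.label}/{fit.task_id}")
    diff = fit.slope - chance_slope
    df = fit.df
    t = diff / fit.slope_se
    p = 2 * sps.t.sf(abs(t), df)
    half = sps.t.ppf(0.975, df) * fit.slope_se
    return CurveComparison(
        contrast=f"{fit.label} vs chance",
        task_id=fit.task_id,
        estimate=diff,
        ci_low=diff - half,
        ci_high=diff + half,
        statistic=t,
        p=float(p),
    )


def compare_groups(curves: pd.DataFrame, task_id: str) -> list[CurveComparison]:
    """Slope-heterogeneity test plus pairwise slope contrasts for one task.

    Fits ``cum_success ~ attempt_index * group`` on the pooled curves,
    reports the interaction F-test as the global comparison, then the
    pairwise slope differences with Wald t contrasts from the fitted
    covariance.  Contrast p-values are invariant to translating the
    attempt index.
    """
    sub = curves[curves["task_id"] == task_id]
    groups = sorted(sub["group"].unique())
    if len(groups) < 2:
        raise ValueError("need at least two groups to compare")
    model = smf.ols("cum_success ~ attempt_index * C(group)", data=sub).fit(
        cov_type="cluster", cov_kwds={"groups": sub["animal_tag"]}, use_t=True
    )
    # global slope-heterogeneity: joint test of all interaction terms
    inter = [n for n in model.params.index if "attempt_index:" in n]
    fres = model.f_test([f"{n} = 0" for n in inter])
    out = [
        CurveComparison(
            contrast="slope heterogeneity",
            task_id=task_id,
            estimate=np.nan,
            ci_low=np.nan,
            ci_high=np.nan,
            statistic=float(fres.fvalue),
            p=float(fres.pvalue),
        )
    ]
    base = groups[0]

    def slope_name(g):
        return None if g == base else f"attempt_index:C(group)[T.{g}]"

    for a, b in combinations(groups, 2):
        expr = (
            f"{slope_name(a)} - {slope_name(b)} = 0"
            if slope_name(a) and slope_name(b)
            else (f"{slope_name(b)} = 0" if slope_name(b) else f"{slope_name(a)} = 0")
        )
        tres = model.t_test(expr)
        est = float(np.squeeze(tres.effect))
        if slope_name(a) is None:
            est = -est  # expr tested b - a; report a - b
            stat = -float(np.squeeze(tres.tvalue))
        else:
            stat = float(np.squeeze(tres.tvalue))
        ci = tres.conf_int()
        lo, hi = float(np.min(ci)), float(np.max(ci))
        if slope_name(a) is None:
            lo, hi = -hi, -lo
        out.append(
            CurveComparison(
                contrast=f"{a} vs {b}",
                task_id=task_id,
                estimate=est,
                ci_low=lo,
                ci_high=hi,
                statistic=stat,
                p=float(np.squeeze(tres.pvalue)),
            )
        )
    return out


def fits_to_frame(fits: dict[str, list[CurveFit]]) -> pd.DataFrame:
    rows = []
    for level, items in fits.items():
        for f in items:
            rows.append({"level": level, **f.__dict__})
    return pd.DataFrame(rows)


def comparisons_to_frame(comps: list[CurveComparison]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in comps])
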