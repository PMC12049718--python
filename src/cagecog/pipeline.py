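"""End-to-end orchestration: raw logs in, tables/plots/run log out."""

from __future__ import annotations

import platform
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .events import CohortTable, VisitEvent
from .io import check_tags, read_cohort, read_visit_log
from .learning import (
    CHANCE_SLOPE,
    compare_groups,
    compare_to_chance,
    comparisons_to_frame,
    curves_from_attempts,
    fit_curves,
    fits_to_frame,
)
from .metrics import METRIC_COLUMNS, aggregate
from .schedule import ChallengePlan, default_plan, plan_from_yaml
from .stats import DegenerateDataError, decide_and_test, results_to_frame


@dataclass
class RunConfig:
    visits: str | Path
    pokes: str | Path
    licks: str | Path
    cohort: str | Path
    out_dir: str | Path
    plan: str | Path | None = None  # YAML; None = bundled default design
    fmt: str = "csv"                # csv | xlsx
    alpha: float = 0.05
    seed: int = 0
    holm: bool = False              # Holm adjustment for post hocs
    make_plots: bool = True
    periods: tuple[str, ...] = ("dark", "light", "total24h", "active")

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.fmt not in ("csv", "xlsx"):
            raise ValueError(f"format must be csv or xlsx, got {self.fmt!r}")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stats_tables(per_animal, alpha, adjust, seed):
    """Decision-tree comparison for every measure × day × period cell."""
    results, posthoc_rows, skipped = [], [], []
    for (day_index, task, period), sub in per_animal.groupby(
        ["day_index", "task_id", "period"], sort=True
    ):
        for measure in METRIC_COLUMNS:
            vals = sub[measure].to_numpy(dtype=float)
            labels = sub["group"].to_numpy()
            keep = ~np.isnan(vals)
            if keep.sum() < 4 or len(pd.unique(labels[keep])) < 2:
                continue
            label = f"{measure}|day{day_index}:{task}|{period}"
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    res = decide_and_test(
                        vals, labels, variable=label, alpha=alpha,
                        posthoc_adjust=adjust, seed=seed,
                    )
            except DegenerateDataError:
                skipped.append(label)
                continue
            results.append(res)
            if res.posthoc is not None:
                ph = res.posthoc.copy()
                ph.insert(0, "variable", label)
                posthoc_rows.append(ph)
    posthoc = (
        pd.concat(posthoc_rows, ignore_index=True)
        if posthoc_rows
        else pd.DataFrame(
            columns=["variable", "group1", "group2", "statistic", "p",
                     "effect_size_name", "effect_size_value"]
        )
    )
    return results_to_frame(results), posthoc, skipped


def _learning_tables(attempts):
    curves = curves_from_attempts(attempts)
    fits = fit_curves(curves)
    contrasts = []
    for f in fits["group"]:
        try:
            contrasts.append(compare_to_chance(f))
        except ValueError:
            continue
    tasks = sorted(curves["task_id"].unique()) if len(curves) else []
    if len(curves) and curves["group"].nunique() >= 2:
        for task in tasks:
            sub = curves[curves["task_id"] == task]
            if sub["group"].nunique() < 2:
                continue
            contrasts.extend(compare_groups(curves, task))
    return curves, fits_to_frame(fits), comparisons_to_frame(contrasts)


def _write(df: pd.DataFrame, out_dir: Path, name: str, fmt: str) -> Path:
    if fmt == "xlsx":
        path = out_dir / f"{name}.xlsx"
        df.to_excel(path, index=False)
    else:
        path = out_dir / f"{name}.csv"
        df.to_csv(path, index=False)
    return path


def run_pipeline(config: RunConfig) -> dict[str, object]:
    """Run the complete analysis and write the output bundle.

    Stages: load → metrics aggregation → learning curves/contrasts →
    decision-tree statistics → tables (+ plots) → run log.  Any stage
    failure aborts with the stage name; files already written for this run
    are removed so the output directory never holds a partial bundle.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    stage = "load"
    try:
        visits = read_visit_log(config.visits, config.pokes, config.licks)
        cohort = read_cohort(config.cohort)
        check_tags(visits, cohort)
        plan = (
            default_plan() if config.plan is None else plan_from_yaml(config.plan)
        )
        _check_groups(plan, cohort)

        stage = "metrics"
        tables = aggregate(visits, plan, cohort)

        stage = "learning"
        curves, fit_table, contrast_table = _learning_tables(tables["attempts"])

        stage = "stats"
        adjust = "holm" if config.holm else None
        stats_table, posthoc_table, skipped = _stats_tables(
            tables["per_animal"], config.alpha, adjust, config.seed
        )

        stage = "write"
        out = {
            "per_animal_metrics": tables["per_animal"],
            "group_summary": tables["group_summary"],
            "welfare": tables["welfare"],
            "learning_curves": curves,
            "curve_fits": fit_table,
            "curve_contrasts": contrast_table,
            "stats_summary": stats_table,
            "posthoc": posthoc_table,
        }
        for name, df in out.items():
            written.append(_write(df, out_dir, name, config.fmt))

        if config.make_plots:
            stage = "plots"
            from .plotting import plot_bundle

            written.extend(
                plot_bundle(
                    tables["group_summary"], curves, fit_table, out_dir / "plots"
                )
            )

        stage = "runlog"
        log = out_dir / "run_log.txt"
        log.write_text(
            "\n".join(
                [
                    f"cagecog {__version__}",
                    f"python {platform.python_version()}",
                    f"numpy {np.__version__} / pandas {pd.__version__}",
                    f"timestamp {datetime.now(timezone.utc).isoformat()}",
                    f"seed {config.seed}",
                    f"alpha {config.alpha}",
                    f"config {config}",
                    f"skipped degenerate comparisons: {len(skipped)}",
                ]
            )
            + "\n"
        )
        written.append(log)
    except Exception as exc:  # noqa: BLE001 — single abort path with stage name
        for p in written:
            try:
                p.unlink()
            except OSError:
                pass
        raise PipelineError(stage, exc) from exc

    return {**out, "written": written, "chance_slope": CHANCE_SLOPE}


def _check_groups(plan: ChallengePlan, cohort: CohortTable) -> None:
    missing = [g for g in cohort.group_names if g not in plan.group_corners]
    if missing:
        raise ValueError(
            f"cohort group(s) {missing} have no corner assignment in the plan"
        )


def analyze_in_memory(
    visits: list[VisitEvent], cohort: CohortTable, plan: ChallengePlan
) -> dict[str, pd.DataFrame]:
    """Library-level entry: metric + learning tables without file output."""
    tables = aggregate(visits, plan, cohort)
    curves, fit_table, contrast_table = _learning_tables(tables["attempts"])
    tables.update(
        learning_curves=curves, curve_fits=fit_table, curve_contrasts=contrast_table
    )
    return tables
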