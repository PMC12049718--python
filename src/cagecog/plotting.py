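"""Quick-inspection figures: bar graphs and learning-curve panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .learning import CHANCE_SLOPE


def plot_bundle(
    group_summary: pd.DataFrame,
    curves: pd.DataFrame,
    fit_table: pd.DataFrame,
    out_dir,
) -> list[Path]:
    """Write one bar graph per measure × period and one curve panel per task.

    Bar graphs show group mean ± SD; learning panels overlay faint
    per-animal curves, the bold pooled group fit with its 95% band, and the
    dashed by-chance line (slope 0.25).  File naming is deterministic:
    ``<measure>_<period>.png`` and ``learning_<task>.png``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    for (measure, period), sub in group_summary.groupby(["measure", "period"]):
        if sub["mean"].isna().all():
            continue
        fig, ax = plt.subplots(figsize=(7, 3.5))
        groups = sorted(sub["group"].unique())
        days = sorted(sub["day_index"].unique())
        width = 0.8 / max(len(groups), 1)
        for gi, g in enumerate(groups):
            cell = sub[sub["group"] == g].set_index("day_index").reindex(days)
            x = np.arange(len(days)) + gi * width
            ax.bar(x, cell["mean"], width=width, label=g,
                   yerr=cell["sd"], capsize=2)
        ax.set_xticks(np.arange(len(days)) + 0.4 - width / 2)
        ax.set_xticklabels(days)
        ax.set_xlabel("task day")
        ax.set_ylabel(measure)
        ax.set_title(f"{measure} — {period} (mean ± SD)")
        ax.legend(fontsize=7)
        path = out_dir / f"{measure}_{period}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        written.append(path)

    if len(curves):
        gfits = fit_table[fit_table["level"] == "group"]
        for task, sub in curves.groupby("task_id"):
            fig, ax = plt.subplots(figsize=(5, 4))
            for _, acurve in sub.groupby("animal_tag"):
                ax.plot(acurve["attempt_index"], acurve["cum_success"],
                        color="gray", alpha=0.3, lw=0.7)
            xmax = sub["attempt_index"].max()
            x = np.array([0, xmax])
            for _, f in gfits[gfits["task_id"] == task].iterrows():
                ax.plot(x, f["intercept"] + f["slope"] * x, lw=2, label=f["label"])
                ax.fill_between(
                    x,
                    f["intercept"] + f["ci_low"] * x,
                    f["intercept"] + f["ci_high"] * x,
                    alpha=0.2,
                )
            ax.plot(x, CHANCE_SLOPE * x, "k--", lw=1.2, label="chance (0.25)")
            ax.set_xlabel("drinking attempt")
            ax.set_ylabel("cumulative successes")
            ax.set_title(task)
            ax.legend(fontsize=7)
            path = out_dir / f"learning_{task}.png"
            fig.savefig(path, dpi=100)
            plt.close(fig)
            written.append(path)
    return written
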