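"""Cohort-level summary tables and figure-style plots.

Assembles the standard readouts of a context-induced-feeding experiment:
training intake per group and day, test intake in contexts A and B, the
per-group context-discrimination contrast (sign-flip permutation test,
Holm-adjusted across groups), training-test regressions per group and
pooled, and — when behaviour/photometry stage outputs are supplied —
behaviour-percentage and peri-event window tables.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .errors import PhotocifError
from .stats import context_discrimination, group_contrasts, training_test_relation

log = logging.getLogger(__name__)


def assemble_report(
    records: pd.DataFrame,
    behavior_table: pd.DataFrame | None = None,
    window_tables: dict[str, pd.DataFrame] | None = None,
    alpha: float = 0.05,
    resamples: int = 10000,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Build the summary-table bundle for one cohort.

    Returns a dict of DataFrames: ``training_intake``, ``test_intake``,
    ``discrimination``, ``train_test_relation`` plus any behaviour /
    peri-event tables passed through.  Missing sessions are tolerated and
    flagged in the log; an empty cohort raises.
    """
    if records is None or not len(records):
        raise PhotocifError("empty cohort: no intake records")

    tables: dict[str, pd.DataFrame] = {}

    training = records[records["phase"] == "training"]
    if len(training):
        tables["training_intake"] = (
            training.groupby(["group", "day"])["intake_g"]
            .agg(mean="mean", sem="sem", n="count")
            .reset_index()
        )

    test = records[records["phase"] == "test"]
    if len(test):
        tables["test_intake"] = (
            test.groupby(["group", "context"])["intake_g"]
            .agg(mean="mean", sem="sem", n="count")
            .reset_index()
        )
        disc = context_discrimination(records)
        tables["discrimination"] = group_contrasts(
            disc, resamples=resamples, seed=seed, alpha=alpha
        )

        if len(training):
            rel_rows = []
            train_mean = training.groupby("mouse")["intake_g"].mean()
            merged = disc.set_index("mouse").join(train_mean.rename("train_g"))
            for label, sub in [("pooled", merged)] + list(merged.groupby("group")):
                if len(sub) < 3 or np.ptp(sub["train_g"].to_numpy()) == 0:
                    log.info("skipping degenerate regression for %s", label)
                    continue
                slope, intercept, r2 = training_test_relation(
                    sub["train_g"].to_numpy(), sub["diff_g"].to_numpy()
                )
                rel_rows.append((label, len(sub), slope, intercept, r2))
            tables["train_test_relation"] = pd.DataFrame(
                rel_rows, columns=["group", "n", "slope", "intercept", "r2"]
            )
    else:
        log.warning("no test-phase records; discrimination tables omitted")

    if behavior_table is not None and len(behavior_table):
        tables["behavior"] = behavior_table.copy()
    if window_tables:
        for name, tab in window_tables.items():
            tables[f"windows_{name}"] = tab.copy()
    return tables


def plot_report(tables: dict[str, pd.DataFrame], outdir) -> list:
    """Write summary figures (PNG) mirroring the standard panel layouts."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if "training_intake" in tables:
        fig, ax = plt.subplots(figsize=(4, 3))
        for group, sub in tables["training_intake"].groupby("group"):
            ax.errorbar(sub["day"], sub["mean"], yerr=sub["sem"], label=group, marker="o")
        ax.set_xlabel("training day")
        ax.set_ylabel("intake (g)")
        ax.set_xticks([1, 2, 3])
        ax.legend(fontsize=7)
        fig.tight_layout()
        p = outdir / "training_intake.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if "test_intake" in tables:
        fig, ax = plt.subplots(figsize=(4, 3))
        tab = tables["test_intake"].pivot(index="group", columns="context", values="mean")
        tab.plot.bar(ax=ax, rot=0)
        ax.set_ylabel("20-min test intake (g)")
        fig.tight_layout()
        p = outdir / "test_intake.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)

    if "discrimination" in tables:
        fig, ax = plt.subplots(figsize=(4, 3))
        tab = tables["discrimination"]
        ax.bar(tab["group"], tab["mean_diff_g"], yerr=tab["sem_g"], color="tab:gray")
        ax.axhline(0, color="k", lw=0.8)
        ax.set_ylabel("context discrimination A−B (g)")
        fig.tight_layout()
        p = outdir / "discrimination.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
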