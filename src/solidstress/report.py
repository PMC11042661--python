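"""Assemble summary tables, comparison tables and figure panels.

The report bundles, per index: a mean ± SEM summary row per group, all
pairwise two-group t-tests (or a one-way ANOVA when more than two
groups are present), and a bar-with-scatter panel.  Every CSV carries
the provenance (configuration digest) of the indices it summarizes, and
re-running with the same inputs produces byte-identical CSVs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from itertools import combinations
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .io import RunConfig
from .stats import compare_many_groups, compare_two_groups

INDEX_COLUMNS = ("dn_um", "ra", "km_per_mm")


def config_digest(config: RunConfig) -> str:
    payload = json.dumps(dataclasses.asdict(config), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:12]


def summarize_groups(table: pd.DataFrame, index_cols=INDEX_COLUMNS) -> pd.DataFrame:
    rows = []
    for (group,), sub in table.groupby(["group"], sort=True):
        for col in index_cols:
            vals = sub[col].dropna().to_numpy(dtype=float)
            rows.append(
                {
                    "group": group,
                    "index": col,
                    "n": vals.size,
                    "mean": vals.mean() if vals.size else np.nan,
                    "sem": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
                }
            )
    return pd.DataFrame(rows)


def _comparison_rows(table: pd.DataFrame, index_cols, test: str) -> pd.DataFrame:
    groups = sorted(table["group"].unique())
    rows = []
    for col in index_cols:
        by_group = {g: table.loc[table["group"] == g, col].dropna().to_numpy(dtype=float) for g in groups}
        if test == "anova" and len(groups) > 2:
            res = compare_many_groups(list(by_group.values()), labels=groups)
            rows.append(
                {"index": col, "comparison": " vs ".join(groups), "test": "anova",
                 "statistic": res.statistic, "p_value": res.p_value}
            )
        else:
            for ga, gb in combinations(groups, 2):
                res = compare_two_groups(by_group[ga], by_group[gb], method=test, labels=(ga, gb))
                rows.append(
                    {"index": col, "comparison": f"{ga} vs {gb}", "test": test,
                     "statistic": res.statistic, "p_value": res.p_value}
                )
    return pd.DataFrame(rows)


def _bar_scatter_panel(table: pd.DataFrame, col: str, path: Path) -> None:
    groups = sorted(table["group"].unique())
    fig, ax = plt.subplots(figsize=(1.2 * len(groups) + 1.5, 3))
    rng = np.random.default_rng(0)
    for i, g in enumerate(groups):
        vals = table.loc[table["group"] == g, col].dropna().to_numpy(dtype=float)
        mean = vals.mean()
        sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
        ax.bar(i, mean, width=0.6, color="lightsteelblue", edgecolor="k", zorder=1)
        ax.errorbar(i, mean, yerr=sem, color="k", capsize=4, zorder=3)
        ax.scatter(i + rng.uniform(-0.12, 0.12, vals.size), vals, s=14, color="k", zorder=2)
    ax.set_xticks(range(len(groups)), groups)
    ax.set_ylabel(col)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def build_report(
    config: RunConfig,
    table: pd.DataFrame,
    out_dir: str | Path,
    index_cols=INDEX_COLUMNS,
    test: str = "welch",
) -> dict[str, Path]:
    """Write summary/comparison CSVs and one panel per index.

    ``table`` needs a ``group`` column plus the index columns.  Returns
    the paths written.  An empty table is an error, never an empty
    report.
    """
    if table.empty:
        raise ValueError("empty table: nothing to report")
    missing = [c for c in ("group", *index_cols) if c not in table.columns]
    if missing:
        raise ValueError(f"table is missing columns {missing}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    digest = config_digest(config)

    summary = summarize_groups(table, index_cols)
    summary["config"] = digest
    summary_path = out_dir / "summary.csv"
    summary.to_csv(summary_path, index=False, float_format="%.10g")

    comparisons = _comparison_rows(table, index_cols, test)
    comparisons["config"] = digest
    comp_path = out_dir / "comparisons.csv"
    comparisons.to_csv(comp_path, index=False, float_format="%.10g")

    paths = {"summary": summary_path, "comparisons": comp_path}
    for col in index_cols:
        p = out_dir / f"panel_{col}.png"
        _bar_scatter_panel(table, col, p)
        paths[f"panel_{col}"] = p
    return paths
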