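"""Group summaries and nonparametric comparisons for morphometry tables.

Measurements of synaptic structures are typically right-skewed and compared
between groups (cortical layers, conditions) without distributional
assumptions: an omnibus Kruskal-Wallis H test followed by pairwise two-sided
Mann-Whitney U tests, with Holm adjustment across the pairwise family.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["summarize", "compare_groups", "GroupComparison", "plot_group_box"]

#: Exact U distribution up to this per-group size (when ties are absent);
#: tie-corrected normal approximation beyond.
EXACT_U_MAX_N = 20


def summarize(
    table: pd.DataFrame,
    group_by: str,
    values: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-group descriptive statistics for each numeric column.

    Returns one row per (group, variable) with n, mean, sample SD, median,
    IQR, min, max and skewness.
    """
    if group_by not in table.columns:
        raise ValueError(f"no column {group_by!r} in table")
    if values is None:
        values = [
            c
            for c in table.columns
            if c != group_by and pd.api.types.is_numeric_dtype(table[c])
        ]
    if not values:
        raise ValueError("no numeric columns to summarize")
    rows = []
    for key, sub in table.groupby(group_by, sort=True):
        if len(sub) == 0:
            raise ValueError(f"empty group {key!r}")
        for col in values:
            x = sub[col].dropna().to_numpy(dtype=float)
            n = len(x)
            rows.append(
                {
                    "group": key,
                    "variable": col,
                    "n": n,
                    "mean": x.mean() if n else np.nan,
                    "sd": x.std(ddof=1) if n > 1 else 0.0,
                    "median": np.median(x) if n else np.nan,
                    "iqr": float(np.subtract(*np.percentile(x, [75, 25]))) if n else np.nan,
                    "min": x.min() if n else np.nan,
                    "max": x.max() if n else np.nan,
                    "skewness": float(stats.skew(x, bias=False)) if n > 2 else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class GroupComparison:
    """Result of an omnibus + post hoc nonparametric comparison."""

    h_statistic: float
    p_value: float
    pairwise: pd.DataFrame  # group_1, group_2, u_statistic, p_raw, p_holm
    groups: list[str]


def _as_groups(values_by_group: Mapping[str, Sequence[float]]) -> dict[str, np.ndarray]:
    return {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}


def compare_groups(values_by_group: Mapping[str, Sequence[float]]) -> GroupComparison:
    """Kruskal-Wallis H (tie-corrected) with Holm-adjusted post hoc U tests.

    Pairwise Mann-Whitney U tests are two-sided, exact for group sizes up to
    20 when the pooled sample has no ties, and use the tie-corrected normal
    approximation otherwise.  Holm adjustment is applied across all pairs.
    """
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    for name, x in groups.items():
        if len(x) < 2:
            raise ValueError(f"group {name!r} has fewer than 2 observations")

    pooled = np.concatenate(list(groups.values()))
    if np.ptp(pooled) == 0:
        warnings.warn(
            "all values identical across groups; H statistic degenerate",
            stacklevel=2,
        )
        names = list(groups)
        pairs = list(itertools.combinations(names, 2))
        pairwise = pd.DataFrame(
            {
                "group_1": [p[0] for p in pairs],
                "group_2": [p[1] for p in pairs],
                "u_statistic": [
                    len(groups[p[0]]) * len(groups[p[1]]) / 2.0 for p in pairs
                ],
                "p_raw": 1.0,
                "p_holm": 1.0,
            }
        )
        return GroupComparison(0.0, 1.0, pairwise, names)

    h, p = stats.kruskal(*groups.values())

    names = list(groups)
    pairs = list(itertools.combinations(names, 2))
    u_stats, p_raw = [], []
    has_ties = len(np.unique(pooled)) < len(pooled)
    for g1, g2 in pairs:
        x, y = groups[g1], groups[g2]
        if max(len(x), len(y)) <= EXACT_U_MAX_N and not has_ties:
            method = "exact"
        else:
            method = "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        u_stats.append(float(res.statistic))
        p_raw.append(float(res.pvalue))
    if pairs:
        _, p_holm, _, _ = multipletests(p_raw, method="holm")
    else:
        p_holm = []
    pairwise = pd.DataFrame(
        {
            "group_1": [p[0] for p in pairs],
            "group_2": [p[1] for p in pairs],
            "u_statistic": u_stats,
            "p_raw": p_raw,
            "p_holm": list(p_holm),
        }
    )
    return GroupComparison(float(h), float(p), pairwise, names)


def plot_group_box(
    table: pd.DataFrame, group_by: str, value: str, path
) -> None:
    """Per-group box plot saved as SVG or PNG (by file extension)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = sorted(table[group_by].dropna().unique())
    data = [table.loc[table[group_by] == g, value].dropna() for g in groups]
    ax.boxplot(data, tick_labels=[str(g) for g in groups])
    ax.set_xlabel(group_by)
    ax.set_ylabel(value)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
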