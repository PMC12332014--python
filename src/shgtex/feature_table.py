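"""Feature-table assembly, cleaning, and group-wise statistics.

Feature records live in a tidy pandas DataFrame with one row per
(image, channel, angle) datapoint: the six texture features plus the labels
channel / group / diagnosis / patient_id / field_id / angle_deg.

Cleaning removes rows with missing or non-finite features ("blanks"), then
flags extreme outliers per class and per feature with Tukey IQR fences at
k = 3 by default — a scale-free rule applied identically to features whose
magnitudes differ by orders of magnitude. Every removal is logged with its
reason so the audit trail survives the pipeline.

Group summaries report per-feature mean, SD and n for the two classes of a
comparison, a two-sided Welch t-test p-value, the conventional star code
(* p<0.05, ** p<0.01, *** p<0.001), and a Holm-corrected p-value column for
transparency (the stars themselves are per-feature, uncorrected).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .texture import FEATURE_NAMES

LABEL_COLUMNS = ("channel", "group", "diagnosis", "patient_id", "field_id", "angle_deg")

#: the four pairwise models; each class selector is a (group, diagnosis) pair
COMPARISONS: dict[str, tuple[tuple[str, str], tuple[str, str]]] = {
    "group1": (("group1", "primary_SCC"), ("group1", "metachronous_HGD")),
    "group2": (("group2", "primary_HGD"), ("group2", "metachronous_HGD")),
    "first_diagnosis": (("group1", "primary_SCC"), ("group2", "primary_HGD")),
    "second_diagnosis": (
        ("group1", "metachronous_HGD"),
        ("group2", "metachronous_HGD"),
    ),
}


class StatisticsError(ValueError):
    """Raised when a comparison class is too small to summarize."""


@dataclass
class GroupComparison:
    """Descriptive statistics for one pairwise model.

    ``table`` has one row per feature with columns mean/sd/n per class,
    ``p_value``, ``p_holm``, and ``stars``.
    """

    name: str
    class_a: tuple[str, str]
    class_b: tuple[str, str]
    table: pd.DataFrame


def records_to_frame(records: list[dict]) -> pd.DataFrame:
    """Stack per-angle record dicts into the tidy feature DataFrame."""
    return pd.DataFrame.from_records(records)


def star_code(p: float) -> str:
    """Significance stars at the conventional 0.05 / 0.01 / 0.001 levels."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


def holm_adjust(p_values: np.ndarray) -> np.ndarray:
    """Holm step-down adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    adjusted = np.empty(m)
    running_max = 0.0
    for rank, idx in enumerate(order):
        val = min(1.0, (m - rank) * p[idx])
        running_max = max(running_max, val)
        adjusted[idx] = running_max
    return adjusted


def select_class(df: pd.DataFrame, selector: tuple[str, str]) -> pd.DataFrame:
    """Rows belonging to one (group, diagnosis) class."""
    group, diagnosis = selector
    return df[(df["group"] == group) & (df["diagnosis"] == diagnosis)]


def clean_records(
    df: pd.DataFrame,
    iqr_k: float = 3.0,
    class_cols: tuple[str, ...] = ("channel", "group", "diagnosis"),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Remove blank rows, then extreme per-class per-feature outliers.

    A row is "blank" if any feature is missing or non-finite. Surviving rows
    are screened feature-by-feature within each class (default class =
    channel x group x diagnosis): values outside
    ``[Q1 - k*IQR, Q3 + k*IQR]`` flag the row for removal.

    Returns
    -------
    (cleaned, log) : pair of DataFrames
        ``log`` has one row per removed record with columns ``reason``
        ("blank" or "outlier"), ``feature`` (the first offending feature),
        and ``value``; ``len(log) == len(df) - len(cleaned)`` always.
    """
    if iqr_k <= 0:
        raise ValueError(f"iqr_k must be positive, got {iqr_k}")
    log_rows: list[dict] = []
    if df.empty:
        return df.copy(), pd.DataFrame(columns=["index", "reason", "feature", "value"])

    feats = df[list(FEATURE_NAMES)].apply(pd.to_numeric, errors="coerce")
    finite = np.isfinite(feats.to_numpy()).all(axis=1)
    for idx in df.index[~finite]:
        row = feats.loc[idx]
        bad = next(name for name in FEATURE_NAMES if not np.isfinite(row[name]))
        log_rows.append(
            {"index": idx, "reason": "blank", "feature": bad, "value": row[bad]}
        )
    kept = df.loc[finite].copy()

    outlier_idx: dict = {}
    group_iter = (
        kept.groupby(list(class_cols), observed=True, sort=True)
        if class_cols
        else [((), kept)]
    )
    for _, sub in group_iter:
        for name in FEATURE_NAMES:
            vals = sub[name].astype(float)
            q1, q3 = vals.quantile([0.25, 0.75])
            iqr = q3 - q1
            lo, hi = q1 - iqr_k * iqr, q3 + iqr_k * iqr
            flagged = sub.index[(vals < lo) | (vals > hi)]
            for idx in flagged:
                outlier_idx.setdefault(idx, (name, float(vals.loc[idx])))
    for idx in sorted(outlier_idx, key=list(kept.index).index):
        name, value = outlier_idx[idx]
        log_rows.append(
            {"index": idx, "reason": "outlier", "feature": name, "value": value}
        )
    cleaned = kept.drop(index=list(outlier_idx))
    log = pd.DataFrame(log_rows, columns=["index", "reason", "feature", "value"])
    return cleaned, log


def summarize_comparison(
    df: pd.DataFrame, comparison: str, channel: str | None = None
) -> GroupComparison:
    """Per-feature descriptive statistics and Welch t-tests for one model.

    Raises :class:`StatisticsError` if either class has fewer than two
    records after filtering.
    """
    if comparison not in COMPARISONS:
        raise ValueError(
            f"unknown comparison {comparison!r}; choose from {sorted(COMPARISONS)}"
        )
    sel_a, sel_b = COMPARISONS[comparison]
    sub = df if channel is None else df[df["channel"] == channel]
    a = select_class(sub, sel_a)
    b = select_class(sub, sel_b)
    for selector, cls in ((sel_a, a), (sel_b, b)):
        if len(cls) < 2:
            raise StatisticsError(
                f"class {selector} has {len(cls)} record(s); need at least 2"
            )
    rows = []
    for name in FEATURE_NAMES:
        va = a[name].astype(float).to_numpy()
        vb = b[name].astype(float).to_numpy()
        if np.allclose(va.var(), 0) and np.allclose(vb.var(), 0):
            p = 1.0 if np.isclose(va.mean(), vb.mean()) else 0.0
        else:
            p = float(stats.ttest_ind(va, vb, equal_var=False).pvalue)
        rows.append(
            {
                "feature": name,
                "mean_a": va.mean(),
                "sd_a": va.std(ddof=1),
                "n_a": va.size,
                "mean_b": vb.mean(),
                "sd_b": vb.std(ddof=1),
                "n_b": vb.size,
                "p_value": p,
            }
        )
    table = pd.DataFrame(rows)
    table["p_holm"] = holm_adjust(table["p_value"].to_numpy())
    table["stars"] = table["p_value"].map(star_code)
    return GroupComparison(comparison, sel_a, sel_b, table)


def plot_comparison(gc: GroupComparison, path) -> None:
    """Write a mean +/- SD bar chart with significance stars (PNG/SVG)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    t = gc.table
    x = np.arange(len(t))
    width = 0.38
    fig, ax = plt.subplots(figsize=(9, 4.5))
    ax.bar(x - width / 2, t["mean_a"], width, yerr=t["sd_a"], capsize=3,
           label=f"{gc.class_a[0]}/{gc.class_a[1]}")
    ax.bar(x + width / 2, t["mean_b"], width, yerr=t["sd_b"], capsize=3,
           label=f"{gc.class_b[0]}/{gc.class_b[1]}")
    tops = np.maximum(t["mean_a"] + t["sd_a"], t["mean_b"] + t["sd_b"])
    for xi, (top, stars) in enumerate(zip(tops, t["stars"])):
        if stars != "ns":
            ax.text(xi, top * 1.02, stars, ha="center", fontsize=11)
    ax.set_xticks(x, t["feature"], rotation=30)
    ax.set_ylabel("feature value")
    ax.set_title(gc.name)
    ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
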