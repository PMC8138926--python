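"""Cohort contingency statistics and 1-D hierarchical clustering.

Cross-tabulation of marker calls against diagnosis groups, the two association
tests used for those tables (two-sided Fisher exact and Pearson chi-squared
without continuity correction), the per-group marker-frequency report, and the
agglomerative clustering of case intensity scores whose k = 2 cut defines the
NL/NR partition.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.cluster import hierarchy


def crosstab(cohort: pd.DataFrame, row_var: str, col_var: str) -> pd.DataFrame:
    """Contingency table of two case variables with deterministic label order."""
    for var in (row_var, col_var):
        if var not in cohort.columns:
            raise KeyError(f"unknown cohort variable: {var!r}")
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    table = pd.crosstab(cohort[row_var], cohort[col_var])
    return table.sort_index(axis=0).sort_index(axis=1)


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table.

    Two-sided by the standard small-sample convention: the p-value sums the
    hypergeometric probabilities of all tables with the observed margins whose
    probability does not exceed the observed table's.
    """
    arr = np.asarray(table)
    if arr.shape != (2, 2):
        raise ValueError(f"Fisher exact requires a 2x2 table, got shape {arr.shape}")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if (arr.sum(axis=0) == 0).any() or (arr.sum(axis=1) == 0).any():
        raise ValueError("all margins must be positive")
    return float(sps.fisher_exact(arr, alternative="two-sided").pvalue)


def chi_squared(table) -> tuple[float, int, float]:
    """Pearson chi-squared test without continuity correction.

    Returns ``(statistic, df, p)`` with df = (R-1)(C-1). Raises on tables with
    a zero expected cell or fewer than two rows/columns.
    """
    arr = np.asarray(table, dtype=np.float64)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("chi-squared requires an RxC table with R, C >= 2")
    if arr.sum() <= 0:
        raise ValueError("empty table")
    expected = np.outer(arr.sum(axis=1), arr.sum(axis=0)) / arr.sum()
    if (expected == 0).any():
        raise ValueError("zero expected cell count")
    res = sps.chi2_contingency(arr, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def hcluster_scores(scores, k: int = 2, method: str = "average"):
    """Agglomerative clustering of 1-D scores; cut into k clusters.

    Euclidean distance on the raw scores with the given linkage (average by
    default). Returns ``(Z, labels)`` where Z is the scipy linkage matrix and
    labels are integer cluster ids (1..k).
    """
    scores = np.asarray(scores, dtype=np.float64).ravel()
    if scores.size < k:
        raise ValueError(f"need at least k={k} points, got {scores.size}")
    if np.unique(scores).size < k:
        raise ValueError(f"need at least k={k} distinct scores")
    Z = hierarchy.linkage(scores.reshape(-1, 1), method=method, metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    if np.unique(labels).size != k:
        raise ValueError(f"could not cut the dendrogram into exactly {k} clusters")
    return Z, labels


def dendrogram_newick(Z, leaf_names=None) -> str:
    """Render a scipy linkage matrix as a Newick-like nested string."""
    tree = hierarchy.to_tree(Z)
    n = tree.get_count()
    names = leaf_names if leaf_names is not None else [str(i) for i in range(n)]

    def walk(node):
        if node.is_leaf():
            return str(names[node.id])
        return f"({walk(node.left)},{walk(node.right)}):{node.dist:.4g}"

    return walk(tree) + ";"


def marker_frequency_report(cohort: pd.DataFrame,
                            markers=("h3k27me3", "atrx", "p53")) -> pd.DataFrame:
    """Per-diagnosis-group marker-state proportions with counts.

    One row per (diagnosis group, marker, state): numerator, denominator and
    proportion, where the denominator excludes cases with a missing (NA) state.
    """
    if len(cohort) == 0:
        raise ValueError("empty cohort")
    rows = []
    for group, sub in cohort.groupby("diagnosis_group", sort=True):
        for marker in markers:
            states = sub[marker][sub[marker] != "NA"]
            denom = len(states)
            if denom == 0:
                continue
            for state, num in states.value_counts().sort_index().items():
                rows.append(
                    {
                        "diagnosis_group": group,
                        "marker": marker,
                        "state": state,
                        "numerator": int(num),
                        "denominator": denom,
                        "proportion": num / denom,
                    }
                )
    return pd.DataFrame(rows)


def marker_frequency(report: pd.DataFrame, group: str, marker: str, state: str):
    """Look up (numerator, denominator, proportion) in a frequency report."""
    sel = report[
        (report["diagnosis_group"] == group)
        & (report["marker"] == marker)
        & (report["state"] == state)
    ]
    if len(sel) == 0:
        denom_sel = report[
            (report["diagnosis_group"] == group) & (report["marker"] == marker)
        ]
        if len(denom_sel) == 0:
            raise KeyError(f"no rows for group={group!r} marker={marker!r}")
        return 0, int(denom_sel["denominator"].iloc[0]), 0.0
    row = sel.iloc[0]
    return int(row["numerator"]), int(row["denominator"]), float(row["proportion"])
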