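"""Inferential statistics for the clinical covariate table.

Group differences between patients with and without esophageal fistula are
tested with the Pearson chi-squared test (categorical covariates, no
continuity correction — the convention of mainstream clinical statistics
software) and the Kruskal-Wallis rank test (ordered or continuous
covariates).  Categories that are empty in both groups (e.g. a tumor stage
no patient has) are dropped before testing.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["ContingencyTable", "pearson_chi2", "kruskal_wallis", "table1_report"]


@dataclass(frozen=True)
class ContingencyTable:
    """An outcome-by-category count table (rows: EF / NEF)."""

    counts: np.ndarray
    row_labels: tuple[str, ...] = ("EF", "NEF")
    col_labels: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        if counts.ndim != 2:
            raise ValueError("contingency table must be 2D")
        if (counts < 0).any():
            raise ValueError("counts must be non-negative")
        if counts.sum() == 0:
            raise ValueError("contingency table is all zero")
        cols = self.col_labels or tuple(f"c{i}" for i in range(counts.shape[1]))
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "col_labels", cols)


def pearson_chi2(
    table: ContingencyTable, drop_empty: bool = True
) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence without continuity correction.

    Returns ``(statistic, df, p)``.  All-zero rows/columns are dropped first
    when ``drop_empty`` (default) — required when a category exists in the
    coding but no patient falls in it.
    """
    counts = table.counts
    if drop_empty:
        counts = counts[counts.sum(axis=1) > 0][:, counts.sum(axis=0) > 0]
    if counts.shape[0] < 2 or counts.shape[1] < 2:
        raise ValueError(
            "table collapses to a single category; chi-squared is undefined"
        )
    stat, p, df, _ = stats.chi2_contingency(counts, correction=False)
    return float(stat), int(df), float(p)


def kruskal_wallis(*groups) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction (chi-squared approximation).

    Identical values across all groups give ``H = 0, p = 1`` by convention.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("groups must be non-empty")
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    h, p = stats.kruskal(*arrays)
    return float(h), float(p)


def table1_report(tables: dict[str, ContingencyTable]) -> pd.DataFrame:
    """Chi-squared report over a set of named contingency tables."""
    rows = []
    for name, tab in tables.items():
        stat, df, p = pearson_chi2(tab)
        rows.append(
            {"covariate": name, "statistic": stat, "df": df, "p": p,
             "test": "pearson_chi2"}
        )
    return pd.DataFrame(rows)
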