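"""Clinicopathologic association tests between subtypes.

Reproduces the contingency-table battery of a subtype characterization
table: per-subtype counts with within-group percentages, Fisher's exact
test for 2x2 tables (two-sided, by point-probability summation), Pearson
chi-square for larger tables, and the Kruskal-Wallis rank test for
continuous covariates.  All tests are overridable by name.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)


@dataclass
class ContingencyTable:
    """Counts of a categorical covariate (rows) by subtype (columns)."""

    counts: pd.DataFrame  # r x c non-negative integers
    percentages: pd.DataFrame  # within-column percent, one decimal

    def __post_init__(self) -> None:
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be non-negative")
        if self.counts.to_numpy().sum() == 0:
            raise ValueError("contingency table is empty")


def crosstab(clinical: pd.DataFrame, covariate: str, labels) -> ContingencyTable:
    """Cross-tabulate a categorical covariate against subtype labels.

    Percentages use the subtype size as denominator and are rounded to one
    decimal, matching clinical-table convention.
    """
    if covariate not in clinical.columns:
        raise KeyError(f"unknown covariate {covariate!r}")
    labels = np.asarray(labels)
    if len(labels) != len(clinical):
        raise ValueError("labels must cover all samples")
    counts = pd.crosstab(clinical[covariate], pd.Series(labels, name="subtype"))
    pct = (100.0 * counts / counts.sum(axis=0)).round(1)
    return ContingencyTable(counts=counts, percentages=pct)


def categorical_test(table: ContingencyTable | pd.DataFrame | np.ndarray, method: str = "auto") -> float:
    """P-value for association in a contingency table.

    ``auto`` uses Fisher's exact test for 2x2 tables and Pearson chi-square
    otherwise; ``fisher`` and ``chi2`` force a method.  A degenerate table
    (some margin entirely zero) carries no information and returns p = 1.
    """
    counts = table.counts if isinstance(table, ContingencyTable) else pd.DataFrame(table)
    arr = counts.to_numpy(dtype=int)
    if arr.sum() == 0 or np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        log.info("degenerate contingency table (zero margin); p = 1")
        return 1.0
    if method == "auto":
        method = "fisher" if arr.shape == (2, 2) else "chi2"
    if method == "fisher":
        if arr.shape != (2, 2):
            raise ValueError("Fisher's exact test implemented for 2x2 tables only")
        return float(stats.fisher_exact(arr, alternative="two-sided")[1])
    if method == "chi2":
        return float(stats.chi2_contingency(arr, correction=False)[1])
    raise ValueError(f"unknown method {method!r}")


def kruskal_wallis(values, labels) -> tuple[float, float]:
    """Kruskal-Wallis rank test of a continuous covariate across groups.

    Returns (H, p) with tie correction; a constant covariate has H = 0 and
    p = 1 by convention.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    groups = [values[labels == g] for g in pd.unique(labels)]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("need at least two non-empty groups")
    if np.ptp(values) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def association_battery(
    clinical: pd.DataFrame,
    labels,
    categorical: list[str] | None = None,
    continuous: list[str] | None = None,
    method: str = "auto",
) -> pd.DataFrame:
    """Run the association tests over a list of covariates.

    Returns one row per covariate with the test used and the p-value
    rounded to three decimals for display (an unrounded column is kept).
    """
    categorical = categorical or []
    continuous = continuous or []
    rows = []
    for cov in categorical:
        tab = crosstab(clinical, cov, labels)
        p = categorical_test(tab, method=method)
        used = ("fisher" if tab.counts.shape == (2, 2) else "chi2") if method == "auto" else method
        rows.append({"covariate": cov, "test": used, "p_value": p})
    for cov in continuous:
        if cov not in clinical.columns:
            raise KeyError(f"unknown covariate {cov!r}")
        h, p = kruskal_wallis(clinical[cov].to_numpy(), labels)
        rows.append({"covariate": cov, "test": "kruskal_wallis", "p_value": p})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["p_display"] = out["p_value"].round(3)
    return out
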