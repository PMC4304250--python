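"""SAM-style one-vs-rest differential expression with permutation q-values.

The per-gene statistic is the regularized t-like

    d_i = (mean_case - mean_rest) / (s_i + s0)

with s_i the pooled standard error of the mean difference and s0 a fudge
factor (default: median of the s_i) that keeps low-variance genes from
dominating.  False discovery rates are estimated by permuting the case
labels: for each gene's |d| threshold the median false-call count over
permutations, divided by the number of genes called at that threshold,
gives the q-value, monotonized to be non-increasing in |d|.

Marker selection follows the "q = 0, up-regulated, order by fold change,
top 20" rule; fold change is the ratio of linear-scale (2**x) group means.
"""

from __future__ import annotations

import logging
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


def _group_stats(X: np.ndarray, case_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    case = X[:, case_mask]
    rest = X[:, ~case_mask]
    n1, n2 = case.shape[1], rest.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each side needs at least two samples")
    diff = case.mean(axis=1) - rest.mean(axis=1)
    ss = ((case - case.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    ss += ((rest - rest.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s = np.sqrt((1.0 / n1 + 1.0 / n2) * ss / (n1 + n2 - 2))
    return diff, s, np.array([n1, n2])


def sam_statistic(X, case_mask, s0: float | None = None) -> np.ndarray:
    """Per-gene SAM d statistic for case vs rest.

    ``s0=None`` uses the median of the per-gene pooled standard errors.
    """
    X = np.asarray(X, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    diff, s, _ = _group_stats(X, case_mask)
    if s0 is None:
        s0 = float(np.median(s))
    return diff / (s + s0)


def _permutation_masks(n: int, n_case: int, n_perm: int, seed: int) -> np.ndarray:
    """n_perm boolean masks with n_case True entries each.

    Falls back to full enumeration when fewer than n_perm distinct masks
    exist.
    """
    total = comb(n, n_case)
    if total <= n_perm:
        log.info("only %d distinct permutations available; enumerating all", total)
        masks = np.zeros((total, n), dtype=bool)
        for i, idx in enumerate(combinations(range(n), n_case)):
            masks[i, list(idx)] = True
        return masks
    rng = np.random.default_rng(seed)
    masks = np.zeros((n_perm, n), dtype=bool)
    for i in range(n_perm):
        masks[i, rng.choice(n, size=n_case, replace=False)] = True
    return masks


def sam_qvalues(X, case_mask, n_perm: int = 1000, seed: int = 0, s0: float | None = None) -> np.ndarray:
    """Permutation FDR q-value per gene.

    The fudge factor s0 is fixed from the observed data and reused for every
    permutation so observed and null d share a scale.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    X = np.asarray(X, dtype=float)
    case_mask = np.asarray(case_mask, dtype=bool)
    _, s, _ = _group_stats(X, case_mask)
    if s0 is None:
        s0 = float(np.median(s))
    d_obs = np.abs(sam_statistic(X, case_mask, s0=s0))

    masks = _permutation_masks(X.shape[1], int(case_mask.sum()), n_perm, seed)
    n_genes = X.shape[0]
    # false-call counts: per permutation, how many null |d| meet each gene's threshold
    false_counts = np.empty((len(masks), n_genes), dtype=np.int32)
    for p, mask in enumerate(masks):
        d_null = np.sort(np.abs(sam_statistic(X, mask, s0=s0)))
        false_counts[p] = n_genes - np.searchsorted(d_null, d_obs, side="left")
    median_false = np.median(false_counts, axis=0)
    called = n_genes - np.searchsorted(np.sort(d_obs), d_obs, side="left")
    q = np.minimum(median_false / called, 1.0)

    # q_i = min FDR over thresholds t <= |d_i|: cumulative min along
    # ascending |d|, which makes q non-increasing in |d|
    order = np.argsort(d_obs, kind="stable")
    q[order] = np.minimum.accumulate(q[order])
    return q


def sam_table(
    X: pd.DataFrame,
    labels,
    subtype: int,
    n_perm: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Full marker table for one subtype vs the rest.

    ``X`` is a log2-scale genes x samples DataFrame.  Fold change is
    computed on the linear scale as mean(2**x, case) / mean(2**x, rest).
    """
    labels = np.asarray(labels)
    case_mask = labels == subtype
    values = X.to_numpy(dtype=float)
    d = sam_statistic(values, case_mask)
    q = sam_qvalues(values, case_mask, n_perm=n_perm, seed=seed)
    linear = np.exp2(values)
    fc = linear[:, case_mask].mean(axis=1) / linear[:, ~case_mask].mean(axis=1)
    return pd.DataFrame(
        {
            "gene_id": X.index,
            "d_stat": d,
            "fold_change": fc,
            "q_value": q,
            "subtype": subtype,
        }
    ).reset_index(drop=True)


def select_markers(marker_table: pd.DataFrame, top_n: int = 20) -> pd.DataFrame:
    """Up-regulated markers: q = 0 and fold change > 1, ordered by fold
    change descending, truncated to ``top_n``."""
    qualifying = marker_table[(marker_table["q_value"] == 0) & (marker_table["fold_change"] > 1)]
    qualifying = qualifying.sort_values("fold_change", ascending=False, kind="stable")
    if len(qualifying) < top_n:
        log.info("only %d genes qualify (q=0, up-regulated); returning all", len(qualifying))
    return qualifying.head(top_n).reset_index(drop=True)
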