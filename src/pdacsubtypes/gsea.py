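"""Gene set enrichment analysis with phenotype permutations.

Genes are ranked by a signal-to-noise score between two phenotype classes;
each gene set gets a weighted Kolmogorov-Smirnov enrichment score (ES): the
running sum gains |score|**p (normalized by the total hit weight) at member
genes and loses 1/(N - set size) at non-members, and ES is the signed
extremum.  Permuting the phenotype labels regenerates the ranking, giving a
null ES pool per set; the normalized score NES divides ES by the mean
|permuted ES| of the same sign, and FDR q compares each NES against the
pooled permuted NES distribution in the standard way.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneSetCollection

log = logging.getLogger(__name__)


def rank_genes(
    X: pd.DataFrame,
    labels,
    positive_class=None,
    sd_floor: float = 0.2,
) -> pd.Series:
    """Signal-to-noise score per gene, sorted descending.

    score = (mean_a - mean_b) / (sd_a + sd_b), with each sd floored at
    ``sd_floor`` so flat genes cannot produce infinite scores.  ``X`` is a
    log2-scale genes x samples DataFrame; ``labels`` must contain exactly
    two classes with at least three samples each.  The first class (or
    ``positive_class``) is the positive direction.
    """
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"need exactly two phenotype classes, got {list(classes)}")
    if positive_class is None:
        positive_class = classes[0]
    mask = labels == positive_class
    if mask.sum() < 3 or (~mask).sum() < 3:
        raise ValueError("each phenotype class needs at least three samples")
    values = X.to_numpy(dtype=float)
    a, b = values[:, mask], values[:, ~mask]
    sd_a = np.maximum(a.std(axis=1, ddof=1), sd_floor)
    sd_b = np.maximum(b.std(axis=1, ddof=1), sd_floor)
    scores = (a.mean(axis=1) - b.mean(axis=1)) / (sd_a + sd_b)
    ranked = pd.Series(scores, index=X.index, name="score")
    return ranked.sort_values(ascending=False, kind="stable")


def enrichment_score(
    ranked: pd.Series, gene_set: list[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS enrichment score of one gene set against a ranked list.

    Returns (ES, running_sum).  A set covering the whole list has no
    complement to contrast against: ES is 0 with a flat running sum.
    """
    hits = ranked.index.isin(gene_set)
    n = len(ranked)
    n_hit = int(hits.sum())
    if n_hit == 0:
        raise ValueError("gene set does not intersect the ranked list")
    if n_hit == n:
        log.info("gene set covers every ranked gene; ES defined as 0")
        return 0.0, np.zeros(n)
    weights = np.abs(ranked.to_numpy()) ** weight_p
    hit_weight = weights * hits
    total_hit = hit_weight.sum()
    if total_hit <= 0:  # all member scores exactly zero: fall back to unweighted steps
        hit_weight = hits.astype(float)
        total_hit = float(n_hit)
    running = np.cumsum(hit_weight / total_hit - (~hits) / (n - n_hit))
    es = running[np.argmax(np.abs(running))]
    return float(es), running


def _es_all_sets(ranked: pd.Series, memberships: np.ndarray, weight_p: float) -> np.ndarray:
    """ES for several sets at once; memberships is sets x genes in the
    ranked order."""
    n = len(ranked)
    weights = np.abs(ranked.to_numpy()) ** weight_p
    hit_w = memberships * weights
    totals = hit_w.sum(axis=1, keepdims=True)
    totals[totals <= 0] = memberships.sum(axis=1, keepdims=True)[totals <= 0]
    n_hit = memberships.sum(axis=1, keepdims=True)
    miss = (1.0 - memberships) / (n - n_hit)
    running = np.cumsum(hit_w / totals - miss, axis=1)
    idx = np.argmax(np.abs(running), axis=1)
    return running[np.arange(len(memberships)), idx]


def gsea_significance(
    X: pd.DataFrame,
    labels,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    weight_p: float = 1.0,
    min_size: int = 15,
    max_size: int = 500,
    sd_floor: float = 0.2,
) -> pd.DataFrame:
    """Enrichment table (ES, NES, FDR q, direction) over a gene-set
    collection.

    Phenotype labels are permuted ``n_perm`` times; each permutation
    re-ranks the genes and recomputes every set's ES.  Sets are filtered to
    ``min_size``-``max_size`` members after intersecting with the expression
    rows.  Rows are sorted by |NES| descending.  ``direction`` names the
    class in which the set is enriched.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    labels = np.asarray(labels)
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError("GSEA stage takes exactly two phenotype classes")

    universe = set(X.index)
    kept: dict[str, list[str]] = {}
    for name, members in collection.sets.items():
        inter = [g for g in members if g in universe]
        if not inter:
            log.info("gene set %s has no overlap with the expression matrix; skipped", name)
            continue
        if not min_size <= len(inter) <= max_size:
            log.info("gene set %s outside size window (%d members); skipped", name, len(inter))
            continue
        kept[name] = inter
    if not kept:
        log.warning("no gene sets overlap the expression matrix")
        return pd.DataFrame(columns=["set_name", "es", "nes", "fdr_q", "direction"])

    names = list(kept)
    gene_pos = {g: i for i, g in enumerate(X.index)}
    member_matrix = np.zeros((len(names), X.shape[0]))
    for row, name in enumerate(names):
        member_matrix[row, [gene_pos[g] for g in kept[name]]] = 1.0

    def es_for_labels(lab: np.ndarray) -> np.ndarray:
        ranked = rank_genes(X, lab, positive_class=classes[0], sd_floor=sd_floor)
        order = [gene_pos[g] for g in ranked.index]
        return _es_all_sets(ranked, member_matrix[:, order], weight_p)

    es_obs = es_for_labels(labels)
    rng = np.random.default_rng(seed)
    es_null = np.empty((n_perm, len(names)))
    for p in range(n_perm):
        es_null[p] = es_for_labels(rng.permutation(labels))

    # normalize by the mean |null ES| of the matching sign, per set
    nes_obs = np.empty(len(names))
    nes_null = np.full_like(es_null, np.nan)
    for j in range(len(names)):
        null = es_null[:, j]
        pos_mean = null[null > 0].mean() if np.any(null > 0) else np.nan
        neg_mean = -null[null < 0].mean() if np.any(null < 0) else np.nan
        nes_obs[j] = es_obs[j] / (pos_mean if es_obs[j] >= 0 else neg_mean)
        with np.errstate(invalid="ignore"):
            nes_null[:, j] = np.where(null >= 0, null / pos_mean, null / neg_mean)
    nes_obs = np.nan_to_num(nes_obs)

    pool = nes_null[np.isfinite(nes_null)]
    fdr = np.empty(len(names))
    for j, nes in enumerate(nes_obs):
        if nes >= 0:
            null_frac = np.mean(pool >= nes) if np.any(pool >= 0) else 0.0
            null_frac = null_frac / max(np.mean(pool >= 0), 1e-12)
            obs_frac = np.mean(nes_obs[nes_obs >= 0] >= nes)
        else:
            null_frac = np.mean(pool <= nes) / max(np.mean(pool < 0), 1e-12)
            obs_frac = np.mean(nes_obs[nes_obs < 0] <= nes)
        fdr[j] = min(null_frac / max(obs_frac, 1e-12), 1.0)

    direction = np.where(nes_obs >= 0, classes[0], classes[1])
    table = pd.DataFrame(
        {
            "set_name": names,
            "es": es_obs,
            "nes": nes_obs,
            "fdr_q": fdr,
            "direction": direction,
        }
    )
    return table.reindex(table["nes"].abs().sort_values(ascending=False, kind="stable").index).reset_index(
        drop=True
    )
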