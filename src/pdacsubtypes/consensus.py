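"""Consensus clustering over NMF restarts and cophenetic rank selection.

For each candidate rank k the factorization is restarted from many seeded
random initializations; each run contributes a binary sample connectivity
matrix (1 where two samples share the dominant metagene), and their mean is
the consensus matrix.  The cophenetic correlation coefficient c of the
consensus — the Pearson correlation between the pairwise consensus distances
1 - consensus and the dendrogrammatic distances of their average-linkage
tree — measures how close the consensus is to a clean ultrametric
partition; the rank with the highest c is selected.  Final subtype labels
come from cutting the consensus dendrogram into k groups, numbered by
decreasing cluster size (subtype 1 = largest).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import cophenet, fcluster, linkage
from scipy.spatial.distance import squareform

from .nmf import fit_nmf

log = logging.getLogger(__name__)


@dataclass
class ConsensusResult:
    """Consensus clustering of one rank."""

    k: int
    consensus: np.ndarray
    cophenetic: float
    labels: np.ndarray
    n_runs: int
    dendrogram: np.ndarray  # scipy linkage matrix of 1 - consensus


def connectivity_matrix(H: np.ndarray) -> np.ndarray:
    """Binary co-clustering matrix of samples under one factorization.

    Entry (i, j) is 1 iff columns i and j of H achieve their maximum on the
    same metagene; ties go to the lowest metagene index (argmax convention).
    """
    H = np.asarray(H, dtype=float)
    if np.any(H.max(axis=0) <= 0):
        raise ValueError("H has an all-zero column; sample has no dominant metagene")
    labels = np.argmax(H, axis=0)
    return (labels[:, None] == labels[None, :]).astype(float)


def consensus_matrix(connectivities: list[np.ndarray]) -> np.ndarray:
    """Elementwise mean of connectivity matrices from repeated runs."""
    if len(connectivities) < 2:
        raise ValueError("need at least two runs to form a consensus")
    shapes = {c.shape for c in connectivities}
    if len(shapes) != 1:
        raise ValueError(f"connectivity shapes differ: {shapes}")
    return np.mean(connectivities, axis=0)


def _consensus_linkage(consensus: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    dist = 1.0 - np.asarray(consensus, dtype=float)
    condensed = squareform(dist, checks=False)
    condensed = np.clip(condensed, 0.0, None)
    return linkage(condensed, method="average"), condensed


def cophenetic_coefficient(consensus: np.ndarray) -> float:
    """Cophenetic correlation of the consensus matrix.

    Correlates the off-diagonal consensus distances 1 - consensus with the
    cophenetic (dendrogrammatic) distances of their average-linkage tree.
    A constant distance matrix carries no disagreement to measure and is
    defined as 1.0.
    """
    Z, condensed = _consensus_linkage(consensus)
    if np.ptp(condensed) == 0.0:
        log.info("constant consensus distances; cophenetic coefficient defined as 1.0")
        return 1.0
    c, _ = cophenet(Z, condensed)
    return float(c)


def assign_subtypes(consensus: np.ndarray, k: int) -> np.ndarray:
    """Cut the consensus dendrogram into k groups.

    Labels are 1-based and ordered by decreasing cluster size, so subtype 1
    is always the largest group.
    """
    m = consensus.shape[0]
    if k > m:
        raise ValueError(f"cannot cut {m} samples into {k} groups")
    Z, _ = _consensus_linkage(consensus)
    raw = fcluster(Z, t=k, criterion="maxclust")
    # order clusters by descending size; ties broken by first appearance
    ids, counts = np.unique(raw, return_counts=True)
    order = ids[np.argsort(-counts, kind="stable")]
    remap = {old: new for new, old in enumerate(order, start=1)}
    return np.array([remap[r] for r in raw], dtype=int)


def consensus_for_rank(
    A: np.ndarray, k: int, n_runs: int, base_seed: int, dtype=np.float32
) -> ConsensusResult:
    """Consensus clustering at a single rank from ``n_runs`` seeded restarts.

    Runs use float32 by default: only the argmax connectivity pattern of H
    feeds the consensus, which is insensitive to working precision.
    """
    if n_runs < 2:
        raise ValueError("n_runs must be at least 2")
    conns = []
    for run in range(n_runs):
        seed = int(np.random.SeedSequence([base_seed, k, run]).generate_state(1)[0] % (2**31))
        fac = fit_nmf(A, k=k, seed=seed, dtype=dtype)
        conns.append(connectivity_matrix(fac.H))
    cons = consensus_matrix(conns)
    Z, _ = _consensus_linkage(cons)
    return ConsensusResult(
        k=k,
        consensus=cons,
        cophenetic=cophenetic_coefficient(cons),
        labels=assign_subtypes(cons, k),
        n_runs=n_runs,
        dendrogram=Z,
    )


def select_rank(
    A: np.ndarray,
    k_min: int = 2,
    k_max: int = 4,
    n_runs: int = 30,
    base_seed: int = 0,
    dtype=np.float32,
) -> tuple[int, dict[int, ConsensusResult]]:
    """Consensus clustering over a rank range; pick the cophenetic maximum.

    Returns the selected rank (ties resolved toward the smallest k) and the
    per-rank consensus results.
    """
    n, m = np.asarray(A).shape
    if k_min < 2:
        raise ValueError("k_min must be at least 2")
    if k_max < k_min:
        raise ValueError("empty rank range")
    if k_max > min(n, m):
        raise ValueError(f"k_max={k_max} exceeds matrix dimensions {n}x{m}")
    results = {k: consensus_for_rank(A, k, n_runs, base_seed, dtype=dtype) for k in range(k_min, k_max + 1)}
    ks = sorted(results)
    best = ks[int(np.argmax([results[k].cophenetic for k in ks]))]
    return best, results
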