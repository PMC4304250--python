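"""Synthetic PDAC-like cohort generator.

Builds expression matrices, clinical tables and ground-truth labels with the
structure the subtyping pipeline assumes: a small number of latent subtypes
of fixed sizes, subtype-specific up-regulated marker genes on a log2-scale
Gaussian background, exponential survival times targeted at per-subtype
medians with independent follow-up censoring, and per-subtype binary
clinicopathologic covariates (margin status, distant metastasis, recurrence).

Defaults mirror a 96-patient resected-PDAC cohort with three subtypes of
sizes 43/45/8, median overall survival 37.6/19.2/13.8 months, and censored
fractions 27/43, 22/45 and 4/8.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .io import GeneSetCollection

LN2 = math.log(2.0)

# Covariate rates per subtype taken from the reference cohort's
# clinicopathologic table: R0 resection 39/43, 31/45, 6/8; distant
# metastasis 17/43, 30/45, 3/8; recurrence 21/43, 32/45, 5/8.
_DEFAULT_COVARIATE_RATES = {
    "r0": (39 / 43, 31 / 45, 6 / 8),
    "distant_met": (17 / 43, 30 / 45, 3 / 8),
    "recurrence": (21 / 43, 32 / 45, 5 / 8),
}


@dataclass
class CohortConfig:
    """Parameters of the simulated cohort.

    All expression quantities are on the log2 scale; survival is in months.
    """

    n_genes: int = 2000
    subtype_sizes: tuple[int, ...] = (43, 45, 8)
    markers_per_subtype: int = 50
    marker_log2_shift: float = 2.0
    noise_sd: float = 0.5
    baseline_mean: float = 8.0
    survival_medians: tuple[float, ...] = (37.6, 19.2, 13.8)
    censor_rate_per_subtype: tuple[float, ...] = (27 / 43, 22 / 45, 4 / 8)
    covariate_rates: dict[str, tuple[float, ...]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        k = len(self.subtype_sizes)
        if self.covariate_rates is None:
            # study-style covariates only make sense for the 3-subtype layout
            self.covariate_rates = dict(_DEFAULT_COVARIATE_RATES) if k == 3 else {}
        if self.n_genes < 1:
            raise ValueError("n_genes must be positive")
        if k < 1 or any(s < 1 for s in self.subtype_sizes):
            raise ValueError("subtype sizes must be positive counts")
        if self.markers_per_subtype < 0:
            raise ValueError("markers_per_subtype must be non-negative")
        if self.markers_per_subtype * k > self.n_genes:
            raise ValueError("marker genes exceed the gene universe")
        if len(self.survival_medians) != k or any(m <= 0 for m in self.survival_medians):
            raise ValueError("survival medians must be positive, one per subtype")
        if len(self.censor_rate_per_subtype) != k or any(
            not 0.0 <= c <= 1.0 for c in self.censor_rate_per_subtype
        ):
            raise ValueError("censor rates must be probabilities, one per subtype")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name, rates in self.covariate_rates.items():
            if len(rates) != k or any(not 0.0 <= r <= 1.0 for r in rates):
                raise ValueError(f"covariate {name!r}: need one probability in [0,1] per subtype")

    @property
    def n_samples(self) -> int:
        return int(sum(self.subtype_sizes))

    @property
    def n_subtypes(self) -> int:
        return len(self.subtype_sizes)


@dataclass
class GroundTruth:
    """Planted structure of a simulated cohort (1-based subtype labels)."""

    labels: np.ndarray
    marker_ids: dict[int, list[str]]
    enriched_set_ids: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        all_markers = [g for ids in self.marker_ids.values() for g in ids]
        if len(all_markers) != len(set(all_markers)):
            raise ValueError("marker sets must be disjoint")


def _followup_window(rate: float, censor_frac: float) -> float:
    """Upper bound of the Uniform(0, u) follow-up window giving the target
    censoring fraction for exponential event times with the given rate.

    P(censored) = P(F < T) = (1 - exp(-rate*u)) / (rate*u), which decreases
    from 1 (u -> 0) to 0 (u -> inf); solved by bisection.
    """
    if not 0.0 < censor_frac < 1.0:
        raise ValueError("censor fraction must be inside (0, 1) to calibrate a window")

    def g(u: float) -> float:
        return (1.0 - math.exp(-rate * u)) / (rate * u) - censor_frac

    lo, hi = 1e-9, 1.0
    while g(hi) > 0:
        hi *= 2.0
    return brentq(g, lo, hi)


def simulate_cohort(config: CohortConfig) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Simulate one cohort.

    Returns ``(expression, clinical, truth)`` where expression is a
    genes x samples log2-scale DataFrame, clinical is a per-sample CSV-style
    table and truth records planted labels and marker genes.  Identical
    config (including seed) gives identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    k = config.n_subtypes

    gene_ids = [f"G{i + 1:06d}" for i in range(config.n_genes)]
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    labels = np.repeat(np.arange(1, k + 1), config.subtype_sizes)

    expr = rng.normal(config.baseline_mean, config.noise_sd, size=(config.n_genes, n))

    marker_pool = rng.choice(config.n_genes, size=config.markers_per_subtype * k, replace=False)
    marker_ids: dict[int, list[str]] = {}
    for s in range(1, k + 1):
        rows = marker_pool[(s - 1) * config.markers_per_subtype : s * config.markers_per_subtype]
        marker_ids[s] = [gene_ids[i] for i in sorted(rows)]
        expr[np.ix_(sorted(rows), np.flatnonzero(labels == s))] += config.marker_log2_shift

    expression = pd.DataFrame(expr, index=gene_ids, columns=sample_ids)

    # Survival: exponential with rate ln2 / median per subtype, censored by an
    # independent uniform follow-up window calibrated per subtype.
    rates = np.array([LN2 / config.survival_medians[s - 1] for s in labels])
    event_time = rng.exponential(scale=1.0 / rates)
    followup = np.full(n, np.inf)
    for s in range(1, k + 1):
        cfrac = config.censor_rate_per_subtype[s - 1]
        idx = labels == s
        if cfrac <= 0.0:
            continue
        if cfrac >= 1.0:
            followup[idx] = 0.0
            continue
        u = _followup_window(LN2 / config.survival_medians[s - 1], cfrac)
        followup[idx] = rng.uniform(0.0, u, size=int(idx.sum()))
    time_obs = np.minimum(event_time, followup)
    event = (event_time <= followup).astype(int)
    # keep times strictly positive at float resolution
    time_obs = np.maximum(time_obs, 1e-6)

    clinical = pd.DataFrame({"sample_id": sample_ids, "time_months": time_obs, "event": event})
    for name, per_subtype in config.covariate_rates.items():
        p = np.array([per_subtype[s - 1] for s in labels])
        clinical[name] = (rng.random(n) < p).astype(int)
    if "r0" in clinical.columns:
        clinical["r_status"] = np.where(clinical.pop("r0") == 1, "R0", "R1R2")
    clinical["subtype_true"] = labels

    truth = GroundTruth(
        labels=labels,
        marker_ids=marker_ids,
        enriched_set_ids=[f"SUBTYPE{s}_MARKERS" for s in range(1, k + 1)],
        gene_ids=gene_ids,
    )
    return expression, clinical, truth


def simulate_genesets(
    truth: GroundTruth,
    n_decoy_sets: int = 10,
    set_size: int = 50,
    seed: int = 0,
) -> GeneSetCollection:
    """Gene-set collection with one planted set per subtype plus random decoys.

    The planted set for subtype ``s`` is a subset of that subtype's marker
    genes (all of them when the marker block is smaller than ``set_size``);
    decoys are drawn uniformly from the gene universe.
    """
    if set_size < 1:
        raise ValueError("set_size must be positive")
    if set_size > len(truth.gene_ids):
        raise ValueError("set_size exceeds the gene universe")
    rng = np.random.default_rng(seed)
    sets: dict[str, list[str]] = {}
    for s, name in zip(sorted(truth.marker_ids), truth.enriched_set_ids):
        markers = truth.marker_ids[s]
        take = min(set_size, len(markers))
        chosen = rng.choice(len(markers), size=take, replace=False)
        sets[name] = [markers[i] for i in sorted(chosen)]
    for d in range(n_decoy_sets):
        chosen = rng.choice(len(truth.gene_ids), size=set_size, replace=False)
        sets[f"DECOY{d + 1:03d}"] = [truth.gene_ids[i] for i in sorted(chosen)]
    return GeneSetCollection(sets=sets, source="simulated")
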