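"""End-to-end subtype discovery pipeline.

Stages: exponential scaling -> consensus NMF rank selection -> subtype
assignment -> survival comparison -> clinicopathologic association battery
-> one-vs-rest SAM marker tables -> GSEA between the two largest subtypes.
Each stage writes its tables to the output directory as it completes, so a
failure keeps earlier results on disk; errors carry the stage name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, consensus, gsea, io, nmf, sam, survival

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Run parameters for the full pipeline."""

    expression_path: str = ""
    clinical_path: str = ""
    geneset_path: str | None = None
    out_dir: str = "pdacsubtypes_out"
    rank_min: int = 2
    rank_max: int = 4
    n_runs: int = 30
    seed: int = 0
    top_n_markers: int = 20
    sam_permutations: int = 1000
    gsea_permutations: int = 1000
    gsea_min_size: int = 15
    gsea_max_size: int = 500
    categorical_covariates: list[str] = field(
        default_factory=lambda: ["r_status", "distant_met", "recurrence"]
    )
    continuous_covariates: list[str] = field(default_factory=list)
    test_method: str = "auto"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:  # noqa: BLE001 - stage tagging is the point
                raise PipelineError(name, exc) from exc

        return wrapped

    return deco


def cluster_expression(
    expression: pd.DataFrame,
    rank_min: int = 2,
    rank_max: int = 4,
    n_runs: int = 30,
    seed: int = 0,
) -> tuple[int, dict[int, consensus.ConsensusResult]]:
    """Scale a log2 matrix and run consensus rank selection."""
    A = nmf.exponential_scale(expression.to_numpy())
    return consensus.select_rank(A, k_min=rank_min, k_max=rank_max, n_runs=n_runs, base_seed=seed)


def run_full_pipeline(config: PipelineConfig) -> dict:
    """Execute every stage and write the report bundle to ``out_dir``.

    Returns a summary dict (also written as ``run_log.json``) with the
    selected rank, per-rank cophenetic coefficients, survival and
    association summaries, and the file names of all written tables.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": asdict(config), "outputs": []}

    @_stage("load")
    def load():
        expression = io.read_expression(config.expression_path)
        clinical = io.read_clinical(config.clinical_path)
        missing = set(expression.columns) - set(clinical["sample_id"])
        if missing:
            raise ValueError(f"samples missing from clinical table: {sorted(missing)[:5]}")
        clinical = clinical.set_index("sample_id").loc[list(expression.columns)].reset_index()
        return expression, clinical

    expression, clinical = load()

    @_stage("cluster")
    def cluster():
        best_k, results = cluster_expression(
            expression, config.rank_min, config.rank_max, config.n_runs, config.seed
        )
        labels = results[best_k].labels
        pd.DataFrame({"sample_id": expression.columns, "subtype": labels}).to_csv(
            out / "labels.tsv", sep="\t", index=False
        )
        coph = {str(k): results[k].cophenetic for k in sorted(results)}
        with open(out / "cophenetic.json", "w") as fh:
            json.dump({"selected_rank": best_k, "cophenetic": coph}, fh, indent=2)
        report["outputs"] += ["labels.tsv", "cophenetic.json"]
        report["selected_rank"] = best_k
        report["cophenetic"] = coph
        return best_k, results, labels

    best_k, rank_results, labels = cluster()

    @_stage("survival")
    def surv():
        summary = survival.survival_summary(clinical, labels)
        with open(out / "survival.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        km_rows = []
        for s in sorted(np.unique(labels)):
            mask = labels == s
            curve = survival.km_estimate(
                clinical.loc[mask, "time_months"], clinical.loc[mask, "event"]
            )
            km_rows.append(
                pd.DataFrame(
                    {
                        "subtype": s,
                        "time_months": curve.event_times,
                        "survival": curve.survival_prob,
                        "at_risk": curve.at_risk,
                    }
                )
            )
        pd.concat(km_rows).to_csv(out / "km_curves.tsv", sep="\t", index=False)
        report["outputs"] += ["survival.json", "km_curves.tsv"]
        report["survival"] = summary
        return summary

    surv()

    @_stage("association")
    def assoc():
        cats = [c for c in config.categorical_covariates if c in clinical.columns]
        conts = [c for c in config.continuous_covariates if c in clinical.columns]
        table = association.association_battery(
            clinical, labels, categorical=cats, continuous=conts, method=config.test_method
        )
        table.to_csv(out / "associations.tsv", sep="\t", index=False)
        report["outputs"].append("associations.tsv")
        report["associations"] = table.to_dict(orient="records")
        return table

    assoc()

    @_stage("sam")
    def markers():
        all_selected = {}
        for s in sorted(np.unique(labels)):
            table = sam.sam_table(
                expression, labels, subtype=int(s), n_perm=config.sam_permutations, seed=config.seed
            )
            selected = sam.select_markers(table, top_n=config.top_n_markers)
            selected.to_csv(out / f"markers_subtype{s}.tsv", sep="\t", index=False)
            report["outputs"].append(f"markers_subtype{s}.tsv")
            all_selected[int(s)] = selected
        report["n_markers"] = {s: len(t) for s, t in all_selected.items()}
        return all_selected

    marker_tables = markers()

    @_stage("gsea")
    def enrich():
        if config.geneset_path is None:
            log.info("no gene-set file supplied; GSEA stage skipped")
            return None
        collection = io.read_gmt(config.geneset_path)
        # compare the two largest subtypes; the smallest is excluded as too
        # small for phenotype permutation
        sizes = pd.Series(labels).value_counts()
        keep = sorted(sizes.index[:2]) if len(sizes) > 2 else sorted(sizes.index)
        mask = np.isin(labels, keep)
        table = gsea.gsea_significance(
            expression.loc[:, mask],
            labels[mask],
            collection,
            n_perm=config.gsea_permutations,
            seed=config.seed,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
        )
        table.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        report["outputs"].append("enrichment.tsv")
        report["gsea_groups"] = [int(k) for k in keep]
        return table

    enrich()

    with open(out / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2, default=str)
    report["marker_tables"] = marker_tables
    report["rank_results"] = rank_results
    return report


def run_validation_clustering(
    expression: pd.DataFrame,
    marker_ids: list[str],
    rank_min: int = 2,
    rank_max: int = 4,
    n_runs: int = 30,
    seed: int = 0,
) -> tuple[int, dict[int, consensus.ConsensusResult]]:
    """Re-cluster an independent cohort on a discovered marker panel.

    Subsets the expression matrix to the markers present in it (logging how
    many were found) and reruns consensus rank selection.
    """
    present = [g for g in dict.fromkeys(marker_ids) if g in expression.index]
    if not present:
        raise ValueError("no marker genes found in the validation expression matrix")
    log.info("validation clustering on %d of %d marker genes", len(present), len(set(marker_ids)))
    subset = expression.loc[present]
    return cluster_expression(subset, rank_min, rank_max, n_runs, seed)
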