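# pdacsubtypes

Molecular subtyping of bulk gene-expression cohorts by consensus
non-negative matrix factorization, with the downstream clinical analyses a
subtype-discovery study needs: Kaplan-Meier / log-rank survival comparison,
clinicopathologic association tests, SAM differential expression with
permutation q-values, and gene set enrichment analysis. The package targets
the pancreatic ductal adenocarcinoma (PDAC) setting — small resected
cohorts (~100 patients), three expression subtypes of very unequal size,
heavily censored overall survival — but the machinery is generic.

Because such cohorts are rarely deposited, the package ships a synthetic
cohort generator that reproduces the statistical shape of a 96-patient
resected-PDAC series: subtypes of 43/45/8 patients with planted marker
genes, exponential survival at per-subtype medians 37.6/19.2/13.8 months
with calibrated censoring, and per-subtype binary covariates (resection
margin, distant metastasis, recurrence). Every stage is testable
end-to-end without downloads.

## Method

Given a log2 expression matrix, the pipeline works on the linear scale
`A = 2^X` (genes x samples, all entries positive) and factorizes

    A ≈ W H,   W: n x k ≥ 0,   H: k x m ≥ 0

by multiplicative updates minimizing the generalized Kullback-Leibler
divergence

    D(A‖WH) = Σᵢⱼ [ Aᵢⱼ log(Aᵢⱼ/(WH)ᵢⱼ) − Aᵢⱼ + (WH)ᵢⱼ ].

Each sample's cluster under one run is the argmax metagene of its H
column. For each rank k in 2..4 the factorization is restarted from many
seeded random initializations; the mean of the binary co-clustering
matrices is the consensus matrix, and its cophenetic correlation
coefficient c — the Pearson correlation between the consensus distances
1 − consensus and the cophenetic distances of their average-linkage
dendrogram — measures how close the consensus is to a clean partition.
The rank with maximal c is selected, and subtype labels come from cutting
the consensus dendrogram into k groups (subtype 1 = largest).

Downstream, subtypes are compared by Kaplan-Meier estimates and log-rank
tests (lifelines), contingency tests (Fisher exact / chi-square) and
Kruskal-Wallis for clinical covariates, one-vs-rest SAM statistics
`d = Δmean / (s + s₀)` with permutation FDR q-values and the
"q = 0, up-regulated, top 20 by fold change" marker rule, and
signal-to-noise-ranked GSEA with phenotype permutations, NES and FDR q.

## Worked example

```sh
pdacsubtypes simulate --seed 11 --outdir cohort
pdacsubtypes run-all --expression cohort/expression.tsv \
    --clinical cohort/clinical.csv --gmt cohort/genesets.gmt \
    --runs 20 --perms 200 --seed 11 --outdir results
```

prints

```
wrote cohort (96 samples, 2000 genes) to cohort
selected rank 3; outputs in results: labels.tsv, cophenetic.json,
survival.json, km_curves.tsv, associations.tsv, markers_subtype1.tsv,
markers_subtype2.tsv, markers_subtype3.tsv, enrichment.tsv
```

`results/cophenetic.json` shows why rank 3 was chosen — the cophenetic
coefficient peaks there:

```json
{"selected_rank": 3, "cophenetic": {"2": 0.9747, "3": 1.0, "4": 0.9988}}
```

`results/survival.json` holds per-subtype KM medians and log-rank tests.
For this cohort the two large subtypes separate clearly: medians 14.8 vs
38.5 months (the third subtype, n = 8, never reaches S ≤ 0.5), log-rank
chi-square 7.02, p = 0.008. `markers_subtype3.tsv` lists the selected
markers, all with q = 0, ordered by fold change (top gene 5.15x), and
`enrichment.tsv` ranks gene sets by |NES| with permutation FDR q.

The same stages are available as library functions
(`pdacsubtypes.simulate_cohort`, `fit_nmf`, `select_rank`,
`survival_summary`, `sam_table`, `gsea_significance`,
`run_full_pipeline`, ...) and as single CLI subcommands
(`cluster`, `survival`, `associate`, `markers`, `gsea`, `validate`).

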