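# Methods

## Model and procedure

The pipeline treats subtype discovery as consensus clustering of samples
under non-negative matrix factorization. Input expression is log2 scale;
the exponential transform `2^x` maps it to a strictly positive matrix `A`
(genes in rows, samples in columns), the orientation all modules assume.

**Factorization.** `A ≈ WH` is fitted by multiplicative updates under the
generalized KL divergence, updating W first and then H with the updated W
(Lee-Seung sweep order). Factors are initialized uniform(0, 1] — strictly
positive so no entry is absorbed at zero — and rescaled so the initial
reconstruction matches the mean of `A`. These updates never increase the
divergence and preserve non-negativity; both properties are asserted in
the test suite at every step on random inputs. Denominators and the
divergence logarithm are floored at 1e-12. The iteration cap is 1000
sweeps; in addition a run stops early once the sample connectivity
pattern (argmax metagene per H column) has survived 40 consecutive checks
taken every 10 sweeps, the natural criterion when only the clustering
pattern feeds downstream consensus. Consensus restarts run in float32
(the connectivity argmax is insensitive to working precision; a rank-2..4
sweep of a 2000 x 96 matrix with 20 restarts per rank takes ~20 s on one
CPU); the reported divergence is always evaluated in float64.

**Consensus and rank selection.** For each rank k in 2..4, restarts from
seeded initializations (seeds derived per (base seed, rank, restart) so
runs are independent and reproducible) yield binary co-clustering
matrices whose mean is the consensus. Distances 1 − consensus are
clustered by average linkage; the cophenetic correlation between those
distances and the dendrogram-induced distances scores the rank, and the
maximum wins (ties to the smaller rank). Labels come from cutting the
consensus dendrogram — not from any single run's H — because the
consensus cut is stable across restarts where individual runs are not.
Labels are numbered by decreasing cluster size. A constant consensus
distance matrix (every pair always or never co-clusters identically) has
no disagreement to correlate and is defined as c = 1.

**Survival.** Kaplan-Meier estimation and log-rank tests are delegated to
lifelines with fixed conventions: times are months and strictly positive,
events precede censoring at tied times, the median is the first event
time with S(t) ≤ 0.5 (infinity — "not reached" — otherwise), pairwise
p-values are unadjusted, and a degenerate comparison with zero variance
reports statistic 0, p = 1.

**Associations.** Fisher's exact test (two-sided, point-probability
summation) for 2x2 tables, Pearson chi-square without continuity
correction otherwise, Kruskal-Wallis for continuous covariates; all
overridable, since clinical studies rarely state which variant produced a
printed p-value. Percentages are displayed to one decimal with the group
size as denominator, p-values to three decimals.

**SAM.** One-vs-rest statistic `d = (mean_case − mean_rest)/(s + s0)`
with `s` the pooled standard error of the mean difference. The fudge
factor `s0` defaults to the median of the per-gene `s` — the standard
simplification of the full SAM tuning search, enough to keep low-variance
genes from dominating — and is held fixed across permutations so observed
and null `d` share a scale. The q-value of a gene is the median, over
permuted case masks, of the number of null |d| values at or above its
threshold, divided by the number of genes called there, then monotonized
by a cumulative minimum along ascending |d| (a gene's q is the best FDR
among thresholds it survives). When fewer distinct masks exist than
requested permutations the full enumeration is used. Fold change is the
ratio of linear-scale (2^x) group means; marker selection keeps q = 0,
fold change > 1, sorts by fold change descending and truncates to 20.
"q = 0" means no more than half the permutations produced any null |d|
at or above the gene's threshold — an estimator statement, not an exact
zero FDR.

**GSEA.** Genes are ranked by signal-to-noise `(μ_a − μ_b)/(σ_a + σ_b)`
with each σ floored at 0.2 (a flat floor; flat genes cannot produce
infinite scores). The enrichment score is the signed extremum of the
weighted running sum (weight p = 1): hits add |score|/Σ|hit scores|,
misses subtract 1/(N − set size). A set covering the whole ranked list
has no complement to contrast against and is defined as ES = 0. Null
distributions come from phenotype-label permutations — appropriate at
tens of samples per class, and matching how two-group comparisons of
subtypes are normally run; the smallest subtype is excluded from this
stage, which takes exactly two groups. NES divides ES by the mean |null
ES| of the same sign; FDR q compares each NES against the pooled permuted
NES of its sign, normalized by the observed fraction at least as extreme,
clipped to [0, 1]. Sets are filtered to 15-500 members after intersection
with the expression rows.

## Synthetic cohorts

The generator emulates the data structure the analysis assumes, with
defaults frozen at the reference cohort's shape:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 2000 | gene universe (log2 scale) |
| `subtype_sizes` | 43, 45, 8 | planted subtype sizes (96 samples) |
| `markers_per_subtype` | 50 | genes up-shifted in one subtype only |
| `marker_log2_shift` | 2.0 | log2 effect size of a marker |
| `noise_sd` | 0.5 | Gaussian noise SD around baseline 8.0 (log2) |
| `survival_medians` | 37.6, 19.2, 13.8 | months, per subtype |
| `censor_rate_per_subtype` | 27/43, 22/45, 4/8 | target censored fractions |
| covariate rates | per subtype | R0 39/43, 31/45, 6/8; distant metastasis 17/43, 30/45, 3/8; recurrence 21/43, 32/45, 5/8 |

Survival times are exponential with rate ln 2 / median — the simplest law
matching a published median — and censoring is an independent uniform
follow-up window Uniform(0, u) with u solved per subtype so the expected
censored fraction hits its target. Gene sets for GSEA testing are one
planted set per subtype (a subset of its markers) plus decoy sets drawn
uniformly from the whole gene universe; on planted cohorts decoys
therefore contain a few genuine markers and may show real enrichment,
which is why null calibration is assessed on pure-noise data.

What the generator does **not** emulate: probe-level microarray
structure, batch or array effects, correlated gene blocks beyond the
planted markers, non-proportional hazards, competing risks, or covariates
unused downstream (operation type, chemotherapy agent). Passing tests
demonstrate the machinery recovers planted structure under these idealized
conditions; they do not certify performance on real microarray data.

A note on statistical power: with exponential survival at medians 37.6 vs
19.2 months and 43 vs 45 patients, the two-group log-rank test has ~0.87
power at α = 0.05 even without censoring, and ~0.48 at the configured
censored fractions (Schoenfeld approximation, confirmed by simulation).
Any single simulated cohort may therefore fail to reach p < 0.05 on the
survival comparison even when clustering recovers the planted subtypes
exactly; the acceptance script reports a detection rate over replicate
draws for this reason, and aggregates KM medians over replicates (a
single 43-patient draw at ~60% censoring has a 10-90% KM-median range of
roughly 28-50 months).

## Numerical choices and degenerate inputs

- epsilon 1e-12 floors NMF denominators and logs; divergence may come out
  a few ulps negative on an exact fit.
- connectivity argmax ties break toward the lowest metagene index;
  cluster-size ties in label numbering break by first appearance.
- `fit_nmf` accepts k = 1 (used by exact-recovery checks); consensus rank
  selection starts at k = 2.
- zero-margin contingency tables, constant Kruskal-Wallis inputs and
  zero-variance log-rank comparisons all degrade to p = 1 with a log
  note rather than raising.
- all randomness flows through explicit integer seeds
  (`numpy.random.default_rng` / `SeedSequence`); identical seeds give
  byte-identical outputs, including file outputs of the pipeline.

## Problem sizes in the test suite

Unit tests run on 96-sample cohorts with 300-2000 genes; the acceptance
suite sweeps twenty 2000-gene cohorts at 20 restarts per rank (~8 minutes
single-core), 1000 null log-rank simulations, 300 Fisher enumeration
checks, and 100-200-permutation SAM/GSEA runs. Smaller shrunken cohorts
(300 genes) proved unsuitable for rank selection checks: the k = 2
consensus becomes perfectly stable and ties the cophenetic coefficient at
1.0, an artifact that disappears at the study's gene count.

## Known limitations

- The SAM implementation omits the original fudge-factor percentile
  search and the asymmetric cutoff interface; `s0` = median standard
  error is a documented simplification.
- GSEA FDR q-values are conservative under the null (mass at 1), as is
  standard for the two-tailed pooled-NES estimator.
- The probe-to-gene collapse of raw microarray data is out of scope; the
  pipeline expects a pre-collapsed genes x samples matrix.
- Validation clustering re-runs the discovery machinery on a marker-gene
  subset of an independent cohort; it does not implement cross-platform
  normalization.
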