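"""Tests for gene set enrichment analysis."""

import numpy as np
import pandas as pd
import pytest

from pdacsubtypes import gsea, synthetic
from pdacsubtypes.io import GeneSetCollection


def brute_force_es(scores, hits, p=1.0):
    """Independent running-sum oracle computed with an explicit loop."""
    n = len(scores)
    nh = hits.sum()
    total = np.sum(np.abs(scores[hits]) ** p)
    run, best = 0.0, 0.0
    for i in range(n):
        if hits[i]:
            run += abs(scores[i]) ** p / total
        else:
            run -= 1.0 / (n - nh)
        if abs(run) > abs(best):
            best = run
    return best


def frame(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes)


class TestRankGenes:
    def test_hand_signal_to_noise(self):
        X = frame([[2, 2, 2, 1, 1, 1]])
        labels = np.array(["a"] * 3 + ["b"] * 3)
        ranked = gsea.rank_genes(X, labels, positive_class="a")
        assert ranked.iloc[0] == pytest.approx(1.0 / 0.4)  # sd floor 0.2 per class

    def test_label_swap_negates_scores(self, rng):
        X = frame(rng.normal(0, 1, size=(30, 10)))
        labels = np.array(["a"] * 5 + ["b"] * 5)
        r1 = gsea.rank_genes(X, labels, positive_class="a")
        r2 = gsea.rank_genes(X, labels, positive_class="b")
        assert np.allclose(r1.sort_index(), -r2.sort_index())

    def test_clean_separation_ranks_first(self, rng):
        X = frame(rng.normal(0, 1, size=(50, 12)))
        labels = np.array(["a"] * 6 + ["b"] * 6)
        X.iloc[7, :6] += 10.0  # no overlap between classes for gene 7
        ranked = gsea.rank_genes(X, labels, positive_class="a")
        assert ranked.index[0] == "g7"

    def test_small_class_rejected(self, rng):
        X = frame(rng.normal(0, 1, size=(10, 5)))
        with pytest.raises(ValueError):
            gsea.rank_genes(X, np.array(["a", "a", "b", "b", "b"]))


class TestEnrichmentScore:
    def test_top_block_scores_high_and_matches_oracle(self, rng):
        scores = np.sort(rng.random(100) + 0.5)[::-1]
        ranked = pd.Series(scores, index=[f"g{i}" for i in range(100)])
        top5 = [f"g{i}" for i in range(5)]
        es, running = gsea.enrichment_score(ranked, top5)
        hits = ranked.index.isin(top5)
        assert es == pytest.approx(brute_force_es(scores, hits))
        assert es > 0.9
        assert -1.0 <= es <= 1.0
        assert len(running) == 100

    def test_full_universe_set_is_degenerate_zero(self, rng):
        ranked = pd.Series(rng.random(10), index=[f"g{i}" for i in range(10)]).sort_values(ascending=False)
        es, running = gsea.enrichment_score(ranked, list(ranked.index))
        assert es == 0.0
        assert np.allclose(running, 0.0)

    def test_reversal_flips_sign(self, rng):
        scores = np.linspace(2.0, -2.0, 40)
        genes = [f"g{i}" for i in range(40)]
        ranked = pd.Series(scores, index=genes)
        one_sided = genes[:6]
        es_fwd, _ = gsea.enrichment_score(ranked, one_sided)
        es_rev, _ = gsea.enrichment_score(ranked.iloc[::-1], one_sided)
        assert np.sign(es_fwd) == -np.sign(es_rev)

    def test_random_sets_always_within_unit_interval(self, rng):
        for _ in range(20):
            n = int(rng.integers(10, 60))
            ranked = pd.Series(rng.normal(0, 1, n), index=[f"g{i}" for i in range(n)])
            ranked = ranked.sort_values(ascending=False)
            size = int(rng.integers(1, n))
            members = list(rng.choice(ranked.index, size=size, replace=False))
            es, _ = gsea.enrichment_score(ranked, members)
            assert -1.0 <= es <= 1.0

    def test_disjoint_set_rejected(self, rng):
        ranked = pd.Series([1.0, 0.5], index=["g0", "g1"])
        with pytest.raises(ValueError):
            gsea.enrichment_score(ranked, ["absent"])


@pytest.fixture(scope="module")
def planted():
    cfg = synthetic.CohortConfig(
        n_genes=300, subtype_sizes=(20, 22, 8), markers_per_subtype=20,
        marker_log2_shift=2.0, noise_sd=0.5, seed=77,
    )
    expr, _, truth = synthetic.simulate_cohort(cfg)
    sets = synthetic.simulate_genesets(truth, n_decoy_sets=8, set_size=20, seed=3)
    keep = truth.labels <= 2  # two largest subtypes only
    return expr.loc[:, keep], truth.labels[keep], sets


class TestGseaSignificance:
    def test_planted_sets_pass_reporting_threshold(self, planted):
        expr, labels, sets = planted
        table = gsea.gsea_significance(expr, labels, sets, n_perm=100, seed=1)
        planted_rows = table[table.set_name.isin(["SUBTYPE1_MARKERS", "SUBTYPE2_MARKERS"])]
        assert len(planted_rows) == 2
        assert (planted_rows["fdr_q"] < 0.25).all()
        # markers of subtype 1 are enriched in subtype 1, and vice versa
        directions = dict(zip(planted_rows.set_name, planted_rows.direction))
        assert directions["SUBTYPE1_MARKERS"] == 1
        assert directions["SUBTYPE2_MARKERS"] == 2

    def test_seeded_determinism(self, planted):
        expr, labels, sets = planted
        t1 = gsea.gsea_significance(expr, labels, sets, n_perm=100, seed=5)
        t2 = gsea.gsea_significance(expr, labels, sets, n_perm=100, seed=5)
        pd.testing.assert_frame_equal(t1, t2)

    def test_sorted_by_abs_nes(self, planted):
        expr, labels, sets = planted
        table = gsea.gsea_significance(expr, labels, sets, n_perm=100, seed=2)
        assert (table["nes"].abs().diff().dropna() <= 1e-12).all()

    def test_null_data_rarely_enriched(self):
        # decoy sets on pure-noise data: pooled fraction passing the 0.25
        # reporting threshold stays small across independent simulations
        fracs = []
        for seed in range(4):
            r = np.random.default_rng(seed)
            X = frame(r.normal(8, 1, size=(200, 30)))
            labels = np.array([1] * 15 + [2] * 15)
            sets = {
                f"DECOY{i}": list(r.choice(X.index, size=20, replace=False)) for i in range(20)
            }
            table = gsea.gsea_significance(X, labels, GeneSetCollection(sets), n_perm=100, seed=seed)
            fracs.append((table["fdr_q"] < 0.25).mean())
        assert np.mean(fracs) <= 0.15

    def test_contract_defaults_and_errors(self, planted):
        import inspect

        expr, labels, sets = planted
        assert inspect.signature(gsea.gsea_significance).parameters["n_perm"].default == 1000
        with pytest.raises(ValueError):
            gsea.gsea_significance(expr, np.ones_like(labels), sets, n_perm=100, seed=0)
        disjoint = GeneSetCollection({"X": [f"zz{i}" for i in range(20)]})
        out = gsea.gsea_significance(expr, labels, disjoint, n_perm=100, seed=0)
        assert out.empty
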