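"""Tests for the synthetic cohort generator."""

import math

import numpy as np
import pandas as pd
import pytest

from pdacsubtypes import io, synthetic
from pdacsubtypes.synthetic import CohortConfig, simulate_cohort, simulate_genesets


class TestCohortConfig:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_genes": 0},
            {"subtype_sizes": (10, 0, 5)},
            {"survival_medians": (37.6, -1.0, 13.8)},
            {"censor_rate_per_subtype": (0.5, 1.5, 0.5)},
            {"noise_sd": -0.1},
            {"n_genes": 10, "markers_per_subtype": 20},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            CohortConfig(**kwargs)

    def test_default_sizes_match_study_cohort(self):
        cfg = CohortConfig()
        assert cfg.subtype_sizes == (43, 45, 8)
        assert cfg.n_samples == 96
        assert cfg.survival_medians == (37.6, 19.2, 13.8)


class TestSimulateCohort:
    def test_noiseless_marker_rows_are_two_valued(self):
        cfg = CohortConfig(n_genes=100, subtype_sizes=(5, 5, 5), markers_per_subtype=10,
                           noise_sd=0.0, marker_log2_shift=2.0, seed=7)
        expr, _, truth = simulate_cohort(cfg)
        for s, markers in truth.marker_ids.items():
            block = expr.loc[markers]
            assert set(np.unique(block.to_numpy())) == {cfg.baseline_mean, cfg.baseline_mean + 2.0}
            in_group = block.loc[:, truth.labels == s]
            assert (in_group.to_numpy() == cfg.baseline_mean + 2.0).all()

    def test_default_config_subtype_counts(self):
        _, _, truth = simulate_cohort(CohortConfig(seed=0))
        assert np.bincount(truth.labels)[1:].tolist() == [43, 45, 8]

    def test_exponential_medians_recovered_without_censoring(self):
        # Monte-Carlo check that survival times follow the exponential law
        # with median ln2 / rate per subtype.
        cfg = CohortConfig(
            n_genes=5,
            subtype_sizes=(10000, 10000, 10000),
            markers_per_subtype=1,
            censor_rate_per_subtype=(0.0, 0.0, 0.0),
            seed=11,
        )
        _, clinical, truth = simulate_cohort(cfg)
        assert (clinical["event"] == 1).all()
        for s, target in zip((1, 2, 3), cfg.survival_medians):
            observed = clinical.loc[truth.labels == s, "time_months"].median()
            assert observed == pytest.approx(target, rel=0.05)

    def test_censoring_rate_near_target(self):
        cfg = CohortConfig(n_genes=5, subtype_sizes=(4000,), markers_per_subtype=1,
                           survival_medians=(20.0,), censor_rate_per_subtype=(0.4,), seed=3)
        _, clinical, _ = simulate_cohort(cfg)
        censored = 1.0 - clinical["event"].mean()
        assert censored == pytest.approx(0.4, abs=0.03)

    def test_determinism_same_seed(self):
        a = simulate_cohort(CohortConfig(n_genes=200, markers_per_subtype=20, seed=5))
        b = simulate_cohort(CohortConfig(n_genes=200, markers_per_subtype=20, seed=5))
        pd.testing.assert_frame_equal(a[0], b[0])
        pd.testing.assert_frame_equal(a[1], b[1])
        assert np.array_equal(a[2].labels, b[2].labels)
        c = simulate_cohort(CohortConfig(n_genes=200, markers_per_subtype=20, seed=6))
        assert not a[0].equals(c[0])

    def test_effect_injection_approaches_shift_as_noise_vanishes(self):
        gaps = []
        for sd in (0.5, 0.05):
            cfg = CohortConfig(n_genes=200, subtype_sizes=(30, 30, 10), markers_per_subtype=15,
                               marker_log2_shift=1.5, noise_sd=sd, seed=9)
            expr, _, truth = simulate_cohort(cfg)
            diffs = []
            for s, markers in truth.marker_ids.items():
                own = expr.loc[markers, truth.labels == s].to_numpy().mean()
                rest = expr.loc[markers, truth.labels != s].to_numpy().mean()
                diffs.append(own - rest)
            gaps.append(abs(np.mean(diffs) - 1.5))
        assert gaps[1] < gaps[0]
        assert gaps[1] < 0.02

    def test_covariate_rates_respected_at_scale(self):
        cfg = CohortConfig(
            n_genes=5,
            subtype_sizes=(5000, 5000),
            markers_per_subtype=1,
            survival_medians=(30.0, 20.0),
            censor_rate_per_subtype=(0.3, 0.3),
            covariate_rates={"distant_met": (0.4, 0.7), "recurrence": (0.5, 0.6)},
            seed=13,
        )
        _, clinical, truth = simulate_cohort(cfg)
        for s, rate in ((1, 0.4), (2, 0.7)):
            assert clinical.loc[truth.labels == s, "distant_met"].mean() == pytest.approx(rate, abs=0.03)


class TestSimulateGenesets:
    def test_no_decoys_gives_one_set_per_subtype(self, small_cohort):
        _, _, _, truth = small_cohort
        coll = simulate_genesets(truth, n_decoy_sets=0, set_size=10, seed=1)
        assert len(coll) == len(truth.marker_ids)

    def test_planted_set_subset_of_markers(self, small_cohort):
        _, _, _, truth = small_cohort
        coll = simulate_genesets(truth, n_decoy_sets=3, set_size=10, seed=1)
        assert set(coll.sets["SUBTYPE2_MARKERS"]) <= set(truth.marker_ids[2])

    def test_gmt_round_trip(self, small_cohort, tmp_path):
        _, _, _, truth = small_cohort
        coll = simulate_genesets(truth, n_decoy_sets=5, set_size=20, seed=2)
        path = tmp_path / "sets.gmt"
        io.write_gmt(coll, path)
        back = io.read_gmt(path)
        assert back.sets == coll.sets

    def test_oversized_sets_rejected(self, small_cohort):
        _, _, _, truth = small_cohort
        with pytest.raises(ValueError):
            simulate_genesets(truth, set_size=10**6)
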