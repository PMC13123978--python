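"""Generator contracts: determinism, planted structure, analytic marginals."""

import numpy as np
import pandas as pd
import pytest

from capspec.repertoire import LEVELS
from capspec.synthetic import (
    BASE_LEVEL,
    ConfigError,
    PlantedSpec,
    SimConfig,
    simulate_companion_tables,
    simulate_population,
    simulate_repertoires,
    simulate_study,
)


def _pop_df(records):
    return pd.DataFrame([(r.isolate_id, r.sc, r.k_locus) for r in records],
                        columns=["id", "sc", "k"])


class TestPopulation:
    def test_zero_switch_rate_pins_klocus_to_lineage(self):
        cfg = SimConfig(n_isolates=200, n_sc=10, k_switch_rate=0.0)
        pop = _pop_df(simulate_population(cfg, seed=5))
        # every SC maps to exactly one K-locus
        assert (pop.groupby("sc")["k"].nunique() == 1).all()

    def test_single_sc_population(self):
        cfg = SimConfig(n_isolates=100, n_sc=1)
        pop = _pop_df(simulate_population(cfg, seed=2))
        assert pop["sc"].nunique() == 1

    def test_determinism_bit_identical(self):
        cfg = SimConfig(n_isolates=500, n_sc=25, k_switch_rate=0.1)
        a = _pop_df(simulate_population(cfg, seed=7))
        b = _pop_df(simulate_population(cfg, seed=7))
        pd.testing.assert_frame_equal(a, b)

    def test_every_sc_occupied(self):
        cfg = SimConfig(n_isolates=60, n_sc=30)
        pop = _pop_df(simulate_population(cfg, seed=1))
        assert pop["sc"].nunique() == 30

    @pytest.mark.parametrize(
        "field,value",
        [("n_sc", 0), ("n_kloci", 1), ("k_switch_rate", 1.5),
         ("sc_concentration", 0.0), ("background_freq_range", (0.5, 0.2))],
    )
    def test_invalid_config_names_field(self, field, value):
        cfg = SimConfig(**{field: value})
        with pytest.raises(ConfigError, match=field):
            simulate_population(cfg, seed=0)


class TestRepertoires:
    def test_perfect_planted_cluster_equals_klocus_indicator(self):
        cfg = SimConfig(
            n_isolates=150, n_sc=10, n_background_clusters=5,
            merge_prob=0.0, split_prob=0.0,
            planted_specs=(PlantedSpec("KL1", sensitivity=1.0, fpr=0.0),),
        )
        iso = simulate_population(cfg, seed=9)
        mats, truth = simulate_repertoires(iso, cfg, seed=9)
        col = mats[BASE_LEVEL.label].df["rbp_KL1"].to_numpy()
        k = np.array([1 if r.k_locus == "KL1" else 0 for r in iso])
        assert np.array_equal(col, k)

    def test_noiseless_copy_identical_to_parent(self):
        cfg = SimConfig(
            n_isolates=100, n_sc=5, n_background_clusters=3,
            merge_prob=0.0, split_prob=0.0,
            planted_specs=(
                PlantedSpec("KL1"),
                PlantedSpec("KL1", kind="correlated_copy", copy_noise=0.0),
            ),
        )
        iso = simulate_population(cfg, seed=4)
        mats, _ = simulate_repertoires(iso, cfg, seed=4)
        df = mats[BASE_LEVEL.label].df
        assert np.array_equal(df["rbp_KL1"].to_numpy(), df["copy_KL1"].to_numpy())

    def test_planted_counts_match_binomial_expectation(self):
        """Carriage counts among target/non-target isolates follow the
        configured sensitivity and false-positive rate (3-sigma band)."""
        cfg = SimConfig(
            n_isolates=500, n_sc=25, n_background_clusters=0,
            merge_prob=0.0, split_prob=0.0,
            planted_specs=(PlantedSpec("KL1", sensitivity=0.9, fpr=0.01),),
        )
        for seed in range(1, 21):
            iso = simulate_population(cfg, seed=seed)
            mats, _ = simulate_repertoires(iso, cfg, seed=seed)
            col = mats[BASE_LEVEL.label].df["rbp_KL1"].to_numpy().astype(bool)
            k = np.array([r.k_locus == "KL1" for r in iso])
            n_t, n_o = k.sum(), (~k).sum()
            tp, fp = (col & k).sum(), (col & ~k).sum()
            assert abs(tp - 0.9 * n_t) <= 3 * np.sqrt(n_t * 0.9 * 0.1) + 1
            assert abs(fp - 0.01 * n_o) <= 3 * np.sqrt(n_o * 0.01 * 0.99) + 1

    def test_background_marginal_frequencies(self):
        """Observed carriage of background clusters stays within
        4*sqrt(f(1-f)/n) of the drawn frequency."""
        cfg = SimConfig(n_isolates=500, n_sc=10, n_background_clusters=40)
        for seed in range(10):
            study = simulate_study(cfg, seed=seed)
            df = study.matrices[BASE_LEVEL.label].df
            n = len(df)
            for cid, f in study.truth.background_freqs.items():
                obs = df[cid].mean()
                assert abs(obs - f) <= 4 * np.sqrt(f * (1 - f) / n)

    def test_truth_implied_precision_recall_converge(self):
        """Empirical precision/recall of a planted column approach the
        analytic values from sensitivity/fpr and K-locus prevalence."""
        cfg = SimConfig(
            n_isolates=5000, n_sc=50, n_background_clusters=0,
            merge_prob=0.0, split_prob=0.0,
            planted_specs=(PlantedSpec("KL1", sensitivity=0.9, fpr=0.01),),
        )
        iso = simulate_population(cfg, seed=13)
        mats, _ = simulate_repertoires(iso, cfg, seed=13)
        col = mats[BASE_LEVEL.label].df["rbp_KL1"].to_numpy().astype(bool)
        k = np.array([r.k_locus == "KL1" for r in iso])
        pi = k.mean()
        precision = (col & k).sum() / col.sum()
        recall = (col & k).sum() / k.sum()
        expected_precision = 0.9 * pi / (0.9 * pi + 0.01 * (1 - pi))
        assert abs(precision - expected_precision) < 0.05
        assert abs(recall - 0.9) < 0.05

    def test_cross_level_map_resolves_everywhere(self, small_study):
        for cid, info in small_study.truth.planted.items():
            assert set(info.level_map) == {lv.label for lv in LEVELS}
            for lv in LEVELS:
                mat = small_study.matrices[lv.label]
                for level_id in info.level_map[lv.label]:
                    assert level_id in mat.df.columns

    def test_matrices_share_isolate_axis(self, small_study):
        axes = {tuple(m.isolates) for m in small_study.matrices.values()}
        assert len(axes) == 1

    def test_merge_unions_and_split_partitions_carriers(self):
        cfg = SimConfig(
            n_isolates=200, n_sc=10, n_background_clusters=10,
            merge_prob=1.0, split_prob=1.0,
            planted_specs=(PlantedSpec("KL1"),),
        )
        iso = simulate_population(cfg, seed=6)
        mats, truth = simulate_repertoires(iso, cfg, seed=6)
        base = mats[BASE_LEVEL.label].df["rbp_KL1"].to_numpy()
        info = truth.planted["rbp_KL1"]
        # strictest level: two sub-clusters partition the carriers
        strict = mats["i80c80"]
        ids = info.level_map["i80c80"]
        assert len(ids) == 2
        combined = strict.df[ids[0]].to_numpy() + strict.df[ids[1]].to_numpy()
        assert combined.max() <= 1
        assert np.array_equal(combined > 0, base > 0)
        # loosest level: merged column is a superset of base carriers
        loose = mats["i0c50"]
        merged_id = info.level_map["i0c50"][0]
        merged = loose.df[merged_id].to_numpy()
        assert np.all(merged >= base)

    def test_absent_target_klocus_raises(self):
        cfg = SimConfig(n_isolates=50, n_sc=5,
                        planted_specs=(PlantedSpec("KL99"),))
        iso = simulate_population(cfg, seed=0)
        with pytest.raises(ConfigError, match="KL99"):
            simulate_repertoires(iso, cfg, seed=0)


class TestCompanionTables:
    def test_fixed_seed_identical_tables(self, small_study):
        again = simulate_companion_tables(
            type(small_study)(isolates=small_study.isolates,
                              matrices=small_study.matrices,
                              truth=small_study.truth),
            seed=2,
        )
        pd.testing.assert_frame_equal(small_study.detection_table, again.detection_table)
        pd.testing.assert_frame_equal(small_study.qc_table, again.qc_table)
        pd.testing.assert_frame_equal(small_study.phrog_hits, again.phrog_hits)
        pd.testing.assert_frame_equal(small_study.ecod_hits, again.ecod_hits)

    def test_true_rbp_hits_are_tail_fibers_with_configured_domain(self, small_study):
        phrog = small_study.phrog_hits
        rows = phrog[phrog["cluster_id"] == "rbp_KL1"]
        assert (rows["category"] == "tail fiber").all()
        ecod = small_study.ecod_hits
        rows = ecod[ecod["cluster_id"] == "rbp_KL1"]
        assert (rows["t_level"] == "207.2.1").all()

    def test_every_isolate_has_detections_and_qc(self, small_study):
        det = small_study.detection_table
        assert set(det["isolate_id"]) == {r.isolate_id for r in small_study.isolates}
        assert set(det["tool"]) == {"virsorter", "phispy"}
        assert len(small_study.qc_table) == len(small_study.isolates)
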