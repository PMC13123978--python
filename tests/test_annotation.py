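"""PHROG/ECOD aggregation, RBP calling and Simpson K-locus diversity."""


import numpy as np
import pandas as pd
import pytest

from capspec.annotation import (
    EcodHit,
    PhrogHit,
    Pc80Annotation,
    annotate_pc80,
    diversity_table,
    is_rbp,
    label_pc50,
    prophage_domain_summary,
    rbp_domains,
    simpson,
)


def _ecod(t_level, prob, tcov=0.5, cid="pc80_1"):
    return EcodHit(cluster_id=cid, x_level=t_level.split(".")[0],
                   t_level=t_level, probability=prob, tcov=tcov)


class TestAnnotatePc80:
    def test_no_passing_hits_empty(self):
        ann = annotate_pc80([_ecod("207.2.1", 0.5)])
        assert ann.t_levels == []

    def test_per_xlevel_max_survives(self):
        ann = annotate_pc80([_ecod("207.2.1", 0.9), _ecod("207.3.1", 0.8)])
        assert [t for t, _ in ann.t_levels] == ["207.2.1"]

    def test_top_five_by_probability(self):
        hits = [_ecod(f"{100 + i}.1.1", 0.72 + i * 0.02) for i in range(7)]
        ann = annotate_pc80(hits)
        assert len(ann.t_levels) == 5
        probs = [p for _, p in ann.t_levels]
        assert probs == sorted(probs, reverse=True)
        assert ann.t_levels[0][0] == "106.1.1"

    def test_mixed_cluster_ids_rejected(self):
        with pytest.raises(ValueError, match="several"):
            annotate_pc80([_ecod("1.1.1", 0.9, cid="a"), _ecod("1.1.1", 0.9, cid="b")])


class TestLabelPc50:
    def _ann(self, *tlevels):
        return Pc80Annotation(pc80_id="m", t_levels=[(t, 0.9) for t in tlevels])

    def test_modal_combination_and_pectin_flag(self):
        members = [self._ann("2007.5.1")] * 3 + [self._ann("207.2.1", "877.1.1")] * 2
        label = label_pc50("pc50_1", members)
        assert label.modal_combination == frozenset({"2007.5.1"})
        assert label.pectin_lyase is True

    def test_single_member(self):
        label = label_pc50("pc50_1", [self._ann("79.1.1")])
        assert label.modal_combination == frozenset({"79.1.1"})
        assert not label.pectin_lyase

    def test_all_unannotated(self):
        label = label_pc50("pc50_1", [self._ann(), self._ann()])
        assert label.modal_combination == frozenset()
        assert not label.pectin_lyase

    def test_member_order_invariant(self):
        members = [self._ann("a.1.1"), self._ann("b.1.1"), self._ann("a.1.1")]
        a = label_pc50("x", members)
        b = label_pc50("x", list(reversed(members)))
        assert a.modal_combination == b.modal_combination


class TestIsRbp:
    def _hit(self, cat, prob=0.95, qcov=0.6, scov=0.7):
        return PhrogHit(cluster_id="c", category=cat, probability=prob,
                        qcov=qcov, scov=scov)

    def test_fibre_spelling_normalized(self):
        assert is_rbp([self._hit("tail fibre")])
        assert is_rbp([self._hit("Tail Fiber protein")])

    def test_probability_boundary(self):
        assert not is_rbp([self._hit("tail fiber", prob=0.89)])
        assert is_rbp([self._hit("tail spike", prob=0.90)])

    def test_non_tail_category(self):
        assert not is_rbp([self._hit("major capsid")])

    def test_threshold_monotonicity(self):
        hits = [self._hit("tail fiber", prob=0.92, qcov=0.55, scov=0.52)]
        assert is_rbp(hits)
        assert is_rbp(hits, min_prob=0.8)  # lowering never removes a call
        assert not is_rbp(hits, min_qcov=0.6)


class TestRbpDomains:
    def test_multi_domain_assignment(self):
        hits = [_ecod("207.2.1", 0.95, tcov=0.3), _ecod("2007.5.1", 0.92, tcov=0.15)]
        assert rbp_domains(hits) == frozenset({"207.2.1", "2007.5.1"})

    def test_low_tcov_excluded(self):
        assert rbp_domains([_ecod("207.2.1", 0.95, tcov=0.05)]) == frozenset()

    def test_no_passing_hits_empty(self):
        assert rbp_domains([_ecod("207.2.1", 0.5)]) == frozenset()


class TestSimpson:
    def test_single_locus_zero(self):
        assert simpson({"KL1": 10}) == 0.0

    def test_even_split(self):
        assert simpson({"KL1": 5, "KL2": 5}) == pytest.approx(0.5)

    def test_worked_example(self):
        assert simpson({"A": 6, "B": 3, "C": 1}) == pytest.approx(0.54)

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError, match="total"):
            simpson({"A": 0})

    @pytest.mark.parametrize("m", range(2, 11))
    def test_uniform_distribution_attains_upper_bound(self, m):
        counts = {f"K{i}": 7 for i in range(m)}
        assert simpson(counts) == pytest.approx(1 - 1 / m)

    def test_permutation_invariant_and_bounded(self, rng):
        for _ in range(20):
            m = int(rng.integers(1, 10))
            vals = rng.integers(1, 50, m)
            counts = {f"K{i}": int(v) for i, v in enumerate(vals)}
            s = simpson(counts)
            assert 0 <= s <= 1 - 1 / m + 1e-12
            shuffled = dict(zip([f"K{i}" for i in rng.permutation(m)], vals.tolist()))
            assert simpson(shuffled) == pytest.approx(s)


class TestDiversityTable:
    def _inputs(self):
        membership = pd.DataFrame(
            [("c1", f"I{i}") for i in range(12)] + [("c2", f"I{i}") for i in range(9)],
            columns=["cluster_id", "isolate_id"],
        )
        kloci = {f"I{i}": "KL2" for i in range(12)}
        scs = {f"I{i}": f"SC{i % 3}" for i in range(12)}
        return membership, kloci, scs

    def test_small_cluster_excluded_large_included(self):
        membership, kloci, scs = self._inputs()
        tab = diversity_table({"c1": frozenset({"207.2.1"}), "c2": frozenset()},
                              membership, kloci, scs)
        assert list(tab["cluster_id"]) == ["c1"]  # c2 has 9 members < 10
        assert tab.iloc[0]["simpson"] == 0.0  # all members KL2

    def test_min_scs_gate(self):
        membership, kloci, _ = self._inputs()
        one_sc = {f"I{i}": "SC0" for i in range(12)}
        tab = diversity_table({"c1": frozenset()}, membership, kloci, one_sc)
        assert len(tab) == 0

    def test_planted_rbp_less_diverse_than_background(self, small_study):
        """A capsule-specific cluster concentrates in one K-locus, so its
        Simpson index falls below the background median."""
        base = small_study.matrices["i50c50"].df
        kloci = small_study.k_map
        from collections import Counter

        def simpson_of(cid):
            carriers = base.index[base[cid] == 1]
            return simpson(Counter(kloci[i] for i in carriers))

        rbp = simpson_of("rbp_KL1")
        bg = [simpson_of(c) for c in small_study.truth.background_ids
              if base[c].sum() >= 2]
        assert rbp < np.median(bg)


class TestProphageDomainSummary:
    def _tables(self):
        gene_order = pd.DataFrame(
            [("ph1", 0, "capsid"), ("ph1", 1, "rbp_a"), ("ph1", 2, "other"),
             ("ph2", 0, "rbp_b"),
             ("ph3", 0, "rbp_c"), ("ph3", 1, "helper"), ("ph3", 2, "enz"),
             ("ph4", 0, "capsid")],
            columns=["prophage_id", "position", "cluster_id"],
        )
        meta = pd.DataFrame(
            [("ph1", "KL1", 95.0), ("ph2", "KL1", 99.0),
             ("ph3", "KL2", 92.0), ("ph4", "KL2", 91.0),
             ("ph5", "KL2", 50.0)],
            columns=["prophage_id", "k_locus", "completeness"],
        )
        rbp_calls = {"rbp_a": True, "rbp_b": True, "rbp_c": True}
        domain_sets = {
            "rbp_a": frozenset({"2007.5.1"}),
            "rbp_b": frozenset({"877.1.1", "2007.5.1"}),
            "rbp_c": frozenset(),
            "enz": frozenset({"207.2.1"}),
        }
        return gene_order, meta, rbp_calls, domain_sets

    def test_strata_assignment(self):
        counts, neighbors = prophage_domain_summary(*self._tables())
        by = {(r.k_locus, r.stratum): r.count for r in counts.itertuples()}
        assert by[("KL1", "single:2007.5.1")] == 1  # ph1
        assert by[("KL1", "multi_domain")] == 1  # ph2
        assert by[("KL2", "rbp_no_domain")] == 1  # ph3
        assert by[("KL2", "no_rbp")] == 1  # ph4

    def test_neighborhood_scan_reports_adjacent_enzyme(self):
        _, neighbors = prophage_domain_summary(*self._tables())
        assert len(neighbors) == 1
        row = neighbors.iloc[0]
        assert row["prophage_id"] == "ph3" and row["domain"] == "207.2.1"
        assert row["offset"] == 2

    def test_strata_partition_high_completeness_set(self):
        counts, _ = prophage_domain_summary(*self._tables())
        assert counts["count"].sum() == 4  # ph5 excluded by completeness

    def test_low_completeness_excluded_everywhere(self):
        counts, _ = prophage_domain_summary(*self._tables())
        assert "ph5" not in set(counts.attrs["per_prophage"]["prophage_id"])
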