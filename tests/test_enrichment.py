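"""Hypergeometric tests, BH adjustment, module enrichment, KO inventories,
pathway completeness."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from modscape import (
    AnnotationMap,
    PathwayDefinition,
    ValidationError,
    bh_adjust,
    enrich_modules,
    hypergeom_upper_tail,
    ko_inventory,
    pathway_completeness,
)
from modscape.community import ModulePartition
from modscape.enrichment import read_pathway_definitions


def _part(assignment):
    return ModulePartition(assignment, resolution=1.0, modularity=0.0, seed=0)


class TestHypergeomUpperTail:
    def test_zero_successes_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 4, 10) == 1.0

    def test_hand_enumerated_case(self):
        # C(4,3)C(6,2) + C(4,4)C(6,1) over C(10,5) = 66/252
        assert hypergeom_upper_tail(3, 5, 4, 10) == pytest.approx(66 / 252, abs=1e-12)

    def test_maximum_k_equals_pmf_point(self):
        for N, M, K in [(10, 4, 6), (20, 8, 5), (30, 15, 15)]:
            k = min(M, K)
            pmf = (
                math.comb(K, k) * math.comb(N - K, M - k) / math.comb(N, M)
            )
            assert hypergeom_upper_tail(k, M, K, N) == pytest.approx(pmf, rel=1e-10)

    @pytest.mark.parametrize(
        "k,M,K,N,msg",
        [
            (5, 4, 6, 10, "min"),
            (1, 11, 4, 10, "M <= N"),
            (1, 4, 11, 10, "K <= N"),
            (-1, 4, 6, 10, "min"),
        ],
    )
    def test_bound_violations_named(self, k, M, K, N, msg):
        with pytest.raises(ValidationError, match=msg):
            hypergeom_upper_tail(k, M, K, N)


class TestBHAdjust:
    def test_hand_stepup_case(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_test_unchanged(self):
        np.testing.assert_allclose(bh_adjust([1.0]), [1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])
        with pytest.raises(ValidationError):
            bh_adjust([-0.1])

    def test_output_order_matches_input_order(self):
        p = [0.04, 0.01, 0.30, 0.02]
        q = bh_adjust(p)
        # q of the i-th input corresponds to the i-th p
        resorted = bh_adjust(sorted(p))
        assert sorted(q) == pytest.approx(list(resorted))
        assert q[2] == max(q)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=40))
    def test_monotone_and_dominates_p(self, p):
        q = bh_adjust(p)
        assert np.all(q >= np.asarray(p) - 1e-15)
        assert np.all(q <= 1.0 + 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestEnrichModules:
    def test_fully_annotated_module_closed_form(self):
        assignment = {f"p{i}": 0 for i in range(5)}
        assignment.update({f"q{i}": 1 for i in range(5)})
        ann = AnnotationMap(
            pathway_of={f"p{i}": {"PWY-X"} for i in range(5)},
            background_size=100,
        )
        df = enrich_modules(_part(assignment), ann, min_K=2)
        row = df[(df.module == 0) & (df.pathway == "PWY-X")].iloc[0]
        assert row.p_value == pytest.approx(1 / math.comb(100, 5), rel=1e-9)
        assert row.k == 5 and row.M == 5 and row.K == 5 and row.N == 100
        assert bool(row.significant)

    def test_absent_pathway_not_tested(self):
        assignment = {"a": 0, "b": 1}
        ann = AnnotationMap(
            pathway_of={"b": {"PWY-Y"}, "x": {"PWY-Y"}}, background_size=50
        )
        df = enrich_modules(_part(assignment), ann, min_K=2)
        assert not ((df.module == 0) & (df.pathway == "PWY-Y")).any()

    def test_min_K_filters_small_pathways(self):
        assignment = {"a": 0}
        ann = AnnotationMap(pathway_of={"a": {"PWY-Z"}}, background_size=10)
        assert enrich_modules(_part(assignment), ann, min_K=2).empty
        assert len(enrich_modules(_part(assignment), ann, min_K=1)) == 1

    def test_background_smaller_than_partition_rejected(self):
        assignment = {f"p{i}": 0 for i in range(10)}
        ann = AnnotationMap(pathway_of={"p0": {"A"}}, background_size=5)
        with pytest.raises(ValidationError, match="background"):
            enrich_modules(_part(assignment), ann)

    def test_sum_rule_k_never_exceeds_K(self):
        rng = np.random.default_rng(0)
        assignment = {f"p{i}": int(rng.integers(3)) for i in range(60)}
        pathway_of = {
            f"p{i}": {f"P{j}" for j in rng.integers(0, 6, size=2)}
            for i in range(60)
            if rng.random() < 0.5
        }
        ann = AnnotationMap(pathway_of=pathway_of, background_size=80)
        df = enrich_modules(_part(assignment), ann, min_K=1)
        for pw, grp in df.groupby("pathway"):
            assert grp.k.sum() <= grp.K.iloc[0]

    def test_per_module_scope_adjusts_within_modules(self):
        assignment = {f"p{i}": i // 10 for i in range(20)}
        rng = np.random.default_rng(1)
        pathway_of = {
            f"p{i}": {f"P{j}" for j in rng.integers(0, 4, size=1)} for i in range(20)
        }
        ann = AnnotationMap(pathway_of=pathway_of, background_size=30)
        pooled = enrich_modules(_part(assignment), ann, scope="pooled", min_K=1)
        per = enrich_modules(_part(assignment), ann, scope="per_module", min_K=1)
        for label in per.module.unique():
            sub = per[per.module == label]
            np.testing.assert_allclose(
                sub.q_value.to_numpy(), bh_adjust(sub.p_value.to_numpy())
            )
        assert len(pooled) == len(per)


class TestKOInventory:
    def test_unique_ko_dedup(self):
        ann = AnnotationMap(
            ko_of={"p1": {"K1"}, "p2": {"K1"}, "p3": {"K2"}}, background_size=3
        )
        inv = ko_inventory({"p1", "p2", "p3"}, ann)
        assert inv.n_proteins == 3
        assert inv.n_with_ko == 3
        assert inv.unique_kos == {"K1", "K2"}

    def test_unannotated_module_empty_inventory(self):
        ann = AnnotationMap(ko_of={"z": {"K9"}}, background_size=5)
        inv = ko_inventory({"p1", "p2"}, ann)
        assert inv.n_with_ko == 0
        assert inv.unique_kos == set()

    def test_categories_counted_by_unique_ko(self):
        ann = AnnotationMap(
            ko_of={"p1": {"K1", "K2"}, "p2": {"K2"}}, background_size=2
        )
        inv = ko_inventory(
            {"p1", "p2"}, ann, category_map={"K1": "energy", "K2": "energy"}
        )
        assert inv.category_counts == {"energy": 2}


class TestPathwayCompleteness:
    def test_full_and_partial_completeness(self):
        ann = AnnotationMap(
            ec_of={"p1": {"1.18.6.1"}, "p2": {"4.2.1.24"}}, background_size=10
        )
        full = pathway_completeness(
            PathwayDefinition("nif", frozenset({"1.18.6.1", "4.2.1.24"})), ann
        )
        assert full.completeness == pytest.approx(1.0)
        partial = pathway_completeness(
            PathwayDefinition("x", frozenset({"1.18.6.1", "4.2.1.24", "9.9.9.9"})), ann
        )
        assert partial.completeness == pytest.approx(2 / 3)
        assert partial.missing_ecs == {"9.9.9.9"}

    def test_module_localisation_inside_and_outside(self):
        ann = AnnotationMap(
            ec_of={"nifD": {"1.18.6.1"}, "nifH": {"1.18.6.1.h"}},
            background_size=10,
        )
        part = _part({"nifD": 0, "other": 1})
        rep = pathway_completeness(
            PathwayDefinition("nif", frozenset({"1.18.6.1", "1.18.6.1.h"})), ann, part
        )
        assert rep.module_localisation["1.18.6.1"] == {0}
        assert rep.module_localisation["1.18.6.1.h"] == {"outside"}

    def test_empty_definition_rejected(self):
        with pytest.raises(ValidationError):
            PathwayDefinition("x", frozenset())

    def test_definition_file_round_trip(self, tmp_path):
        f = tmp_path / "defs.tsv"
        f.write_text("nif\t1.18.6.1,1.18.6.1.h\nmev\t2.3.3.10\n")
        defs = read_pathway_definitions(f)
        assert defs[0].required_ecs == {"1.18.6.1", "1.18.6.1.h"}
        assert defs[1].pathway_id == "mev"
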