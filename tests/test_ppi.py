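"""Feature vectors, family clustering, and edge inference against
independently coded brute-force oracles."""

import itertools
import random

import numpy as np
import pandas as pd
import pytest

from modscape import (
    FeatureSimilarityParams,
    ValidationError,
    assemble_network,
    cluster_families,
    compute_feature_vector,
    default_index_set,
    gen_panel,
    infer_network,
    neighbourhood_edges,
    profile_edges,
)
from modscape.io_formats import GenomeRecord, ProteinEntry
from modscape.ppi import ProteinFamily, family_id_for_seed
from modscape.propensity import CANONICAL_RESIDUES, IndexSet


def _uniform_table(value: float) -> dict:
    return {r: value for r in CANONICAL_RESIDUES}


class TestFeatureVector:
    def test_constant_sequence_returns_table_value(self):
        table = _uniform_table(0.0)
        table["A"] = 1.0
        idx = IndexSet(names=("t",), tables=(table,))
        assert compute_feature_vector("AAAA", idx)[0] == pytest.approx(1.0)

    def test_two_residue_arithmetic_mean(self):
        table = _uniform_table(0.0)
        table.update({"A": 1.0, "G": 3.0})
        idx = IndexSet(names=("t",), tables=(table,))
        assert compute_feature_vector("AG", idx)[0] == pytest.approx(2.0)

    def test_x_residue_takes_table_mean(self):
        table = {r: float(i) for i, r in enumerate(CANONICAL_RESIDUES)}
        idx = IndexSet(names=("t",), tables=(table,))
        expected = (table["A"] + np.mean(list(table.values()))) / 2
        assert compute_feature_vector("AX", idx)[0] == pytest.approx(expected)

    def test_random_sequence_matches_summation_oracle(self):
        rng = random.Random(42)
        seq = "".join(rng.choice(CANONICAL_RESIDUES) for _ in range(100))
        idx = default_index_set()
        got = compute_feature_vector(seq, idx)
        # independent per-residue summation
        for i, table in enumerate(idx.tables):
            expected = sum(table[r] for r in seq) / len(seq)
            assert abs(got[i] - expected) <= 1e-12 * max(1.0, abs(expected))

    def test_empty_sequence_and_bad_residue_rejected(self):
        idx = IndexSet(names=("t",), tables=(_uniform_table(1.0),))
        with pytest.raises(ValidationError):
            compute_feature_vector("", idx)
        with pytest.raises(ValidationError, match="offset 1"):
            compute_feature_vector("AZA", idx)


def _genome(genome_id, seqs, contig=None):
    return GenomeRecord(
        genome_id=genome_id,
        proteins=[
            ProteinEntry(f"{genome_id}_{i}", s, position=i, contig_id=contig)
            for i, s in enumerate(seqs)
        ],
    )


class TestClusterFamilies:
    def test_identical_copies_join_reference_families(self):
        seqs = ["MKLVW" * 10, "ARNDC" * 12, "WYHKR" * 9]
        ref = _genome("ref", seqs)
        other = _genome("B", seqs)
        families, profiles = cluster_families([ref, other], "ref")
        seeded = [f for f in families if f.reference_members]
        assert len(seeded) == 3
        assert all(any(g == "B" for g, _ in f.members) for f in seeded)
        assert (profiles.loc[[f.family_id for f in seeded], "B"] == 1).all()
        assert (profiles.loc[[f.family_id for f in seeded], "ref"] == 1).all()

    def test_tie_goes_to_lexicographically_smaller_family(self):
        seq = "MKLVW" * 10
        ref = GenomeRecord(
            "ref",
            [
                ProteinEntry("pB", seq, 0),
                ProteinEntry("pA", seq, 1),
            ],
        )
        other = _genome("Z", [seq])
        families, _ = cluster_families([ref, other], "ref")
        fam = next(f for f in families if ("Z", "Z_0") in f.members)
        assert fam.family_id == family_id_for_seed("pA")

    def test_unmatched_protein_becomes_singleton(self):
        ref = _genome("ref", ["MKLVW" * 10])
        other = _genome("B", ["DDDDDDDDDD"])
        families, profiles = cluster_families([ref, other], "ref")
        singletons = [f for f in families if not f.reference_members]
        assert len(singletons) == 1
        assert profiles.loc[singletons[0].family_id, "ref"] == 0

    def test_missing_reference_rejected(self):
        with pytest.raises(ValidationError, match="nope"):
            cluster_families([_genome("A", ["MK" * 40])], "nope")

    def test_planted_panel_mutation_zero_recovers_truth(self):
        panel, truth = gen_panel(5, 12, mutation_rate=0.0, seed=3)
        families, _ = cluster_families(panel, "G00")
        member_to_family = {
            m: f.family_id for f in families for m in f.members
        }
        for (g, pid), fam in truth.membership.items():
            if truth.presence.loc[fam, "G00"] == 1:
                assert member_to_family[(g, pid)] == family_id_for_seed(f"G00_{fam}")


def _families_from_profiles(profiles: pd.DataFrame) -> list[ProteinFamily]:
    """One single-reference-member family per profile row."""
    return [
        ProteinFamily(fid, members={("ref", f"r_{fid}")}, reference_members={f"r_{fid}"})
        for fid in profiles.index
    ]


def _brute_profile_edges(profiles, h, g_min, ubiquity):
    """All-pairs comparator, coded independently of the implementation."""
    edges = set()
    fids = list(profiles.index)
    n_genomes = profiles.shape[1]
    for fa, fb in itertools.combinations(fids, 2):
        ra, rb = profiles.loc[fa], profiles.loc[fb]
        ok = True
        for row in (ra, rb):
            if row.sum() < g_min:
                ok = False
            if ubiquity and row.sum() == n_genomes:
                ok = False
        if ok and int((ra != rb).sum()) <= h:
            edges.add(tuple(sorted((f"r_{fa}", f"r_{fb}"))))
    return edges


class TestProfileEdges:
    @pytest.mark.parametrize("ubiquity,expected_edges", [(True, 1), (False, 1)])
    def test_exact_match_rule(self, ubiquity, expected_edges):
        profiles = pd.DataFrame(
            [[1, 1, 0, 1], [1, 1, 0, 1], [1, 1, 1, 1]],
            index=["fA", "fB", "fC"],
            columns=list("wxyz"),
        )
        fams = _families_from_profiles(profiles)
        edges = profile_edges(
            profiles, fams, max_hamming=0, min_support=2, ubiquity_filter=ubiquity
        )
        assert len(edges) == expected_edges
        assert ("r_fA", "r_fB") in edges

    def test_random_matrix_matches_brute_force(self):
        rng = np.random.default_rng(17)
        profiles = pd.DataFrame(
            rng.integers(0, 2, size=(30, 8)).astype(np.int8),
            index=[f"f{i:02d}" for i in range(30)],
            columns=[f"g{j}" for j in range(8)],
        )
        fams = _families_from_profiles(profiles)
        for h, g_min, ubi in [(0, 3, True), (1, 2, False), (2, 1, True)]:
            got = profile_edges(profiles, fams, h, g_min, ubi)
            assert got == _brute_profile_edges(profiles, h, g_min, ubi)

    def test_monotone_in_hamming_and_support(self):
        rng = np.random.default_rng(8)
        profiles = pd.DataFrame(
            rng.integers(0, 2, size=(20, 6)).astype(np.int8),
            index=[f"f{i:02d}" for i in range(20)],
            columns=[f"g{j}" for j in range(6)],
        )
        fams = _families_from_profiles(profiles)
        tight = profile_edges(profiles, fams, 0, 3, False)
        assert tight <= profile_edges(profiles, fams, 1, 3, False)
        assert tight <= profile_edges(profiles, fams, 0, 2, False)


class TestNeighbourhoodEdges:
    def _panel_with_adjacency(self, adjacent_in):
        """Families A,B adjacent in the listed genomes, separated elsewhere."""
        seq = {"A": "MKLVW" * 10, "B": "ARNDC" * 10, "C": "WYHKR" * 10}
        panel = []
        for gid in ["g1", "g2", "g3", "g4"]:
            order = ["A", "B", "C"] if gid in adjacent_in else ["A", "C", "B"]
            panel.append(_genome(gid, [seq[f] for f in order]))
        families = []
        for fam in ["A", "B", "C"]:
            members = set()
            refm = set()
            for gid in ["g1", "g2", "g3", "g4"]:
                order = ["A", "B", "C"] if gid in adjacent_in else ["A", "C", "B"]
                pid = f"{gid}_{order.index(fam)}"
                members.add((gid, pid))
                if gid == "g1":
                    refm.add(pid)
            families.append(ProteinFamily(f"fam{fam}", members, refm))
        return panel, families

    def test_adjacency_in_enough_genomes_makes_edge(self):
        panel, families = self._panel_with_adjacency({"g1", "g2", "g3"})
        edges = neighbourhood_edges(panel, families, window=1, min_genomes=2)
        assert ("g1_0", "g1_1") in edges  # A-B in the reference genome g1

    def test_reference_only_adjacency_below_support(self):
        panel, families = self._panel_with_adjacency({"g1"})
        edges = neighbourhood_edges(panel, families, window=1, min_genomes=2)
        assert ("g1_0", "g1_1") not in edges

    def test_random_panel_matches_quadratic_scan(self):
        panel, truth = gen_panel(6, 15, mutation_rate=0.0, seed=9)
        families, _ = cluster_families(panel, "G00")
        fam_of = {m: f.family_id for f in families for m in f.members}
        ref_of = {}
        for f in families:
            for pid in f.reference_members:
                ref_of.setdefault(f.family_id, set()).add(pid)
        for w, n_min in [(1, 3), (2, 2)]:
            got = neighbourhood_edges(panel, families, window=w, min_genomes=n_min)
            # oracle: direct quadratic scan over every genome's gene order
            support = {}
            for genome in panel:
                for p, q in itertools.combinations(genome.proteins, 2):
                    if p.contig_id != q.contig_id:
                        continue
                    if abs(p.position - q.position) > w:
                        continue
                    fa = fam_of[(genome.genome_id, p.protein_id)]
                    fb = fam_of[(genome.genome_id, q.protein_id)]
                    if fa != fb:
                        support.setdefault(frozenset((fa, fb)), set()).add(
                            genome.genome_id
                        )
            expected = set()
            for pair, genomes in support.items():
                if len(genomes) < n_min:
                    continue
                fa, fb = sorted(pair)
                for a in ref_of.get(fa, ()):
                    for b in ref_of.get(fb, ()):
                        expected.add(tuple(sorted((a, b))))
            assert got == expected


class TestAssembleNetwork:
    def test_union_merge_and_isolated_reporting(self):
        ref = _genome("ref", ["MK" * 40] * 4)
        ids = ref.protein_ids()  # ref_0 .. ref_3
        net, isolated = assemble_network(
            {(ids[0], ids[1])},
            {(ids[0], ids[1]), (ids[1], ids[2])},
            ref,
        )
        assert net.evidence(ids[0], ids[1]) == {"profile", "neighbourhood"}
        assert net.evidence(ids[1], ids[2]) == {"neighbourhood"}
        assert isolated == [ids[3]]

    def test_empty_inputs_all_isolated(self):
        ref = _genome("ref", ["MK" * 40] * 3)
        net, isolated = assemble_network(set(), set(), ref)
        assert net.number_of_edges() == 0
        assert isolated == ref.protein_ids()

    def test_per_tag_totals_equal_input_sizes(self):
        ref = _genome("ref", ["MK" * 40] * 5)
        ids = ref.protein_ids()
        p = {(ids[0], ids[1]), (ids[2], ids[3])}
        n = {(ids[0], ids[1]), (ids[1], ids[2]), (ids[3], ids[4])}
        net, _ = assemble_network(p, n, ref)
        counts = net.evidence_counts()
        assert counts["profile"] == len(p)
        assert counts["neighbourhood"] == len(n)

    def test_foreign_endpoint_rejected(self):
        ref = _genome("ref", ["MK" * 40])
        with pytest.raises(ValidationError, match="alien"):
            assemble_network({("ref_0", "alien")}, set(), ref)


def test_inference_is_deterministic():
    panel, _ = gen_panel(5, 12, mutation_rate=0.02, seed=21)
    sim = FeatureSimilarityParams()
    r1 = infer_network(panel, "G00", sim=sim)
    r2 = infer_network(panel, "G00", sim=sim)
    assert r1.network == r2.network
    assert r1.isolated == r2.isolated
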