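"""Per-node merge machinery: initial clusters, synteny, finalization."""

import numpy as np
import pytest

from synclust.node_clustering import (
    InitialCluster,
    MergeConfig,
    Orthogroup,
    SyntenyMatrix,
    finalize,
    initial_clusters,
    leaf_state,
    merge_node,
    resolve_at_root,
    synteny_matrix,
    syntenic_fraction,
)
from synclust.similarity import Hit, HitTable, builtin_search

from conftest import make_gene, random_protein


def _og(og_id, members, node_id="N", mark=None):
    members = frozenset(members)
    return Orthogroup(
        og_id=og_id, node_id=node_id, members=members,
        representatives=tuple(sorted(members)), paralogue_mark=mark,
    )


def _hit(q, s, bit, ev=1e-30):
    return Hit(query_id=q, subject_id=s, bitscore=bit, evalue=ev)


def _recip(q, s, bit):
    return [_hit(q, s, bit), _hit(s, q, bit)]


class TestOrthogroupInvariants:
    def test_empty_members_rejected(self):
        with pytest.raises(ValueError):
            Orthogroup(og_id="x", node_id="N", members=frozenset(), representatives=())

    def test_rep_must_be_member(self):
        with pytest.raises(ValueError):
            Orthogroup(og_id="x", node_id="N", members=frozenset(["a"]), representatives=("b",))


class TestLeafState:
    def test_singletons_sorted(self):
        genes = [make_gene("g2", 100, 200), make_gene("g1", 0, 50)]
        ogs = leaf_state("A", genes)
        assert [og.og_id for og in ogs] == ["A|g1", "A|g2"]
        assert all(og.members == frozenset([og.representatives[0]]) for og in ogs)
        assert all(og.paralogue_mark is None for og in ogs)


class TestInitialClusters:
    def test_components_of_size_two_plus(self):
        c1 = [_og("A1", ["a1"]), _og("A2", ["a2"])]
        c2 = [_og("B1", ["b1"]), _og("B2", ["b2"])]
        pairs = {frozenset(("a1", "b1")), frozenset(("a2", "b1"))}
        clusters = initial_clusters(c1, c2, pairs)
        assert len(clusters) == 1
        assert {og.og_id for og in clusters[0].child_ogs} == {"A1", "A2", "B1"}

    def test_no_pairs_no_clusters(self):
        assert initial_clusters([_og("A1", ["a1"])], [_og("B1", ["b1"])], set()) == []

    def test_unknown_gene_in_pair_is_error(self):
        with pytest.raises(ValueError, match="zz"):
            initial_clusters(
                [_og("A1", ["a1"])], [_og("B1", ["b1"])], {frozenset(("a1", "zz"))}
            )

    def test_deterministic_ids(self):
        c1 = [_og("A1", ["a1"]), _og("A2", ["c2"])]
        c2 = [_og("B1", ["b1"]), _og("B2", ["d2"])]
        pairs = {frozenset(("c2", "d2")), frozenset(("a1", "b1"))}
        clusters = initial_clusters(c1, c2, pairs)
        # components ordered by smallest og id: {A1,B1} then {A2,B2}
        assert [c.cluster_id for c in clusters] == ["C0", "C1"]
        assert {og.og_id for og in clusters[0].child_ogs} == {"A1", "B1"}


class TestSyntenicFraction:
    def test_worked_example(self):
        og_of = {"x1": "L1", "y1": "L1", "x2": "L2", "y2": "L2", "x3": "L3", "y3": "L4"}
        frac = syntenic_fraction({"x1", "x2", "x3"}, {"y1", "y2", "y3"}, og_of)
        assert frac == pytest.approx(2 / 4)

    def test_multiset_counting(self):
        # two left neighbours with one shared label on the right:
        # min(2, 1) = 1 shared, denominator 2 + 1 - 1 = 2
        og_of = {"x1": "L", "x2": "L", "y1": "L"}
        assert syntenic_fraction({"x1", "x2"}, {"y1"}, og_of) == pytest.approx(0.5)

    def test_unmapped_genes_are_unique_sentinels(self):
        assert syntenic_fraction({"x1"}, {"y1"}, {}) == 0.0

    def test_empty_windows(self):
        assert syntenic_fraction(set(), set(), {}) == 0.0

    def test_identical_windows_give_one(self):
        og_of = {"x1": "L1", "x2": "L2"}
        assert syntenic_fraction({"x1", "x2"}, {"x1", "x2"}, og_of) == 1.0

    def test_range_and_symmetry_property(self, rng):
        labels = [f"L{i}" for i in range(5)]
        for _ in range(100):
            genes_a = {f"a{i}" for i in range(int(rng.integers(0, 6)))}
            genes_b = {f"b{i}" for i in range(int(rng.integers(0, 6)))}
            og_of = {
                g: labels[int(rng.integers(5))]
                for g in genes_a | genes_b
                if rng.random() < 0.7
            }
            f_ab = syntenic_fraction(genes_a, genes_b, og_of)
            f_ba = syntenic_fraction(genes_b, genes_a, og_of)
            assert 0.0 <= f_ab <= 1.0
            assert f_ab == f_ba


class TestSyntenyMatrix:
    def test_bounds_enforced(self):
        syn = SyntenyMatrix()
        with pytest.raises(ValueError):
            syn.set("A", "B", 1.2)

    def test_mean_over_member_pairs(self):
        # A1 = {a1, a2}, B1 = {b1}; syn(a1,b1)=1, syn(a2,b1)=0 -> mean 0.5
        cluster = InitialCluster("C0", [_og("A1", ["a1", "a2"]), _og("B1", ["b1"])])
        hoods = {"a1": {"x"}, "a2": {"y"}, "b1": {"z"}}
        og_of = {"x": "L", "z": "L", "y": "M"}
        syn = synteny_matrix(cluster, {"A1"}, hoods, og_of)
        assert syn.get("A1", "B1") == pytest.approx(0.5)
        assert syn.get("B1", "A1") == pytest.approx(0.5)


class TestFinalize:
    def test_phase1_then_phase2(self):
        cluster = InitialCluster(
            "C0",
            [_og("A1", ["a1"]), _og("A2", ["a2"]), _og("B1", ["b1"]), _og("B2", ["b2"])],
        )
        syn = SyntenyMatrix()
        syn.set("A1", "B1", 0.9)
        hits = HitTable(_recip("a1", "b1", 100) + _recip("a2", "b2", 80))
        res = finalize(cluster, syn, hits, child1_ids={"A1", "A2"})
        assert [(a.og_id, b.og_id, p) for a, b, p in res.merged] == [
            ("A1", "B1", 1), ("A2", "B2", 2)
        ]
        assert res.marked == []

    def test_unmerged_og_marked_with_best_hit(self):
        cluster = InitialCluster(
            "C0", [_og("A1", ["a1"]), _og("B1", ["b1"]), _og("B2", ["b2"])]
        )
        syn = SyntenyMatrix()
        syn.set("A1", "B1", 0.9)
        hits = HitTable(
            _recip("a1", "b1", 100) + [_hit("b2", "a1", 60), _hit("b2", "b1", 70)]
        )
        res = finalize(cluster, syn, hits, child1_ids={"A1"})
        assert [(a.og_id, b.og_id) for a, b, _ in res.merged] == [("A1", "B1")]
        assert [(og.og_id, t) for og, t in res.marked] == [("B2", "b1")]

    def test_syn_tie_broken_by_bitscore(self):
        cluster = InitialCluster(
            "C0", [_og("A1", ["a1"]), _og("B1", ["b1"]), _og("B2", ["b2"])]
        )
        syn = SyntenyMatrix()
        syn.set("A1", "B1", 0.6)
        syn.set("A1", "B2", 0.6)
        hits = HitTable(_recip("a1", "b1", 50) + _recip("a1", "b2", 90))
        res = finalize(cluster, syn, hits, child1_ids={"A1"})
        assert res.merged[0][1].og_id == "B2"

    def test_full_tie_broken_lexicographically(self):
        cluster = InitialCluster(
            "C0", [_og("A1", ["a1"]), _og("B1", ["b1"]), _og("B2", ["b2"])]
        )
        syn = SyntenyMatrix()
        syn.set("A1", "B1", 0.6)
        syn.set("A1", "B2", 0.6)
        hits = HitTable(_recip("a1", "b1", 70) + _recip("a1", "b2", 70))
        res = finalize(cluster, syn, hits, child1_ids={"A1"})
        assert res.merged[0][1].og_id == "B1"

    def test_below_threshold_falls_to_rbh(self):
        cluster = InitialCluster("C0", [_og("A1", ["a1"]), _og("B1", ["b1"])])
        syn = SyntenyMatrix()
        syn.set("A1", "B1", 0.4)  # below default 0.5
        hits = HitTable(_recip("a1", "b1", 100))
        res = finalize(cluster, syn, hits, child1_ids={"A1"})
        assert res.merged[0][2] == 2

    def test_bad_threshold(self):
        cluster = InitialCluster("C0", [_og("A1", ["a1"]), _og("B1", ["b1"])])
        with pytest.raises(ValueError):
            finalize(cluster, SyntenyMatrix(), HitTable(), {"A1"}, syn_threshold=2.0)

    def test_matching_partition_property(self, rng):
        """Every og appears exactly once in merged+marked; merges cross
        children; at most one merge per og."""
        for _ in range(50):
            n1, n2 = int(rng.integers(1, 5)), int(rng.integers(1, 5))
            ids1 = [f"A{i}" for i in range(n1)]
            ids2 = [f"B{j}" for j in range(n2)]
            ogs = [_og(i, [i.lower()]) for i in ids1 + ids2]
            cluster = InitialCluster("C0", ogs)
            syn = SyntenyMatrix()
            hits_list = []
            for i in ids1:
                for j in ids2:
                    if rng.random() < 0.6:
                        syn.set(i, j, float(rng.random()))
                    if rng.random() < 0.7:
                        hits_list.extend(_recip(i.lower(), j.lower(), float(rng.uniform(30, 150))))
            res = finalize(cluster, syn, HitTable(hits_list), child1_ids=set(ids1))
            seen = []
            for a, b, phase in res.merged:
                assert phase in (1, 2)
                assert (a.og_id in ids1) != (b.og_id in ids1)
                seen.extend([a.og_id, b.og_id])
            seen.extend(og.og_id for og, _ in res.marked)
            assert sorted(seen) == sorted(ids1 + ids2)


class TestMergeNode:
    def _setup(self, rng):
        p1 = random_protein(rng, 110)
        p2 = random_protein(rng, 110)
        genes = {
            "a1": make_gene("a1", 0, 330, protein=p1, genome_id="GA"),
            "a2": make_gene("a2", 500, 830, protein=p2, genome_id="GA"),
            "b1": make_gene("b1", 0, 330, protein=p1, genome_id="GB"),
            "b2": make_gene("b2", 500, 830, protein=p2, genome_id="GB"),
        }
        hoods = {"a1": {"a2"}, "a2": {"a1"}, "b1": {"b2"}, "b2": {"b1"}}
        return genes, hoods

    def test_homologous_pairs_merge_with_synteny(self, rng):
        genes, hoods = self._setup(rng)
        c1 = leaf_state("A", [genes["a1"], genes["a2"]])
        c2 = leaf_state("B", [genes["b1"], genes["b2"]])
        hits = builtin_search([genes["a1"], genes["a2"]], [genes["b1"], genes["b2"]])
        state = merge_node("N", c1, c2, hits, hoods, genes)
        assert state.stats["n_orthogroups"] == 2
        assert state.stats["n_phase1_merges"] == 2
        members = sorted(sorted(og.members) for og in state.orthogroups)
        assert members == [["a1", "b1"], ["a2", "b2"]]
        assert [og.og_id for og in state.orthogroups] == ["N_00000", "N_00001"]

    def test_gene_conservation_and_pass_through_mark(self, rng):
        genes, hoods = self._setup(rng)
        # an extra marked orthogroup with no homology evidence at all
        extra_gene = make_gene("a9", 900, 1200, protein=random_protein(rng, 110), genome_id="GA")
        genes["a9"] = extra_gene
        hoods["a9"] = set()
        c1 = leaf_state("A", [genes["a1"], genes["a2"]])
        c1.append(_og("A|a9", ["a9"], node_id="A", mark="b1"))
        c2 = leaf_state("B", [genes["b1"], genes["b2"]])
        hits = builtin_search(
            [genes["a1"], genes["a2"], extra_gene], [genes["b1"], genes["b2"]]
        )
        state = merge_node("N", c1, c2, hits, hoods, genes)
        union = frozenset().union(*(og.members for og in state.orthogroups))
        assert union == {"a1", "a2", "b1", "b2", "a9"}
        passed = [og for og in state.orthogroups if og.members == {"a9"}]
        assert passed[0].paralogue_mark == "b1"

    def test_mark_removed_on_merge(self, rng):
        genes, hoods = self._setup(rng)
        c1 = [_og("A|a1", ["a1"], node_id="A", mark="stale_mark")]
        c2 = [_og("B|b1", ["b1"], node_id="B")]
        hits = builtin_search([genes["a1"]], [genes["b1"]])
        state = merge_node("N", c1, c2, hits, {"a1": set(), "b1": set()}, genes)
        (merged,) = [og for og in state.orthogroups if len(og.members) == 2]
        assert merged.paralogue_mark is None


class TestResolveAtRoot:
    GG = {"a1": "GA", "a2": "GA", "b1": "GB"}

    def _root_ogs(self):
        return [
            _og("R1", ["a1", "b1"], node_id="R"),
            _og("R2", ["a2"], node_id="R", mark="b1"),
        ]

    def test_annotate_policy(self):
        clusters = resolve_at_root(self._root_ogs(), self.GG, policy="annotate")
        assert [c.cluster_id for c in clusters] == ["OG000000", "OG000001"]
        by_id = {c.cluster_id: c for c in clusters}
        assert by_id["OG000000"].members == {"a1", "b1"}
        assert by_id["OG000000"].paralogue_of is None
        assert by_id["OG000001"].members == {"a2"}
        assert by_id["OG000001"].paralogue_of == "OG000000"

    def test_merge_policy(self):
        clusters = resolve_at_root(self._root_ogs(), self.GG, policy="merge")
        assert len(clusters) == 1
        assert clusters[0].members == {"a1", "a2", "b1"}
        assert clusters[0].per_genome_counts == {"GA": 2, "GB": 1}
        assert clusters[0].paralogue_of is None

    def test_merge_collapses_mark_chains(self):
        ogs = [
            _og("R1", ["g1"], node_id="R", mark="g2"),
            _og("R2", ["g2"], node_id="R", mark="g3"),
            _og("R3", ["g3"], node_id="R"),
        ]
        gg = {"g1": "GA", "g2": "GB", "g3": "GC"}
        clusters = resolve_at_root(ogs, gg, policy="merge")
        assert len(clusters) == 1 and clusters[0].members == {"g1", "g2", "g3"}

    def test_dangling_mark_dropped(self, caplog):
        ogs = [_og("R1", ["g1"], node_id="R", mark="nonexistent")]
        clusters = resolve_at_root(ogs, {"g1": "GA"}, policy="annotate")
        assert clusters[0].paralogue_of is None

    def test_partition_property(self):
        for policy in ("annotate", "merge"):
            clusters = resolve_at_root(self._root_ogs(), self.GG, policy=policy)
            all_members = [g for c in clusters for g in c.members]
            assert sorted(all_members) == ["a1", "a2", "b1"]

    def test_bad_policy(self):
        with pytest.raises(ValueError):
            resolve_at_root([], {}, policy="drop")
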