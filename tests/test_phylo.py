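import itertools
import math
import random

import numpy as np
import pytest

from haploblock.phylo import (
    DistanceMatrix,
    SaturationError,
    SegmentPartition,
    Tree,
    clade_membership,
    congruence_scan,
    nj_tree,
    rf_distance,
    t92_distance,
    t92_params,
)
from haploblock.simulate import simulate_alignment

from conftest import additive_matrix, random_binary_tree


def brute_force_bipartitions(tree: Tree) -> set[frozenset]:
    """Independent split enumeration via adjacency-graph edge cuts."""
    import networkx as nx

    g = nx.Graph()
    counter = itertools.count()

    def walk(node, parent_id):
        nid = next(counter) if not node.is_leaf() else node.name
        g.add_edge(parent_id, nid)
        for c in node.children:
            walk(c, nid)
        return nid

    root_id = "root"
    g.add_node(root_id)
    for c in tree.root.children:
        walk(c, root_id)
    leaves = set(tree.leaf_names())
    ref = min(leaves)
    splits = set()
    for u, v in list(g.edges):
        g.remove_edge(u, v)
        comp = nx.node_connected_component(g, u)
        side = frozenset(x for x in comp if x in leaves)
        g.add_edge(u, v)
        if 1 < len(side) < len(leaves) - 1:
            side = side if ref not in side else frozenset(leaves - side)
            splits.add(side)
    return splits


class TestT92:
    def _pair(self):
        # theta 0.5 alignment with 20 transitions and 10 transversions in 200 cols
        sa = "AG" * 50 + "CT" * 50
        sb = list(sa)
        a_pos = [i for i, c in enumerate(sa) if c == "A"][:20]
        for i in a_pos:
            sb[i] = "G"  # transitions
        c_pos = [i for i, c in enumerate(sa) if c == "C"][:10]
        for i in c_pos:
            sb[i] = "G"  # transversions
        return sa, "".join(sb)

    def test_identical_sequences_zero(self):
        assert t92_distance("ACGTACGT", "ACGTACGT") == 0.0

    def test_closed_form_evaluation(self):
        sa, sb = self._pair()
        p = t92_params(sa, sb)
        h = 2 * p.theta * (1 - p.theta)
        expected = -h * math.log(1 - p.P / h - p.Q) - 0.5 * (1 - h) * math.log(1 - 2 * p.Q)
        assert abs(t92_distance(sa, sb) - expected) < 1e-12

    def test_transversion_only_distance_exceeds_raw_q(self):
        sa = "AC" * 100
        sb = ("CC" * 10 + "AC" * 90)  # 10 A->C transversions
        p = t92_params(sa, sb)
        assert p.P == 0 and p.Q > 0
        assert t92_distance(sa, sb) > p.Q

    def test_reduces_to_k2p_at_half_theta(self):
        sa, sb = self._pair()
        p = t92_params(sa, sb)
        k2p = -0.5 * math.log((1 - 2 * p.P - p.Q) * math.sqrt(1 - 2 * p.Q))
        assert abs(t92_distance(sa, sb, theta=0.5) - k2p) < 1e-12

    def test_gap_and_n_columns_excluded(self):
        assert t92_distance("ACG-AN", "ACGTAT") == 0.0

    def test_saturation_raises(self):
        sa = "A" * 100 + "C" * 100
        sb = "C" * 100 + "A" * 100  # all transversions
        with pytest.raises(SaturationError):
            t92_distance(sa, sb)

    def test_symmetry(self):
        sa, sb = self._pair()
        assert t92_distance(sa, sb) == t92_distance(sb, sa)


class TestNeighborJoining:
    def test_three_taxa_unique_topology_and_lengths(self):
        # three-point formulas: la = (dab + dac - dbc)/2 etc.
        d = np.array([[0, 5, 9], [5, 0, 10], [9, 10, 0]], dtype=float)
        t = nj_tree(DistanceMatrix(["A", "B", "C"], d))
        lengths = {leaf.name: leaf.length for leaf in t.leaves()}
        assert lengths == {"A": 2.0, "B": 3.0, "C": 7.0}

    def test_four_taxon_additive_recovery(self):
        # tree ((A,B),(C,D)) with internal branch 2
        d = np.array(
            [[0, 3, 7, 8], [3, 0, 8, 9], [7, 8, 0, 5], [8, 9, 5, 0]], dtype=float
        )
        t = nj_tree(DistanceMatrix(["A", "B", "C", "D"], d))
        assert frozenset({"A", "B"}) in t.bipartitions() or frozenset({"C", "D"}) in t.bipartitions()

    def test_additive_matrices_recover_generating_trees(self, rng):
        recovered = 0
        trials = 50
        for k in range(trials):
            n = rng.randint(4, 8)
            true = random_binary_tree(n, rng)
            dm = additive_matrix(true)
            est = nj_tree(dm)
            if est.bipartitions() == true.bipartitions():
                recovered += 1
        assert recovered == trials

    def test_rejects_fewer_than_three_taxa(self):
        with pytest.raises(ValueError):
            nj_tree(DistanceMatrix(["A", "B"], np.array([[0.0, 1.0], [1.0, 0.0]])))

    def test_deterministic_under_ties(self):
        d = np.ones((4, 4)) - np.eye(4)
        t1 = nj_tree(DistanceMatrix(list("ABCD"), d))
        t2 = nj_tree(DistanceMatrix(list("ABCD"), d))
        assert t1.newick() == t2.newick()


class TestRobinsonFoulds:
    def test_identical_trees_zero(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,D:1):1,E:1);")
        assert rf_distance(t, t) == 0

    def test_two_four_taxon_topologies(self):
        t1 = Tree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = Tree.from_newick("((A:1,C:1):1,B:1,D:1);")
        assert rf_distance(t1, t2) == 2

    def test_leaf_set_mismatch_errors(self):
        t1 = Tree.from_newick("((A:1,B:1):1,C:1,D:1);")
        t2 = Tree.from_newick("((A:1,B:1):1,C:1,E:1);")
        with pytest.raises(ValueError):
            rf_distance(t1, t2)

    def test_matches_brute_force_on_random_pairs(self, rng):
        for _ in range(100):
            t1 = random_binary_tree(6, rng)
            t2 = random_binary_tree(6, rng)
            oracle = len(
                brute_force_bipartitions(t1) ^ brute_force_bipartitions(t2)
            )
            assert rf_distance(t1, t2) == oracle

    def test_matches_dendropy(self, rng):
        dendropy = pytest.importorskip("dendropy")
        for _ in range(20):
            t1 = random_binary_tree(7, rng)
            t2 = random_binary_tree(7, rng)
            tns = dendropy.TaxonNamespace()
            d1 = dendropy.Tree.get(data=t1.newick(), schema="newick", taxon_namespace=tns)
            d2 = dendropy.Tree.get(data=t2.newick(), schema="newick", taxon_namespace=tns)
            oracle = dendropy.calculate.treecompare.symmetric_difference(d1, d2)
            assert rf_distance(t1, t2) == oracle


class TestCladeMembership:
    def test_cherry_is_monophyletic(self):
        t = Tree.from_newick("((A:1,B:1):1,(C:1,(D:1,E:1):1):1,F:1);")
        out = clade_membership(t, {"cherry": {"D", "E"}, "split": {"A", "C"}})
        assert out == {"cherry": True, "split": False}

    def test_small_group_vacuous(self):
        t = Tree.from_newick("((A:1,B:1):1,C:1,D:1);")
        assert clade_membership(t, {"solo": {"A"}})["solo"] is True


class TestCongruenceScan:
    TREE = Tree.from_newick(
        "(((A:0.05,B:0.05):0.05,(C:0.05,D:0.05):0.05):0.02,(E:0.05,F:0.05):0.07);"
    )
    PART = SegmentPartition(
        [("s1", (0, 1000)), ("s2", (1000, 2000)), ("s3", (2000, 3000)), ("s4", (3000, 4000))]
    )

    def test_single_tree_no_flags(self):
        names, rows, _ = simulate_alignment(self.TREE, 4000, seed=21)
        rep = congruence_scan(names, rows, self.PART)
        assert all(v == 0 for v in rep.rf.values())
        assert rep.flagged == []

    def test_conversion_creates_breakpoint_flag(self):
        names, rows, _ = simulate_alignment(
            self.TREE, 4000, seed=22,
            conversion={"donor": "C", "recipient": "A", "start": 0, "end": 2000, "gc_bias": 0.7},
        )
        rep = congruence_scan(names, rows, self.PART)
        assert rep.flagged
        boundaries = [col for _, _, col in rep.flagged]
        assert any(abs(b - 2000) <= 1000 for b in boundaries)

    def test_three_taxa_no_flags_possible(self):
        tree = Tree.from_newick("(A:0.1,B:0.1,C:0.1);")
        names, rows, _ = simulate_alignment(tree, 2000, seed=23)
        rep = congruence_scan(names, rows, SegmentPartition([("s1", (0, 1000)), ("s2", (1000, 2000))]))
        assert len(rep.segment_trees) == 2
        assert rep.flagged == []

    def test_short_segment_skipped_with_warning(self):
        names, rows, _ = simulate_alignment(self.TREE, 1100, seed=24)
        part = SegmentPartition([("tiny", (0, 30)), ("rest", (30, 1100))])
        rep = congruence_scan(names, rows, part)
        assert "tiny" in rep.skipped
        assert "rest" in rep.segment_trees

    def test_partition_tsv_round_trip(self, tmp_path):
        p = tmp_path / "part.tsv"
        p.write_text("exon1\t1\t270\nintron1\t271\t470\n")
        part = SegmentPartition.read_tsv(p)
        assert part.segments == [("exon1", (0, 270)), ("intron1", (270, 470))]

    def test_overlapping_segments_rejected(self):
        with pytest.raises(ValueError):
            SegmentPartition([("a", (0, 100)), ("b", (50, 150))])
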