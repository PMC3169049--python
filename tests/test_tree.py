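"""Tree model, Newick I/O, bipartitions, RF distance, random topologies."""

import numpy as np
import pytest
from scipy.stats import chi2

import dendropy

from cophylo.tree import (
    HostAssociation,
    NewickError,
    PhyloTree,
    TreeError,
    bipartition_set,
    enumerate_topologies,
    internal_edges,
    map_and_prune,
    max_rf_distance,
    n_unrooted_topologies,
    nni_neighbors,
    parse_newick,
    random_topology,
    rf_distance,
    rf_distance_normalized,
    spr_move,
    topologies_equal,
    write_newick,
)


def random_tree_with_lengths(n, rng, lo=0.01, hi=1.0):
    t = random_topology([f"t{i}" for i in range(n)], rng)
    for e in t.edges():
        e.length = float(rng.uniform(lo, hi))
    return t


# ---------------------------------------------------------------------------
# Newick parsing and writing
# ---------------------------------------------------------------------------

class TestNewick:
    def test_rooted_three_leaf(self):
        t = parse_newick("((A:1,B:1):0.5,C:1);")
        assert t.rooted
        assert t.leaf_names() == {"A", "B", "C"}
        assert t.find_leaf("A").length == 1.0

    def test_star_without_lengths(self):
        t = parse_newick("(A,B,C);")
        assert not t.rooted
        assert not t.has_branch_lengths()
        assert t.n_leaves == 3

    def test_quoted_labels_and_comments(self):
        t = parse_newick("('sigma virus':0.1,[&U]'it''s':0.2,C:0.3);")
        assert "sigma virus" in t.leaf_names()
        assert "it's" in t.leaf_names()
        rt = parse_newick(write_newick(t))
        assert rt.leaf_names() == t.leaf_names()

    @pytest.mark.parametrize(
        "bad",
        ["((A,B);", "(A,B))", "(A,A);", "(A:-1,B:1);", "", "(A,B):x;"],
    )
    def test_parse_errors(self, bad):
        with pytest.raises((NewickError, TreeError)):
            parse_newick(bad)

    def test_duplicate_label_named_in_error(self):
        with pytest.raises(TreeError, match="dup"):
            parse_newick("(dup,(dup,B));")

    def test_round_trip_random_trees(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            t = random_tree_with_lengths(10, rng)
            rt = parse_newick(write_newick(t))
            assert topologies_equal(t, rt)
            orig = {n.name: n.length for n in t.leaves()}
            back = {n.name: n.length for n in rt.leaves()}
            for name in orig:
                assert back[name] == pytest.approx(orig[name], rel=1e-9)

    def test_dendropy_reads_our_newick(self):
        rng = np.random.default_rng(5)
        t = random_tree_with_lengths(8, rng)
        dt = dendropy.Tree.get(data=write_newick(t), schema="newick")
        assert {l.taxon.label for l in dt.leaf_node_iter()} == set(t.leaf_names())


# ---------------------------------------------------------------------------
# Bipartitions
# ---------------------------------------------------------------------------

class TestBipartitions:
    def test_single_internal_split(self):
        t = parse_newick("((A,B),(C,D));")
        assert bipartition_set(t) == frozenset({frozenset({"C", "D"})})

    def test_seven_leaf_binary_has_four(self):
        rng = np.random.default_rng(0)
        t = random_topology([f"x{i}" for i in range(7)], rng)
        assert len(bipartition_set(t)) == 7 - 3

    def test_root_invariance(self):
        rng = np.random.default_rng(1)
        t = random_tree_with_lengths(8, rng)
        for leaf in ("t0", "t4", "t7"):
            assert bipartition_set(t.rerooted_at(leaf)) == bipartition_set(t)

    def test_small_trees_empty(self):
        assert bipartition_set(parse_newick("(A,B,C);")) == frozenset()


# ---------------------------------------------------------------------------
# Robinson-Foulds distance
# ---------------------------------------------------------------------------

def dendropy_rf(t1: PhyloTree, t2: PhyloTree) -> int:
    """Independent RF oracle via dendropy's bipartition machinery."""
    tns = dendropy.TaxonNamespace()
    d1 = dendropy.Tree.get(data=write_newick(t1), schema="newick",
                           taxon_namespace=tns)
    d2 = dendropy.Tree.get(data=write_newick(t2), schema="newick",
                           taxon_namespace=tns)
    d1.encode_bipartitions()
    d2.encode_bipartitions()
    return dendropy.calculate.treecompare.symmetric_difference(d1, d2)


class TestRFDistance:
    def test_identity(self):
        rng = np.random.default_rng(2)
        for n in (4, 6, 9):
            t = random_topology([f"a{i}" for i in range(n)], rng)
            assert rf_distance(t, t) == 0
            assert topologies_equal(t, t.copy())

    def test_quartet_distance_two(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,C),(B,D));")
        assert rf_distance(t1, t2) == 2
        assert rf_distance_normalized(t1, t2) == 1.0

    def test_matches_dendropy_on_random_pairs(self):
        rng = np.random.default_rng(3)
        taxa = [f"s{i}" for i in range(8)]
        for _ in range(50):
            t1 = random_topology(taxa, rng)
            t2 = random_topology(taxa, rng)
            assert rf_distance(t1, t2) == dendropy_rf(t1, t2)

    def test_metric_properties(self):
        rng = np.random.default_rng(4)
        taxa = [f"m{i}" for i in range(7)]
        for _ in range(25):
            a, b, c = (random_topology(taxa, rng) for _ in range(3))
            assert rf_distance(a, b) == rf_distance(b, a)
            assert (rf_distance(a, b) == 0) == topologies_equal(a, b)
            assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)
            assert 0 <= rf_distance(a, b) <= max_rf_distance(7)

    def test_leaf_mismatch_reports_difference(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((A,B),(C,E));")
        with pytest.raises(TreeError, match="E"):
            rf_distance(t1, t2)


# ---------------------------------------------------------------------------
# Random topologies
# ---------------------------------------------------------------------------

class TestRandomTopology:
    def test_uniform_n4(self):
        rng = np.random.default_rng(6)
        counts = {}
        for _ in range(9999):
            key = frozenset(bipartition_set(random_topology("ABCD", rng)))
            counts[key] = counts.get(key, 0) + 1
        assert len(counts) == 3
        expected = 9999 / 3
        stat = sum((c - expected) ** 2 / expected for c in counts.values())
        assert stat < chi2.ppf(0.99, df=2)

    def test_all_fifteen_n5_topologies_seen(self):
        rng = np.random.default_rng(7)
        seen = {
            frozenset(bipartition_set(random_topology("ABCDE", rng)))
            for _ in range(10_000)
        }
        assert len(seen) == n_unrooted_topologies(5) == 15

    def test_seed_determinism(self):
        taxa = [f"r{i}" for i in range(9)]
        seq1 = [random_topology(taxa, np.random.default_rng(42)) for _ in range(5)]
        seq2 = [random_topology(taxa, np.random.default_rng(42)) for _ in range(5)]
        for a, b in zip(seq1, seq2):
            assert topologies_equal(a, b)

    def test_too_few_taxa(self):
        with pytest.raises(TreeError):
            random_topology(["A", "B"], np.random.default_rng(0))

    def test_enumeration_count(self):
        assert len(enumerate_topologies("ABCDE")) == 15
        tops = enumerate_topologies("ABCDE")
        keys = {frozenset(bipartition_set(t)) for t in tops}
        assert len(keys) == 15


# ---------------------------------------------------------------------------
# Host association, pruning, relabelling
# ---------------------------------------------------------------------------

class TestMapAndPrune:
    def make_assoc(self, n_mapped):
        return HostAssociation({f"v{i}": f"H{i}" for i in range(n_mapped)})

    def test_prune_and_relabel(self):
        rng = np.random.default_rng(8)
        taxa = [f"v{i}" for i in range(7)] + ["out1", "out2", "out3"]
        t = random_tree_with_lengths(10, rng)
        for leaf, name in zip(t.leaves(), taxa):
            leaf.name = name
        t = PhyloTree(t.root)
        assoc = self.make_assoc(7)
        pruned = map_and_prune(t, assoc)
        assert pruned.leaf_names() == {f"H{i}" for i in range(7)}
        assert not pruned.has_branch_lengths()

    def test_split_restriction_oracle(self):
        rng = np.random.default_rng(9)
        taxa = [f"v{i}" for i in range(6)] + ["outA", "outB"]
        t = random_topology(taxa, rng)
        assoc = self.make_assoc(6)
        pruned = map_and_prune(t, assoc)
        # brute-force restriction of the original splits to the mapped taxa
        host_of = dict(assoc.items())
        mapped = set(assoc.virus_taxa)
        restricted = set()
        for side in bipartition_set(t):
            cut = frozenset(host_of[x] for x in side if x in mapped)
            comp = frozenset(host_of[x] for x in mapped - set(side))
            if len(cut) >= 2 and len(comp) >= 2:
                ref = min(cut | comp)
                restricted.add(cut if ref not in cut else comp)
        assert bipartition_set(pruned) == restricted

    def test_full_cover_is_relabel_only(self, switch3_bundle):
        b = switch3_bundle
        pruned = map_and_prune(b.virus_tree, b.association)
        assert pruned.leaf_names() == b.host_tree.leaf_names()
        assert len(bipartition_set(pruned)) == len(bipartition_set(b.virus_tree))

    def test_missing_mapped_taxon_named(self):
        t = parse_newick("((v0,v1),(v2,out));")
        assoc = HostAssociation({"v0": "H0", "v1": "H1", "v9": "H9"})
        with pytest.raises(TreeError, match="v9"):
            map_and_prune(t, assoc)

    def test_association_must_be_injective(self):
        with pytest.raises(TreeError, match="H1"):
            HostAssociation({"a": "H1", "b": "H1"})


# ---------------------------------------------------------------------------
# Topology equality
# ---------------------------------------------------------------------------

class TestTopologiesEqual:
    def test_rerooted_copy_equal(self):
        rng = np.random.default_rng(10)
        t = random_tree_with_lengths(8, rng)
        assert topologies_equal(t, t.rerooted_at("t5"))

    def test_nni_neighbor_differs(self):
        rng = np.random.default_rng(12)
        t = random_topology([f"n{i}" for i in range(6)], rng)
        edge = internal_edges(t)[0]
        for nb in nni_neighbors(t, edge):
            assert not topologies_equal(t, nb)
            assert rf_distance(t, nb) == 2

    def test_child_order_irrelevant(self):
        t1 = parse_newick("((A,B),(C,D));")
        t2 = parse_newick("((D,C),(B,A));")
        assert topologies_equal(t1, t2)


class TestNNI:
    def test_quartet_neighbors_are_other_resolutions(self):
        t = parse_newick("((A,B),(C,D));")
        edge = internal_edges(t)[0]
        got = {frozenset(bipartition_set(nb)) for nb in nni_neighbors(t, edge)}
        expected = {
            frozenset({frozenset({"B", "D"})}),
            frozenset({frozenset({"B", "C"})}),
        }
        assert got == expected

    def test_terminal_edge_rejected(self):
        t = parse_newick("((A,B),(C,D));")
        with pytest.raises(TreeError):
            nni_neighbors(t, ("A",))

    def test_involution(self):
        rng = np.random.default_rng(13)
        t = random_topology([f"i{i}" for i in range(8)], rng)
        edge = internal_edges(t)[2]
        nb = nni_neighbors(t, edge)[0]
        new_split = next(iter(bipartition_set(nb) - bipartition_set(t)))
        back = nni_neighbors(nb, tuple(sorted(new_split)))
        assert any(topologies_equal(x, t) for x in back)


class TestSPR:
    def test_changes_topology_and_keeps_leaves(self):
        rng = np.random.default_rng(14)
        t = random_tree_with_lengths(8, rng)
        moved = spr_move(t, rng)
        assert moved.leaf_names() == t.leaf_names()
        assert rf_distance(t, moved) >= 2
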