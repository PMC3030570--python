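"""Neighbor joining and duplication-loss reconciliation."""

import dendropy
import numpy as np
import pytest

from fbxscape.trees import (ReconciliationSummary, aggregate_gains_losses,
                            branch_label, load_species_tree, nj_tree,
                            reconcile, root_by_dl)
from oracles import brute_force_dl_cost


def _topology(tree: dendropy.Tree) -> str:
    t = tree.clone(depth=1)
    for e in t.preorder_edge_iter():
        e.length = None
    t.update_bipartitions(suppress_unifurcations=True)
    return t.as_string(schema="newick", suppress_rooting=True)


def _tree(newick: str) -> dendropy.Tree:
    return dendropy.Tree.get(data=newick, schema="newick")


class TestNeighborJoining:
    def test_additive_four_taxon_distances_recover_topology(self):
        # tree ((A:1,B:2):1,(C:3,D:4):1) -> additive matrix
        D = np.array([
            [0, 3, 6, 7],
            [3, 0, 7, 8],
            [6, 7, 0, 7],
            [7, 8, 7, 0],
        ], dtype=float)
        tree = nj_tree(D, ["A", "B", "C", "D"])
        bips = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                for e in tree.preorder_edge_iter()}
        assert frozenset({"A", "B"}) in bips or frozenset({"C", "D"}) in bips

    def test_three_taxa_unique_topology(self):
        D = np.array([[0, 2, 3], [2, 0, 3], [3, 3, 0]], dtype=float)
        tree = nj_tree(D, ["x", "y", "z"])
        assert len(tree.leaf_nodes()) == 3

    def test_label_permutation_invariance(self, rng):
        n = 6
        base = rng.uniform(0.5, 2.0, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"t{i}" for i in range(n)]
        perm = list(rng.permutation(n))
        D2 = D[np.ix_(perm, perm)]
        labels2 = [labels[i] for i in perm]
        t1 = nj_tree(D, labels)
        t2 = nj_tree(D2, labels2)
        b1 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in t1.preorder_edge_iter()}
        b2 = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
              for e in t2.preorder_edge_iter()}
        assert b1 == b2

    def test_matches_reference_nj_topology(self, rng):
        # independent cross-check against scikit-bio's NJ
        import skbio

        n = 7
        base = rng.uniform(0.5, 3.0, size=(n, n))
        D = (base + base.T) / 2
        np.fill_diagonal(D, 0)
        labels = [f"s{i}" for i in range(n)]
        mine = nj_tree(D, labels)
        theirs = skbio.tree.nj(skbio.DistanceMatrix(D, ids=labels))
        my_bips = {frozenset(l.taxon.label for l in e.head_node.leaf_iter())
                   for e in mine.preorder_edge_iter()
                   if e.head_node.parent_node}
        my_bips = {b if len(b) <= n // 2 else frozenset(labels) - b
                   for b in my_bips if 1 < len(b) < n - 1}
        their_bips = set()
        for node in theirs.non_tips(include_self=False):
            tips = frozenset(t.name for t in node.tips())
            if 1 < len(tips) < n - 1:
                their_bips.add(tips if len(tips) <= n // 2
                               else frozenset(labels) - tips)
        assert my_bips == their_bips


SPECIES_AB = "(A,B);"


class TestReconcile:
    def test_congruent_single_copy_has_no_events(self):
        gt = _tree("((a1,b1),c1);")
        st = _tree("((A,B),C);")
        summary = reconcile(gt, st, {"a1": "A", "b1": "B", "c1": "C"})
        assert summary.total_gains == 0 and summary.total_losses == 0

    def test_within_species_duplication(self):
        gt = _tree("((a1,a2),b1);")
        summary = reconcile(gt, _tree(SPECIES_AB),
                            {"a1": "A", "a2": "A", "b1": "B"})
        assert summary.gains == {"A": 1}
        assert summary.total_losses == 0

    def test_root_duplication_with_loss(self):
        gt = _tree("((a1,b1),a2);")
        summary = reconcile(gt, _tree(SPECIES_AB),
                            {"a1": "A", "b1": "B", "a2": "A"})
        assert summary.total_gains == 1
        assert summary.gains == {"A+B": 1}
        assert summary.losses == {"B": 1}

    def test_cost_invariant_under_within_species_relabeling(self):
        st = _tree("((A,B),C);")
        m1 = {"a1": "A", "a2": "A", "b1": "B", "c1": "C"}
        g1 = _tree("(((a1,b1),a2),c1);")
        g2 = _tree("(((a2,b1),a1),c1);")
        s1 = reconcile(g1, st, m1)
        s2 = reconcile(g2, st, m1)
        assert s1.cost == s2.cost

    @pytest.mark.parametrize("gene_newick,mapping", [
        ("((a1,b1),(a2,b2));", {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}),
        ("((a1,(b1,c1)),(a2,c2));",
         {"a1": "A", "b1": "B", "c1": "C", "a2": "A", "c2": "C"}),
        ("(((a1,b1),(a2,b2)),(c1,c2));",
         {"a1": "A", "b1": "B", "a2": "A", "b2": "B", "c1": "C", "c2": "C"}),
    ])
    def test_cost_matches_exhaustive_mapping_enumeration(self, gene_newick,
                                                         mapping):
        st = _tree("((A,B),C);")
        gt = _tree(gene_newick)
        summary = reconcile(gt, st, mapping)
        assert summary.cost == brute_force_dl_cost(gt, st, mapping)


class TestRootByDl:
    def test_congruent_tree_roots_to_zero_cost(self):
        gt = _tree("((a1,b1),c1);")
        st = _tree("((A,B),C);")
        rooted, summary = root_by_dl(gt, st,
                                     {"a1": "A", "b1": "B", "c1": "C"})
        assert summary.cost == 0

    def test_two_copy_tree_costs_one_duplication(self):
        gt = _tree("((a1,b1),(a2,b2));")
        st = _tree(SPECIES_AB)
        mapping = {"a1": "A", "b1": "B", "a2": "A", "b2": "B"}
        _, summary = root_by_dl(gt, st, mapping)
        assert summary.total_gains == 1 and summary.total_losses == 0

    def test_chosen_rooting_is_globally_optimal(self, rng):
        # exhaustive check over every rooting on trees up to 6 leaves
        st = _tree("((A,B),(C,D));")
        gt = _tree("((a1,(b1,c1)),((a2,d1),c2));")
        mapping = {"a1": "A", "b1": "B", "c1": "C", "a2": "A", "d1": "D",
                   "c2": "C"}
        _, summary = root_by_dl(gt, st, mapping)
        best = min(
            brute_force_dl_cost(t, st, mapping)
            for t in _all_rootings(gt)
        )
        assert summary.cost == best


def _all_rootings(tree):
    newick = tree.as_string(schema="newick")
    base = dendropy.Tree.get(data=newick, schema="newick")
    keys = {branch_label(e.head_node) for e in base.preorder_edge_iter()
            if e.head_node.parent_node is not None}
    out = []
    for key in sorted(keys):
        t = dendropy.Tree.get(data=newick, schema="newick")
        edge = next(e for e in t.preorder_edge_iter()
                    if e.head_node.parent_node is not None
                    and branch_label(e.head_node) == key)
        t.reroot_at_edge(edge, update_bipartitions=False)
        out.append(t)
    return out


class TestAggregate:
    def test_single_species_clusters_count_as_terminal_gains(self):
        total = aggregate_gains_losses([], [("A", 3), ("B", 2), ("A", 1)])
        assert total.gains == {"A": 4, "B": 2}
        assert total.total_losses == 0

    def test_small_multispecies_clusters_excluded(self):
        s = ReconciliationSummary(gains={"A": 5}, losses={"B": 2})
        total = aggregate_gains_losses([(3, s), (2, s)], [])
        assert total.total_gains == 0 and total.total_losses == 0

    def test_qualifying_clusters_summed(self):
        s1 = ReconciliationSummary(gains={"A": 1}, losses={"B": 1})
        s2 = ReconciliationSummary(gains={"A": 2}, losses={"C": 1})
        total = aggregate_gains_losses([(4, s1), (5, s2)], [("D", 1)])
        assert total.gains == {"A": 3, "D": 1}
        assert total.losses == {"B": 1, "C": 1}


def test_packaged_species_tree_has_18_species():
    tree = load_species_tree()
    labels = sorted(l.taxon.label for l in tree.leaf_node_iter())
    assert len(labels) == 18
    assert {"At", "Os", "Cr", "Zm"} <= set(labels)
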