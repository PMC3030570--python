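"""Neighbor-joining gene trees and duplication-loss reconciliation.

Gene trees per cluster are built with neighbor joining (deterministic tie
breaking), rooted by duplication+loss parsimony against the fixed species
tree, and reconciled by LCA mapping: a gene node is a duplication iff its
mapping equals a child's mapping; losses are the species-tree branches
skipped along mapped child paths.  Per-branch gain/loss totals aggregate
cluster summaries under the >=4-species rule (single-species clusters count
as terminal-branch gains; 2-3-species clusters are excluded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import dendropy
import numpy as np


def load_species_tree() -> dendropy.Tree:
    """The packaged 18-species plant tree used throughout the pipeline."""
    text = (resources.files("fbxscape") / "data" / "species_tree.nwk").read_text()
    return dendropy.Tree.get(data=text, schema="newick")


def branch_label(node: dendropy.Node) -> str:
    """Stable branch id: sorted descendant leaf labels joined with '+'."""
    leaves = sorted(l.taxon.label for l in node.leaf_iter())
    return leaves[0] if len(leaves) == 1 else "+".join(leaves)


# ---------------------------------------------------------------------------
# neighbor joining


def nj_tree(distances: np.ndarray, labels: Sequence[str]) -> dendropy.Tree:
    """Saitou-Nei neighbor joining; deterministic under label relabeling.

    Ties in the Q criterion are broken by the lexicographically smallest
    (canonical-label) pair, so permuting the input order yields the same
    topology.  Negative branch lengths are clamped to zero.  With n < 3 the
    trivial topology is returned.
    """
    D = np.asarray(distances, dtype=float)
    n = len(labels)
    if D.shape != (n, n):
        raise ValueError("distance matrix does not match labels")
    if not np.allclose(D, D.T):
        raise ValueError("distance matrix must be symmetric")

    taxa = dendropy.TaxonNamespace(list(labels))
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = {}
    for i, lab in enumerate(labels):
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes[i] = node
    canon = {i: labels[i] for i in range(n)}

    if n == 1:
        tree.seed_node.add_child(nodes[0])
        return tree
    if n == 2:
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = nodes[1].edge.length = max(D[0, 1] / 2, 0.0)
        return tree

    active = list(range(n))
    Dm = {(i, j): D[i, j] for i in range(n) for j in range(n)}
    next_id = n
    while len(active) > 3:
        m = len(active)
        r = {i: sum(Dm[min(i, k), max(i, k)] for k in active if k != i)
             for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (m - 2) * Dm[min(i, j), max(i, j)] - r[i] - r[j]
                key = (q, min(canon[i], canon[j]), max(canon[i], canon[j]))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        dij = Dm[min(i, j), max(i, j)]
        li = 0.5 * dij + (r[i] - r[j]) / (2 * (m - 2))
        lj = dij - li
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = max(li, 0.0)
        nodes[j].edge.length = max(lj, 0.0)
        nodes[next_id] = parent
        canon[next_id] = min(canon[i], canon[j])
        for k in active:
            if k in (i, j):
                continue
            dik = Dm[min(i, k), max(i, k)]
            djk = Dm[min(j, k), max(j, k)]
            Dm[min(next_id, k), max(next_id, k)] = 0.5 * (dik + djk - dij)
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1

    # final trifurcation
    i, j, k = active
    dij = Dm[min(i, j), max(i, j)]
    dik = Dm[min(i, k), max(i, k)]
    djk = Dm[min(j, k), max(j, k)]
    for node, length in ((nodes[i], (dij + dik - djk) / 2),
                         (nodes[j], (dij + djk - dik) / 2),
                         (nodes[k], (dik + djk - dij) / 2)):
        tree.seed_node.add_child(node)
        node.edge.length = max(length, 0.0)
    return tree


def kmer_distance_matrix(seqs: Sequence[str], k: int = 3) -> np.ndarray:
    """Alignment-free Jaccard k-mer distance between protein sequences."""
    sets = [{s[i : i + k] for i in range(max(len(s) - k + 1, 0))} for s in seqs]
    n = len(seqs)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            union = len(sets[i] | sets[j])
            inter = len(sets[i] & sets[j])
            D[i, j] = D[j, i] = 1.0 - (inter / union if union else 1.0)
    return D


# ---------------------------------------------------------------------------
# duplication-loss reconciliation


@dataclass
class ReconciliationSummary:
    gains: dict[str, int] = field(default_factory=dict)  # per branch label
    losses: dict[str, int] = field(default_factory=dict)

    @property
    def total_gains(self) -> int:
        return sum(self.gains.values())

    @property
    def total_losses(self) -> int:
        return sum(self.losses.values())

    @property
    def cost(self) -> int:
        return self.total_gains + self.total_losses

    def add(self, other: "ReconciliationSummary") -> None:
        for b, c in other.gains.items():
            self.gains[b] = self.gains.get(b, 0) + c
        for b, c in other.losses.items():
            self.losses[b] = self.losses.get(b, 0) + c


def _species_index(species_tree: dendropy.Tree):
    """Precompute ancestry info for LCA queries on the species tree."""
    parent: dict[int, dendropy.Node | None] = {}
    depth: dict[int, int] = {}
    for node in species_tree.preorder_node_iter():
        p = node.parent_node
        parent[id(node)] = p
        depth[id(node)] = 0 if p is None else depth[id(p)] + 1
    leaf_of = {leaf.taxon.label: leaf
               for leaf in species_tree.leaf_node_iter()}
    return parent, depth, leaf_of


def _lca(a, b, parent, depth):
    while depth[id(a)] > depth[id(b)]:
        a = parent[id(a)]
    while depth[id(b)] > depth[id(a)]:
        b = parent[id(b)]
    while a is not b:
        a, b = parent[id(a)], parent[id(b)]
    return a


def reconcile(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    species_map: Mapping[str, str],
) -> ReconciliationSummary:
    """Standard LCA duplication-loss reconciliation of a rooted gene tree."""
    parent, depth, leaf_of = _species_index(species_tree)
    mapping: dict[int, dendropy.Node] = {}
    summary = ReconciliationSummary()

    def resolve_children(node):
        kids = node.child_nodes()
        if len(kids) <= 2:
            return kids
        # polytomy: resolve by canonical leaf order (caller was warned)
        kids = sorted(kids, key=lambda c: min(
            l.taxon.label for l in c.leaf_iter()))
        return [kids[0], kids[1]] if len(kids) == 2 else kids

    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            label = node.taxon.label
            sp = species_map.get(label)
            if sp is None or sp not in leaf_of:
                raise ValueError(f"gene leaf {label!r} has no species mapping")
            mapping[id(node)] = leaf_of[sp]
        else:
            kids = node.child_nodes()
            m = mapping[id(kids[0])]
            for c in kids[1:]:
                m = _lca(m, mapping[id(c)], parent, depth)
            mapping[id(node)] = m

    for node in gene_tree.postorder_node_iter():
        if node.is_leaf():
            continue
        kids = node.child_nodes()
        mu = mapping[id(node)]
        is_dup = any(mapping[id(c)] is mu for c in kids)
        if is_dup:
            b = branch_label(mu)
            summary.gains[b] = summary.gains.get(b, 0) + 1
        for c in kids:
            # losses: species branches skipped between M(node) and M(child)
            path = []
            x = mapping[id(c)]
            while x is not mu:
                path.append(x)
                x = parent[id(x)]
            path.reverse()  # top-down from just under mu to M(child)
            skipped = path if is_dup else path[1:]
            prev = mu if is_dup else (path[0] if path else mu)
            for y in skipped:
                py = parent[id(y)]
                for sib in py.child_nodes():
                    if sib is not y:
                        b = branch_label(sib)
                        summary.losses[b] = summary.losses.get(b, 0) + 1
    return summary


def _edge_key(edge: dendropy.Edge) -> str:
    return branch_label(edge.head_node)


def root_by_dl(
    gene_tree: dendropy.Tree,
    species_tree: dendropy.Tree,
    species_map: Mapping[str, str],
) -> tuple[dendropy.Tree, ReconciliationSummary]:
    """Root an unrooted gene tree on the edge minimising duplications+losses.

    Ties go to the rooting with fewer duplications, then canonical edge
    order.
    """
    newick = gene_tree.as_string(schema="newick")
    candidates = []
    base = dendropy.Tree.get(data=newick, schema="newick")
    edge_ids = sorted(
        {_edge_key(e) for e in base.preorder_edge_iter()
         if e.head_node.parent_node is not None}
    )
    for key in edge_ids:
        t = dendropy.Tree.get(data=newick, schema="newick")
        edge = next(e for e in t.preorder_edge_iter()
                    if e.head_node.parent_node is not None
                    and _edge_key(e) == key)
        length = edge.length or 0.0
        t.reroot_at_edge(edge, length1=length / 2, length2=length / 2,
                         update_bipartitions=False)
        summary = reconcile(t, species_tree, species_map)
        candidates.append(((summary.cost, summary.total_gains, key), t, summary))
    candidates.sort(key=lambda c: c[0])
    _, tree, summary = candidates[0]
    return tree, summary


def aggregate_gains_losses(
    cluster_summaries: Sequence[tuple[int, ReconciliationSummary]],
    single_species_clusters: Sequence[tuple[str, int]] = (),
    min_species: int = 4,
) -> ReconciliationSummary:
    """Per-branch totals over clusters.

    ``cluster_summaries``: (n_species, summary) pairs; clusters with
    1 < n_species < min_species are excluded.  ``single_species_clusters``:
    (species, size) pairs counted as that many gains on the terminal branch.
    """
    total = ReconciliationSummary()
    for n_species, summary in cluster_summaries:
        if n_species >= min_species:
            total.add(summary)
    for species, size in single_species_clusters:
        total.gains[species] = total.gains.get(species, 0) + size
    return total
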