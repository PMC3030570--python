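"""All-vs-all similarity graph, Markov clustering, and taxonomic-scale bins.

Orthologous groups (OGs) are MCL clusters of the all-against-all protein
similarity graph.  Each OG's bin is the number of distinct species among
its members; genes in no OG are "orphan".  Small taxonomic scale (STS) =
orphan plus bins 1-4; large taxonomic scale (LTS) = bins 5 and up.
Protein-coding members are subdivided into STSP/LTSP accordingly, while
pseudogenes keep their own status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .search import local_align, e_value

EDGE_WEIGHT_CAP = 200.0
STS_MAX_BIN = 4


def build_similarity_graph(
    proteins: Mapping[str, str],
    species_map: Mapping[str, str] | None = None,
    e_cutoff: float = 1e-5,
    normalize: bool = True,
) -> nx.Graph:
    """All-against-all local-alignment graph.

    Edge iff either direction passes the E-value cutoff; raw weight is
    -log10(E) of the better direction, capped.  With ``normalize`` (the
    orthologous-group setting) each edge weight is rescaled by the
    geometric mean of its endpoints' best weights, so a gene's strongest
    partners approach 1 regardless of absolute similarity — the stand-in
    for OrthoMCL's weight normalisation.  Self-edges excluded.
    """
    if not proteins:
        raise ValueError("need at least one protein")
    graph = nx.Graph()
    names = sorted(proteins)
    for name in names:
        graph.add_node(name, species=(species_map or {}).get(name, ""))
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            hit = local_align(proteins[a], proteins[b])
            # alignment is symmetric; E differs only through m*n symmetry,
            # so one evaluation covers both directions
            if hit.e_value <= e_cutoff:
                w = min(-math.log10(max(hit.e_value, 1e-300)),
                        EDGE_WEIGHT_CAP)
                graph.add_edge(a, b, weight=max(w, 1e-6))
    if normalize and graph.number_of_edges():
        best = {
            n: max((d["weight"] for _, _, d in graph.edges(n, data=True)),
                   default=1.0)
            for n in graph.nodes
        }
        for a, b, d in graph.edges(data=True):
            d["weight"] = (d["weight"] / math.sqrt(best[a] * best[b])) ** 2
    return graph


def mcl_cluster(
    graph: nx.Graph,
    inflation: float = 4.0,
    max_iter: int = 10_000,
    prune: float = 1e-8,
    tol: float = 1e-10,
) -> list[set[str]]:
    """Markov clustering: alternate expansion (matrix square) and inflation
    (entrywise power + column renormalisation) to convergence.

    Clusters are the connected components of the converged attractor matrix.
    """
    if inflation <= 1:
        raise ValueError("inflation must exceed 1")
    nodes = sorted(graph.nodes)
    if not nodes:
        return []
    idx = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)
    M = np.zeros((n, n))
    for a, b, data in graph.edges(data=True):
        w = data.get("weight", 1.0)
        M[idx[a], idx[b]] = w
        M[idx[b], idx[a]] = w
    np.fill_diagonal(M, 1.0)  # self-loops stabilise odd-cycle oscillation
    M /= M.sum(axis=0, keepdims=True)

    for _ in range(max_iter):
        expanded = M @ M
        inflated = expanded**inflation
        inflated[inflated < prune] = 0.0
        colsum = inflated.sum(axis=0, keepdims=True)
        colsum[colsum == 0] = 1.0
        inflated /= colsum
        if np.abs(inflated - M).max() < tol:
            M = inflated
            break
        M = inflated
    else:
        raise RuntimeError("MCL failed to converge")

    support = nx.Graph()
    support.add_nodes_from(range(n))
    rows, cols = np.nonzero(M > 1e-6)
    support.add_edges_from(zip(rows.tolist(), cols.tolist()))
    return [
        {nodes[i] for i in comp}
        for comp in sorted(nx.connected_components(support),
                           key=lambda c: min(c))
    ]


@dataclass
class OrthologousGroup:
    og_id: str
    members: list[str]
    species_count: int
    bin: int | str  # 1..n_species or "orphan"
    scale: str = ""  # "STS" | "LTS"

    def __post_init__(self) -> None:
        if not self.scale:
            self.scale = classify_scale(self.bin)


def classify_scale(bin_value: int | str, sts_max_bin: int = STS_MAX_BIN) -> str:
    if bin_value == "orphan":
        return "STS"
    return "STS" if int(bin_value) <= sts_max_bin else "LTS"


def assign_bins(
    clusters: Sequence[set[str]],
    species_map: Mapping[str, str],
    sts_max_bin: int = STS_MAX_BIN,
) -> list[OrthologousGroup]:
    """Bin clusters by distinct-species count; unclustered singletons are
    orphans (also STS)."""
    groups = []
    for k, cluster in enumerate(clusters):
        unknown = [m for m in cluster if m not in species_map]
        if unknown:
            raise ValueError(f"unknown species tag for {unknown[:3]}")
        members = sorted(cluster)
        if len(members) == 1:
            groups.append(OrthologousGroup(f"OG{k:04d}", members, 1, "orphan",
                                           "STS"))
            continue
        n_species = len({species_map[m] for m in members})
        groups.append(OrthologousGroup(
            f"OG{k:04d}", members, n_species, n_species,
            classify_scale(n_species, sts_max_bin)))
    return groups


def gene_scale_table(
    groups: Sequence[OrthologousGroup],
    coding_status: Mapping[str, str],
) -> dict[str, str]:
    """Per-gene final label: LTSP / STSP for coding genes, 'pseudogene'
    kept as its own status regardless of scale."""
    out = {}
    for og in groups:
        for m in og.members:
            if coding_status.get(m, "coding") == "pseudogene":
                out[m] = "pseudogene"
            else:
                out[m] = "LTSP" if og.scale == "LTS" else "STSP"
    return out


def subdivide_large_cluster(
    cluster: Sequence[str],
    distances: np.ndarray,
    max_size: int = 1000,
) -> list[list[str]]:
    """Split an oversized cluster by cutting the longest internal branches
    of its neighbor-joining tree until every part fits.

    ``distances`` is the symmetric pairwise distance matrix in the order of
    ``cluster``.
    """
    members = list(cluster)
    if len(members) <= max_size:
        return [members]
    from .trees import nj_tree  # local import to avoid a cycle

    tree = nj_tree(distances, labels=members)
    # iteratively remove the longest internal edge of the largest part
    parts = [tree]
    while any(len(t.leaf_nodes()) > max_size for t in parts):
        parts.sort(key=lambda t: -len(t.leaf_nodes()))
        big = parts.pop(0)
        edge = max(
            (e for e in big.preorder_edge_iter()
             if e.head_node and e.head_node.parent_node
             and not e.head_node.is_leaf()),
            key=lambda e: (e.length or 0.0),
            default=None,
        )
        if edge is None:  # cannot split further
            parts.append(big)
            break
        sub = big.extract_tree_with_taxa(
            taxa=[l.taxon for l in edge.head_node.leaf_iter()])
        keep_taxa = [t for t in big.taxon_namespace
                     if t.label not in {l.taxon.label
                                        for l in edge.head_node.leaf_iter()}]
        rest = big.extract_tree_with_taxa(taxa=keep_taxa)
        parts.extend([sub, rest])
    return sorted(
        (sorted(l.taxon.label for l in t.leaf_node_iter()) for t in parts),
        key=lambda p: p[0],
    )
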