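"""Independent brute-force oracles used by the unit and acceptance suites.

Each oracle re-derives an expected value by exhaustive enumeration or
exact arithmetic, sharing no code path with the implementation it checks.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction
from functools import lru_cache

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")
_ALPH = str(_B62.alphabet)

GAP_OPEN_TOTAL = 12  # first gapped element
GAP_EXTEND = 1


def blosum(a: str, b: str) -> float:
    return float(_B62[_ALPH.index(a), _ALPH.index(b)])


def brute_force_local_align(query: str, target: str) -> float:
    """Optimal local alignment score by enumerating all monotone matchings.

    Residue pairs score BLOSUM62; unmatched residues between consecutive
    pairs cost affine gaps (open 12 including first element, extend 1);
    residues outside the aligned span are free.  Feasible for len <= 8.
    """
    best = 0.0
    nq, nt = len(query), len(target)
    for k in range(1, min(nq, nt) + 1):
        for q_idx in itertools.combinations(range(nq), k):
            for t_idx in itertools.combinations(range(nt), k):
                score = sum(blosum(query[i], target[j])
                            for i, j in zip(q_idx, t_idx))
                for step in range(1, k):
                    gq = q_idx[step] - q_idx[step - 1] - 1
                    gt = t_idx[step] - t_idx[step - 1] - 1
                    for g in (gq, gt):
                        if g > 0:
                            score -= GAP_OPEN_TOTAL + GAP_EXTEND * (g - 1)
                best = max(best, score)
    return best


# ---------------------------------------------------------------------------
# spliced alignment oracle (same state model, independent top-down search)


def brute_force_spliced_align(protein: str, window: str, sc) -> float:
    """Best local spliced-alignment score by memoised top-down recursion.

    Mirrors the model definition: codon match (stops at a fixed penalty),
    2/4-base frameshift codons, affine protein/genome-codon gaps, GT..AG
    introns (length-neutral, three phases, split codons score 0, no
    back-to-back introns).  Independent of the bottom-up vectorised DP.
    """
    from fbxscape.seqs import CODON_TO_AA

    stops = {"TAA", "TAG", "TGA"}
    Lp, Lw = len(protein), len(window)
    donors = [j for j in range(Lw - 1) if window[j : j + 2] == "GT"]
    acceptors = [j for j in range(2, Lw + 1) if window[j - 2 : j] == "AG"]
    open1, ext = -sc.gap_open, -sc.gap_extend

    def codon_score(i, codon):
        if codon in stops:
            return sc.stop_penalty
        aa = CODON_TO_AA.get(codon)
        if aa is None:
            return -math.inf
        return blosum(protein[i], aa)

    @lru_cache(maxsize=None)
    def best_end(i, j, state):
        """Best score of an alignment ENDING at protein i, window j.

        state: 0 codon-boundary, 1 protein-gap run, 2 genome-gap run.
        """
        cands = [0.0] if state == 0 else [-math.inf]
        if state == 0:
            if i >= 1 and j >= 3:
                s = codon_score(i - 1, window[j - 3 : j])
                cands.append(best_any(i - 1, j - 3) + s)
            if i >= 1 and j >= 2:
                cands.append(best_any(i - 1, j - 2) + sc.frameshift_penalty)
            if i >= 1 and j >= 4:
                cands.append(best_any(i - 1, j - 4) + sc.frameshift_penalty)
            # intron closing at an acceptor; split codons score 0
            if j in set(acceptors):
                for d in donors:
                    if j - d >= sc.min_intron:
                        cands.append(best_any(i, d, allow_intron=False)
                                     + sc.intron_open)
            if j >= 2 and (j - 2) in set(acceptors):
                for d in donors:
                    if (j - 2) - d >= sc.min_intron and d >= 1 and i >= 1:
                        cands.append(best_any(i - 1, d - 1,
                                              allow_intron=False)
                                     + sc.intron_open)
            if j >= 1 and (j - 1) in set(acceptors):
                for d in donors:
                    if (j - 1) - d >= sc.min_intron and d >= 2 and i >= 1:
                        cands.append(best_any(i - 1, d - 2,
                                              allow_intron=False)
                                     + sc.intron_open)
        elif state == 1 and i >= 1:
            cands.append(best_end(i - 1, j, 0) - open1)
            cands.append(best_end(i - 1, j, 1) - ext)
        elif state == 2 and j >= 3:
            cands.append(best_end(i, j - 3, 0) - open1)
            cands.append(best_end(i, j - 3, 2) - ext)
        return max(cands)

    def best_any(i, j, allow_intron=True):
        v = max(best_end(i, j, 1), best_end(i, j, 2))
        if allow_intron:
            v = max(v, best_end(i, j, 0))
        else:
            # donor side of an intron: codon-boundary value computed
            # without a directly preceding intron closure
            v = max(v, _no_intron_end(i, j))
        return v

    @lru_cache(maxsize=None)
    def _no_intron_end(i, j):
        cands = [0.0]
        if i >= 1 and j >= 3:
            cands.append(best_any(i - 1, j - 3)
                         + codon_score(i - 1, window[j - 3 : j]))
        if i >= 1 and j >= 2:
            cands.append(best_any(i - 1, j - 2) + sc.frameshift_penalty)
        if i >= 1 and j >= 4:
            cands.append(best_any(i - 1, j - 4) + sc.frameshift_penalty)
        return max(cands)

    best = 0.0
    for i in range(Lp + 1):
        for j in range(Lw + 1):
            best = max(best, best_end(i, j, 0))
    return best


# ---------------------------------------------------------------------------
# NG86 pathway enumeration


def enumerate_pathway_differences(c1: str, c2: str):
    """(mean syn, mean nonsyn) over minimal substitution pathways by
    depth-first recursion; stop-crossing pathways excluded (with the same
    all-pathway fallback convention)."""
    from fbxscape.seqs import CODON_TO_AA

    stops = {"TAA", "TAG", "TGA"}

    def walk(cur, remaining, allow_stops):
        if not remaining:
            return [(0, 0)]
        results = []
        for pos in remaining:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in stops and not allow_stops:
                continue
            syn = 1 if CODON_TO_AA[cur] == CODON_TO_AA[nxt] else 0
            for s, n in walk(nxt, tuple(p for p in remaining if p != pos),
                             allow_stops):
                results.append((syn + s, (1 - syn) + n))
        return results

    diff = tuple(p for p in range(3) if c1[p] != c2[p])
    if not diff:
        return 0.0, 0.0
    paths = walk(c1, diff, False)
    if not paths:
        paths = walk(c1, diff, True)
    return (sum(p[0] for p in paths) / len(paths),
            sum(p[1] for p in paths) / len(paths))


# ---------------------------------------------------------------------------
# exact rational Fisher


def rational_fisher_upper_tail(a: int, b: int, c: int, d: int) -> Fraction:
    """P(X >= a) by exact rational hypergeometric summation."""
    n = a + b + c + d
    k = a + c  # successes
    r = a + b  # group-1 size

    def comb(x, y):
        return Fraction(math.comb(x, y)) if 0 <= y <= x else Fraction(0)

    total = comb(n, r)
    tail = Fraction(0)
    for x in range(a, min(k, r) + 1):
        tail += comb(k, x) * comb(n - k, r - x)
    return tail / total


# ---------------------------------------------------------------------------
# rank-test enumeration


def enumerate_wilcoxon_less(x, y) -> float:
    """Exact one-tailed rank-sum p (H1: x smaller) by enumerating all
    label assignments of the pooled sample."""
    pooled = list(x) + list(y)
    n = len(x)
    ranks = _average_ranks(pooled)
    obs = sum(ranks[i] for i in range(n))
    count = 0
    total = 0
    for subset in itertools.combinations(range(len(pooled)), n):
        stat = sum(ranks[i] for i in subset)
        total += 1
        if stat <= obs + 1e-12:
            count += 1
    return count / total


def enumerate_ks_two_sided(x, y) -> tuple[float, float]:
    """Exact two-sample KS statistic and permutation p-value."""
    def ks_stat(a, b):
        grid = sorted(set(a) | set(b))
        d = 0.0
        for g in grid:
            fa = sum(v <= g for v in a) / len(a)
            fb = sum(v <= g for v in b) / len(b)
            d = max(d, abs(fa - fb))
        return d

    obs = ks_stat(x, y)
    pooled = list(x) + list(y)
    n = len(x)
    count = total = 0
    for subset in itertools.combinations(range(len(pooled)), n):
        a = [pooled[i] for i in subset]
        b = [pooled[i] for i in range(len(pooled)) if i not in subset]
        total += 1
        if ks_stat(a, b) >= obs - 1e-12:
            count += 1
    return obs, count / total


def _average_ranks(values):
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


# ---------------------------------------------------------------------------
# duplication-loss reconciliation oracle


def brute_force_dl_cost(gene_tree, species_tree, species_map) -> int:
    """Minimum duplications+losses over ALL valid species mappings.

    Enumerates every mapping that sends each internal gene node to an
    ancestor of its children's images; cost per mapping uses the standard
    per-edge depth formula.  The LCA mapping is optimal, so this equals
    the reconciliation cost — computed here without LCA shortcuts.
    """
    sp_nodes = list(species_tree.preorder_node_iter())
    parent = {id(n): n.parent_node for n in sp_nodes}
    depth = {}
    for n in sp_nodes:
        depth[id(n)] = 0 if n.parent_node is None else depth[id(n.parent_node)] + 1
    leaf_of = {l.taxon.label: l for l in species_tree.leaf_node_iter()}

    def is_ancestor(a, b):  # a ancestor-or-equal of b
        while b is not None:
            if a is b:
                return True
            b = parent[id(b)]
        return False

    gene_nodes = list(gene_tree.postorder_node_iter())
    internal = [g for g in gene_nodes if not g.is_leaf()]
    fixed = {
        id(g): leaf_of[species_map[g.taxon.label]]
        for g in gene_nodes if g.is_leaf()
    }

    best = math.inf
    for assignment in itertools.product(sp_nodes, repeat=len(internal)):
        m = dict(fixed)
        for g, s in zip(internal, assignment):
            m[id(g)] = s
        ok = True
        for g in internal:
            for child in g.child_nodes():
                if not is_ancestor(m[id(g)], m[id(child)]):
                    ok = False
                    break
            if not ok:
                break
        if not ok:
            continue
        cost = 0
        for g in internal:
            # speciation only when the children map into distinct child
            # subtrees of the node's image; otherwise it is a duplication
            mu = m[id(g)]
            subtrees = []
            dup = False
            for c in g.child_nodes():
                mc = m[id(c)]
                if mc is mu:
                    dup = True
                    break
                branch = mc
                while parent[id(branch)] is not mu:
                    branch = parent[id(branch)]
                subtrees.append(id(branch))
            if not dup and len(set(subtrees)) < len(subtrees):
                dup = True
            if dup:
                cost += 1
            for c in g.child_nodes():
                d = depth[id(m[id(c)])] - depth[id(mu)]
                cost += d if dup else max(d - 1, 0)
        best = min(best, cost)
    return int(best)
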