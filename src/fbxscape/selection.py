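"""Selection-pressure machinery: Ka/Ks against a reconstructed ancestor.

For each query gene the two closest non-self reference sequences are
found, the three coding sequences are codon-aligned (progressive protein
alignment threaded back to codons), the most recent common ancestor (MRCA)
sequence is reconstructed by Fitch parsimony on the midpoint-rooted
triplet, and the query is compared to the MRCA:

* NG86 (Nei-Gojobori): pathway-counting Ka/Ks with Jukes-Cantor correction;
* GY94 (Goldman-Yang): pairwise 61-codon maximum likelihood with
  transition/transversion ratio kappa and selection ratio omega, used for
  the neutrality likelihood-ratio test LR = 2(lnL_free - lnL_fixed(omega=1))
  against the chi-square 5% critical value 3.84.

Records with Ks < 0.005 (too similar) or Ks > 3 (too divergent) are
filtered; boundary values are retained.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize

from .search import BLOSUM62, sw_score, bit_score
from .seqs import CODON_TO_AA, SENSE_CODONS, STOP_CODONS, is_transition, translate

KS_MIN = 0.005
KS_MAX = 3.0
LRT_CRITICAL = 3.84  # chi-square(1) at the 5% level

_ALPH = str(BLOSUM62.alphabet)
_B62 = np.array(BLOSUM62)


# ---------------------------------------------------------------------------
# reference picking


def pick_references(
    query_id: str,
    proteins: Mapping[str, str],
) -> tuple[str, str] | None:
    """Top two non-self entries by local-alignment bit score (ties by id).

    Returns None when fewer than two usable references exist.
    """
    query = proteins[query_id]
    scored = []
    for name, seq in proteins.items():
        if name == query_id:
            continue
        scored.append((-bit_score(sw_score(query, seq)), name))
    if len(scored) < 2:
        return None
    scored.sort()
    return scored[0][1], scored[1][1]


# ---------------------------------------------------------------------------
# triplet codon alignment


def _b62_score(a: str, b: str) -> float:
    return float(_B62[_ALPH.index(a), _ALPH.index(b)])


def _nw_profile(profile: list[list[str]], seq: str,
                gap_open: float = -11.0, gap_extend: float = -1.0):
    """Global alignment of a sequence against an aligned-column profile.

    Returns (new profile columns, aligned seq string).  Column score is the
    mean BLOSUM62 score over non-gap residues (0 for all-gap columns).
    """
    n, m = len(profile), len(seq)

    def colscore(col, aa):
        residues = [r for r in col if r != "-"]
        if not residues:
            return 0.0
        return sum(_b62_score(r, aa) for r in residues) / len(residues)

    M = np.full((n + 1, m + 1), -np.inf)
    X = np.full((n + 1, m + 1), -np.inf)  # gap in seq (consume profile)
    Y = np.full((n + 1, m + 1), -np.inf)  # gap in profile (consume seq)
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        X[i, 0] = gap_open + gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0, j] = gap_open + gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = colscore(profile[i - 1], seq[j - 1])
            best_prev = max(M[i - 1, j - 1], X[i - 1, j - 1], Y[i - 1, j - 1])
            M[i, j] = best_prev + s
            X[i, j] = max(M[i - 1, j] + gap_open, X[i - 1, j] + gap_extend,
                          Y[i - 1, j] + gap_open)
            Y[i, j] = max(M[i, j - 1] + gap_open, Y[i, j - 1] + gap_extend,
                          X[i, j - 1] + gap_open)
    # traceback
    i, j = n, m
    state = max(("M", "X", "Y"), key=lambda s: {"M": M, "X": X, "Y": Y}[s][i, j])
    new_profile: list[list[str]] = []
    new_seq: list[str] = []
    while i > 0 or j > 0:
        if state == "M":
            new_profile.append(profile[i - 1])
            new_seq.append(seq[j - 1])
            s = colscore(profile[i - 1], seq[j - 1])
            prev = M[i, j] - s
            i, j = i - 1, j - 1
            state = next(k for k, tbl in (("M", M), ("X", X), ("Y", Y))
                         if math.isclose(tbl[i, j], prev, abs_tol=1e-9))
        elif state == "X":
            new_profile.append(profile[i - 1])
            new_seq.append("-")
            v = X[i, j]
            if math.isclose(M[i - 1, j] + gap_open, v, abs_tol=1e-9):
                state = "M"
            elif math.isclose(Y[i - 1, j] + gap_open, v, abs_tol=1e-9):
                state = "Y"
            i -= 1
        else:
            new_profile.append(["-"] * len(profile[0]) if profile else ["-"])
            new_seq.append(seq[j - 1])
            v = Y[i, j]
            if math.isclose(M[i, j - 1] + gap_open, v, abs_tol=1e-9):
                state = "M"
            elif math.isclose(X[i, j - 1] + gap_open, v, abs_tol=1e-9):
                state = "X"
            j -= 1
    new_profile.reverse()
    new_seq.reverse()
    return new_profile, "".join(new_seq)


def _p_distance(a: str, b: str) -> float:
    shared = [(x, y) for x, y in zip(a, b) if x != "-" and y != "-"]
    if not shared:
        return 1.0
    return sum(1 for x, y in shared if x != y) / len(shared)


@dataclass
class TripletAlignment:
    names: list[str]  # query first
    codon_rows: dict[str, str]  # aligned CDS with '---' gaps
    protein_rows: dict[str, str]
    outgroup: str  # midpoint-rooted triplet: ((in1, in2), outgroup)

    @property
    def length(self) -> int:
        return len(next(iter(self.codon_rows.values())))


def align_triplet(
    names: Sequence[str],
    cds: Mapping[str, str],
) -> TripletAlignment:
    """Codon-align three CDSs via progressive protein alignment.

    The closest pair (protein p-distance) is aligned first; the third
    sequence is aligned to the pair profile.  The guide tree is the
    three-leaf NJ star; the root is placed at the midpoint of the path
    between the two most distant leaves, making the remaining leaf part of
    the ingroup pair.
    """
    names = list(names)
    if len(names) != 3:
        raise ValueError("triplet required")
    proteins = {}
    for n in names:
        seq = cds[n]
        if seq.endswith(tuple(STOP_CODONS)) and len(seq) % 3 == 0:
            seq = seq[:-3]
        if len(seq) % 3:
            raise ValueError(f"{n}: CDS length not divisible by 3")
        prot = translate(seq)
        if "*" in prot:
            raise ValueError(f"{n}: internal stop codon in input CDS")
        proteins[n] = prot
        cds = {**cds, n: seq}

    # closest pair first
    pairs = list(itertools.combinations(names, 2))
    dists = {
        (a, b): _p_distance(proteins[a], proteins[b]) for a, b in pairs
    }
    (a, b) = min(pairs, key=lambda p: (dists[p], p))
    c = next(n for n in names if n not in (a, b))
    profile_cols, row_b = _nw_profile([[r] for r in proteins[a]], proteins[b])
    row_a = "".join(col[0] for col in profile_cols)
    merged = [[x, y] for x, y in zip(row_a, row_b)]
    merged_cols, row_c = _nw_profile(merged, proteins[c])
    prot_rows = {
        a: "".join(col[0] for col in merged_cols),
        b: "".join(col[1] for col in merged_cols),
        c: row_c,
    }

    codon_rows = {}
    for n in names:
        codons = [cds[n][i : i + 3] for i in range(0, len(cds[n]), 3)]
        out, k = [], 0
        for aa in prot_rows[n]:
            if aa == "-":
                out.append("---")
            else:
                out.append(codons[k])
                k += 1
        codon_rows[n] = "".join(out)

    # midpoint rooting of the 3-leaf star from pairwise distances
    d = {n: 0.0 for n in names}
    (x, y, z) = names
    dxy, dxz, dyz = (_p_distance(prot_rows[x], prot_rows[y]),
                     _p_distance(prot_rows[x], prot_rows[z]),
                     _p_distance(prot_rows[y], prot_rows[z]))
    lengths = {x: (dxy + dxz - dyz) / 2, y: (dxy + dyz - dxz) / 2,
               z: (dxz + dyz - dxy) / 2}
    far_pair = max(itertools.combinations(names, 2),
                   key=lambda p: (lengths[p[0]] + lengths[p[1]], p))
    i, j = far_pair
    # the root lies on the longer of the two branches to the far pair;
    # the leaf owning that branch becomes the outgroup
    outgroup = i if lengths[i] >= lengths[j] else j
    return TripletAlignment(names, codon_rows, prot_rows, outgroup)


# ---------------------------------------------------------------------------
# MRCA by Fitch parsimony


def mrca_parsimony(triplet: TripletAlignment) -> str:
    """Per-column Fitch parsimony on the rooted triplet ((x, y), outgroup).

    Root-set ambiguity is resolved in favour of the query's state (the
    query is the first name); an all-gap column is dropped.
    """
    query = triplet.names[0]
    out = triplet.outgroup
    ingroup = [n for n in triplet.names if n != out]
    rows = triplet.codon_rows
    L = triplet.length
    mrca = []
    for col in range(L):
        states = {n: rows[n][col] for n in triplet.names}
        if all(s == "-" for s in states.values()):
            mrca.append("-")  # keeps column numbering aligned with the rows
            continue
        sx, sy = states[ingroup[0]], states[ingroup[1]]
        f1 = {sx} & {sy} or {sx} | {sy}
        root = f1 & {states[out]} or f1 | {states[out]}
        if states[query] in root:
            choice = states[query]
        else:
            choice = min(root)
        mrca.append(choice)
    return "".join(mrca)


# ---------------------------------------------------------------------------
# NG86


_SYN_SITE_CACHE: dict[str, tuple[float, float]] = {}


def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts; nonsense changes disregarded."""
    if codon in _SYN_SITE_CACHE:
        return _SYN_SITE_CACHE[codon]
    syn = nonsyn = 0.0
    aa = CODON_TO_AA[codon]
    for pos in range(3):
        alts = [codon[:pos] + b + codon[pos + 1 :]
                for b in "ACGT" if b != codon[pos]]
        alts = [c for c in alts if c not in STOP_CODONS]
        if not alts:
            continue
        n_syn = sum(1 for c in alts if CODON_TO_AA[c] == aa)
        syn += n_syn / len(alts)
        nonsyn += 1 - n_syn / len(alts)
    _SYN_SITE_CACHE[codon] = (syn, nonsyn)
    return syn, nonsyn


def _pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """Mean (syn, nonsyn) differences over all minimal substitution pathways
    between two codons; pathways through stop codons are excluded."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        syn = nonsyn = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                ok = False
                break
            if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                syn += 1
            else:
                nonsyn += 1
            cur = nxt
        if ok:
            results.append((syn, nonsyn))
    if not results:  # every pathway passes a stop: fall back to all pathways
        for order in itertools.permutations(diff_pos):
            cur = c1
            syn = nonsyn = 0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                if CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                    syn += 1
                else:
                    nonsyn += 1
                cur = nxt
            results.append((syn, nonsyn))
    s = sum(r[0] for r in results) / len(results)
    n = sum(r[1] for r in results) / len(results)
    return s, n


def jukes_cantor(p: float) -> float:
    if p >= 0.75:
        raise ValueError("proportion >= 3/4: distance undefined")
    return -0.75 * math.log(1 - 4 * p / 3)


def ng86_kaks(seq: str, mrca: str) -> tuple[float, float]:
    """NG86 Ka and Ks between codon-aligned sequences (gap codons skipped).

    Raises ValueError when a proportion reaches 3/4 (undefined distance).
    """
    if len(seq) != len(mrca):
        raise ValueError("aligned lengths differ")
    S = N = Sd = Nd = 0.0
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c1, c2 = seq[i : i + 3], mrca[i : i + 3]
        if "-" in c1 or "-" in c2:
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        S += (s1 + s2) / 2
        N += (n1 + n2) / 2
        sd, nd = _pathway_differences(c1, c2)
        Sd += sd
        Nd += nd
    if S == 0 or N == 0:
        raise ValueError("no countable sites")
    ks = jukes_cantor(Sd / S)
    ka = jukes_cantor(Nd / N)
    return ka, ks


# ---------------------------------------------------------------------------
# GY94 pairwise codon model (equal codon frequencies)

_N_CODON = len(SENSE_CODONS)
_CODON_IDX = {c: i for i, c in enumerate(SENSE_CODONS)}


def _build_masks():
    ts_syn = np.zeros((_N_CODON, _N_CODON))
    tv_syn = np.zeros((_N_CODON, _N_CODON))
    ts_non = np.zeros((_N_CODON, _N_CODON))
    tv_non = np.zeros((_N_CODON, _N_CODON))
    for i, ci in enumerate(SENSE_CODONS):
        for j, cj in enumerate(SENSE_CODONS):
            if i == j:
                continue
            diffs = [p for p in range(3) if ci[p] != cj[p]]
            if len(diffs) != 1:
                continue
            p = diffs[0]
            ts = is_transition(ci[p], cj[p])
            syn = CODON_TO_AA[ci] == CODON_TO_AA[cj]
            (ts_syn if (ts and syn) else
             tv_syn if syn else
             ts_non if ts else tv_non)[i, j] = 1.0
    return ts_syn, tv_syn, ts_non, tv_non


_TS_SYN, _TV_SYN, _TS_NON, _TV_NON = _build_masks()


def _rate_matrix(kappa: float, omega: float) -> np.ndarray:
    Q = (_TS_SYN * kappa + _TV_SYN + _TS_NON * kappa * omega
         + _TV_NON * omega)
    np.fill_diagonal(Q, 0.0)
    rowsum = Q.sum(axis=1)
    np.fill_diagonal(Q, -rowsum)
    mean_rate = rowsum.mean()  # equal codon frequencies
    return Q / mean_rate


def _pair_counts(seq: str, mrca: str) -> np.ndarray:
    counts = np.zeros((_N_CODON, _N_CODON))
    for i in range(0, len(seq) - len(seq) % 3, 3):
        c1, c2 = seq[i : i + 3], mrca[i : i + 3]
        if c1 in _CODON_IDX and c2 in _CODON_IDX:
            counts[_CODON_IDX[c1], _CODON_IDX[c2]] += 1
    return counts


def _log_likelihood(counts: np.ndarray, t: float, kappa: float,
                    omega: float) -> float:
    Q = _rate_matrix(kappa, omega)
    # equal frequencies make Q symmetric: orthogonal eigendecomposition
    vals, vecs = np.linalg.eigh(Q)
    P = (vecs * np.exp(vals * t)) @ vecs.T
    P = np.clip(P, 1e-300, None)
    n_obs = counts.sum()
    return float((counts * np.log(P)).sum() + n_obs * math.log(1 / _N_CODON))


@dataclass
class Gy94Fit:
    lnl: float
    t: float
    kappa: float
    omega: float
    converged: bool = True


def gy94_pairwise(
    seq: str,
    mrca: str,
    omega_mode: str = "free",
    seed: int = 0,
    min_codons: int = 10,
) -> Gy94Fit:
    """Maximum-likelihood pairwise fit of the GY94 codon model.

    ``omega_mode='fixed_1'`` constrains omega = 1 (the neutral null);
    'free' estimates it.  Equal codon frequencies (1/61).
    """
    counts = _pair_counts(seq, mrca)
    if counts.sum() < min_codons:
        raise ValueError("fewer than %d informative codons" % min_codons)
    fixed = omega_mode == "fixed_1"

    def objective(params):
        logt, logk = params[0], params[1]
        logw = 0.0 if fixed else params[2]
        return -_log_likelihood(counts, math.exp(logt), math.exp(logk),
                                math.exp(logw))

    rng = np.random.default_rng(seed)
    starts = [np.array([math.log(0.3), math.log(2.0)] +
                       ([] if fixed else [math.log(0.5)]))]
    for _ in range(2):
        starts.append(np.array(
            [rng.uniform(-3, 0.5), rng.uniform(-1, 2)] +
            ([] if fixed else [rng.uniform(-2, 1)])))
    bounds = [(math.log(1e-4), math.log(15.0)),
              (math.log(0.05), math.log(50.0))]
    if not fixed:
        bounds.append((math.log(1e-4), math.log(40.0)))
    best = None
    ok = False
    for x0 in starts:
        res = minimize(objective, x0, method="L-BFGS-B", bounds=bounds,
                       options={"ftol": 1e-12, "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
        ok = ok or res.success
    t, kappa = math.exp(best.x[0]), math.exp(best.x[1])
    omega = 1.0 if fixed else math.exp(best.x[2])
    return Gy94Fit(-float(best.fun), t, kappa, omega, converged=ok)


def simulate_codon_pair(
    n_codons: int,
    t: float,
    kappa: float,
    omega: float,
    rng: np.random.Generator,
) -> tuple[str, str]:
    """Simulate an (ancestor, descendant) codon-sequence pair under GY94."""
    Q = _rate_matrix(kappa, omega)
    vals, vecs = np.linalg.eigh(Q)
    P = (vecs * np.exp(vals * t)) @ vecs.T
    P = np.clip(P, 0.0, None)
    P /= P.sum(axis=1, keepdims=True)
    anc_idx = rng.integers(_N_CODON, size=n_codons)
    anc, dec = [], []
    for i in anc_idx:
        anc.append(SENSE_CODONS[i])
        dec.append(SENSE_CODONS[rng.choice(_N_CODON, p=P[i])])
    return "".join(anc), "".join(dec)


# ---------------------------------------------------------------------------
# records, filtering, classification


@dataclass
class KaKsRecord:
    locus_id: str
    region: str  # "full" | "FBXD" | "dFBXD"
    ka: float = math.nan
    ks: float = math.nan
    omega: float = math.nan
    lnl_fixed: float = math.nan
    lnl_free: float = math.nan
    lr: float = math.nan
    selection_class: str = "filtered"
    mrca: str = ""
    filter_reason: str = ""

    @property
    def filtered(self) -> bool:
        return self.selection_class == "filtered"


def ks_filter_ok(ks: float, ks_min: float = KS_MIN,
                 ks_max: float = KS_MAX) -> bool:
    """Retain exactly the records with ks_min <= Ks <= ks_max."""
    return ks_min <= ks <= ks_max


def classify_selection(lr: float, omega: float,
                       critical: float = LRT_CRITICAL) -> str:
    """Neutral when the LRT cannot reject omega=1; otherwise the omega
    estimate decides purifying vs adaptive."""
    if lr < critical:
        return "neutral"
    assert omega != 1.0, "significant LRT with omega exactly 1"
    return "purifying" if omega < 1.0 else "adaptive"


def kaks_record(
    locus_id: str,
    seq: str,
    mrca: str,
    region: str = "full",
    seed: int = 0,
    ks_min: float = KS_MIN,
    ks_max: float = KS_MAX,
) -> KaKsRecord:
    """Full Ka/Ks record for one aligned (query, MRCA) pair."""
    rec = KaKsRecord(locus_id, region, mrca=mrca)
    # drop gap codons pairwise
    codons = [(seq[i : i + 3], mrca[i : i + 3])
              for i in range(0, min(len(seq), len(mrca)) - 2, 3)]
    kept = [(a, b) for a, b in codons if "-" not in a and "-" not in b]
    if len(kept) < 10:
        rec.filter_reason = "region shorter than 10 informative codons"
        return rec
    s = "".join(a for a, _ in kept)
    m = "".join(b for _, b in kept)
    try:
        rec.ka, rec.ks = ng86_kaks(s, m)
    except ValueError as exc:
        rec.filter_reason = str(exc)
        return rec
    if not ks_filter_ok(rec.ks, ks_min, ks_max):
        rec.filter_reason = f"Ks={rec.ks:.4g} outside [{ks_min}, {ks_max}]"
        return rec
    try:
        fit0 = gy94_pairwise(s, m, "fixed_1", seed=seed)
        fit1 = gy94_pairwise(s, m, "free", seed=seed)
    except ValueError as exc:
        rec.filter_reason = str(exc)
        return rec
    rec.lnl_fixed, rec.lnl_free = fit0.lnl, fit1.lnl
    rec.lr = max(0.0, 2.0 * (fit1.lnl - fit0.lnl))
    rec.omega = fit1.omega
    rec.selection_class = classify_selection(rec.lr, rec.omega)
    return rec


def region_kaks(
    locus_id: str,
    triplet: TripletAlignment,
    mrca: str,
    fbxd_protein_range: tuple[int, int],
    seed: int = 0,
) -> dict[str, KaKsRecord]:
    """Records for the full CDS, the domain region, and the remainder.

    ``fbxd_protein_range`` is on the ungapped query protein; the two
    sub-alignments partition the full alignment's codon columns.
    """
    query = triplet.names[0]
    row = triplet.codon_rows[query]
    n_cols = len(row) // 3
    # map alignment codon columns to ungapped query residue indices
    res_idx = []
    k = 0
    for col in range(n_cols):
        if row[3 * col : 3 * col + 3] == "---":
            res_idx.append(None)
        else:
            res_idx.append(k)
            k += 1
    lo, hi = fbxd_protein_range
    in_domain = [r is not None and lo <= r < hi for r in res_idx]

    def subseq(s: str, mask) -> str:
        return "".join(s[3 * c : 3 * c + 3]
                       for c in range(n_cols) if mask[c])

    out = {}
    full_mask = [True] * n_cols
    masks = {"full": full_mask, "FBXD": in_domain,
             "dFBXD": [not d for d in in_domain]}
    for region, mask in masks.items():
        out[region] = kaks_record(locus_id, subseq(row, mask),
                                  subseq(mrca, mask), region, seed=seed)
    return out


def kaks_for_locus(
    locus_id: str,
    cds_db: Mapping[str, str],
    protein_db: Mapping[str, str],
    fbxd_protein_range: tuple[int, int] | None = None,
    seed: int = 0,
) -> dict[str, KaKsRecord]:
    """End-to-end Ka/Ks for one locus: pick references, align triplet,
    reconstruct the MRCA, and compare the query to it."""
    refs = pick_references(locus_id, protein_db)
    if refs is None:
        return {"full": KaKsRecord(locus_id, "full",
                                   filter_reason="fewer than 2 references")}
    triplet = align_triplet([locus_id, *refs], cds_db)
    mrca = mrca_parsimony(triplet)
    if fbxd_protein_range is not None:
        return region_kaks(locus_id, triplet, mrca, fbxd_protein_range, seed)
    row = triplet.codon_rows[locus_id]
    return {"full": kaks_record(locus_id, row, mrca, "full", seed=seed)}
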