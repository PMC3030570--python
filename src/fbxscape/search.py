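"""Self-contained similarity search: local protein alignment, six-frame
translated genome search, PSSM domain scanning, and redundancy removal.

The local aligner is an exact affine-gap Smith-Waterman (no heuristic
seeding); significance uses the Karlin-Altschul form E = K*m*n*exp(-lambda*S).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .intervals import GenomicInterval
from .seqs import reverse_complement, translate

# Gapped BLOSUM62 defaults (open 11 / extend 1) with the standard
# Karlin-Altschul calibration for that scheme.
BLOSUM62 = substitution_matrices.load("BLOSUM62")
GAP_OPEN = 11
GAP_EXTEND = 1
KA_LAMBDA = 0.267
KA_K = 0.041

_ALPHABET = str(BLOSUM62.alphabet)
_AA_INDEX = {aa: i for i, aa in enumerate(_ALPHABET)}
_MATRIX = np.array(BLOSUM62, dtype=np.float32)
# Local alignments must never cross a translated stop segment boundary.
_STOP = _AA_INDEX["*"]
_MATRIX[_STOP, :] = -1e6
_MATRIX[:, _STOP] = -1e6


def encode_protein(seq: str) -> np.ndarray:
    return np.array([_AA_INDEX.get(aa, _AA_INDEX["X"]) for aa in seq], dtype=np.int64)


@dataclass(frozen=True)
class SearchHit:
    query_id: str
    target_id: str
    raw_score: float
    bit_score: float
    e_value: float
    query_start: int = 0
    query_end: int = 0
    target_start: int = 0
    target_end: int = 0
    interval: GenomicInterval | None = None  # set for genomic (translated) hits
    frame: int = 0


def bit_score(raw: float) -> float:
    return (KA_LAMBDA * raw - math.log(KA_K)) / math.log(2)


def e_value(raw: float, m: int, n: int) -> float:
    return KA_K * m * n * math.exp(-KA_LAMBDA * raw)


try:  # optional scalar kernels; the numpy path below is the fallback
    from numba import njit as _njit

    @_njit(cache=True, fastmath=False)
    def _sw_best_nb(query_idx, target_idx, matrix, open1, ext):  # pragma: no cover
        n = target_idx.shape[0]
        h_prev = np.zeros(n + 1, dtype=np.float64)
        f = np.full(n + 1, -1e30, dtype=np.float64)
        best = 0.0
        bi = 0
        bj = 0
        for i in range(query_idx.shape[0]):
            qi = query_idx[i]
            h_left = 0.0
            e = -1e30
            diag = h_prev[0]
            for j in range(1, n + 1):
                fj = max(h_prev[j] - open1, f[j] - ext)
                f[j] = fj
                e = max(e - ext, h_left - open1)
                h = diag + matrix[qi, target_idx[j - 1]]
                if fj > h:
                    h = fj
                if e > h:
                    h = e
                if h < 0.0:
                    h = 0.0
                diag = h_prev[j]
                h_prev[j] = h
                h_left = h
                if h > best:
                    best = h
                    bi = i + 1
                    bj = j
        return best, bi, bj

    _MATRIX64 = _MATRIX.astype(np.float64)
    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False


def _sw_matrix(query_idx: np.ndarray, target_idx: np.ndarray) -> tuple[float, int, int]:
    if _HAVE_NUMBA:
        best, bi, bj = _sw_best_nb(
            np.ascontiguousarray(query_idx),
            np.ascontiguousarray(target_idx),
            _MATRIX64, float(GAP_OPEN + GAP_EXTEND), float(GAP_EXTEND))
        return float(best), int(bi), int(bj)
    return _sw_matrix_numpy(query_idx, target_idx)


def _sw_matrix_numpy(query_idx: np.ndarray, target_idx: np.ndarray) -> tuple[float, int, int]:
    """Vectorised affine Smith-Waterman; returns (score, end_q, end_t).

    end coordinates are exclusive (alignment ends just before them).
    """
    n = len(target_idx)
    h_prev = np.zeros(n + 1, dtype=np.float32)
    f_prev = np.full(n + 1, -np.inf, dtype=np.float32)
    best, best_i, best_j = 0.0, 0, 0
    ext_ramp = np.arange(n, dtype=np.float32) * GAP_EXTEND
    for i, qi in enumerate(query_idx):
        srow = _MATRIX[qi][target_idx]
        f = np.maximum(h_prev - GAP_OPEN - GAP_EXTEND, f_prev - GAP_EXTEND)
        h_diag = h_prev[:-1] + srow
        h_open = np.maximum(h_diag, f[1:])
        np.maximum(h_open, 0.0, out=h_open)
        # gap-in-query (horizontal) closed form via prefix max:
        #   E[j] = max_{k<j} H'[k] - open - ext*(j-k)
        a = np.maximum.accumulate(h_open + ext_ramp)
        e = a - ext_ramp - GAP_OPEN - GAP_EXTEND
        e[1:] = e[:-1]
        e[0] = -np.inf
        h = np.maximum(h_open, e)
        j = int(np.argmax(h))
        if h[j] > best:
            best, best_i, best_j = float(h[j]), i + 1, j + 1
        h_prev[1:] = h
        h_prev[0] = 0.0
        f_prev[1:] = f[1:]
    return best, best_i, best_j


def sw_score(query: str, target: str) -> float:
    """Optimal local alignment score (affine gaps, BLOSUM62)."""
    if not query or not target:
        raise ValueError("empty sequence")
    score, _, _ = _sw_matrix(encode_protein(query), encode_protein(target))
    return score


def local_align(query: str, target: str, query_id: str = "query",
                target_id: str = "target") -> SearchHit:
    """Optimal local protein alignment as a scored SearchHit."""
    if not query or not target:
        raise ValueError("empty sequence")
    qi, ti = encode_protein(query), encode_protein(target)
    score, eq, et = _sw_matrix(qi, ti)
    if score <= 0:
        return SearchHit(query_id, target_id, 0.0, bit_score(0.0),
                         e_value(0.0, len(query), len(target)))
    # alignment start from the reversed-prefix problem
    _, lq, lt = _sw_matrix(qi[:eq][::-1], ti[:et][::-1])
    return SearchHit(
        query_id, target_id, score, bit_score(score),
        e_value(score, len(query), len(target)),
        query_start=eq - lq, query_end=eq,
        target_start=et - lt, target_end=et,
    )


def _column_best_profile(query_idx: np.ndarray, target_idx: np.ndarray) -> np.ndarray:
    """max over query rows of H[i][j]: best local score ending at each target j."""
    n = len(target_idx)
    h_prev = np.zeros(n + 1, dtype=np.float32)
    f_prev = np.full(n + 1, -np.inf, dtype=np.float32)
    profile = np.zeros(n, dtype=np.float32)
    ext_ramp = np.arange(n, dtype=np.float32) * GAP_EXTEND
    for qi in query_idx:
        srow = _MATRIX[qi][target_idx]
        f = np.maximum(h_prev - GAP_OPEN - GAP_EXTEND, f_prev - GAP_EXTEND)
        h_open = np.maximum(h_prev[:-1] + srow, f[1:])
        np.maximum(h_open, 0.0, out=h_open)
        a = np.maximum.accumulate(h_open + ext_ramp)
        e = a - ext_ramp - GAP_OPEN - GAP_EXTEND
        e[1:] = e[:-1]
        e[0] = -np.inf
        h = np.maximum(h_open, e)
        np.maximum(profile, h, out=profile)
        h_prev[1:] = h
        h_prev[0] = 0.0
        f_prev[1:] = f[1:]
    return profile


def _profile_hits(query: str, target: str, min_score: float,
                  pad: int | None = None) -> list[tuple[float, int, int, int, int]]:
    """All well-separated local hits of query in target above min_score.

    Returns (score, q_start, q_end, t_start, t_end) tuples. Separate hits
    are recovered by local re-alignment around each peak of the
    best-score-ending-here profile.
    """
    qi, ti = encode_protein(query), encode_protein(target)
    profile = _column_best_profile(qi, ti)
    pad = pad or 2 * len(query) + 20
    hits = []
    seen: set[tuple[int, int]] = set()
    candidates = np.flatnonzero(profile >= min_score)
    while candidates.size:
        j = int(candidates[np.argmax(profile[candidates])])
        lo = max(0, j + 1 - pad)
        score, eq, et = _sw_matrix(qi, ti[lo : j + 1])
        _, lq, lt = _sw_matrix(qi[:eq][::-1], ti[lo : lo + et][::-1])
        t_start, t_end = lo + et - lt, lo + et
        if (t_start, t_end) not in seen:
            seen.add((t_start, t_end))
            hits.append((score, eq - lq, eq, t_start, t_end))
        keep = ((candidates < t_start) | (candidates >= t_end + len(query) // 2))
        keep &= candidates != j
        candidates = candidates[keep]
    return hits


def translated_search(
    queries: Mapping[str, str],
    genome: Mapping[str, str],
    e_cutoff: float = 1.0,
) -> list[SearchHit]:
    """tBLASTn-style search: protein queries vs six-frame genome translation.

    Hits are reported on forward-strand genomic coordinates with the frame
    recorded (1..3 forward, -1..-3 reverse).
    """
    if e_cutoff <= 0:
        raise ValueError("e_cutoff must be positive")
    total_n = sum(len(s) for s in genome.values())
    hits: list[SearchHit] = []
    for chrom, seq in sorted(genome.items()):
        if set(seq) - set("ACGTN"):
            raise ValueError(f"non-ACGTN symbols in sequence {chrom}")
        for strand in "+-":
            dna = seq if strand == "+" else reverse_complement(seq)
            for offset in range(3):
                prot = translate(dna[offset:])
                if not prot:
                    continue
                frame = (offset + 1) if strand == "+" else -(offset + 1)
                for qid, qseq in sorted(queries.items()):
                    # minimum raw score that could pass the E cutoff
                    smin = (math.log(KA_K * len(qseq) * total_n / e_cutoff)
                            / KA_LAMBDA)
                    for score, qs, qe, ts, te in _profile_hits(qseq, prot,
                                                               max(smin, 1.0)):
                        ev = e_value(score, len(qseq), total_n)
                        if ev > e_cutoff:
                            continue
                        # protein positions -> forward-strand genomic interval
                        g1 = offset + 3 * ts
                        g2 = offset + 3 * te
                        if strand == "-":
                            g1, g2 = len(seq) - g2, len(seq) - g1
                        hits.append(SearchHit(
                            qid, chrom, score, bit_score(score), ev,
                            query_start=qs, query_end=qe,
                            target_start=g1, target_end=g2,
                            interval=GenomicInterval(chrom, g1, g2, strand),
                            frame=frame,
                        ))
    hits.sort(key=lambda h: (-h.raw_score, h.interval.start if h.interval else 0,
                             0 if (h.interval and h.interval.strand == "+") else 1))
    return hits


def six_frame_concat(dna: str) -> str:
    """All six translated frames joined with stop sentinels.

    Local alignments cannot cross '*' (it scores -inf), so one kernel pass
    over the concatenation yields the best per-frame local score.
    """
    frames = []
    rc = reverse_complement(dna)
    for strand_seq in (dna, rc):
        for offset in range(3):
            frames.append(translate(strand_seq[offset:]))
    return "*".join(frames)


def best_translated_scores(
    queries: Mapping[str, str],
    dna: str,
    e_cutoff: float | None = None,
    n_effective: int | None = None,
) -> dict[str, tuple[float, float, float]]:
    """Best six-frame local score per query: {id: (raw, bits, E)}.

    Score-only fast path (no hit coordinates) used for reference ranking
    inside annotation windows.  ``n_effective`` overrides the search-space
    length used for E-values (defaults to len(dna)).
    """
    target = encode_protein(six_frame_concat(dna))
    n = n_effective if n_effective is not None else len(dna)
    out = {}
    for name in sorted(queries):
        qseq = queries[name]
        raw, _, _ = _sw_matrix(encode_protein(qseq), target)
        ev = e_value(raw, len(qseq), n)
        if e_cutoff is None or ev <= e_cutoff:
            out[name] = (raw, bit_score(raw), ev)
    return out


@dataclass
class DomainModel:
    """Position weight matrix over the 20 residues for a protein domain."""

    model_id: str
    pwm: np.ndarray  # shape (L, 20), log-odds scores
    score_threshold: float
    consensus: str = ""
    alphabet: str = "ACDEFGHIKLMNPQRSTVWY"
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._index = {aa: i for i, aa in enumerate(self.alphabet)}

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    @property
    def max_score(self) -> float:
        return float(self.pwm.max(axis=1).sum())

    @classmethod
    def from_consensus(cls, model_id: str, consensus: str,
                       match_prob: float = 0.6,
                       threshold_fraction: float = 0.5) -> "DomainModel":
        """Log-odds PWM for a consensus with uniform mismatch probability."""
        alphabet = "ACDEFGHIKLMNPQRSTVWY"
        bg = 1.0 / 20
        mismatch = (1.0 - match_prob) / 19
        pwm = np.full((len(consensus), 20), math.log2(mismatch / bg))
        for i, aa in enumerate(consensus):
            pwm[i, alphabet.index(aa)] = math.log2(match_prob / bg)
        model = cls(model_id, pwm, 0.0, consensus=consensus)
        model.score_threshold = threshold_fraction * model.max_score
        return model

    def window_scores(self, protein: str) -> np.ndarray:
        """PWM score of every length-L window of the protein."""
        L = self.length
        if len(protein) < L:
            return np.empty(0)
        idx = np.array([self._index.get(aa, -1) for aa in protein])
        scores = np.zeros(len(protein) - L + 1)
        floor = float(self.pwm.min())
        for pos in range(L):
            col = idx[pos : pos + len(scores)]
            vals = np.where(col >= 0, self.pwm[pos][np.clip(col, 0, 19)], floor)
            # non-standard residues score the worst entry of that column
            scores += vals
        return scores


@dataclass(frozen=True)
class DomainHit:
    model_id: str
    start: int  # protein offset, 0-based half-open
    end: int
    score: float
    e_value: float


def pssm_scan(protein: str, model: DomainModel,
              e_cutoff: float | None = None) -> list[DomainHit]:
    """All non-overlapping windows scoring above the model threshold,
    best-scoring first."""
    if not protein:
        raise ValueError("empty protein")
    scores = model.window_scores(protein)
    hits: list[DomainHit] = []
    taken = np.zeros(len(protein), dtype=bool)
    order = np.argsort(-scores, kind="stable")
    for pos in order:
        s = float(scores[pos])
        if s < model.score_threshold:
            break
        if taken[pos : pos + model.length].any():
            continue
        ev = e_value(s, model.length, len(protein))
        if e_cutoff is not None and ev > e_cutoff:
            continue
        hits.append(DomainHit(model.model_id, int(pos), int(pos) + model.length,
                              s, ev))
        taken[pos : pos + model.length] = True
    return hits


def _global_identity(a: str, b: str) -> float:
    """Fraction identical over the shorter sequence, from a local alignment."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = BLOSUM62
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    aln = aligner.align(a, b)[0]
    matches = sum(
        1
        for (qs, qe), (ts, te) in zip(*aln.aligned)
        for x, y in zip(a[qs:qe], b[ts:te])
        if x == y
    )
    return matches / min(len(a), len(b))


def pairwise_identity(a: str, b: str) -> float:
    return _global_identity(a, b)


def dedup_collection(proteins: Mapping[str, str],
                     identity_threshold: float = 0.95) -> dict[str, str]:
    """CD-HIT-style greedy redundancy removal.

    Longest sequences are considered first and become representatives;
    any later sequence whose identity to a representative (over the shorter
    sequence) exceeds the threshold is dropped.
    """
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity_threshold must be in (0, 1]")
    order = sorted(proteins, key=lambda k: (-len(proteins[k]), k))
    kept: dict[str, str] = {}
    for name in order:
        seq = proteins[name]
        redundant = any(
            _global_identity(seq, rep) > identity_threshold
            for rep in kept.values()
        )
        if not redundant:
            kept[name] = seq
    return {k: proteins[k] for k in proteins if k in kept}
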