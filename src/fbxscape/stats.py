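"""EST-based expression calls and the statistical toolbox.

An EST supports a locus when (i) alignment identity exceeds 95%, (ii) at
least 75% of the EST or of the CDS is aligned, and (iii) at least 50
aligned nucleotides are involved; ties between loci go to the highest
identity, then longest alignment, then lexicographic id.

Group comparisons use one-sided Fisher exact tests (hypergeometric upper
tail: is the first-listed group's expressed fraction greater?), Spearman
rank correlation with tie-averaged ranks, the two-sided two-sample
Kolmogorov-Smirnov test, and the one-tailed Wilcoxon rank-sum test.

The module also ships a published 18-species F-box superfamily census
(per-species totals, LTSP/STSP/pseudogene splits, genome sizes, and
expressed/non-expressed counts per group) used as a worked dataset.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import Align
from scipy import stats as sps

EST_MIN_IDENTITY = 0.95
EST_MIN_COVERAGE = 0.75
EST_MIN_OVERLAP = 50


@dataclass
class ExpressionEvidence:
    locus_id: str
    est_count: int

    @property
    def expressed(self) -> bool:
        return self.est_count >= 1


def _dna_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 2
    aligner.mismatch_score = -3
    aligner.open_gap_score = -7
    aligner.extend_gap_score = -2
    return aligner


def _est_match(est: str, cds: str, aligner) -> tuple[bool, float, int]:
    """Apply the three expression criteria; returns (ok, identity, length)."""
    if min(len(est), len(cds)) < EST_MIN_OVERLAP:
        return False, 0.0, 0
    aln = aligner.align(est, cds)
    if not len(aln):
        return False, 0.0, 0
    best = aln[0]
    matches = 0
    length = 0
    for (qs, qe), (ts, te) in zip(*best.aligned):
        length += qe - qs
        matches += sum(1 for x, y in zip(est[qs:qe], cds[ts:te]) if x == y)
    if length == 0:
        return False, 0.0, 0
    identity = matches / length
    coverage = max(length / len(est), length / len(cds))
    ok = (identity > EST_MIN_IDENTITY
          and coverage >= EST_MIN_COVERAGE
          and length >= EST_MIN_OVERLAP)
    return ok, identity, length


def map_ests(
    ests: Mapping[str, str],
    cds_set: Mapping[str, str],
    kmer: int = 25,
) -> dict[str, ExpressionEvidence]:
    """Count supporting ESTs per locus under the three criteria.

    A k-mer prefilter limits alignments to loci sharing an exact 25-mer
    with the EST (guaranteed to exist at the identity threshold for reads
    of the lengths generated here).
    """
    index: dict[str, set[str]] = {}
    for name, cds in cds_set.items():
        for i in range(0, max(len(cds) - kmer + 1, 1), 5):
            index.setdefault(cds[i : i + kmer], set()).add(name)
    aligner = _dna_aligner()
    counts = {name: 0 for name in cds_set}
    for est_id, est in ests.items():
        candidates: set[str] = set()
        for i in range(0, max(len(est) - kmer + 1, 1)):
            candidates |= index.get(est[i : i + kmer], set())
        scored = []
        for name in sorted(candidates):
            ok, ident, length = _est_match(est, cds_set[name], aligner)
            if ok:
                scored.append((-ident, -length, name))
        if scored:
            scored.sort()
            counts[scored[0][2]] += 1
    return {name: ExpressionEvidence(name, n) for name, n in counts.items()}


# ---------------------------------------------------------------------------
# tests


def fisher_exact_one_sided(a: int, b: int, c: int, d: int) -> float:
    """P(X >= a) for the 2x2 table [[a, b], [c, d]] with fixed margins.

    Tests whether group 1 (row 1) has a greater success fraction than
    group 2.  Exact hypergeometric tail (log-factorial computation).
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n_total = a + b + c + d
    if n_total == 0 or a + c == 0:
        return 1.0
    return float(sps.hypergeom.sf(a - 1, n_total, a + c, a + b))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant vector: correlation undefined")
    return float(sps.spearmanr(x, y).statistic)


def ks_two_sample(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    res = sps.ks_2samp(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def wilcoxon_one_tailed(x: Sequence[float], y: Sequence[float]) -> float:
    """One-tailed rank-sum p for H1: x stochastically smaller than y.

    Exact for small tie-free samples, normal approximation with continuity
    correction otherwise (scipy's method='auto')."""
    if len(x) == 0 or len(y) == 0:
        raise ValueError("samples must be non-empty")
    return float(sps.mannwhitneyu(x, y, alternative="less").pvalue)


# ---------------------------------------------------------------------------
# group expression tests

COMPARISONS = (("LTSP", "STSP"), ("LTSP", "pseudogene"),
               ("STSP", "pseudogene"))


def group_expression_tests(
    expressed: Mapping[str, bool],
    labels: Mapping[str, str],
) -> dict[str, float | None]:
    """Three ordered one-sided Fisher tests on expressed/not counts.

    Comparisons: LTSP>STSP, LTSP>pseudogene, STSP>pseudogene; a comparison
    involving an empty group reports None.
    """
    tallies = {g: [0, 0] for g in ("LTSP", "STSP", "pseudogene")}
    for locus, label in labels.items():
        if label not in tallies:
            continue
        tallies[label][0 if expressed.get(locus, False) else 1] += 1
    out: dict[str, float | None] = {}
    for g1, g2 in COMPARISONS:
        (a, b), (c, d) = tallies[g1], tallies[g2]
        key = f"{g1}>{g2}"
        if a + b == 0 or c + d == 0:
            out[key] = None
        else:
            out[key] = fisher_exact_one_sided(a, b, c, d)
    return out


def expression_tests_from_counts(
    west: Mapping[str, int], woest: Mapping[str, int]
) -> dict[str, float]:
    """Same three tests from pre-tabulated expressed (West) / not (Woest)
    counts keyed by group name."""
    out = {}
    for g1, g2 in COMPARISONS:
        out[f"{g1}>{g2}"] = fisher_exact_one_sided(
            west[g1], woest[g1], west[g2], woest[g2])
    return out


# ---------------------------------------------------------------------------
# packaged published census


def load_fbx_counts() -> pd.DataFrame:
    """Published per-species F-box counts (18 plant species): genome size,
    total loci, LTSP/STSP/pseudogene splits."""
    path = resources.files("fbxscape") / "data" / "plant_fbx_counts.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def load_expression_counts() -> pd.DataFrame:
    """Published expressed/non-expressed EST counts per group and species."""
    path = resources.files("fbxscape") / "data" / "plant_fbx_expression_counts.tsv"
    with resources.as_file(path) as p:
        return pd.read_csv(p, sep="\t")


def census_spearman() -> dict[str, float]:
    """Spearman rho of LTSP and STSP counts vs genome size in the census."""
    df = load_fbx_counts()
    return {
        "ltsp_vs_genome_size": spearman_rho(df["genome_size_mb"], df["ltsp"]),
        "stsp_vs_genome_size": spearman_rho(df["genome_size_mb"], df["stsp"]),
    }


def census_expression_tests(species: str) -> dict[str, float]:
    """The three one-sided Fisher tests for one census species row."""
    df = load_expression_counts().set_index("species")
    row = df.loc[species]
    west = {"LTSP": row["ltsp_west"], "STSP": row["stsp_west"],
            "pseudogene": row["pseudo_west"]}
    woest = {"LTSP": row["ltsp_woest"], "STSP": row["stsp_woest"],
             "pseudogene": row["pseudo_woest"]}
    return expression_tests_from_counts(west, woest)
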