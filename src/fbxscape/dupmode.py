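"""Tandem / segmental duplication-mode classification.

Collinear (segmental) blocks are found by dynamic-programming chaining of
homologous gene pairs over gene-order coordinates (the DAGchainer idea);
tandem pairs are same-chromosome paralogs separated by at most a fixed
number of intervening genes.  Block membership takes precedence over
tandem membership when both apply.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

MIN_BLOCK_PAIRS = 6
MAX_ORDINAL_GAP = 10
MAX_INTERVENING = 10


@dataclass(frozen=True)
class GenePosition:
    gene_id: str
    chromosome: str
    ordinal: int  # gene-order index along the chromosome
    midpoint: int = 0


@dataclass
class CollinearBlock:
    block_id: str
    pairs: list[tuple[str, str]]
    chrom_a: str
    chrom_b: str
    score: float

    @property
    def genes(self) -> set[str]:
        return {g for pair in self.pairs for g in pair}


def chain_collinear(
    homolog_pairs: Sequence[tuple[str, str]],
    positions: Mapping[str, GenePosition],
    min_pairs: int = MIN_BLOCK_PAIRS,
    max_gap: int = MAX_ORDINAL_GAP,
    match_bonus: float = 10.0,
    gap_penalty: float = 3.0,  # per skipped ordinal, DAGchainer-like
) -> list[CollinearBlock]:
    """DP chaining of homolog pairs into collinear blocks.

    Within each chromosome pair, anchors (ordinal_a, ordinal_b) are chained
    so both ordinals strictly increase (or a strictly decreases for
    inverted blocks), with a per-skipped-ordinal gap penalty.  Chains with
    at least ``min_pairs`` anchors are reported; a gene may join several
    blocks on different chromosome pairs.
    """
    by_chrom_pair: dict[tuple[str, str], list[tuple[int, int, str, str]]] = {}
    for a, b in homolog_pairs:
        if a not in positions or b not in positions:
            raise ValueError(f"missing position for pair ({a}, {b})")
        pa, pb = positions[a], positions[b]
        if (pa.chromosome == pb.chromosome
                and abs(pa.ordinal - pb.ordinal) <= max_gap):
            # near-diagonal self matches are tandem-array structure, not
            # collinearity evidence
            continue
        key = (pa.chromosome, pb.chromosome)
        if key[0] > key[1] or (key[0] == key[1] and pa.ordinal > pb.ordinal):
            pa, pb = pb, pa
            key = (pa.chromosome, pb.chromosome)
        by_chrom_pair.setdefault(key, []).append(
            (pa.ordinal, pb.ordinal, pa.gene_id, pb.gene_id))

    blocks: list[CollinearBlock] = []
    for (ca, cb), anchors in sorted(by_chrom_pair.items()):
        anchors = sorted(set(anchors))
        for direction in (+1, -1):
            n = len(anchors)
            score = [match_bonus] * n
            back = [-1] * n
            for i in range(n):
                for j in range(i):
                    da = anchors[i][0] - anchors[j][0]
                    db = direction * (anchors[i][1] - anchors[j][1])
                    if da <= 0 or db <= 0 or da > max_gap or db > max_gap:
                        continue
                    cand = score[j] + match_bonus - gap_penalty * (da + db - 2)
                    if cand > score[i]:
                        score[i] = cand
                        back[i] = j
            used = [False] * n
            order = sorted(range(n), key=lambda k: -score[k])
            for end in order:
                if used[end]:
                    continue
                chain = []
                k = end
                while k != -1 and not used[k]:
                    used[k] = True
                    chain.append(anchors[k])
                    k = back[k]
                chain.reverse()
                if len(chain) >= min_pairs:
                    blocks.append(CollinearBlock(
                        f"blk{len(blocks):03d}",
                        [(g1, g2) for _, _, g1, g2 in chain],
                        ca, cb, score[end]))
    return blocks


def call_tandem(
    paralog_pairs: Sequence[tuple[str, str]],
    positions: Mapping[str, GenePosition],
    max_intervening: int = MAX_INTERVENING,
) -> set[tuple[str, str]]:
    """Pairs on the same chromosome with <= max_intervening genes between."""
    tandem = set()
    for a, b in paralog_pairs:
        pa, pb = positions[a], positions[b]
        if pa.chromosome != pb.chromosome:
            continue
        if abs(pa.ordinal - pb.ordinal) - 1 <= max_intervening:
            tandem.add((min(a, b), max(a, b)))
    return tandem


def classify_duplication(
    gene_id: str,
    blocks: Sequence[CollinearBlock],
    tandem_pairs: set[tuple[str, str]],
) -> str:
    """segmental > tandem > other (block membership is stronger evidence)."""
    if any(gene_id in blk.genes for blk in blocks):
        return "segmental"
    if any(gene_id in pair for pair in tandem_pairs):
        return "tandem"
    return "other"


def classify_all(
    gene_ids: Sequence[str],
    homolog_pairs: Sequence[tuple[str, str]],
    positions: Mapping[str, GenePosition],
    min_pairs: int = MIN_BLOCK_PAIRS,
    max_gap: int = MAX_ORDINAL_GAP,
    max_intervening: int = MAX_INTERVENING,
) -> dict[str, str]:
    blocks = chain_collinear(homolog_pairs, positions, min_pairs, max_gap)
    tandem = call_tandem(homolog_pairs, positions, max_intervening)
    return {g: classify_duplication(g, blocks, tandem) for g in gene_ids}
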