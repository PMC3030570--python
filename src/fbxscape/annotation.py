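"""CTT window trimming and two/three-reference consensus gene models.

A candidate locus is a translated-search domain hit.  A 10-kb window around
the hit is iteratively trimmed (CTT) until the best-matching reference
protein's predicted coding region covers the domain hit; the surviving
window is then annotated with the top two or three reference proteins and a
locus is accepted as coding or pseudogene only when at least two references
agree on the verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .intervals import GenomicInterval
from .search import best_translated_scores
from .spliced import (DEFAULT_SCORING, SplicedAlignment, SplicedScoring,
                      best_strand_alignment)

WINDOW_SIZE = 10_000
CTT_MAX_ITER = 6
BLASTX_E = 1e-5


@dataclass
class AnnotationWindow:
    """Current annotation window; always contains the target domain hit."""

    interval: GenomicInterval
    target: GenomicInterval  # the FBXD hit being annotated
    iteration: int = 0
    trim_log: list[str] = field(default_factory=list)
    flagged: bool = False

    def __post_init__(self) -> None:
        if not self.interval.contains(self.target):
            raise ValueError("window must contain the target domain interval")


@dataclass
class CttResult:
    status: str  # "converged" | "failed"
    window: AnnotationWindow
    top_reference: str | None = None
    alignment: SplicedAlignment | None = None
    strand: str = "+"
    ranking: list[tuple[str, float]] | None = None  # valid for final window
    region: GenomicInterval | None = None  # converged coding region (genome)


@dataclass
class TranscriptModel:
    locus_id: str
    exons: list[GenomicInterval]
    cds: str
    classification: str  # "coding" | "pseudogene" | "unresolved"
    supporting_refs: list[str]
    best_score: float
    strand: str = "+"
    frameshift_positions: list[int] = field(default_factory=list)
    stop_positions: list[int] = field(default_factory=list)
    reason: str = ""
    fbxd: GenomicInterval | None = None

    @property
    def interval(self) -> GenomicInterval | None:
        if not self.exons:
            return None
        return GenomicInterval(
            self.exons[0].sequence_id,
            min(e.start for e in self.exons),
            max(e.end for e in self.exons),
            self.strand,
        )


def _rank_references(
    window_seq: str,
    reference_db: Mapping[str, str],
    e_cutoff: float = BLASTX_E,
) -> list[tuple[str, float]]:
    """References with translated-search hits in the window, ranked by bit
    score (ties broken by id)."""
    scores = best_translated_scores(reference_db, window_seq, e_cutoff)
    return sorted(((name, bits) for name, (_, bits, _) in scores.items()),
                  key=lambda kv: (-kv[1], kv[0]))


def ctt_trim(
    window: AnnotationWindow,
    genome: Mapping[str, str],
    reference_db: Mapping[str, str],
    scoring: SplicedScoring = DEFAULT_SCORING,
    max_iter: int = CTT_MAX_ITER,
    e_cutoff: float = BLASTX_E,
) -> CttResult:
    """Iterate translated search / spliced alignment / trimming (<= max_iter).

    Convergence: the best reference's coding region covers the target
    domain interval.  Otherwise that region's span (never any target base)
    is trimmed off the window and the next round starts.
    """
    if not reference_db:
        raise ValueError("reference_db is empty")
    chrom = window.interval.sequence_id
    target = window.target
    for _ in range(max_iter):
        window.iteration += 1
        iv = window.interval
        wseq = genome[chrom][iv.start : iv.end]
        ranked = _rank_references(wseq, reference_db, e_cutoff)
        if not ranked:
            window.trim_log.append(f"iter {window.iteration}: no reference hits")
            return CttResult("failed", window)
        top_ref = ranked[0][0]
        aln, strand = best_strand_alignment(reference_db[top_ref], wseq, scoring)
        if aln is None:
            window.trim_log.append(
                f"iter {window.iteration}: no spliced alignment >= min score")
            return CttResult("failed", window)
        gs, ge = (iv.start + aln.span[0], iv.start + aln.span[1])
        if gs <= target.start and target.end <= ge:
            window.trim_log.append(
                f"iter {window.iteration}: converged on {top_ref}")
            return CttResult("converged", window, top_ref, aln, strand,
                             ranking=ranked,
                             region=GenomicInterval(chrom, gs, ge, strand))
        # trim the predicted region's span, keeping the side with the target
        if ge <= target.start:
            new_start, new_end = ge, iv.end
            window.trim_log.append(
                f"iter {window.iteration}: trimmed left span [{gs},{ge})")
        elif gs >= target.end:
            new_start, new_end = iv.start, gs
            window.trim_log.append(
                f"iter {window.iteration}: trimmed right span [{gs},{ge})")
        else:
            # region straddles the target boundary without covering it:
            # trim only the non-overlapping part and flag the case
            window.flagged = True
            if gs < target.start:
                new_start, new_end = target.start, iv.end
            else:
                new_start, new_end = iv.start, target.end
            window.trim_log.append(
                f"iter {window.iteration}: partial overlap [{gs},{ge}), flagged")
        window.interval = GenomicInterval(chrom, new_start, new_end, iv.strand)
    window.trim_log.append(f"failed after {max_iter} iterations")
    return CttResult("failed", window)


def classify_transcript(alignments: list[SplicedAlignment]) -> str:
    """Two-reference consensus verdict.

    pseudogene iff >=2 alignments each carry a frameshift or premature
    stop; coding iff >=2 alignments are event-free; unresolved otherwise.
    """
    if not alignments:
        raise ValueError("need at least one alignment")
    defects = sum(1 for a in alignments if a.has_defect)
    clean = sum(1 for a in alignments if not a.has_defect)
    if defects >= 2:
        return "pseudogene"
    if clean >= 2:
        return "coding"
    return "unresolved"


def annotate_locus(
    fbxd_hit: GenomicInterval,
    genome: Mapping[str, str],
    reference_db: Mapping[str, str],
    scoring: SplicedScoring = DEFAULT_SCORING,
    window_size: int = WINDOW_SIZE,
    max_iter: int = CTT_MAX_ITER,
    e_cutoff: float = BLASTX_E,
    exclude: str | None = None,
    locus_id: str | None = None,
) -> TranscriptModel | None:
    """Annotate one domain hit; returns None when CTT fails (locus omitted)."""
    chrom = fbxd_hit.sequence_id
    chrom_len = len(genome[chrom])
    mid = fbxd_hit.midpoint
    start = max(0, mid - window_size // 2)
    end = min(chrom_len, start + window_size)
    start = min(start, fbxd_hit.start)
    end = max(end, fbxd_hit.end)
    refs = dict(reference_db)
    if exclude is not None:
        refs.pop(exclude, None)
    locus_id = locus_id or f"{chrom}:{fbxd_hit.start}-{fbxd_hit.end}"

    window = AnnotationWindow(GenomicInterval(chrom, start, end), fbxd_hit)
    ctt = ctt_trim(window, genome, refs, scoring, max_iter, e_cutoff)
    if ctt.status != "converged":
        return None

    # final annotation acts on the single converged coding region (plus a
    # small pad for reference length variation), not the whole window:
    # tandem neighbours left in the window must not attract the model
    pad = 300
    iv = GenomicInterval(
        chrom,
        max(window.interval.start, ctt.region.start - pad),
        min(window.interval.end, ctt.region.end + pad),
    )
    wseq = genome[chrom][iv.start : iv.end]
    ranked = _rank_references(wseq, refs, e_cutoff)
    if len(ranked) < 2:
        return TranscriptModel(locus_id, [], "", "unresolved", [], 0.0,
                               reason="insufficient references",
                               fbxd=fbxd_hit)
    n_refs = 2 if len(ranked) == 2 else 3
    chosen = [name for name, _ in ranked[:n_refs]]
    alignments: dict[str, tuple[SplicedAlignment, str]] = {}
    for name in chosen:
        aln, strand = best_strand_alignment(refs[name], wseq, scoring,
                                            preferred_strand=ctt.strand)
        if aln is not None:
            alignments[name] = (aln, strand)
    if len(alignments) < 2:
        return TranscriptModel(locus_id, [], "", "unresolved", [], 0.0,
                               reason="insufficient references",
                               fbxd=fbxd_hit)
    verdict = classify_transcript([a for a, _ in alignments.values()])
    best_name = min(alignments, key=lambda k: (-alignments[k][0].score, k))
    best_aln, strand = alignments[best_name]
    exons = [
        GenomicInterval(chrom, iv.start + b.genome_start,
                        iv.start + b.genome_end, strand)
        for b in best_aln.blocks
    ]
    return TranscriptModel(
        locus_id=locus_id,
        exons=exons,
        cds=best_aln.coding_sequence(wseq),
        classification=verdict,
        supporting_refs=sorted(alignments),
        best_score=best_aln.score,
        strand=strand,
        frameshift_positions=[iv.start + g for g, _ in best_aln.frameshifts],
        stop_positions=[iv.start + g for g in best_aln.stops],
        fbxd=fbxd_hit,
    )


def reannotate_known(
    locus_id: str,
    locus_interval: GenomicInterval,
    genome: Mapping[str, str],
    reference_db: Mapping[str, str],
    scoring: SplicedScoring = DEFAULT_SCORING,
    **kwargs,
) -> TranscriptModel | None:
    """Re-annotate an already-annotated locus excluding its own protein.

    Used for pseudogene re-screening: the locus's own reference entry
    (matched by id) never supports its own re-annotation.
    """
    return annotate_locus(
        locus_interval, genome, reference_db, scoring,
        exclude=locus_id, locus_id=locus_id, **kwargs,
    )
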