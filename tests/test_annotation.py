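"""CTT window trimming and two/three-reference consensus classification."""

import numpy as np
import pytest

from fbxscape import seqs
from fbxscape.annotation import (AnnotationWindow, annotate_locus,
                                 classify_transcript, ctt_trim,
                                 reannotate_known)
from fbxscape.intervals import GenomicInterval
from fbxscape.spliced import SplicedAlignment, ExonBlock


def _mk_alignment(frameshifts=(), stops=()):
    return SplicedAlignment(
        blocks=[ExonBlock(0, 300, 0, 100)],
        frameshifts=list(frameshifts), stops=list(stops),
        score=500.0, protein_length=100, protein_end=100)


class TestClassifyTranscript:
    def test_two_defective_alignments_mean_pseudogene(self):
        alns = [_mk_alignment(frameshifts=[(30, 2)]),
                _mk_alignment(frameshifts=[(33, 1)])]
        assert classify_transcript(alns) == "pseudogene"

    def test_stop_and_frameshift_also_count(self):
        alns = [_mk_alignment(stops=[60]), _mk_alignment(frameshifts=[(9, 2)])]
        assert classify_transcript(alns) == "pseudogene"

    def test_all_clean_means_coding(self):
        assert classify_transcript([_mk_alignment()] * 3) == "coding"

    def test_split_verdict_is_unresolved(self):
        assert classify_transcript(
            [_mk_alignment(), _mk_alignment(stops=[12])]) == "unresolved"

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            classify_transcript([])


def _family_genome(rng, n_genes=1, gap=900):
    """A small chromosome with n same-family genes in tandem."""
    base_prot = seqs.random_protein(110, rng)
    base_cds = seqs.back_translate(base_prot, rng)
    parts = [seqs.random_dna(1500, rng)]
    intervals = []
    for k in range(n_genes):
        cds = list(base_cds)
        for _ in range(10):  # light member divergence
            i = int(rng.integers(len(cds)))
            cds[i] = "ACGT"[rng.integers(4)]
        for i in range(0, len(cds), 3):
            if "".join(cds[i : i + 3]) in ("TAA", "TAG", "TGA"):
                cds[i] = "C"
        cds = "".join(cds)
        start = sum(len(p) for p in parts)
        intervals.append((start, start + len(cds), cds))
        parts.append(cds)
        parts.append(seqs.random_dna(gap, rng))
    parts.append(seqs.random_dna(1500, rng))
    genome = {"chr": "".join(parts)}
    refs = {f"ref{k}": seqs.translate(iv[2]) for k, iv in enumerate(intervals)}
    refs["base"] = base_prot
    return genome, refs, intervals


class TestCtt:
    def test_single_gene_converges_first_iteration(self, rng):
        genome, refs, ivs = _family_genome(rng, n_genes=1)
        s, e, _ = ivs[0]
        target = GenomicInterval("chr", s, s + 120)
        window = AnnotationWindow(
            GenomicInterval("chr", max(0, s - 1000), e + 1000), target)
        res = ctt_trim(window, genome, refs)
        assert res.status == "converged"
        assert window.iteration == 1
        assert res.region.contains(target)

    def test_tandem_neighbor_trimmed_then_converges(self, rng):
        genome, refs, ivs = _family_genome(rng, n_genes=2)
        (s1, e1, _), (s2, e2, _) = ivs
        # target the SECOND gene but give the first a longer, better ref:
        # extend ref0 so the neighbor outscores the target
        target = GenomicInterval("chr", s2, s2 + 120)
        window = AnnotationWindow(GenomicInterval("chr", s1 - 500, e2 + 500),
                                  target)
        res = ctt_trim(window, genome, refs)
        assert res.status == "converged"
        assert res.region.contains(target)
        assert window.interval.contains(target)
        # the window never loses target bases and shrinks when trimming ran
        if window.iteration > 1:
            assert len(window.interval) < (e2 + 500) - (s1 - 500)

    def test_seven_decoys_fail_after_six_iterations(self, rng):
        # seven unrelated decoy genes surround a weak target, outermost
        # strongest and alternating sides, so each round trims exactly the
        # strongest remaining decoy; one decoy still outscores the target
        # when the round limit is reached
        target_dom = seqs.random_protein(40, rng)
        target_cds = seqs.back_translate(target_dom, rng)
        lengths = [160, 150, 140, 130, 120, 110, 100]
        decoys = [seqs.random_protein(L, rng) for L in lengths]
        left_idx = [0, 2, 4, 6]   # outer -> inner on the left
        right_idx = [1, 3, 5]     # outer -> inner on the right
        parts = [seqs.random_dna(200, rng)]
        for i in left_idx:
            parts += [seqs.back_translate(decoys[i], rng),
                      seqs.random_dna(120, rng)]
        t_start = sum(len(p) for p in parts)
        parts.append(target_cds)
        for i in reversed(right_idx):
            parts += [seqs.random_dna(120, rng),
                      seqs.back_translate(decoys[i], rng)]
        parts.append(seqs.random_dna(200, rng))
        genome = {"chr": "".join(parts)}
        refs = {f"decoy{i}": p for i, p in enumerate(decoys)}
        refs["target"] = target_dom
        target = GenomicInterval("chr", t_start, t_start + len(target_cds))
        window = AnnotationWindow(
            GenomicInterval("chr", 0, len(genome["chr"])), target)
        res = ctt_trim(window, genome, refs, max_iter=6)
        assert res.status == "failed"
        assert window.iteration == 6
        assert window.interval.contains(target)

    def test_empty_reference_db_rejected(self, rng):
        genome, _, ivs = _family_genome(rng, 1)
        s, e, _ = ivs[0]
        window = AnnotationWindow(GenomicInterval("chr", s - 100, e + 100),
                                  GenomicInterval("chr", s, s + 120))
        with pytest.raises(ValueError):
            ctt_trim(window, genome, {})


class TestAnnotateLocus:
    def test_coding_consensus_recovers_cds(self, sim_data):
        genome, refs, truth = sim_data
        locus = next(l for l in truth.loci
                     if l.locus_class == "coding" and len(l.exons) == 1)
        model = annotate_locus(locus.fbxd_interval, genome, refs)
        assert model is not None and model.classification == "coding"
        assert model.cds == locus.cds

    def test_pseudogene_consensus(self, sim_data):
        genome, refs, truth = sim_data
        hits = 0
        for locus in truth.loci:
            if locus.locus_class != "pseudogene":
                continue
            model = annotate_locus(locus.fbxd_interval, genome, refs)
            if model is not None and model.classification == "pseudogene":
                hits += 1
            if hits >= 3:
                break
        assert hits >= 3

    def test_reannotation_excludes_self(self, sim_data):
        genome, refs, truth = sim_data
        locus = next(l for l in truth.loci if l.locus_class == "coding")
        model = reannotate_known(locus.locus_id, locus.fbxd_interval,
                                 genome, refs)
        assert model is not None
        assert locus.locus_id not in model.supporting_refs

    def test_insufficient_references_is_unresolved(self, rng):
        genome, refs, ivs = _family_genome(rng, 1)
        s, e, _ = ivs[0]
        target = GenomicInterval("chr", s, s + 120)
        only_one = {"ref0": refs["ref0"]}
        model = annotate_locus(target, genome, only_one)
        assert model is not None
        assert model.classification == "unresolved"
        assert model.reason == "insufficient references"
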