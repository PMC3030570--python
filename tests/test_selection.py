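"""Ka/Ks machinery: reference picking, triplet alignment, Fitch MRCA,
NG86 pathway counting, and the GY94 likelihood machinery."""

import itertools
import math

import numpy as np
import pytest

from fbxscape import seqs
from fbxscape.search import sw_score
from fbxscape.selection import (KS_MAX, KS_MIN, align_triplet,
                                classify_selection, gy94_pairwise,
                                kaks_record, ks_filter_ok, mrca_parsimony,
                                ng86_kaks, pick_references, region_kaks,
                                simulate_codon_pair, _pathway_differences)
from oracles import enumerate_pathway_differences


def _clean_cds(protein, rng):
    return seqs.back_translate(protein, rng)


def _mutate(cds, n, rng):
    out = list(cds)
    for _ in range(n):
        p = int(rng.integers(len(out)))
        out[p] = "ACGT"[rng.integers(4)]
    for i in range(0, len(out), 3):
        if "".join(out[i : i + 3]) in ("TAA", "TAG", "TGA"):
            out[i] = "C"
    return "".join(out)


class TestPickReferences:
    def test_self_never_selected(self, rng):
        p = seqs.random_protein(80, rng)
        db = {"q": p, "twin": p, "other": seqs.random_protein(80, rng)}
        refs = pick_references("q", db)
        assert "q" not in refs

    def test_exactly_two_nonself_always_selected(self, rng):
        db = {"q": seqs.random_protein(60, rng),
              "r1": seqs.random_protein(60, rng),
              "r2": seqs.random_protein(60, rng)}
        assert set(pick_references("q", db)) == {"r1", "r2"}

    def test_selection_equals_exhaustive_ranking(self, rng):
        db = {f"p{i}": seqs.random_protein(70, rng) for i in range(8)}
        db["q"] = seqs.random_protein(70, rng)
        refs = pick_references("q", db)
        scores = sorted(
            ((-sw_score(db["q"], v), k) for k, v in db.items() if k != "q"))
        assert list(refs) == [scores[0][1], scores[1][1]]

    def test_too_few_references_returns_none(self, rng):
        db = {"q": seqs.random_protein(50, rng),
              "only": seqs.random_protein(50, rng)}
        assert pick_references("q", db) is None


class TestAlignTriplet:
    def test_identical_sequences_align_without_gaps(self, rng):
        cds = _clean_cds(seqs.random_protein(50, rng), rng)
        tri = align_triplet(["a", "b", "c"], {n: cds for n in "abc"})
        assert all(row == cds for row in tri.codon_rows.values())

    def test_planted_codon_deletion_gives_in_frame_gap(self, rng):
        cds = _clean_cds(seqs.random_protein(60, rng), rng)
        short = cds[:90] + cds[93:]  # one codon removed
        tri = align_triplet(["a", "b", "c"],
                            {"a": short, "b": cds, "c": cds})
        row = tri.codon_rows["a"]
        assert len(row) == len(cds)
        assert row.count("-") == 3
        gap_at = row.index("-")
        assert gap_at % 3 == 0

    def test_outgroup_is_most_distant_sequence(self, rng):
        cds = _clean_cds(seqs.random_protein(70, rng), rng)
        near = _mutate(cds, 6, rng)
        far = _mutate(cds, 60, rng)
        tri = align_triplet(["q", "n", "f"], {"q": cds, "n": near, "f": far})
        assert tri.outgroup == "f"

    def test_internal_stop_rejected(self, rng):
        cds = _clean_cds(seqs.random_protein(40, rng), rng)
        bad = cds[:30] + "TAA" + cds[33:]
        with pytest.raises(ValueError):
            align_triplet(["a", "b", "c"], {"a": bad, "b": cds, "c": cds})


class TestMrcaParsimony:
    def test_identical_triplet_reproduces_input(self, rng):
        cds = _clean_cds(seqs.random_protein(40, rng), rng)
        tri = align_triplet(["a", "b", "c"], {n: cds for n in "abc"})
        assert mrca_parsimony(tri) == cds

    def test_outgroup_private_state_excluded(self, rng):
        # column {query: A, near: A, far: G}: ingroup intersection wins
        cds = _clean_cds(seqs.random_protein(50, rng), rng)
        near = _mutate(cds, 4, rng)
        far = _mutate(cds, 45, rng)
        tri = align_triplet(["q", "n", "f"], {"q": cds, "n": near, "f": far})
        mrca = mrca_parsimony(tri)
        rows = tri.codon_rows
        for col in range(len(mrca)):
            if rows["q"][col] == rows["n"][col] != rows["f"][col]:
                assert mrca[col] == rows["q"][col]

    def test_three_way_tie_resolved_to_query(self, rng):
        cds = _clean_cds(seqs.random_protein(50, rng), rng)
        n = _mutate(cds, 30, rng)
        f = _mutate(cds, 50, rng)
        tri = align_triplet(["q", "n", "f"], {"q": cds, "n": n, "f": f})
        mrca = mrca_parsimony(tri)
        rows = tri.codon_rows
        for col in range(len(mrca)):
            trio = {rows[k][col] for k in ("q", "n", "f")}
            if len(trio) == 3:
                assert mrca[col] == rows["q"][col]


class TestNg86:
    def test_identical_sequences_have_zero_rates(self, rng):
        cds = _clean_cds(seqs.random_protein(40, rng), rng)
        ka, ks = ng86_kaks(cds, cds)
        assert ka == 0 and ks == 0

    def test_single_synonymous_difference(self):
        ka, ks = ng86_kaks("GGT" + "CTT" * 19, "GGC" + "CTT" * 19)
        assert ka == 0 and ks > 0

    def test_single_nonsynonymous_difference(self):
        ka, ks = ng86_kaks("ATG" + "CTT" * 19, "AGG" + "CTT" * 19)
        assert ks == 0 and ka > 0

    def test_pathway_counts_match_enumeration_on_all_codon_pairs(self):
        sense = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                 if a + b + c not in ("TAA", "TAG", "TGA")]
        for c1, c2 in itertools.islice(
                itertools.product(sense, sense), 0, None, 7):
            got = _pathway_differences(c1, c2)
            want = enumerate_pathway_differences(c1, c2)
            assert got == pytest.approx(want, abs=1e-12), (c1, c2)

    def test_random_short_pairs_match_enumeration(self, rng):
        for _ in range(20):
            p = seqs.random_protein(5, rng)
            a = _clean_cds(p, rng)
            b = _mutate(a, 4, rng)
            sd = nd = 0.0
            for i in range(0, 15, 3):
                s, n = enumerate_pathway_differences(a[i:i+3], b[i:i+3])
                sd += s
                nd += n
            got_sd = got_nd = 0.0
            for i in range(0, 15, 3):
                s, n = _pathway_differences(a[i:i+3], b[i:i+3])
                got_sd += s
                got_nd += n
            assert (got_sd, got_nd) == pytest.approx((sd, nd), abs=1e-12)

    def test_saturated_proportion_is_rejected(self):
        with pytest.raises(ValueError):
            ng86_kaks("GGT" * 20, "GGC" * 20)


class TestGy94:
    def test_free_likelihood_dominates_fixed(self, rng):
        anc, dec = simulate_codon_pair(150, 0.4, 2.0, 0.5, rng)
        f0 = gy94_pairwise(anc, dec, "fixed_1")
        f1 = gy94_pairwise(anc, dec, "free")
        assert f1.lnl >= f0.lnl - 1e-6

    def test_purifying_omega_recovered(self):
        hits = 0
        for i in range(8):
            rng = np.random.default_rng(500 + i)
            anc, dec = simulate_codon_pair(300, 0.5, 2.0, 0.1, rng)
            fit = gy94_pairwise(anc, dec, "free", seed=i)
            hits += fit.omega < 0.3
        assert hits >= 7

    def test_too_few_codons_rejected(self, rng):
        anc, dec = simulate_codon_pair(5, 0.3, 2.0, 1.0, rng)
        with pytest.raises(ValueError):
            gy94_pairwise(anc, dec, "free")


class TestClassification:
    def test_low_lr_is_neutral(self):
        assert classify_selection(2.0, 0.4) == "neutral"

    def test_threshold_boundary(self):
        assert classify_selection(3.839, 0.2) == "neutral"
        assert classify_selection(3.841, 0.2) == "purifying"

    def test_significant_directions(self):
        assert classify_selection(10.0, 0.2) == "purifying"
        assert classify_selection(10.0, 1.6) == "adaptive"

    def test_ks_filter_keeps_boundaries(self):
        assert ks_filter_ok(KS_MIN) and ks_filter_ok(KS_MAX)
        assert not ks_filter_ok(KS_MIN - 1e-9)
        assert not ks_filter_ok(KS_MAX + 1e-9)
        assert ks_filter_ok(0.5)


class TestRegions:
    def test_region_columns_partition_full(self, rng):
        cds = _clean_cds(seqs.random_protein(80, rng), rng)
        tri = align_triplet(["q", "n", "f"],
                            {"q": cds, "n": _mutate(cds, 20, rng),
                             "f": _mutate(cds, 30, rng)})
        mrca = mrca_parsimony(tri)
        recs = region_kaks("q", tri, mrca, (0, 40), seed=0)
        assert set(recs) == {"full", "FBXD", "dFBXD"}
        n_cols = tri.length // 3
        assert len(tri.codon_rows["q"]) == 3 * n_cols

    def test_identical_sequences_all_regions_zero(self, rng):
        cds = _clean_cds(seqs.random_protein(60, rng), rng)
        tri = align_triplet(["q", "n", "f"], {n: cds for n in ("q", "n", "f")})
        mrca = mrca_parsimony(tri)
        recs = region_kaks("q", tri, mrca, (0, 30), seed=0)
        for rec in recs.values():
            # zero divergence is filtered as "too similar", with ka=ks=0
            assert rec.ka == 0 and rec.ks == 0
            assert rec.filtered

    def test_small_region_filtered(self, rng):
        cds = _clean_cds(seqs.random_protein(40, rng), rng)
        tri = align_triplet(["q", "n", "f"],
                            {"q": cds, "n": _mutate(cds, 10, rng),
                             "f": _mutate(cds, 15, rng)})
        mrca = mrca_parsimony(tri)
        recs = region_kaks("q", tri, mrca, (0, 5), seed=0)
        assert recs["FBXD"].filtered
        assert "10 informative codons" in recs["FBXD"].filter_reason
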