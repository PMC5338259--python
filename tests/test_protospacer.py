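import numpy as np
import pytest

from crisprbim.protospacer import (
    annotate_hit,
    extract_pam,
    find_protospacers,
    match_pam,
    pam_consensus,
    predict_targeting,
)
from crisprbim.seqio import IUPAC_CODES, FeatureSpan, SequenceRecord, revcomp
from oracles import naive_protospacer_scan


def _rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


def _genome_with(rng, insert, pos, length=1000, gid="g"):
    bg = _rand_seq(rng, length)
    return SequenceRecord(id=gid, seq=bg[:pos] + insert + bg[pos + len(insert):])


class TestFindProtospacers:
    def test_planted_forward_hit(self):
        rng = np.random.default_rng(0)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer, 100)
        hits = [h for h in find_protospacers(spacer, g, max_mismatch=0)]
        assert any((h.start, h.strand, h.mismatches) == (100, "+", 0) for h in hits)

    def test_planted_reverse_hit_same_coordinates(self):
        rng = np.random.default_rng(1)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, revcomp(spacer), 200)
        hits = find_protospacers(spacer, g, max_mismatch=0)
        assert [(h.start, h.end, h.strand) for h in hits if h.mismatches == 0] == [(200, 230, "-")]

    def test_short_genome_empty(self):
        rng = np.random.default_rng(2)
        spacer = _rand_seq(rng, 30)
        assert find_protospacers(spacer, SequenceRecord(id="g", seq="ACGTACGTACGT")) == []

    def test_short_spacer_rejected(self):
        with pytest.raises(ValueError, match="spacer too short"):
            find_protospacers("ACGTACGTAC", SequenceRecord(id="g", seq="A" * 100))

    @pytest.mark.parametrize("chunk", range(4))
    def test_matches_naive_scan_on_planted_mismatch_cases(self, chunk):
        for seed in range(chunk * 50, chunk * 50 + 50):
            rng = np.random.default_rng(seed)
            spacer = _rand_seq(rng, 30)
            mutated = list(spacer)
            for p in rng.choice(30, size=3, replace=False):
                mutated[p] = str(rng.choice([b for b in "ACGT" if b != spacer[p]]))
            g = _genome_with(rng, "".join(mutated), int(rng.integers(0, 970)), 1000)
            got = sorted(
                (h.mismatches, h.start, h.strand)
                for h in find_protospacers(spacer, g, max_mismatch=3)
            )
            assert got == naive_protospacer_scan(spacer, g.seq, 3)
            assert (3, int([i for i in range(971) if g.seq[i:i + 30] == "".join(mutated)][0]), "+") in got

    def test_strand_involution(self):
        rng = np.random.default_rng(99)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer, 300, 800)
        rc = SequenceRecord(id="g_rc", seq=revcomp(g.seq))
        fwd = {(h.start, h.end, h.strand, h.mismatches)
               for h in find_protospacers(spacer, g, max_mismatch=2)}
        flipped = {
            (len(g.seq) - h.end, len(g.seq) - h.start,
             "+" if h.strand == "-" else "-", h.mismatches)
            for h in find_protospacers(spacer, rc, max_mismatch=2)
        }
        assert fwd == flipped


class TestPam:
    def test_extract_forward(self):
        rng = np.random.default_rng(3)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer + "TTAGAAT", 100)
        (h,) = [h for h in find_protospacers(spacer, g, 0) if h.start == 100]
        assert extract_pam(h, g) == "TTAGAAT" and not h.pam_truncated

    def test_extract_reverse_mirror(self):
        rng = np.random.default_rng(3)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer + "TTAGAAT", 100)
        g_rc = SequenceRecord(id="rc", seq=revcomp(g.seq))
        (h,) = [h for h in find_protospacers(spacer, g_rc, 0) if h.strand == "-"]
        assert extract_pam(h, g_rc) == "TTAGAAT"

    def test_truncated_at_genome_edge(self):
        rng = np.random.default_rng(4)
        spacer = _rand_seq(rng, 30)
        g = SequenceRecord(id="g", seq=_rand_seq(rng, 50) + spacer + "ACT")
        (h,) = [h for h in find_protospacers(spacer, g, 0) if h.strand == "+"]
        assert extract_pam(h, g) == "ACT" and h.pam_truncated

    @pytest.mark.parametrize(
        "pam,ok", [("TTAGAAT", True), ("CCAGAAA", True), ("TTTGAAT", False)]
    )
    def test_match_against_nnagaaw(self, pam, ok):
        assert match_pam(pam) is ok

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="length"):
            match_pam("TTAGAA")

    def test_consensus_of_identical_pams(self):
        assert pam_consensus(["AAAGAAT"] * 5).consensus == "AAAGAAT"

    def test_consensus_recovered_from_conforming_sample(self):
        rng = np.random.default_rng(5)
        pams = [
            "".join(str(rng.choice(sorted(IUPAC_CODES[c]))) for c in "NNAGAAW")
            for _ in range(50)
        ]
        profile = pam_consensus(pams, threshold=0.9)
        assert profile.consensus == "NNAGAAW"
        assert profile.n_pams == 50
        for col in profile.counts:
            assert sum(col.values()) == 50

    def test_two_divergent_pams_give_degenerate_columns(self):
        profile = pam_consensus(["AAAAAAA", "TTTTTTT"])
        assert profile.consensus == "W" * 7

    def test_fewer_than_two_pams_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            pam_consensus(["AAAGAAT"])

    def test_permutation_invariant(self):
        pams = ["TTAGAAT", "CCAGAAA", "GGAGAAT", "ATAGAAA"]
        assert pam_consensus(pams).consensus == pam_consensus(pams[::-1]).consensus


class TestTargeting:
    def test_perfect_match_with_consensus_pam_targets(self):
        rng = np.random.default_rng(6)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer + "TTAGAAT", 400)
        call = predict_targeting(spacer, g)
        assert call.targeting and call.best_hit.mismatches == 0

    def test_near_match_27_of_30_does_not_target(self):
        rng = np.random.default_rng(7)
        spacer = _rand_seq(rng, 30)
        mutated = list(spacer)
        for p in (5, 14, 22):
            mutated[p] = str(rng.choice([b for b in "ACGT" if b != spacer[p]]))
        g = _genome_with(rng, "".join(mutated) + "TTAGAAT", 400)
        call = predict_targeting(spacer, g)
        assert not call.targeting
        assert call.best_hit.matched_nt == 27 and "27/30" in call.rationale

    def test_perfect_match_with_bad_pam_does_not_target(self):
        rng = np.random.default_rng(8)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer + "GGGGGGG", 400)
        assert not predict_targeting(spacer, g).targeting

    def test_monotone_in_mismatch_tolerance(self):
        rng = np.random.default_rng(9)
        spacer = _rand_seq(rng, 30)
        g = _genome_with(rng, spacer + "TTAGAAT", 400)
        for mm in (0, 1, 2, 3):
            assert predict_targeting(spacer, g, max_mismatch=mm).targeting


class TestAnnotate:
    def _hit(self, start, end):
        from crisprbim.protospacer import ProtospacerHit

        return ProtospacerHit("s", "g", start, end, "+", 0)

    def test_hit_inside_feature(self):
        feats = [FeatureSpan("orf6", 100, 400)]
        assert annotate_hit(self._hit(150, 180), feats).gene_label == "orf6"

    def test_larger_overlap_wins(self):
        feats = [FeatureSpan("a", 0, 110), FeatureSpan("b", 110, 300)]
        # hit [100,130): 10 nt overlap with a, 20 nt with b
        assert annotate_hit(self._hit(100, 130), feats).gene_label == "b"

    def test_tied_overlap_prefers_leftmost_feature(self):
        feats = [FeatureSpan("b", 115, 300), FeatureSpan("a", 0, 115)]
        assert annotate_hit(self._hit(100, 130), feats).gene_label == "a"

    def test_intergenic_hit_unlabelled(self):
        feats = [FeatureSpan("a", 0, 50)]
        assert annotate_hit(self._hit(60, 90), feats).gene_label == ""
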