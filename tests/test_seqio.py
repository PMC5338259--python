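import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crisprbim.seqio import (
    FeatureSpan,
    SequenceRecord,
    gc_content,
    in_silico_pcr,
    iupac_match,
    orf_scan,
    read_fasta,
    read_genbank,
    revcomp,
    write_fasta,
    write_genbank,
)
from oracles import brute_force_orfs

dna = st.text(alphabet="ACGT", min_size=1, max_size=120)


class TestFasta:
    def test_single_record_normalized(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">x\nacgt\n")
        recs = read_fasta(p)
        assert len(recs) == 1 and recs[0].id == "x" and recs[0].seq == "ACGT"

    def test_order_preserved_and_u_converted(self, tmp_path):
        p = tmp_path / "x.fa"
        p.write_text(">a\nAUGC\n>b\nTTTT\n")
        recs = read_fasta(p)
        assert [r.id for r in recs] == ["a", "b"]
        assert recs[0].seq == "ATGC"

    def test_empty_file_rejected(self, tmp_path):
        p = tmp_path / "empty.fa"
        p.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            read_fasta(p)

    def test_duplicate_ids_rejected_by_name(self, tmp_path):
        p = tmp_path / "dup.fa"
        p.write_text(">same\nACGT\n>same\nTTTT\n")
        with pytest.raises(ValueError, match="same"):
            read_fasta(p)

    def test_non_iupac_rejected(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">x\nACGX\n")
        with pytest.raises(ValueError, match="non-IUPAC"):
            read_fasta(p)

    @given(st.lists(dna, min_size=1, max_size=30, unique=True))
    def test_round_trip(self, seqs):
        import tempfile

        recs = [SequenceRecord(id=f"s{i}", seq=s) for i, s in enumerate(seqs)]
        with tempfile.TemporaryDirectory() as tmp:
            p = f"{tmp}/rt.fa"
            write_fasta(recs, p, width=70)
            back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]

    def test_large_round_trip(self, tmp_path):
        rng = np.random.default_rng(7)
        recs = [
            SequenceRecord(
                id=f"rec{i}",
                seq="".join(rng.choice(list("ACGT"), size=int(rng.integers(50, 300)))),
            )
            for i in range(1000)
        ]
        p = tmp_path / "big.fa"
        write_fasta(recs, p)
        back = read_fasta(p)
        assert [(r.id, r.seq) for r in back] == [(r.id, r.seq) for r in recs]


class TestGenbank:
    def _minimal(self, tmp_path, location: str) -> str:
        gb = (
            "LOCUS       test                40 bp    DNA     linear   PHG 01-JAN-2000\n"
            "DEFINITION  minimal record.\n"
            "ACCESSION   test\n"
            "FEATURES             Location/Qualifiers\n"
            f"     CDS             {location}\n"
            '                     /locus_tag="orfA"\n'
            "ORIGIN\n"
            "        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt\n"
            "//\n"
        )
        p = tmp_path / "t.gb"
        p.write_text(gb)
        return str(p)

    def test_coordinate_conversion(self, tmp_path):
        rec = read_genbank(self._minimal(tmp_path, "10..30"))
        (f,) = rec.features
        assert (f.start, f.end, f.strand, f.label) == (9, 30, "+", "orfA")

    def test_complement_strand(self, tmp_path):
        rec = read_genbank(self._minimal(tmp_path, "complement(10..30)"))
        assert rec.features[0].strand == "-"

    def test_missing_origin_rejected(self, tmp_path):
        p = tmp_path / "noorigin.gb"
        p.write_text(
            "LOCUS       test                40 bp    DNA     linear   PHG 01-JAN-2000\n"
            "DEFINITION  no sequence.\nACCESSION   test\n//\n"
        )
        with pytest.raises(ValueError, match="ORIGIN"):
            read_genbank(p)

    def test_write_read_feature_set(self, tmp_path):
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        feats = [
            FeatureSpan(label=f"orf{i}", start=i * 180, end=i * 180 + 150,
                        strand="+" if i % 2 == 0 else "-")
            for i in range(10)
        ]
        rec = SequenceRecord(id="synth", seq=seq, features=feats)
        p = tmp_path / "synth.gb"
        write_genbank(rec, p)
        back = read_genbank(p)
        assert back.seq == seq
        assert {(f.label, f.start, f.end, f.strand) for f in back.features} == {
            (f.label, f.start, f.end, f.strand) for f in feats
        }


class TestGc:
    @pytest.mark.parametrize(
        "seq,expected", [("ATAT", 0.0), ("GCGC", 100.0), ("ATGC", 50.0)]
    )
    def test_known_values(self, seq, expected):
        assert gc_content(seq) == expected

    def test_n_excluded_from_denominator(self):
        assert gc_content("GCNN") == 100.0

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            gc_content("NNNN")

    @given(dna)
    def test_invariant_under_reverse_complement(self, seq):
        assert gc_content(seq) == pytest.approx(gc_content(revcomp(seq)))


class TestRevcompIupac:
    def test_palindrome(self):
        assert revcomp("ACGT") == "ACGT"

    @given(dna)
    def test_involution(self, seq):
        assert revcomp(revcomp(seq)) == seq

    @pytest.mark.parametrize(
        "base,code,expected",
        [("T", "W", True), ("A", "W", True), ("G", "W", False), ("C", "N", True)],
    )
    def test_iupac_table(self, base, code, expected):
        assert iupac_match(base, code) is expected

    def test_unknown_code_rejected(self):
        with pytest.raises(ValueError):
            iupac_match("A", "Z")


class TestOrfScan:
    def _orf(self, n_codons: int) -> str:
        sense = "GCT" * n_codons  # alanine codons, no internal stops/starts
        return "CCC" + "ATG" + sense + "TAA" + "CCC"

    def test_threshold_boundary_counted_with_start(self):
        calls = [c for c in orf_scan(self._orf(30)) if c.strand == "+"]
        assert len(calls) == 1 and calls[0].aa_length == 31

    def test_below_threshold_empty(self):
        assert [c for c in orf_scan(self._orf(28)) if c.strand == "+"] == []

    def test_orf_without_stop_discarded(self):
        seq = "ATG" + "GCT" * 50  # runs off the end
        assert orf_scan(seq) == []

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_on_random_sequences(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACGT"), size=2000))
        got = {(c.strand, c.start, c.end, c.aa_length) for c in orf_scan(seq, min_aa=10)}
        assert got == brute_force_orfs(seq, min_aa=10)

    def test_span_divisible_by_three(self):
        rng = np.random.default_rng(11)
        seq = "".join(rng.choice(list("ACGT"), size=3000))
        for c in orf_scan(seq, min_aa=5):
            assert (c.end - c.start) % 3 == 0


class TestInSilicoPcr:
    FWD = "TGCTGAGACAACCTAGTCTCTC"
    REV = "TAAACAGAGCCTCCCTATCC"

    def _genome(self, rng, core_len=200):
        pad = lambda n: "".join(rng.choice(list("ACGT"), size=n))
        core = pad(core_len)
        return pad(50) + self.FWD + core + revcomp(self.REV) + pad(50), core

    def test_planted_amplicon_recovered(self):
        rng = np.random.default_rng(0)
        genome, core = self._genome(rng)
        res = in_silico_pcr(SequenceRecord(id="g", seq=genome), self.FWD, self.REV)
        assert res.found and not res.multiple_products
        assert res.amplicons[0].seq == self.FWD + core + revcomp(self.REV)

    def test_absent_primers_give_empty_result_not_error(self):
        rng = np.random.default_rng(1)
        genome = "".join(rng.choice(list("ACGT"), size=500))
        res = in_silico_pcr(SequenceRecord(id="g", seq=genome), self.FWD, self.REV)
        assert not res.found and res.amplicons == []

    def test_misordered_sites_no_amplicon(self):
        rng = np.random.default_rng(2)
        pad = "".join(rng.choice(list("ACGT"), size=60))
        genome = pad + revcomp(self.REV) + pad + self.FWD + pad
        res = in_silico_pcr(SequenceRecord(id="g", seq=genome), self.FWD, self.REV)
        assert not res.found

    def test_two_planted_sites_flagged(self):
        rng = np.random.default_rng(3)
        g1, c1 = self._genome(rng, 150)
        g2, c2 = self._genome(rng, 90)
        res = in_silico_pcr(SequenceRecord(id="g", seq=g1 + g2), self.FWD, self.REV)
        assert res.multiple_products and len(res.amplicons) == 2
        assert res.amplicons[0].seq.endswith(revcomp(self.REV))

    def test_short_primer_rejected(self):
        with pytest.raises(ValueError, match="15"):
            in_silico_pcr(SequenceRecord(id="g", seq="ACGT" * 50), "ACGTACGT", self.REV)
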