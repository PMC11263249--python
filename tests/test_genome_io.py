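"""Coordinate model, GenBank/FASTA I/O, translation, ORF scanning."""

import warnings

import pytest
from hypothesis import given
from hypothesis import strategies as st

from mitocomp.genome_io import (CODE4, GeneFeature, GeneticCode, Mitogenome,
                                extract_gene_sequence, find_orfs,
                                GenomeIOError, read_fasta, read_genbank,
                                reverse_complement, translate, write_fasta,
                                write_genbank)

DNA = st.text(alphabet="ACGT", min_size=0, max_size=200)


def make_genome(seq, feats=(), topology="circular", gid="G1"):
    return Mitogenome(id=gid, species="Test species", sequence=seq,
                      topology=topology, features=list(feats))


class TestGenBank:
    def test_roundtrip_two_records(self, tmp_path):
        g1 = make_genome("ATGAAATAA" + "ACGT" * 10,
                         [GeneFeature("CDS", "atp9", "+", [(0, 9)])], gid="A1")
        g2 = make_genome("TTGAAATAG" + "TGCA" * 12,
                         [GeneFeature("CDS", "cob", "-", [(0, 9)])],
                         topology="linear", gid="B1")
        path = tmp_path / "two.gb"
        write_genbank([g1, g2], path)
        back = read_genbank(path)
        assert len(back) == 2
        for orig, rec in zip([g1, g2], back):
            assert rec.sequence == orig.sequence
            assert rec.topology == orig.topology
            assert [(f.kind, f.gene, f.strand, f.segments) for f in rec.features] \
                == [(f.kind, f.gene, f.strand, f.segments) for f in orig.features]

    def test_one_based_inclusive_converted(self, tmp_path):
        # GenBank location "10..18" must become the 0-based segment [9, 18)
        g = make_genome("A" * 30, [GeneFeature("CDS", "atp8", "+", [(9, 18)])])
        path = tmp_path / "x.gb"
        write_genbank([g], path)
        text = path.read_text()
        assert "10..18" in text
        assert read_genbank(path)[0].features[0].segments == [(9, 18)]

    def test_join_location_multi_segment(self, tmp_path):
        g = make_genome("A" * 400,
                        [GeneFeature("CDS", "cox1", "+", [(99, 150), (299, 360)])])
        path = tmp_path / "j.gb"
        write_genbank([g], path)
        assert "join(100..150,300..360)" in path.read_text()
        feat = read_genbank(path)[0].features[0]
        assert len(feat.segments) == 2
        assert [e - s for s, e in feat.segments] == [51, 61]

    def test_empty_file_errors(self, tmp_path):
        p = tmp_path / "empty.gb"
        p.write_text("")
        with pytest.raises(GenomeIOError):
            read_genbank(p)


class TestExtract:
    def test_plus_strand(self):
        g = make_genome("ATGAAACCC")
        f = GeneFeature("CDS", "x", "+", [(0, 6)])
        assert extract_gene_sequence(g, f) == "ATGAAA"

    def test_minus_strand_reverse_complement(self):
        g = make_genome("ATGAAACCC")
        f = GeneFeature("CDS", "x", "-", [(0, 3)])
        assert extract_gene_sequence(g, f) == "CAT"

    def test_origin_spanning_circular(self):
        seq = "".join("ACGT"[i % 4] for i in range(100))
        g = make_genome(seq)
        f = GeneFeature("CDS", "x", "+", [(95, 100), (0, 5)])
        assert extract_gene_sequence(g, f) == seq[95:] + seq[:5]

    def test_length_equals_segment_sum(self, small_cohort):
        for g in small_cohort.genomes[:2]:
            for f in g.features:
                if f.kind == "CDS":
                    assert len(extract_gene_sequence(g, f)) == f.length

    @given(DNA)
    def test_revcomp_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s


class TestTranslate:
    def test_table4_tga_is_tryptophan(self):
        assert translate("TGA" + "TAA") == "W"
        assert CODE4.codons["TGA"] == "W"

    def test_atgtga_table4_vs_table1(self):
        assert translate("ATGTGA") == "MW"
        code1 = GeneticCode.from_table(1)
        assert translate("ATGTGA", code1) == "M"  # trailing stop dropped

    def test_trailing_stop_dropped(self):
        assert translate("ATGAAATAA") == "MK"

    def test_internal_stop_policy(self):
        with pytest.raises(GenomeIOError):
            translate("ATGTAAAAATAA", internal_stop="error")
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert translate("ATGTAAAAATAA", internal_stop="warn") == "M*K"
            assert any("internal stop" in str(x.message) for x in w)

    def test_partial_codon_truncated_with_warning(self):
        with warnings.catch_warnings(record=True) as w:
            warnings.simplefilter("always")
            assert translate("ATGAAAT") == "MK"
            assert any("not divisible" in str(x.message) for x in w)

    def test_n_codon_is_x(self):
        assert translate("ATGANA") == "MX"


def _orf_oracle(seq, min_codons, code=CODE4):
    """Brute-force six-frame ORF scan on a plain string (start..stop)."""
    found = []
    for strand, s in (("+", seq), ("-", reverse_complement(seq))):
        for frame in range(3):
            i = frame
            start = None
            while i + 3 <= len(s):
                codon = s[i:i + 3]
                if code.is_stop(codon):
                    if start is not None and (i - start) // 3 >= min_codons:
                        found.append((strand, start, i + 3))
                    start = None
                elif start is None and codon in {"ATG", "GTG", "TTG"}:
                    start = i
                i += 3
    return sorted(found)


class TestOrfs:
    def test_region_below_threshold_skipped(self, rng):
        body = "ATG" + "GCT" * 90 + "TAA"  # 276 nt valid ORF
        seq = body + "C" * (299 - len(body))
        g = make_genome(seq, topology="linear")
        assert find_orfs(g, [(0, 299)], min_orf_codons=50) == []
        assert len(find_orfs(g, [(0, 299)], min_region_nt=200,
                             min_orf_codons=50)) >= 1

    def test_constructed_99_codon_orf(self, rng):
        from tests.conftest import random_dna
        orf = "ATG" + "GCT" * 98 + "TAA"   # 99 codons + stop = 300 nt
        seq = "CCC" * 10 + orf + "C" * 70  # 400 nt total
        assert len(seq) == 400
        g = make_genome(seq, topology="linear")
        res = [o for o in find_orfs(g, [(0, 400)], min_orf_codons=50)
               if o.strand == "+"]
        assert len(res) == 1
        assert res[0].length_codons == 99
        assert "*" not in res[0].protein

    def test_all_n_region(self):
        g = make_genome("N" * 500, topology="linear")
        assert find_orfs(g, [(0, 500)], min_orf_codons=10) == []

    def test_matches_brute_force_oracle(self, rng):
        from tests.conftest import random_dna
        seq = random_dna(rng, 900)
        g = make_genome(seq, topology="linear")
        got = sorted((o.strand, o.start, o.end)
                     for o in find_orfs(g, [(0, 900)], min_region_nt=100,
                                        min_orf_codons=20))
        expect = []
        for strand, a, b in _orf_oracle(seq, 20):
            if strand == "+":
                expect.append((strand, a, b))
            else:
                expect.append((strand, len(seq) - b, len(seq) - a))
        assert got == sorted(expect)


class TestFasta:
    def test_roundtrip(self, tmp_path):
        recs = [("s1", "ACGT" * 40)]
        p = tmp_path / "x.fa"
        write_fasta(recs, p)
        assert read_fasta(p) == recs
        # 60-column wrapping
        lines = p.read_text().splitlines()
        assert max(len(l) for l in lines if not l.startswith(">")) == 60

    def test_empty_list(self, tmp_path):
        p = tmp_path / "e.fa"
        write_fasta([], p)
        assert p.read_text() == ""
        assert read_fasta(p) == []

    def test_duplicate_id_errors(self, tmp_path):
        with pytest.raises(GenomeIOError, match="duplicate"):
            write_fasta([("a", "ACGT"), ("a", "TTTT")], tmp_path / "d.fa")

    def test_id_with_spaces_reads_back_first_token(self, tmp_path):
        p = tmp_path / "s.fa"
        write_fasta([("name extra words", "ACGT")], p)
        assert ">name extra words" in p.read_text()
        assert read_fasta(p) == [("name", "ACGT")]
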