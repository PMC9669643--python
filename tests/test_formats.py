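"""File-format contracts: FASTA, FASTQ, GenBank, feature table, adapters."""

import gzip
import os

import pytest

from plastopipe.errors import AssemblyNotFound, CandidateOverflow, ConfigError, FormatError
from plastopipe.formats import (
    discover_assembler_output,
    read_fasta,
    read_fastq_pairs,
    read_genbank,
    write_assembler_config,
    write_fasta,
    write_feature_table,
    write_fastq_pair,
    write_genbank,
)
from plastopipe.model import AnnotationSet, Feature, ReadPair, Segment, SequenceRecord


class TestFasta:
    def test_concatenation_and_uppercase(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">x\nacgt\nACGT\n")
        (rec,) = read_fasta(str(p))
        assert (rec.id, rec.bases) == ("x", "ACGTACGT")

    def test_multi_record(self, tmp_path):
        p = tmp_path / "a.fa"
        p.write_text(">a\nAC\n>b\nGT\n")
        recs = read_fasta(str(p))
        assert [r.id for r in recs] == ["a", "b"]

    @pytest.mark.parametrize(
        "content,fragment",
        [
            (">x\n", "empty sequence"),
            (">x\nAC!T\n", "non-IUPAC"),
            ("", "empty FASTA"),
        ],
    )
    def test_format_errors(self, tmp_path, content, fragment):
        p = tmp_path / "bad.fa"
        p.write_text(content)
        with pytest.raises(FormatError, match=fragment):
            read_fasta(str(p))

    def test_round_trip_fixed_point(self, tmp_path, truth):
        p1, p2 = str(tmp_path / "1.fa"), str(tmp_path / "2.fa")
        write_fasta([truth.annotation.sequence], p1)
        recs = read_fasta(p1)
        write_fasta(recs, p2)
        assert open(p1).read() == open(p2).read()
        assert recs[0].bases == truth.annotation.sequence.bases

    def test_wrapping(self, tmp_path):
        p = tmp_path / "w.fa"
        write_fasta([SequenceRecord("x", "", "A" * 71)], str(p), width=70)
        lines = p.read_text().splitlines()
        assert [len(l) for l in lines[1:]] == [70, 1]

    def test_empty_list_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            write_fasta([], str(tmp_path / "e.fa"))


class TestFastq:
    def test_round_trip_and_gzip(self, tmp_path):
        pairs = [ReadPair("r1", "ACGT", "IIII", "TTGG", "IIII")]
        p1, p2 = str(tmp_path / "r1.fq"), str(tmp_path / "r2.fq")
        write_fastq_pair(pairs, p1, p2)
        gz = str(tmp_path / "r1.fq.gz")
        with open(p1, "rb") as src, gzip.open(gz, "wb") as dst:
            dst.write(src.read())
        got = list(read_fastq_pairs(gz, p2))
        assert got[0].seq1 == "ACGT" and got[0].seq2 == "TTGG"
        assert got[0].qual1 == "IIII"


GB_SNIPPET = """LOCUS       toy                      100 bp    DNA     circular PLN 01-JAN-2000
DEFINITION  toy record.
ACCESSION   toy
VERSION     toy.1
SOURCE      .
  ORGANISM  .
FEATURES             Location/Qualifiers
     gene            5..10
                     /gene="z"
     CDS             complement(join(10..20,30..40))
                     /gene="x"
     CDS             order(45..60,complement(70..81))
                     /gene="y"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


class TestGenBank:
    def test_location_grammar(self, tmp_path):
        p = tmp_path / "toy.gb"
        p.write_text(GB_SNIPPET)
        ref = read_genbank(str(p))
        by_name = {f.name: f for f in ref.features}
        z = by_name["z"]
        assert [(s.start, s.end, s.strand) for s in z.segments] == [(4, 10, 1)]
        x = by_name["x"]
        assert [(s.start, s.end, s.strand) for s in x.segments] == [(9, 20, -1), (29, 40, -1)]
        assert not x.trans_spliced
        y = by_name["y"]
        assert y.trans_spliced
        assert {s.strand for s in y.segments} == {1, -1}

    def test_round_trip_preserves_features(self, tmp_path, truth_annotation):
        p1, p2 = str(tmp_path / "a.gb"), str(tmp_path / "b.gb")
        write_genbank(truth_annotation, p1)
        ref = read_genbank(p1)
        assert ref.sequence.bases == truth_annotation.sequence.bases
        assert len(ref.features) == len(truth_annotation.features)
        for got, want in zip(ref.features, truth_annotation.features):
            assert got.key == want.key
            assert got.trans_spliced == want.trans_spliced
            assert [(s.start, s.end, s.strand) for s in got.segments] == [
                (s.start, s.end, s.strand) for s in want.segments
            ]
            for k, v in want.qualifiers.items():
                assert got.qualifiers[k] == [str(x) for x in v]
        # writer is a fixed point on its own output
        write_genbank(
            AnnotationSet(sequence=ref.sequence, features=ref.features,
                          organism=ref.organism, topology=ref.topology),
            p2,
        )
        assert open(p1).read() == open(p2).read()

    def test_minus_strand_location_text(self, tmp_path):
        ann = AnnotationSet(
            sequence=SequenceRecord("m", "", "ACGT" * 30),
            features=[Feature("gene", {"gene": ["g"]}, [Segment(0, 90, -1)])],
        )
        p = tmp_path / "m.gb"
        write_genbank(ann, str(p))
        assert "complement(1..90)" in p.read_text()

    def test_missing_origin_rejected(self, tmp_path):
        p = tmp_path / "bad.gb"
        p.write_text(GB_SNIPPET.split("ORIGIN")[0] + "ORIGIN\n//\n")
        with pytest.raises(FormatError):
            read_genbank(str(p))


class TestFeatureTable:
    def seq(self, n=120):
        return SequenceRecord("chr", "", "ACGT" * (n // 4))

    def test_plus_strand_gene_layout(self, tmp_path):
        ann = AnnotationSet(
            sequence=self.seq(),
            features=[Feature("gene", {"gene": ["psbA"]}, [Segment(0, 90, 1)])],
        )
        p = tmp_path / "a.tbl"
        write_feature_table(ann, str(p))
        lines = p.read_text().splitlines()
        assert lines[0] == ">Feature chr"
        assert lines[1] == "1\t90\tgene"
        assert lines[2] == "\t\t\tgene\tpsbA"

    def test_minus_strand_reversed_coordinates(self, tmp_path):
        ann = AnnotationSet(
            sequence=self.seq(),
            features=[Feature("gene", {"gene": ["g"]}, [Segment(0, 90, -1)])],
        )
        p = tmp_path / "b.tbl"
        write_feature_table(ann, str(p))
        assert p.read_text().splitlines()[1] == "90\t1\tgene"

    def test_multi_interval_continuation(self, tmp_path):
        ann = AnnotationSet(
            sequence=self.seq(),
            features=[
                Feature("CDS", {"gene": ["g"]}, [Segment(0, 30, 1), Segment(49, 100, 1)])
            ],
        )
        p = tmp_path / "c.tbl"
        write_feature_table(ann, str(p))
        lines = p.read_text().splitlines()
        assert lines[1] == "1\t30\tCDS"
        assert lines[2] == "50\t100"

    def test_exon_intron_not_emitted(self, tmp_path):
        ann = AnnotationSet(
            sequence=self.seq(),
            features=[
                Feature("gene", {"gene": ["g"]}, [Segment(0, 30, 1)]),
                Feature("exon", {}, [Segment(0, 10, 1)]),
                Feature("intron", {}, [Segment(10, 20, 1)]),
            ],
        )
        p = tmp_path / "d.tbl"
        write_feature_table(ann, str(p))
        text = p.read_text()
        assert "exon" not in text and "intron" not in text
        assert text.count(">Feature") == 1

    def test_zero_segment_feature_rejected(self, tmp_path):
        ann = AnnotationSet(sequence=self.seq(), features=[Feature("gene", {}, [])])
        with pytest.raises(ValueError):
            write_feature_table(ann, str(tmp_path / "e.tbl"))


class _Sample:
    prefix = "sampleX"
    seed = "seed.fa"
    size_range = (120_000, 200_000)


class TestAssemblerAdapters:
    def test_config_contains_stated_defaults(self, tmp_path):
        p = str(tmp_path / "cfg.txt")
        write_assembler_config(_Sample(), ("f.fq", "r.fq"), p)
        text = open(p).read()
        assert "120000-200000" in text
        assert "K-mer                 = 29" in text
        assert "Type                  = chloro" in text
        assert "Read Length           = 151" in text
        assert "Insert size           = 300" in text
        assert "Single/Paired         = PE" in text

    def test_missing_seed_rejected(self, tmp_path):
        s = _Sample()
        s.seed = None
        with pytest.raises(ConfigError):
            write_assembler_config(s, ("f", "r"), str(tmp_path / "cfg"))
        assert not os.path.exists(tmp_path / "cfg")

    def _mk(self, d, name):
        (d / name).write_text(">c\nACGTACGT\n")

    def test_discovery_counts(self, tmp_path):
        self._mk(tmp_path, "Circularized_assembly_1_sampleX.fasta")
        assert len(discover_assembler_output(str(tmp_path), "sampleX")) == 1
        os.remove(tmp_path / "Circularized_assembly_1_sampleX.fasta")
        self._mk(tmp_path, "Option_1_sampleX.fasta")
        self._mk(tmp_path, "Option_2_sampleX.fasta")
        recs = discover_assembler_output(str(tmp_path), "sampleX")
        assert len(recs) == 2

    def test_overflow_and_absence(self, tmp_path):
        with pytest.raises(AssemblyNotFound):
            discover_assembler_output(str(tmp_path), "sampleX")
        self._mk(tmp_path, "Option_1_sampleX.fasta")
        self._mk(tmp_path, "Option_2_sampleX.fasta")
        self._mk(tmp_path, "Option_3_sampleX.fasta")
        with pytest.raises(CandidateOverflow):
            discover_assembler_output(str(tmp_path), "sampleX")
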