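"""Annotation transfer: template extraction, mapping rounds, gene models, QC."""

import pytest

from plastopipe.annotate import (
    DEFAULT_ROUNDS,
    build_annotation,
    extract_reference_features,
    map_features,
    qc_internal_stops,
)
from plastopipe.model import (
    AnnotationSet,
    Feature,
    FeatureTemplate,
    MappedFeature,
    Segment,
    SequenceRecord,
)
from plastopipe.synthetic import generate_plastome, mutate, plant_divergence


@pytest.fixture(scope="module")
def templates(truth):
    return extract_reference_features(truth.annotation)


@pytest.fixture(scope="module")
def truth():
    return generate_plastome(2000, 400, 600, rng_seed=42)


class TestExtractReferenceFeatures:
    def test_one_template_per_gene_level_feature(self, templates):
        assert [(t.name, t.key) for t in templates] == [
            ("toyA", "CDS"), ("toyB", "CDS"), ("toyTrn", "tRNA"),
            ("toyRps12", "CDS"), ("toyIR", "rRNA"), ("toyIR", "rRNA"),
        ]

    def test_segment_sequences_are_strand_applied(self, truth, templates):
        by = {t.name: t for t in templates}
        a = by["toyA"]
        assert a.segment_sequences[0] == truth.genome.bases[100:400]
        assert a.segment_sequences[0].startswith("ATG")
        r12 = by["toyRps12"]
        assert r12.trans_spliced
        joined = "".join(r12.segment_sequences)
        assert joined.startswith("ATG") and joined.endswith("TAA")

    def test_multi_exon_lengths(self, templates):
        b = next(t for t in templates if t.name == "toyB")
        assert [len(s) for s in b.segment_sequences] == [99, 102]

    def test_orphan_cds_synthesized_with_warning(self, truth, caplog):
        import logging

        ref = truth.annotation
        orphan = Feature("CDS", {"gene": ["orphan"]}, [Segment(10, 40, 1)])
        hacked = type(ref)(ref.sequence, ref.features + [orphan], ref.organism)
        with caplog.at_level(logging.WARNING, logger="plastopipe.annotate"):
            tpls = extract_reference_features(hacked)
        assert any(t.name == "orphan" for t in tpls)
        assert any("no parent gene" in r.message for r in caplog.records)


class TestMapFeatures:
    def test_self_mapping_is_exact_round_one(self, truth, templates):
        target = SequenceRecord("self", "", truth.annotation.sequence.bases)
        mapped, unmapped = map_features(target, templates)
        assert not unmapped
        for m in mapped:
            assert m.round_index == 1
            assert all(i == 1.0 for i in m.per_segment_identity)
            assert [(s.start, s.end, s.strand) for s in m.target_segments] == [
                (s.start, s.end, s.strand) for s in m.template.segments
            ]

    def test_rotation_wraps_origin(self, truth, templates):
        """Features crossing the origin of a rotated target still map."""
        g = truth.annotation.sequence.bases
        L = len(g)
        rot = 150  # toyA [100,400) now wraps: starts at L-50
        target = SequenceRecord("rot", "", g[rot:] + g[:rot])
        mapped, unmapped = map_features(target, templates)
        assert not unmapped
        a = next(m for m in mapped if m.template.name == "toyA")
        assert a.target_segments[0].start == (100 - rot) % L == L - 50
        assert a.target_segments[0].end == L - 50 + 300

    def test_divergence_rescued_in_round_three(self, truth, templates):
        diverged = plant_divergence(truth, 0.12, exclude_boundaries=3, rng_seed=1)
        target = SequenceRecord("div", "", diverged.bases)
        mapped, unmapped = map_features(target, templates, DEFAULT_ROUNDS)
        assert not unmapped
        assert {m.round_index for m in mapped} == {3}
        assert all(0.80 <= min(m.per_segment_identity) < 0.90 for m in mapped)

    def test_moderate_divergence_exact_boundaries(self, truth, templates):
        mutated = mutate(truth, 0.01, exclude_boundaries=3, rng_seed=8)
        target = SequenceRecord("mut", "", mutated.bases)
        mapped, unmapped = map_features(target, templates)
        assert not unmapped
        exact = sum(
            m.target_segments == m.template.segments for m in mapped
        )
        assert exact == len(mapped)

    def test_ir_duplicates_get_distinct_placements(self, truth, templates):
        mutated = mutate(truth, 0.01, exclude_boundaries=3, rng_seed=13)
        target = SequenceRecord("mut", "", mutated.bases)
        mapped, _ = map_features(target, templates)
        spots = [
            (m.target_segments[0].start, m.target_segments[0].strand)
            for m in mapped
            if m.template.name == "toyIR"
        ]
        assert len(set(spots)) == 2

    def test_thresholds_must_decrease(self, truth, templates):
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        with pytest.raises(ValueError):
            map_features(target, templates, [(0.9, 1.0), (0.95, 0.9)])

    def test_unmappable_template_reported(self, truth, templates):
        foreign = FeatureTemplate(
            key="CDS", name="toyZ", qualifiers={"gene": ["toyZ"]},
            segments=[Segment(0, 60, 1)], trans_spliced=False,
            segment_sequences=["ATGC" * 15],
        )
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        mapped, unmapped = map_features(target, [foreign])
        assert not mapped and [t.name for t in unmapped] == ["toyZ"]


class TestBuildAnnotation:
    def test_single_segment_gene_no_exons(self, truth, templates):
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        mapped, unmapped = map_features(target, templates)
        ann = build_annotation(target, mapped, unmapped)
        toya = [f for f in ann.features if f.name == "toyA"]
        assert {f.key for f in toya} == {"gene", "CDS"}

    def test_two_exon_cds_derives_exons_and_intron(self, truth, templates):
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        mapped, _ = map_features(target, templates)
        ann = build_annotation(target, mapped)
        toyb = [f for f in ann.features if f.name == "toyB" or
                (f.key in ("exon", "intron") and f.qualifiers.get("gene") == ["toyB"])]
        keys = sorted(f.key for f in toyb)
        assert keys == ["CDS", "exon", "exon", "gene", "intron"]
        exons = [f for f in toyb if f.key == "exon"]
        intron = next(f for f in toyb if f.key == "intron")
        # intron is exactly the gap between consecutive exons
        assert intron.segments[0].start == exons[0].segments[0].end
        assert intron.segments[0].end == exons[1].segments[0].start
        cds = next(f for f in toyb if f.key == "CDS")
        gene = next(f for f in toyb if f.key == "gene")
        assert gene.segments[0].start == cds.segments[0].start
        assert gene.segments[0].end == cds.segments[-1].end

    def test_trans_spliced_keeps_order_no_introns(self, truth, templates):
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        mapped, _ = map_features(target, templates)
        ann = build_annotation(target, mapped)
        r12 = [f for f in ann.features if f.name == "toyRps12" and f.key == "CDS"][0]
        assert r12.trans_spliced
        introns = [f for f in ann.features if f.key == "intron"
                   and f.qualifiers.get("gene") == ["toyRps12"]]
        assert introns == []

    def test_unmapped_absent_from_features(self, truth, templates):
        foreign = FeatureTemplate(
            key="CDS", name="toyZ", qualifiers={"gene": ["toyZ"]},
            segments=[Segment(0, 60, 1)], trans_spliced=False,
            segment_sequences=["ATGC" * 15],
        )
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        mapped, unmapped = map_features(target, templates + [foreign])
        ann = build_annotation(target, mapped, unmapped)
        assert all(f.name != "toyZ" for f in ann.features)
        assert [t.name for t in ann.unmapped] == ["toyZ"]

    def test_overlapping_segments_rejected(self, truth):
        tpl = FeatureTemplate(
            key="CDS", name="bad", qualifiers={},
            segments=[Segment(0, 30, 1), Segment(10, 40, 1)],
            trans_spliced=False, segment_sequences=["A" * 30, "A" * 30],
        )
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        m = MappedFeature(tpl, [Segment(0, 30, 1), Segment(10, 40, 1)], [1.0, 1.0], 1)
        with pytest.raises(ValueError, match="overlapping"):
            build_annotation(target, [m])


def _cds_annotation(bases, segments=None, quals=None, trans=False):
    seq = SequenceRecord("q", "", bases + "ACGT" * 10)
    segs = segments or [Segment(0, len(bases), 1)]
    f = Feature("CDS", {"gene": ["g"], **(quals or {})}, segs, trans)
    return AnnotationSet(sequence=seq, features=[f])


class TestQcInternalStops:
    def test_internal_stop_flagged(self):
        flags = qc_internal_stops(_cds_annotation("ATGTGATAA"))
        assert any("internal stop codon at codon 2" in msg for _, msg in flags)

    def test_clean_orf_unflagged(self):
        assert qc_internal_stops(_cds_annotation("ATGAAATAA")) == []

    def test_length_not_multiple_of_three(self):
        flags = qc_internal_stops(_cds_annotation("ATGAAATAAG"))
        assert any("not a multiple of 3" in msg for _, msg in flags)

    def test_missing_terminal_stop(self):
        flags = qc_internal_stops(_cds_annotation("ATGAAAAAA"))
        assert flags == [("g", "missing terminal stop codon")]

    def test_codon_start_honored(self):
        # two junk bases then a clean frame
        flags = qc_internal_stops(_cds_annotation("CCATGAAATAA", quals={"codon_start": ["3"]}))
        assert flags == []

    def test_synthetic_reference_is_clean(self, truth):
        templates = extract_reference_features(truth.annotation)
        target = SequenceRecord("t", "", truth.annotation.sequence.bases)
        mapped, _ = map_features(target, templates)
        ann = build_annotation(target, mapped)
        assert qc_internal_stops(ann) == []

    def test_planted_stop_flags_exactly_one_cds(self, truth):
        g = list(truth.annotation.sequence.bases)
        # plant TAA at codon 11 of toyA (starts at 100)
        g[130:133] = "TAA"
        target = SequenceRecord("t", "", "".join(g))
        templates = extract_reference_features(truth.annotation)
        mapped, _ = map_features(target, templates)
        ann = build_annotation(target, mapped)
        flags = qc_internal_stops(ann)
        internal = [(n, m) for n, m in flags if "internal stop" in m]
        assert len(internal) == 1 and internal[0][0] == "toyA"
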