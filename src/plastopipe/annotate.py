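"""Reference-based annotation transfer with multi-round identity thresholds.

Every gene-level feature of the reference is turned into a template whose
strand-applied segment sequences are searched against the doubled target on
both strands.  Mapping runs in rounds of decreasing identity/coverage
thresholds - features that fail a stringent round get rescued by a more
permissive one - mirroring a multi-round nucleotide-search transfer.  Gene
models are then rebuilt (gene + CDS/tRNA/rRNA + derived exon/intron
features, order() locations for trans-spliced genes) and coding features are
checked for internal stop codons under the plastid/bacterial genetic code.
"""

from __future__ import annotations

import logging

from Bio.Seq import Seq

from .align import locate
from .model import (
    AnnotationSet,
    Feature,
    FeatureTemplate,
    MappedFeature,
    ReferenceAnnotation,
    Segment,
    SequenceRecord,
    reverse_complement,
)

logger = logging.getLogger(__name__)

#: (identity, query coverage) per round, strictly decreasing identity
DEFAULT_ROUNDS: list[tuple[float, float]] = [(0.98, 1.00), (0.90, 0.95), (0.80, 0.90)]

_TEMPLATE_KEYS = ("CDS", "tRNA", "rRNA")


def extract_reference_features(ref: ReferenceAnnotation) -> list[FeatureTemplate]:
    """Build one transfer template per gene-level reference feature.

    Segment structure comes from the CDS/tRNA/rRNA location itself (so
    multi-exon and trans-spliced genes keep their pieces); minus-strand
    segment sequences are stored reverse-complemented (sense).  Duplicate
    gene copies inside the IRs yield separate templates.  A CDS without a
    parent gene is templated from itself with a warning.
    """
    bases = ref.sequence.bases
    gene_features = [f for f in ref.features if f.key == "gene"]

    def parent_gene(child: Feature) -> Feature | None:
        for g in gene_features:
            if g.name == child.name and _overlaps(g, child):
                return g
        return None

    templates: list[FeatureTemplate] = []
    claimed_genes: set[int] = set()
    for f in ref.features:
        if f.key not in _TEMPLATE_KEYS:
            continue
        gene = parent_gene(f)
        if gene is None:
            logger.warning(
                "reference %s %r has no parent gene feature; template synthesized "
                "from the %s itself", f.key, f.name, f.key,
            )
            gene_quals = {"gene": [f.name]} if f.name else {}
        else:
            claimed_genes.add(id(gene))
            gene_quals = dict(gene.qualifiers)
        seqs = [
            bases[s.start : s.end] if s.strand == 1 else reverse_complement(bases[s.start : s.end])
            for s in f.segments
        ]
        templates.append(
            FeatureTemplate(
                key=f.key,
                name=f.name,
                qualifiers=dict(f.qualifiers),
                segments=list(f.segments),
                trans_spliced=f.trans_spliced,
                segment_sequences=seqs,
                gene_qualifiers=gene_quals,
            )
        )
    # standalone genes (no CDS/tRNA/rRNA child) still transfer
    for g in gene_features:
        if id(g) not in claimed_genes:
            seqs = [
                bases[s.start : s.end] if s.strand == 1 else reverse_complement(bases[s.start : s.end])
                for s in g.segments
            ]
            templates.append(
                FeatureTemplate(
                    key="gene",
                    name=g.name,
                    qualifiers=dict(g.qualifiers),
                    segments=list(g.segments),
                    trans_spliced=g.trans_spliced,
                    segment_sequences=seqs,
                    gene_qualifiers=dict(g.qualifiers),
                )
            )
    return templates


def _overlaps(a: Feature, b: Feature) -> bool:
    return any(
        sa.start < sb.end and sb.start < sa.end for sa in a.segments for sb in b.segments
    )


def _segment_hits(
    query: str, doubled: str, rc_doubled: str, L: int, identity_min: float, coverage_min: float
) -> list[tuple[int, int, int, float, float]]:
    """All candidate placements of one segment: (start, end, strand, id, cov)."""
    max_edits = int(len(query) * (1 - identity_min) * 2) + 5
    hits: dict[tuple[int, int], tuple[int, int, int, float, float]] = {}
    for start, end, ident, cov in locate(query, doubled, max_edits):
        if ident >= identity_min and cov >= coverage_min:
            key = (start % L, 1)
            if key not in hits or ident > hits[key][3]:
                hits[key] = (start % L, start % L + (end - start), 1, ident, cov)
    for start, end, ident, cov in locate(query, rc_doubled, max_edits):
        if ident >= identity_min and cov >= coverage_min:
            fwd_start = 2 * L - end
            key = (fwd_start % L, -1)
            if key not in hits or ident > hits[key][3]:
                hits[key] = (fwd_start % L, fwd_start % L + (end - start), -1, ident, cov)
    return list(hits.values())


def _circ_dist(a: int, b: int, L: int) -> int:
    d = (a - b) % L
    return min(d, L - d)


def map_features(
    target: SequenceRecord,
    templates: list[FeatureTemplate],
    rounds: list[tuple[float, float]] | None = None,
) -> tuple[list[MappedFeature], list[FeatureTemplate]]:
    """Place reference templates on the target across decreasing-threshold rounds.

    Each segment is searched independently on both strands of the doubled
    target; a template maps in the first round where every segment clears
    that round's identity and coverage thresholds.  Competing placements are
    scored by identity x coverage, ties resolved by consistency with the
    circular shift implied by unambiguously placed templates.
    """
    if rounds is None:
        rounds = DEFAULT_ROUNDS
    if not rounds:
        raise ValueError("at least one mapping round is required")
    for (id_a, _), (id_b, _) in zip(rounds, rounds[1:]):
        if id_b >= id_a:
            raise ValueError("round identity thresholds must be strictly decreasing")

    L = len(target)
    doubled = target.bases + target.bases
    rc_doubled = reverse_complement(doubled)

    mapped: list[MappedFeature] = []
    remaining = list(templates)
    expected_shift: int | None = None

    for round_index, (identity_min, coverage_min) in enumerate(rounds, start=1):
        if not remaining:
            break
        candidates: dict[int, list[list[tuple[int, int, int, float, float]]]] = {}
        for ti, tpl in enumerate(remaining):
            per_segment = [
                _segment_hits(q, doubled, rc_doubled, L, identity_min, coverage_min)
                for q in tpl.segment_sequences
            ]
            if all(per_segment):
                candidates[ti] = per_segment
        # estimate the global circular shift from unambiguous placements
        shifts = [
            (hits[0][0] - tpl_seg.start) % L
            for ti, per_segment in candidates.items()
            for hits, tpl_seg in zip(per_segment, remaining[ti].segments)
            if len(hits) == 1
        ]
        if shifts:
            expected_shift = max(set(shifts), key=shifts.count)

        # templates with identical queries (IR-duplicated genes) compete for
        # the same placements; within such a group each copy must claim a
        # distinct placement, chosen by positional consistency
        groups: dict[tuple[str, ...], list[int]] = {}
        for ti in candidates:
            groups.setdefault(tuple(remaining[ti].segment_sequences), []).append(ti)
        claimed: dict[int, set[tuple[int, int]]] = {ti: set() for ti in candidates}
        for tis in groups.values():
            if len(tis) < 2:
                continue
            tis.sort(key=lambda ti: remaining[ti].segments[0].start)
            taken: set[tuple[int, int]] = set()
            for ti in tis:
                claimed[ti] = taken
                seg = remaining[ti].segments[0]
                hits = candidates[ti][0]
                free = [h for h in hits if (h[0], h[2]) not in taken] or hits
                if expected_shift is not None:
                    choice = min(
                        free,
                        key=lambda h: (
                            _circ_dist(h[0], (seg.start + expected_shift) % L, L),
                            -h[3] * h[4],
                        ),
                    )
                else:
                    choice = min(free, key=lambda h: (-h[3] * h[4],))
                taken = taken | {(choice[0], choice[2])}
                claimed[ti] = {(h[0], h[2]) for h in hits} - {(choice[0], choice[2])}

        still: list[FeatureTemplate] = []
        for ti, tpl in enumerate(remaining):
            if ti not in candidates:
                still.append(tpl)
                continue
            segs: list[Segment] = []
            idents: list[float] = []
            ok = True
            for seg, hits in zip(tpl.segments, candidates[ti]):
                free = [h for h in hits if (h[0], h[2]) not in claimed[ti]] or hits

                def rank(h):
                    start, _end, _strand, ident, cov = h
                    dist = (
                        _circ_dist(start, (seg.start + expected_shift) % L, L)
                        if expected_shift is not None
                        else 0
                    )
                    return (-ident * cov, dist)
                best = min(free, key=rank)
                start, end, strand, ident, _cov = best
                segs.append(Segment(start, end, strand))
                idents.append(ident)
            # strand-pattern consistency: placements must preserve the
            # template's relative strand pattern (all kept or all inverted)
            rel = {s.strand * t.strand for s, t in zip(segs, tpl.segments)}
            if len(rel) > 1:
                ok = False
            if ok:
                mapped.append(MappedFeature(tpl, segs, idents, round_index))
            else:
                still.append(tpl)
        remaining = still
    return mapped, remaining


def build_annotation(
    target: SequenceRecord,
    mapped: list[MappedFeature],
    unmapped: list[FeatureTemplate] | None = None,
) -> AnnotationSet:
    """Render mapped templates as GenBank-ready gene models.

    Per template: a gene feature spanning its segments, the CDS/tRNA/rRNA
    feature itself, and for multi-segment features one exon per segment plus
    introns in the gaps (trans-spliced features keep their order() segment
    list and derive no introns).
    """
    L = len(target)
    features: list[Feature] = []
    for m in mapped:
        tpl = m.template
        segs = m.target_segments
        for i, a in enumerate(segs):
            for b in segs[i + 1 :]:
                if a.start < b.end and b.start < a.end:
                    raise ValueError(
                        f"feature {tpl.name!r}: overlapping segments "
                        f"[{a.start},{a.end}) and [{b.start},{b.end})"
                    )
        gene_quals = dict(tpl.gene_qualifiers) or {"gene": [tpl.name]}
        if tpl.trans_spliced:
            gene_segs = list(segs)
        else:
            first = segs[0]
            span = (segs[-1].end - first.start) % L or (segs[-1].end - first.start)
            gene_segs = [Segment(first.start, first.start + span, first.strand)]
        features.append(Feature("gene", gene_quals, gene_segs, tpl.trans_spliced))
        if tpl.key != "gene":
            features.append(Feature(tpl.key, dict(tpl.qualifiers), list(segs), tpl.trans_spliced))
        if len(segs) > 1:
            exon_quals = {"gene": [tpl.name]} if tpl.name else {}
            for i, s in enumerate(segs, start=1):
                features.append(
                    Feature("exon", {**exon_quals, "number": [str(i)]}, [Segment(s.start, s.end, s.strand)])
                )
            if not tpl.trans_spliced:
                ordered = sorted(segs, key=lambda s: s.start)
                for a, b in zip(ordered, ordered[1:]):
                    if b.start > a.end:
                        features.append(
                            Feature("intron", dict(exon_quals), [Segment(a.end, b.start, a.strand)])
                        )
    features.sort(key=lambda f: (f.start, f.key != "gene", f.key))
    return AnnotationSet(
        sequence=target, features=features, unmapped=list(unmapped or []), qc_flags=[]
    )


def qc_internal_stops(annotation: AnnotationSet, translation_table: int = 11) -> list[tuple[str, str]]:
    """Flag CDS features with internal stops, frame problems or missing stops.

    The coding sequence is rebuilt by concatenating strand-applied segments
    in biological order (reverse textual order for minus-strand multi-exon
    genes; as-given order for trans-spliced genes), trimmed by codon_start,
    and translated with the plastid/bacterial code.  Flags are warnings; the
    annotation is never modified.
    """
    doubled = annotation.sequence.bases + annotation.sequence.bases
    flags: list[tuple[str, str]] = []
    for f in annotation.features:
        if f.key != "CDS":
            continue
        segs = list(f.segments)
        if not f.trans_spliced and f.strand == -1 and len(segs) > 1:
            segs = segs[::-1]
        parts = [
            doubled[s.start : s.end] if s.strand == 1 else reverse_complement(doubled[s.start : s.end])
            for s in segs
        ]
        cds = "".join(parts)
        codon_start = int(f.qualifiers.get("codon_start", ["1"])[0])
        cds = cds[codon_start - 1 :]
        if len(cds) % 3 != 0:
            flags.append((f.name, f"length {len(cds)} not a multiple of 3"))
        aa = str(Seq(cds[: len(cds) - len(cds) % 3]).translate(table=translation_table))
        internal = aa[:-1] if aa else ""
        if "*" in internal:
            flags.append((f.name, f"internal stop codon at codon {internal.index('*') + 1}"))
        if aa and not aa.endswith("*"):
            flags.append((f.name, "missing terminal stop codon"))
    annotation.qc_flags = flags
    return flags


def annotation_report(annotation: AnnotationSet, mapped: list[MappedFeature] | None = None) -> str:
    """Tab-separated transfer report: mapped features, unmapped, QC flags."""
    lines = ["#section\tname\tkey\tdetail"]
    if mapped:
        for m in mapped:
            locs = ";".join(
                f"{s.start + 1}..{s.end}({'+' if s.strand == 1 else '-'})"
                for s in m.target_segments
            )
            ident = min(m.per_segment_identity)
            lines.append(
                f"mapped\t{m.template.name}\t{m.template.key}\t"
                f"round={m.round_index},identity>={ident:.3f},{locs}"
            )
    for tpl in annotation.unmapped:
        lines.append(f"unmapped\t{tpl.name}\t{tpl.key}\tfailed all rounds")
    for name, issue in annotation.qc_flags:
        lines.append(f"qc\t{name}\tCDS\t{issue}")
    return "\n".join(lines) + "\n"
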