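"""Readers and writers for every file format the pipeline touches.

FASTA and the NCBI 5-column feature table are written by small strict
emitters so that validation errors can cite exact line numbers; GenBank flat
files go through Biopython's SeqIO, with locations converted between the
1-based inclusive GenBank convention and the package's internal 0-based
half-open convention at this boundary only.  FASTQ reading is streaming and
transparently gunzips.
"""

from __future__ import annotations

import glob
import gzip
import io
import os
import re
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord as BioSeqRecord

from .errors import AssemblyNotFound, CandidateOverflow, ConfigError, FormatError
from .model import (
    AnnotationSet,
    Feature,
    IUPAC_CODES,
    ReadPair,
    ReferenceAnnotation,
    Segment,
    SequenceRecord,
)

# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: str) -> list[SequenceRecord]:
    """Parse a FASTA file into uppercase-normalized records.

    Raises FormatError naming the offending line for empty sequences and
    non-IUPAC characters.
    """
    records: list[SequenceRecord] = []
    header: str | None = None
    header_line = 0
    parts: list[str] = []

    def _flush() -> None:
        if header is None:
            return
        bases = "".join(parts)
        if not bases:
            raise FormatError(f"{path}:{header_line}: record {header!r} has an empty sequence")
        sid, _, desc = header.partition(" ")
        records.append(SequenceRecord(sid, desc.strip(), bases))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                _flush()
                header = line[1:].strip()
                if not header:
                    raise FormatError(f"{path}:{lineno}: empty FASTA header")
                header_line = lineno
                parts = []
            else:
                if header is None:
                    raise FormatError(f"{path}:{lineno}: sequence data before any '>' header")
                chunk = line.upper()
                bad = set(chunk) - IUPAC_CODES
                if bad:
                    raise FormatError(
                        f"{path}:{lineno}: non-IUPAC characters {sorted(bad)} in record {header!r}"
                    )
                parts.append(chunk)
    _flush()
    if not records:
        raise FormatError(f"{path}: empty FASTA file")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str, width: int = 70) -> str:
    """Write records as wrapped FASTA; round-trips with read_fasta."""
    records = list(records)
    if not records:
        raise ValueError("write_fasta: no records to write")
    with open(path, "w") as fh:
        for rec in records:
            header = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{header}\n")
            for i in range(0, len(rec.bases), width):
                fh.write(rec.bases[i : i + width] + "\n")
    return path


# ---------------------------------------------------------------------------
# FASTQ


def _open_maybe_gz(path: str):
    if path.endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path)


def read_fastq_pairs(path1: str, path2: str) -> Iterator[ReadPair]:
    """Stream mate pairs from two FASTQ files (plain or gzip)."""
    with _open_maybe_gz(path1) as fh1, _open_maybe_gz(path2) as fh2:
        it1 = SeqIO.parse(fh1, "fastq")
        it2 = SeqIO.parse(fh2, "fastq")
        for r1, r2 in zip(it1, it2):
            yield ReadPair(
                id=r1.id,
                seq1=str(r1.seq).upper(),
                qual1="".join(chr(q + 33) for q in r1.letter_annotations["phred_quality"]),
                seq2=str(r2.seq).upper(),
                qual2="".join(chr(q + 33) for q in r2.letter_annotations["phred_quality"]),
            )


def write_fastq_pair(pairs: Iterable[ReadPair], path1: str, path2: str) -> None:
    with open(path1, "w") as fh1, open(path2, "w") as fh2:
        for p in pairs:
            fh1.write(f"@{p.id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            fh2.write(f"@{p.id}/2\n{p.seq2}\n+\n{p.qual2}\n")


# ---------------------------------------------------------------------------
# GenBank

_GENE_LEVEL_KEYS = {"gene", "CDS", "tRNA", "rRNA", "exon", "intron"}


def _location_to_segments(location) -> tuple[list[Segment], bool]:
    """Convert a Biopython location into textual-order segments.

    Returns (segments, trans_spliced).  GenBank writes complement(join(a,b))
    with a,b in ascending textual order; Biopython stores the parts in
    biological order, so minus-strand compound locations are flipped back to
    textual order here.  An order() operator or mixed strands mark the
    feature as trans-spliced.
    """
    parts = list(location.parts)
    operator = getattr(location, "operator", "join")
    strands = {p.strand for p in parts}
    if len(parts) > 1 and strands == {-1}:
        parts = parts[::-1]
    segments = [Segment(int(p.start), int(p.end), -1 if p.strand == -1 else 1) for p in parts]
    trans = operator == "order" or len(strands) > 1
    return segments, trans


def _segments_to_location(feature: Feature, genome_length: int | None = None):
    """Build a Biopython location from textual-order segments.

    A segment whose end exceeds the genome length wraps the origin and is
    split into a join of its two linear pieces.
    """
    parts: list[SimpleLocation] = []
    for seg in feature.segments:
        strand = seg.strand
        if genome_length is not None and seg.end > genome_length:
            parts.append(SimpleLocation(seg.start, genome_length, strand))
            parts.append(SimpleLocation(0, seg.end - genome_length, strand))
        else:
            parts.append(SimpleLocation(seg.start, seg.end, strand))
    if len(parts) == 1:
        return parts[0]
    operator = "order" if feature.trans_spliced else "join"
    strands = {p.strand for p in parts}
    if strands == {-1} and operator == "join":
        parts = parts[::-1]  # back to biological order for Biopython
    return CompoundLocation(parts, operator=operator)


def read_genbank(path: str) -> ReferenceAnnotation:
    """Parse an annotated reference plastome from a GenBank flat file."""
    try:
        record = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise FormatError(f"{path}: not a readable single-record GenBank file: {exc}") from exc
    try:
        bases = str(record.seq).upper()
    except Exception as exc:  # undefined sequence: LOCUS without ORIGIN data
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence: {exc}") from exc
    if not bases:
        raise FormatError(f"{path}: GenBank record has no ORIGIN sequence")
    features: list[Feature] = []
    for bf in record.features:
        if bf.type == "source":
            continue
        try:
            segments, trans = _location_to_segments(bf.location)
        except Exception as exc:
            raise FormatError(
                f"{path}: unparseable location for feature {bf.type}: {exc}"
            ) from exc
        quals = {k: list(v) for k, v in bf.qualifiers.items()}
        features.append(Feature(bf.type, quals, segments, trans))
    return ReferenceAnnotation(
        sequence=SequenceRecord(record.id or record.name, record.description or "", bases),
        features=features,
        organism=record.annotations.get("organism", ""),
        topology=record.annotations.get("topology", "circular"),
    )


def write_genbank(annotation: AnnotationSet, path: str) -> str:
    """Emit an AnnotationSet as a circular-DNA GenBank flat file."""
    n = len(annotation.sequence)
    for f in annotation.features:
        for s in f.segments:
            if s.start < 0 or s.end - s.start > n:
                raise ValueError(
                    f"feature {f.key}/{f.name}: segment [{s.start},{s.end}) out of bounds"
                )
    record = BioSeqRecord(
        Seq(annotation.sequence.bases),
        id=annotation.sequence.id,
        name=re.sub(r"\W", "_", annotation.sequence.id)[:16],
        description=annotation.sequence.description,
        annotations={
            "molecule_type": "DNA",
            "topology": annotation.topology,
            "organism": annotation.organism or ".",
        },
    )
    record.features = [
        SeqFeature(
            _segments_to_location(f, n),
            type=f.key,
            qualifiers={k: list(v) for k, v in f.qualifiers.items()},
        )
        for f in annotation.features
    ]
    with open(path, "w") as fh:
        SeqIO.write(record, fh, "genbank")
    return path


# ---------------------------------------------------------------------------
# NCBI 5-column feature table

_TBL_KEYS = ("gene", "CDS", "tRNA", "rRNA")
_TBL_QUALIFIER_ORDER = ("gene", "product", "codon_start", "transl_table", "note")


def write_feature_table(annotation: AnnotationSet, path: str) -> str:
    """Write the BankIt/table2asn 5-column feature table (.tbl).

    Only gene-level keys are emitted (exons/introns are implicit in the
    interval lists).  Minus-strand intervals are written start > end;
    coordinates are 1-based inclusive.
    """
    if not annotation.sequence.id:
        raise ValueError("feature table requires a sequence id")
    n = len(annotation.sequence)
    lines = [f">Feature {annotation.sequence.id}"]
    for f in annotation.features:
        if f.key not in _TBL_KEYS:
            continue
        if not f.segments:
            raise ValueError(f"feature {f.key}/{f.name}: zero segments")
        for i, seg in enumerate(f.segments):
            start, end = seg.start + 1, seg.end
            if end > n:  # wraps the origin: two intervals
                intervals = [(start, n), (1, end - n)]
            else:
                intervals = [(start, end)]
            for j, (a, b) in enumerate(intervals):
                if seg.strand == -1:
                    a, b = b, a
                if i == 0 and j == 0:
                    lines.append(f"{a}\t{b}\t{f.key}")
                else:
                    lines.append(f"{a}\t{b}")
        for qual in _TBL_QUALIFIER_ORDER:
            for val in f.qualifiers.get(qual, []):
                lines.append(f"\t\t\t{qual}\t{val}")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# External assembler (NOVOPlasty-style) adapter formats

ASSEMBLER_DEFAULTS = {
    "type": "chloro",
    "kmer": 29,
    "read_length": 151,
    "insert_size": 300,
    "platform": "illumina",
    "single_paired": "PE",
}


def write_assembler_config(sample, trimmed_read_paths: tuple[str, str], path: str) -> str:
    """Write the key = value config the external organelle assembler expects.

    ``sample`` needs ``prefix``, ``seed`` and ``size_range`` attributes;
    assembler parameters default to type chloro, k-mer 29, read length 151,
    insert size 300, paired-end.
    """
    seed = getattr(sample, "seed", None)
    size_range = getattr(sample, "size_range", None)
    if not seed:
        raise ConfigError(f"sample {getattr(sample, 'prefix', '?')}: no seed path configured")
    if not size_range or size_range[0] >= size_range[1]:
        raise ConfigError(f"sample {sample.prefix}: invalid assembly size range {size_range}")
    d = ASSEMBLER_DEFAULTS
    fwd, rev = trimmed_read_paths
    lines = [
        "Project:",
        "-----------------------",
        f"Project name          = {sample.prefix}",
        f"Type                  = {d['type']}",
        f"Genome Range          = {size_range[0]}-{size_range[1]}",
        f"K-mer                 = {d['kmer']}",
        "Max memory            = ",
        "Extended log          = 0",
        "Save assembled reads  = no",
        f"Seed Input            = {seed}",
        "Extend seed directly  = no",
        "Reference sequence    = ",
        "Variance detection    = ",
        "",
        "Dataset 1:",
        "-----------------------",
        f"Read Length           = {d['read_length']}",
        f"Insert size           = {d['insert_size']}",
        f"Platform              = {d['platform']}",
        f"Single/Paired         = {d['single_paired']}",
        f"Forward reads         = {fwd}",
        f"Reverse reads         = {rev}",
        "",
    ]
    with open(path, "w") as fh:
        fh.write("\n".join(lines))
    return path


def discover_assembler_output(directory: str, prefix: str) -> list[SequenceRecord]:
    """Find the assembler's candidate assemblies by its naming convention.

    A finished run leaves either one circularized assembly or two isomer
    candidates (Option_1 / Option_2, differing in SSC orientation); anything
    beyond two candidates aborts the sample.
    """
    if not os.path.isdir(directory):
        raise AssemblyNotFound(f"assembler output directory {directory!r} does not exist")
    circular = sorted(glob.glob(os.path.join(directory, f"Circularized_assembly_*_{prefix}.fasta")))
    options = sorted(
        glob.glob(os.path.join(directory, f"Option_*_{prefix}.fasta")),
        key=lambda p: os.path.basename(p),
    )
    paths = circular + options
    if not paths:
        raise AssemblyNotFound(f"assembly failed: no candidate assemblies under {directory!r}")
    if len(paths) > 2:
        raise CandidateOverflow(
            f"{len(paths)} candidate assemblies under {directory!r}; "
            "the assembler could not decide on an assembly (at most 2 supported)"
        )
    out = []
    for p in paths:
        rec = read_fasta(p)[0]
        out.append(rec)
    return out
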