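"""Shared domain types for the plastome toolchain.

Coordinates are 0-based half-open everywhere inside the package; the 1-based
inclusive GenBank/feature-table convention appears only in readers and
writers.  Intervals on a circular molecule are stored with ``start`` in
``[0, L)`` and ``end = start + length``; ``end`` may exceed the molecule
length, which means the interval wraps the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field


IUPAC_CODES = set("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def reverse_complement(bases: str) -> str:
    """Reverse complement over the full IUPAC nucleotide alphabet."""
    bad = set(bases.upper()) - IUPAC_CODES
    if bad:
        raise ValueError(f"non-IUPAC nucleotide characters: {sorted(bad)}")
    return bases.translate(_COMPLEMENT)[::-1]


@dataclass
class SequenceRecord:
    """One FASTA-style sequence: id, free-text description, uppercase bases."""

    id: str
    description: str
    bases: str

    def __post_init__(self) -> None:
        if not self.id or any(c.isspace() for c in self.id):
            raise ValueError(f"invalid sequence id: {self.id!r}")
        if not self.bases:
            raise ValueError(f"record {self.id!r}: empty sequence")

    def __len__(self) -> int:
        return len(self.bases)


@dataclass
class ReadPair:
    """A paired-end read: mate sequences with their quality strings."""

    id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self) -> None:
        if len(self.seq1) != len(self.qual1) or len(self.seq2) != len(self.qual2):
            raise ValueError(f"read {self.id!r}: sequence/quality length mismatch")


@dataclass
class Segment:
    """One strand-aware interval of a feature; 0-based half-open."""

    start: int
    end: int
    strand: int  # +1 or -1

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty segment [{self.start}, {self.end})")
        if self.strand not in (1, -1):
            raise ValueError(f"strand must be +1/-1, got {self.strand}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Feature:
    """A genomic feature ready for GenBank / feature-table emission."""

    key: str  # gene, CDS, tRNA, rRNA, exon, intron, ...
    qualifiers: dict[str, list[str]] = field(default_factory=dict)
    segments: list[Segment] = field(default_factory=list)
    trans_spliced: bool = False

    @property
    def name(self) -> str:
        vals = self.qualifiers.get("gene") or self.qualifiers.get("product") or [""]
        return vals[0]

    @property
    def start(self) -> int:
        return min(s.start for s in self.segments)

    @property
    def strand(self) -> int:
        return self.segments[0].strand


@dataclass
class FeatureTemplate:
    """One reference feature prepared for transfer onto a target.

    ``segments`` follow the reference coordinate system; ``segment_sequences``
    hold the strand-applied (sense) nucleotide string of each segment, i.e.
    minus-strand segments are stored reverse-complemented.
    """

    key: str
    name: str
    qualifiers: dict[str, list[str]]
    segments: list[Segment]
    trans_spliced: bool
    segment_sequences: list[str]
    gene_qualifiers: dict[str, list[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError(f"template {self.name!r}: no segments")
        if len(self.segments) != len(self.segment_sequences):
            raise ValueError(f"template {self.name!r}: segment/sequence count mismatch")
        for seg, seq in zip(self.segments, self.segment_sequences):
            if len(seg) != len(seq):
                raise ValueError(
                    f"template {self.name!r}: segment length {len(seg)} != "
                    f"sequence length {len(seq)}"
                )


@dataclass
class MappedFeature:
    """A template placed on the target, with per-segment identities."""

    template: FeatureTemplate
    target_segments: list[Segment]
    per_segment_identity: list[float]
    round_index: int


@dataclass
class ReferenceAnnotation:
    """A parsed reference GenBank record: sequence plus raw features."""

    sequence: SequenceRecord
    features: list[Feature]
    organism: str = ""
    topology: str = "circular"

    def __post_init__(self) -> None:
        n = len(self.sequence)
        for f in self.features:
            for s in f.segments:
                if s.start < 0 or s.end > n:
                    raise ValueError(
                        f"feature {f.key}/{f.name}: segment [{s.start},{s.end}) "
                        f"outside sequence of length {n}"
                    )


@dataclass
class AnnotationSet:
    """A target sequence with its transferred features, ready for emission."""

    sequence: SequenceRecord
    features: list[Feature]
    unmapped: list[FeatureTemplate] = field(default_factory=list)
    qc_flags: list[tuple[str, str]] = field(default_factory=list)
    topology: str = "circular"
    organism: str = ""


@dataclass
class CircularSequence:
    """A circular nucleotide molecule (a plastome assembly candidate)."""

    id: str
    bases: str
    circular: bool = True

    def __len__(self) -> int:
        return len(self.bases)

    def fragment(self, start: int, end: int) -> str:
        """Extract [start, end) with wraparound; end may exceed length."""
        n = len(self.bases)
        start %= n
        end = start + (end - start)
        if end <= n:
            return self.bases[start:end]
        return (self.bases + self.bases)[start:end]

    def rotated(self, offset: int) -> "CircularSequence":
        n = len(self.bases)
        offset %= n
        return CircularSequence(self.id, self.bases[offset:] + self.bases[:offset])


@dataclass
class Region:
    """One of the four plastome regions on the circle."""

    name: str  # LSC / IRb / SSC / IRa
    start: int
    end: int  # may exceed genome length (wraps the origin)

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class RepeatPair:
    """An inverted repeat: two non-overlapping copies on the circle."""

    copy_a: tuple[int, int]
    copy_b: tuple[int, int]
    identity: float
    orientation: str = "inverted"

    @property
    def length(self) -> int:
        return self.copy_a[1] - self.copy_a[0]


@dataclass
class PlastomeStructure:
    """The quadripartite LSC-IRb-SSC-IRa partition of a plastome."""

    lsc: Region
    irb: Region
    ssc: Region
    ira: Region
    genome_length: int

    def regions(self) -> list[Region]:
        return [self.lsc, self.irb, self.ssc, self.ira]


@dataclass
class StandardizedAssembly:
    """A canonical LSC-IRb-SSC-IRa linearization with its provenance."""

    sequence: SequenceRecord
    structure: PlastomeStructure
    candidate_index: int = 0
    rotation_offset: int = 0
    flipped: bool = False
    ssc_flipped: bool = False
    corrected_positions: list[int] = field(default_factory=list)
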