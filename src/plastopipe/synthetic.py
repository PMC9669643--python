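"""Ground-truthed synthetic plastomes for desk-scale testing.

The generator emits a circular genome assembled in canonical order
LSC-IRb-SSC-IRa with a planted gene set addressable by name:

* ``toyA``     - single-exon CDS, plus strand, in the LSC
* ``toyB``     - two-exon CDS (with intron), plus strand, in the LSC
* ``toyRps12`` - trans-spliced two-segment CDS, 5' segment in the LSC and
  3' segment on the minus strand of the SSC (an order() location, the way
  plastid rps12 is annotated)
* ``toyTrn``   - tRNA on the minus strand of the LSC
* ``toyIR``    - rRNA planted inside IRb; its mirror copy in IRa is
  annotated as a separate minus-strand feature

The flanking bases of both single-copy regions are pinned so that the
planted IR pair is maximal (it cannot be extended by a chance complementary
base), which makes exact boundary recovery a well-posed expectation.  Every
operation is a pure function of its arguments including the RNG seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .model import (
    CircularSequence,
    Feature,
    PlastomeStructure,
    ReadPair,
    ReferenceAnnotation,
    Region,
    Segment,
    SequenceRecord,
    reverse_complement,
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_SENSE_CODONS = [
    a + b + c
    for a in _BASES
    for b in _BASES
    for c in _BASES
    if a + b + c not in _STOPS and a + b + c != "ATG"
]

MIN_LSC = 1300
MIN_IR = 250
MIN_SSC = 250


@dataclass
class SyntheticTruth:
    """A synthetic plastome with its planted structure and annotation."""

    genome: CircularSequence
    structure: PlastomeStructure
    annotation: ReferenceAnnotation
    rng_seed: int
    rotation: int = 0
    flipped: bool = False
    ssc_flipped: bool = False
    mutations: list[tuple[int, str, str]] = field(default_factory=list)
    ambiguous: list[tuple[int, str]] = field(default_factory=list)


def _random_bases(rng: random.Random, n: int) -> list[str]:
    return [rng.choice(_BASES) for _ in range(n)]


def _clean_orf(rng: random.Random, length: int) -> str:
    """A stop-free open reading frame of ``length`` bases (ATG ... stop)."""
    assert length % 3 == 0 and length >= 9
    codons = ["ATG"] + [rng.choice(_SENSE_CODONS) for _ in range(length // 3 - 2)] + ["TAA"]
    return "".join(codons)


def generate_plastome(
    lsc_len: int = 2000, ir_len: int = 400, ssc_len: int = 600, rng_seed: int = 0
) -> SyntheticTruth:
    """Generate a canonical synthetic plastome with the planted gene set."""
    if lsc_len < MIN_LSC or ir_len < MIN_IR or ssc_len < MIN_SSC:
        raise ValueError(
            f"region lengths too small to host the planted gene set "
            f"(need LSC>={MIN_LSC}, IR>={MIN_IR}, SSC>={MIN_SSC})"
        )
    rng = random.Random(("plastome", rng_seed, lsc_len, ir_len, ssc_len).__repr__())
    lsc = _random_bases(rng, lsc_len)
    ir = _random_bases(rng, ir_len)
    ssc = _random_bases(rng, ssc_len)
    # pin single-copy edge bases so the IR pair cannot extend by chance:
    # outward extension pairs LSC[-1-t] with comp(LSC[t]) and SSC[t] with
    # comp(SSC[-1-t]), so four all-'A' bases on each edge give four
    # guaranteed mismatches in a row - enough to stop even mismatch-tolerant
    # extension, keeping the planted IR maximal
    lsc[0:4] = lsc[-4:] = ["A"] * 4
    ssc[0:4] = ssc[-4:] = ["A"] * 4

    features: list[Feature] = []

    def plant(region: list[str], offset: int, coding: str) -> None:
        region[offset : offset + len(coding)] = list(coding)

    def add(name: str, key: str, segs: list[Segment], trans: bool = False, **quals) -> None:
        q = {"gene": [name], **{k: [str(v)] for k, v in quals.items()}}
        gene_segs = segs if trans else [Segment(min(s.start for s in segs),
                                                max(s.end for s in segs), segs[0].strand)]
        features.append(Feature("gene", {"gene": [name]}, gene_segs, trans))
        features.append(Feature(key, q, segs, trans))

    # toyA: single-exon CDS in the LSC
    orf_a = _clean_orf(rng, 300)
    plant(lsc, 100, orf_a)
    add("toyA", "CDS", [Segment(100, 400, 1)], product="toyA protein",
        codon_start=1, transl_table=11)

    # toyB: two-exon CDS (99 + 102 coding bases, 80 bp intron)
    orf_b = _clean_orf(rng, 201)
    plant(lsc, 500, orf_b[:99])
    plant(lsc, 679, orf_b[99:])
    add("toyB", "CDS", [Segment(500, 599, 1), Segment(679, 781, 1)],
        product="toyB protein", codon_start=1, transl_table=11)

    # toyTrn: tRNA on the minus strand (annotates the bases in place)
    add("toyTrn", "tRNA", [Segment(900, 972, -1)], product="tRNA-Toy")

    # toyRps12: trans-spliced CDS, 5' segment in the LSC (+), 3' segment in
    # the SSC (-); genome holds the reverse complement of the 3' coding part
    orf_r = _clean_orf(rng, 174)
    plant(lsc, 1100, orf_r[:60])
    ssc_off = 100
    ssc_seg_start = lsc_len + ir_len + ssc_off
    plant(ssc, ssc_off, reverse_complement(orf_r[60:]))
    add(
        "toyRps12",
        "CDS",
        [Segment(1100, 1160, 1), Segment(ssc_seg_start, ssc_seg_start + 114, -1)],
        trans=True,
        product="toyRps12 protein",
        codon_start=1,
        transl_table=11,
    )

    # toyIR: rRNA inside IRb; the IRa mirror copy becomes its own feature
    rr = "".join(_random_bases(rng, 150))
    ir_off = 50
    plant(ir, ir_off, rr)
    irb_start = lsc_len
    ira_start = lsc_len + ir_len + ssc_len
    b_lo = irb_start + ir_off
    add("toyIR", "rRNA", [Segment(b_lo, b_lo + 150, 1)], product="toyIR ribosomal RNA")
    a_lo = ira_start + (ir_len - ir_off - 150)
    add("toyIR", "rRNA", [Segment(a_lo, a_lo + 150, -1)], product="toyIR ribosomal RNA")

    genome = "".join(lsc) + "".join(ir) + "".join(ssc) + reverse_complement("".join(ir))
    L = len(genome)
    structure = PlastomeStructure(
        lsc=Region("LSC", 0, lsc_len),
        irb=Region("IRb", lsc_len, lsc_len + ir_len),
        ssc=Region("SSC", lsc_len + ir_len, lsc_len + ir_len + ssc_len),
        ira=Region("IRa", lsc_len + ir_len + ssc_len, L),
        genome_length=L,
    )
    features.sort(key=lambda f: (f.start, f.key != "gene"))
    seq = SequenceRecord(f"synth{rng_seed}", "synthetic plastome", genome)
    annotation = ReferenceAnnotation(seq, features, organism="Toyplantus syntheticus")
    return SyntheticTruth(
        genome=CircularSequence(seq.id, genome),
        structure=structure,
        annotation=annotation,
        rng_seed=rng_seed,
    )


def _flip_interval(bases: str, start: int, length: int) -> str:
    """Reverse-complement [start, start+length) in place on the circle."""
    L = len(bases)
    start %= L
    if start + length <= L:
        return bases[:start] + reverse_complement(bases[start : start + length]) + bases[start + length :]
    rot = bases[start:] + bases[:start]
    rot = reverse_complement(rot[:length]) + rot[length:]
    return rot[L - start :] + rot[: L - start]


def transform(
    truth: SyntheticTruth, rotation: int = 0, flip: bool = False, ssc_flip: bool = False
) -> CircularSequence:
    """Produce an isomer of the canonical genome.

    Applies a rotation, then an optional whole-molecule reverse complement,
    then an optional in-place reverse complement of the SSC (the flip-flop
    isomer).  The transformation is recorded on the truth object.
    """
    bases = truth.genome.bases
    L = len(bases)
    rotation %= L
    bases = bases[rotation:] + bases[:rotation]
    ssc_start = (truth.structure.ssc.start - rotation) % L
    ssc_len = len(truth.structure.ssc)
    if flip:
        bases = reverse_complement(bases)
        ssc_start = (L - (ssc_start + ssc_len)) % L
    if ssc_flip:
        bases = _flip_interval(bases, ssc_start, ssc_len)
    truth.rotation, truth.flipped, truth.ssc_flipped = rotation, flip, ssc_flip
    return CircularSequence(truth.genome.id, bases)


def mutate(
    truth: SyntheticTruth,
    rate: float,
    exclude_boundaries: int = 0,
    rng_seed: int = 0,
    interval: tuple[int, int] | None = None,
) -> CircularSequence:
    """Bernoulli point substitutions, skipping feature-segment boundary windows.

    ``interval`` restricts mutation to one region of the circle (e.g. a
    single IR copy).  Mutated positions are recorded on the truth object.
    """
    if not 0 <= rate < 0.25:
        raise ValueError("mutation rate must be in [0, 0.25)")
    rng = random.Random(("mutate", rng_seed, rate).__repr__())
    bases = list(truth.genome.bases)
    L = len(bases)
    protected = set()
    for f in truth.annotation.features:
        for s in f.segments:
            for edge in (s.start, s.end):
                for d in range(-exclude_boundaries, exclude_boundaries):
                    protected.add((edge + d) % L)
    if interval is not None:
        a, b = interval
        eligible = [(a + t) % L for t in range(b - a)]
    else:
        eligible = range(L)
    truth.mutations = []
    for p in eligible:
        if p in protected:
            continue
        if rng.random() < rate:
            old = bases[p]
            new = rng.choice([c for c in _BASES if c != old])
            bases[p] = new
            truth.mutations.append((p, old, new))
    return CircularSequence(truth.genome.id, "".join(bases))


def plant_divergence(
    truth: SyntheticTruth, fraction: float, exclude_boundaries: int = 3, rng_seed: int = 0
) -> CircularSequence:
    """Substitute an exact fraction of each feature segment's interior bases.

    Used to build fixtures whose per-segment divergence is the stated
    fraction rather than a Bernoulli sample of it.
    """
    rng = random.Random(("diverge", rng_seed, fraction).__repr__())
    bases = list(truth.genome.bases)
    truth.mutations = []
    done = set()
    for f in truth.annotation.features:
        if f.key == "gene":
            continue
        for s in f.segments:
            span = (s.start, s.end)
            if span in done:
                continue
            done.add(span)
            interior = list(range(s.start + exclude_boundaries, s.end - exclude_boundaries))
            n_sub = round(fraction * len(s))
            for p in rng.sample(interior, min(n_sub, len(interior))):
                old = bases[p]
                new = rng.choice([c for c in _BASES if c != old])
                bases[p] = new
                truth.mutations.append((p, old, new))
    return CircularSequence(truth.genome.id, "".join(bases))


def inject_ambiguity(
    seq: CircularSequence | SequenceRecord, n_positions: int, rng_seed: int = 0
) -> tuple[CircularSequence, list[tuple[int, str]]]:
    """Replace n random distinct positions with 'N', recording the originals."""
    bases = list(seq.bases)
    if n_positions >= len(bases) / 100:
        raise ValueError("too many ambiguous positions (limit: 1% of genome)")
    rng = random.Random(("ambig", rng_seed, n_positions).__repr__())
    record: list[tuple[int, str]] = []
    for p in sorted(rng.sample(range(len(bases)), n_positions)):
        record.append((p, bases[p]))
        bases[p] = "N"
    return CircularSequence(seq.id, "".join(bases)), record


def simulate_reads(
    genome: CircularSequence,
    coverage: float = 30.0,
    read_len: int = 100,
    insert: int = 300,
    error_rate: float = 0.0,
    rng_seed: int = 0,
) -> list[ReadPair]:
    """Simulate paired-end reads from uniform circular fragments.

    Fragments wrap the origin; mate 2 is the reverse complement of the
    fragment's far end.  Read count is ceil(coverage x length / (2 x
    read_len)); substitution errors only; uniform qualities.
    """
    L = len(genome)
    if not read_len < insert < L:
        raise ValueError("need read_len < insert < genome length")
    rng = random.Random(("reads", rng_seed, coverage, read_len, insert, error_rate).__repr__())
    doubled = genome.bases + genome.bases
    n_pairs = math.ceil(coverage * L / (2 * read_len))
    qual = "I" * read_len

    def with_errors(s: str) -> str:
        if error_rate <= 0:
            return s
        out = list(s)
        for i in range(len(out)):
            if rng.random() < error_rate:
                out[i] = rng.choice([c for c in _BASES if c != out[i]])
        return "".join(out)

    pairs = []
    for i in range(n_pairs):
        start = rng.randrange(L)
        frag = doubled[start : start + insert]
        r1 = with_errors(frag[:read_len])
        r2 = with_errors(reverse_complement(frag[-read_len:]))
        pairs.append(ReadPair(f"sim{i}", r1, qual, r2, qual))
    return pairs


def truth_report(truth: SyntheticTruth) -> str:
    """Tab-separated ground-truth listing (regions, features, transforms)."""
    lines = ["#type\tname\tstart\tend\tstrand\textra"]
    for r in truth.structure.regions():
        lines.append(f"region\t{r.name}\t{r.start}\t{r.end}\t+\t")
    for f in truth.annotation.features:
        for s in f.segments:
            strand = "+" if s.strand == 1 else "-"
            lines.append(f"feature\t{f.name}\t{s.start}\t{s.end}\t{strand}\t{f.key}")
    lines.append(
        f"transform\t-\t{truth.rotation}\t-\t-\t"
        f"flip={truth.flipped},ssc_flip={truth.ssc_flipped}"
    )
    for p, old in truth.ambiguous:
        lines.append(f"ambiguous\t-\t{p}\t-\t-\ttrue={old}")
    for p, old, new in truth.mutations:
        lines.append(f"mutation\t-\t{p}\t-\t-\t{old}>{new}")
    return "\n".join(lines) + "\n"
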