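"""Canonical orientation of plastome assemblies and ambiguous-base repair.

An assembler can hand back a circular plastome starting anywhere, on either
strand, and in either flip-flop isomer (the two SSC orientations).  This
module rotates/flips a structure-resolved candidate into the canonical
LSC-IRb-SSC-IRa linearization oriented against a reference, selects between
two assembler isomer candidates by SSC orientation, and repairs non-ACGT
positions by majority vote of k-mer-anchored reads.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .align import global_identity
from .errors import NoQuadripartite
from .model import (
    CircularSequence,
    PlastomeStructure,
    ReadPair,
    ReferenceAnnotation,
    Region,
    SequenceRecord,
    StandardizedAssembly,
    reverse_complement,
)
from .structure import find_inverted_repeats, resolve_quadripartite

_ACGT = set("ACGT")


@dataclass
class CandidateSet:
    """The 1-2 isomer candidates an assembler run produced."""

    candidates: list[CircularSequence]
    source: str = "assembler-output"

    def __post_init__(self) -> None:
        if not 1 <= len(self.candidates) <= 2:
            raise ValueError(f"expected 1-2 candidates, got {len(self.candidates)}")


def _reference_structure(
    reference: ReferenceAnnotation, **detect_kwargs
) -> tuple[CircularSequence, PlastomeStructure]:
    ref_seq = CircularSequence(reference.sequence.id, reference.sequence.bases)
    repeats = find_inverted_repeats(ref_seq, **detect_kwargs)
    return ref_seq, resolve_quadripartite(ref_seq, repeats)


def _orient_to_lsc(
    seq: CircularSequence, structure: PlastomeStructure, ref_lsc: str
) -> tuple[str, int, bool, tuple[int, int, int]]:
    """Rotate (and possibly flip) so the string starts at LSC base 1.

    Returns (bases, rotation_offset, flipped, (lsc_len, ir_len, ssc_len)).
    Of the two strand choices the one whose LSC aligns better to the
    reference LSC wins; ties keep the forward strand.
    """
    L = len(seq)
    llen, n, slen = len(structure.lsc), len(structure.irb), len(structure.ssc)
    fwd_off = structure.lsc.start % L
    fwd = seq.bases[fwd_off:] + seq.bases[:fwd_off]
    rev_all = reverse_complement(seq.bases)
    rev_off = (L - (structure.lsc.end % L)) % L
    rev = rev_all[rev_off:] + rev_all[:rev_off]
    id_fwd = global_identity(fwd[:llen], ref_lsc)
    id_rev = global_identity(rev[:llen], ref_lsc)
    if id_fwd >= id_rev:
        return fwd, fwd_off, False, (llen, n, slen)
    return rev, rev_off, True, (llen, n, slen)


def canonicalize(
    seq: CircularSequence,
    structure: PlastomeStructure,
    reference: ReferenceAnnotation,
    reference_structure: PlastomeStructure | None = None,
    **detect_kwargs,
) -> StandardizedAssembly:
    """Standardize a structure-resolved assembly to LSC-IRb-SSC-IRa.

    The molecule is rotated (and reverse-complemented if the opposite strand
    matches the reference LSC better) to begin at LSC base 1; the SSC is then
    flipped in place if its reverse complement matches the reference SSC
    better.  Provenance records every transformation applied.
    """
    if reference_structure is None:
        ref_seq, reference_structure = _reference_structure(reference, **detect_kwargs)
    else:
        ref_seq = CircularSequence(reference.sequence.id, reference.sequence.bases)
    ref_lsc = ref_seq.fragment(reference_structure.lsc.start, reference_structure.lsc.end)
    ref_ssc = ref_seq.fragment(reference_structure.ssc.start, reference_structure.ssc.end)

    bases, offset, flipped, (llen, n, slen) = _orient_to_lsc(seq, structure, ref_lsc)
    ssc = bases[llen + n : llen + n + slen]
    ssc_flipped = global_identity(reverse_complement(ssc), ref_ssc) > global_identity(ssc, ref_ssc)
    if ssc_flipped:
        bases = bases[: llen + n] + reverse_complement(ssc) + bases[llen + n + slen :]

    L = len(bases)
    out_structure = PlastomeStructure(
        lsc=Region("LSC", 0, llen),
        irb=Region("IRb", llen, llen + n),
        ssc=Region("SSC", llen + n, llen + n + slen),
        ira=Region("IRa", llen + n + slen, L),
        genome_length=L,
    )
    return StandardizedAssembly(
        sequence=SequenceRecord(seq.id, "standardized LSC-IRb-SSC-IRa", bases),
        structure=out_structure,
        rotation_offset=offset,
        flipped=flipped,
        ssc_flipped=ssc_flipped,
    )


def select_candidate(
    candidates: CandidateSet | list[CircularSequence],
    reference: ReferenceAnnotation,
    reference_structure: PlastomeStructure | None = None,
    **detect_kwargs,
) -> CircularSequence:
    """Pick the assembler candidate whose SSC orientation matches the reference.

    Each candidate is structure-resolved and strand-oriented by its LSC; the
    candidate whose native (unflipped) SSC has the higher forward identity to
    the reference SSC is returned.  A single candidate is returned unchanged.
    """
    cands = candidates.candidates if isinstance(candidates, CandidateSet) else list(candidates)
    if len(cands) == 1:
        return cands[0]
    if reference_structure is None:
        ref_seq, reference_structure = _reference_structure(reference, **detect_kwargs)
    else:
        ref_seq = CircularSequence(reference.sequence.id, reference.sequence.bases)
    ref_lsc = ref_seq.fragment(reference_structure.lsc.start, reference_structure.lsc.end)
    ref_ssc = ref_seq.fragment(reference_structure.ssc.start, reference_structure.ssc.end)

    scores: list[float] = []
    failures: list[str] = []
    for cand in cands:
        try:
            repeats = find_inverted_repeats(cand, **detect_kwargs)
            st = resolve_quadripartite(cand, repeats)
        except NoQuadripartite as exc:
            failures.append(str(exc))
            scores.append(-1.0)
            continue
        bases, _, _, (llen, n, slen) = _orient_to_lsc(cand, st, ref_lsc)
        ssc = bases[llen + n : llen + n + slen]
        scores.append(global_identity(ssc, ref_ssc))
    if max(scores) < 0:
        raise NoQuadripartite(
            "no candidate has a resolvable quadripartite structure: " + "; ".join(failures)
        )
    return cands[scores.index(max(scores))]


# ---------------------------------------------------------------------------
# Ambiguous-base correction


@dataclass
class CorrectionEntry:
    position: int
    original: str
    votes: dict[str, int] = field(default_factory=dict)
    action: str = "unchanged"
    new_base: str = ""
    note: str = ""


def correct_ambiguous(
    seq: SequenceRecord,
    reads: Iterable[ReadPair],
    k: int = 21,
    min_depth: int = 5,
    min_majority: float = 0.7,
    max_anchor_offset: int = 30,
) -> tuple[SequenceRecord, list[CorrectionEntry]]:
    """Resolve non-ACGT positions by majority vote of anchored reads.

    For each ambiguous position the nearest clean k-mer on each side (within
    ``max_anchor_offset`` bases) anchors reads by exact k-mer match on either
    strand; the bases those reads place at the position are pooled, and the
    position is rewritten when depth >= min_depth and the modal base reaches
    min_majority.  Already-unambiguous positions are never touched.
    """
    bases = list(seq.bases)
    L = len(bases)
    ambiguous = [p for p, b in enumerate(bases) if b not in _ACGT]
    entries = {p: CorrectionEntry(p, bases[p]) for p in ambiguous}
    if not ambiguous:
        return seq, []

    doubled = "".join(bases) + "".join(bases)

    def clean(w: int) -> bool:
        return all(c in _ACGT for c in doubled[w : w + k])

    # anchor windows: k-mer -> list of (position voted on, delta into window)
    anchors: dict[str, list[tuple[int, int]]] = {}
    for p in ambiguous:
        placed = False
        for off in range(max_anchor_offset + 1):
            w = p - k - off  # left flank, possibly wrapping below zero
            if clean(w % L):
                window = doubled[w % L : w % L + k]
                anchors.setdefault(window, []).append((p, p - w))
                placed = True
                break
        for off in range(max_anchor_offset + 1):
            w = p + 1 + off
            if clean(w % L):
                window = doubled[w % L : w % L + k]
                anchors.setdefault(window, []).append((p, p - w))
                placed = True
                break
        if not placed:
            entries[p].note = "no clean anchor window"

    # one vote per read strand per position; conflicting votes are dropped
    votes: dict[int, dict[tuple[int, int, int], str]] = {p: {} for p in ambiguous}
    for ridx, pair in enumerate(reads):
        for midx, mate in enumerate((pair.seq1, pair.seq2)):
            for oidx, oriented in enumerate((mate, reverse_complement(mate))):
                for q in range(len(oriented) - k + 1):
                    hits = anchors.get(oriented[q : q + k])
                    if not hits:
                        continue
                    for p, delta in hits:
                        vi = q + delta
                        if not 0 <= vi < len(oriented):
                            continue
                        base = oriented[vi]
                        if base not in _ACGT:
                            continue
                        key = (ridx, midx, oidx)
                        prev = votes[p].get(key)
                        if prev is not None and prev != base:
                            votes[p][key] = "-"  # internal conflict: discard
                        elif prev is None:
                            votes[p][key] = base

    for p in ambiguous:
        tally: dict[str, int] = {}
        for base in votes[p].values():
            if base in _ACGT:
                tally[base] = tally.get(base, 0) + 1
        entry = entries[p]
        entry.votes = dict(sorted(tally.items(), key=lambda kv: -kv[1]))
        depth = sum(tally.values())
        if depth < min_depth:
            entry.action = "unchanged"
            entry.note = entry.note or f"depth {depth} < {min_depth}"
            continue
        modal, count = max(tally.items(), key=lambda kv: kv[1])
        if count / depth >= min_majority:
            bases[p] = modal
            entry.action = "corrected"
            entry.new_base = modal
        else:
            entry.action = "unchanged"
            entry.note = f"majority {count}/{depth} below {min_majority}"

    corrected = SequenceRecord(seq.id, seq.description, "".join(bases))
    return corrected, [entries[p] for p in ambiguous]


def correction_report(entries: list[CorrectionEntry]) -> str:
    """Tab-separated correction report (position 1-based, votes, action)."""
    lines = ["#position\toriginal\tvotes\taction\tnew_base\tnote"]
    for e in entries:
        votes = ",".join(f"{b}:{c}" for b, c in e.votes.items()) or "-"
        lines.append(
            f"{e.position + 1}\t{e.original}\t{votes}\t{e.action}\t{e.new_base or '-'}\t{e.note or '-'}"
        )
    return "\n".join(lines) + "\n"
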