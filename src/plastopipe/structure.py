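"""Inverted-repeat detection and quadripartite-structure resolution.

A plastome is a circular molecule whose two inverted-repeat copies (IRa,
IRb) separate a large and a small single-copy region (LSC, SSC).  The
detector is a seed-and-extend self-comparison: k-mers of the reverse
complement are indexed against the forward strand, seed hits are extended
without gaps, and the resulting maximal inverted pairs define the IRs.  All
searches run on circular coordinates (the sequence conceptually doubled), so
repeats wrapping the origin are found like any other.
"""

from __future__ import annotations

from .align import global_identity
from .errors import AmbiguousStructure, NoQuadripartite
from .model import (
    CircularSequence,
    PlastomeStructure,
    ReferenceAnnotation,
    Region,
    RepeatPair,
    reverse_complement,
)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

# extension scoring: mismatches are penalized hard so extension stops near
# the true repeat boundary instead of coasting on the repeat's interior
# identity surplus; ends are trimmed to the outermost maximum-score point,
# so an isolated substitution right at a repeat end costs at most the
# mismatch itself, never the matching bases beyond it
_MATCH = 1
_MISMATCH = -2
_XDROP = 8


def find_inverted_repeats(
    seq: CircularSequence | str,
    min_length: int = 1000,
    min_identity: float = 0.99,
    k: int | None = None,
) -> list[RepeatPair]:
    """Find maximal inverted repeat pairs on a circular sequence.

    Pairs whose copies overlap on the circle (palindromic self-hits) are
    discarded.  Results are sorted by length descending.  With
    ``min_identity`` of 1.0 extension is exact, which makes the result
    directly comparable to exhaustive substring-pair enumeration.
    """
    bases = (seq.bases if isinstance(seq, CircularSequence) else seq).upper()
    L = len(bases)
    if k is None:
        k = min(17, max(4, min_length))
    if L < 2 * k:
        return []
    doubled = bases + bases

    index: dict[str, list[int]] = {}
    for i in range(L):
        index.setdefault(doubled[i : i + k], []).append(i)

    def cget(p: int) -> str:
        return bases[p % L]

    def comp(b: str) -> str:
        return _COMP.get(b, "?")  # ambiguity codes never match anything

    exact = min_identity >= 1.0
    pairs: list[tuple[int, int, int]] = []  # (start_a, start_b, length) in seed space

    def covered(i: int, j: int) -> bool:
        c = (i + j + k) % L
        for sa, sb, n in pairs:
            if (sa + sb + n) % L == c:
                if (i - sa) % L <= n - k and (j - sb) % L <= n - k:
                    return True
                if (j - sa) % L <= n - k and (i - sb) % L <= n - k:
                    return True
        return False

    def extend(i: int, j: int) -> tuple[int, int, int]:
        """Gapless two-sided extension of the seed pair ([i,i+k), [j,j+k))."""
        ia, jb, n = i, j, k
        # headroom before the two copies would collide on the circle
        gap_r = (jb - (ia + n)) % L
        gap_l = L - n - gap_r - n
        if gap_l < 0:
            gap_l = 0
        # direction 1: copy_a grows right, copy_b grows left
        best, score, best_ext = 0, 0, 0
        for t in range(1, gap_r):
            a, b = cget(ia + n - 1 + t), cget(jb - t)
            if exact and a != comp(b):
                break
            score += _MATCH if a == comp(b) else _MISMATCH
            if score >= best:
                best, best_ext = score, t
            elif score < best - _XDROP:
                break
            if exact:
                best_ext = t
        ia2, jb2, n2 = ia, jb - best_ext, n + best_ext
        # direction 2: copy_a grows left, copy_b grows right
        gap_l = (ia2 - (jb2 + n2)) % L
        best, score, best_ext = 0, 0, 0
        for t in range(1, gap_l):
            a, b = cget(ia2 - t), cget(jb2 + n2 - 1 + t)
            if exact and a != comp(b):
                break
            score += _MATCH if a == comp(b) else _MISMATCH
            if score >= best:
                best, best_ext = score, t
            elif score < best - _XDROP:
                break
            if exact:
                best_ext = t
        return ia2 - best_ext, jb2, n2 + best_ext

    for j in range(L):
        window = reverse_complement(doubled[j : j + k])
        for i in index.get(window, ()):
            if i == j:
                continue  # a k-mer that is its own reverse complement
            if covered(i, j):
                continue
            ia, jb, n = extend(i, j)
            sa, sb = ia % L, jb % L
            if n > L // 2:
                continue
            # palindromic / overlapping copies are not a repeat pair
            if (sb - sa) % L < n or (sa - sb) % L < n:
                continue
            pairs.append((sa, sb, n))

    out: list[RepeatPair] = []
    seen: set[tuple[int, int, int]] = set()
    for sa, sb, n in pairs:
        lo, hi = (sa, sb) if sa <= sb else (sb, sa)
        if (lo, hi, n) in seen:
            continue
        seen.add((lo, hi, n))
        if n < min_length:
            continue
        frag_a = (doubled + doubled)[lo : lo + n]
        frag_b = (doubled + doubled)[hi : hi + n]
        matches = sum(1 for x, y in zip(frag_a, reverse_complement(frag_b)) if x == y)
        identity = matches / n
        if identity < min_identity:
            continue
        out.append(RepeatPair((lo, lo + n), (hi, hi + n), identity))
    # containment: drop pairs both of whose copies sit inside a longer pair
    out.sort(key=lambda p: (-p.length, p.copy_a[0], p.copy_b[0]))
    kept: list[RepeatPair] = []
    for p in out:
        contained = any(_pair_contains(q, p, L) for q in kept)
        if not contained:
            kept.append(p)
    return kept


def _interval_contains(big: tuple[int, int], small: tuple[int, int], L: int) -> bool:
    return (small[0] - big[0]) % L + (small[1] - small[0]) <= big[1] - big[0]


def _pair_contains(big: RepeatPair, small: RepeatPair, L: int) -> bool:
    return (
        _interval_contains(big.copy_a, small.copy_a, L)
        and _interval_contains(big.copy_b, small.copy_b, L)
    ) or (
        _interval_contains(big.copy_b, small.copy_a, L)
        and _interval_contains(big.copy_a, small.copy_b, L)
    )


def resolve_quadripartite(
    seq: CircularSequence,
    repeats: list[RepeatPair],
    reference: ReferenceAnnotation | None = None,
    reference_structure: PlastomeStructure | None = None,
    **ref_detect_kwargs,
) -> PlastomeStructure:
    """Resolve LSC, IRb, SSC and IRa from the longest inverted repeat pair.

    The longest pair defines the IRs; the longer arc between the copies is
    the LSC and the shorter the SSC.  IRb is the IR copy immediately
    clockwise of the LSC.  When the two arcs tie in length the arc with the
    higher alignment identity to the reference LSC wins; without a reference
    the tie raises AmbiguousStructure.
    """
    if not repeats:
        raise NoQuadripartite(f"{seq.id}: no inverted repeat pair found")
    ir = repeats[0]
    L = len(seq)
    n = ir.length
    sa, sb = ir.copy_a[0], ir.copy_b[0]
    arc1 = ((sa + n) % L, (sb - sa - n) % L)  # after copy_a, before copy_b
    arc2 = ((sb + n) % L, (sa - sb - n) % L)  # after copy_b, before copy_a
    if arc1[1] == 0 or arc2[1] == 0:
        raise NoQuadripartite(f"{seq.id}: IR copies are adjacent; no single-copy regions")

    if arc1[1] > arc2[1]:
        lsc, ssc = arc1, arc2
    elif arc2[1] > arc1[1]:
        lsc, ssc = arc2, arc1
    else:
        ref_struct = reference_structure
        if ref_struct is None and reference is not None:
            ref_seq = CircularSequence(reference.sequence.id, reference.sequence.bases)
            ref_struct = resolve_quadripartite(
                ref_seq, find_inverted_repeats(ref_seq, **ref_detect_kwargs)
            )
        if ref_struct is None:
            raise AmbiguousStructure(
                f"{seq.id}: the two single-copy arcs are the same length and "
                "no reference was supplied to break the tie"
            )
        ref_cs = CircularSequence(reference.sequence.id, reference.sequence.bases)
        ref_lsc = ref_cs.fragment(ref_struct.lsc.start, ref_struct.lsc.end)
        id1 = global_identity(seq.fragment(arc1[0], arc1[0] + arc1[1]), ref_lsc)
        id2 = global_identity(seq.fragment(arc2[0], arc2[0] + arc2[1]), ref_lsc)
        lsc, ssc = (arc1, arc2) if id1 >= id2 else (arc2, arc1)

    ls, llen = lsc
    # IRb starts where LSC ends
    irb_start = (ls + llen) % L
    slen = ssc[1]
    regions = []
    pos = ls
    for name, length in (("LSC", llen), ("IRb", n), ("SSC", slen), ("IRa", n)):
        regions.append(Region(name, pos % L, pos % L + length))
        pos += length
    assert llen + slen + 2 * n == L
    assert regions[1].start == irb_start
    return PlastomeStructure(*regions, genome_length=L)


def structure_report(structure: PlastomeStructure) -> str:
    """Tab-separated region report (name, start, end, length; 1-based inclusive)."""
    L = structure.genome_length
    lines = ["region\tstart\tend\tlength"]
    for r in structure.regions():
        start1 = r.start + 1
        end1 = (r.end - 1) % L + 1
        lines.append(f"{r.name}\t{start1}\t{end1}\t{len(r)}")
    return "\n".join(lines) + "\n"
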