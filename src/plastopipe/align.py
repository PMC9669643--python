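"""Thin pairwise-alignment helpers shared by standardization and annotation.

Global (NW) alignment backs every orientation decision; infix (HW) alignment
backs feature-segment search.  Identity is defined as matched columns over
aligned columns of the optimal alignment.
"""

from __future__ import annotations

import re

import edlib

_CIGAR_RE = re.compile(r"(\d+)([=XIDM])")


def _cigar_stats(cigar: str) -> tuple[int, int, int]:
    """Return (matches, aligned_columns, query_consumed) from an edlib cigar."""
    matches = columns = query = 0
    for count, op in _CIGAR_RE.findall(cigar):
        c = int(count)
        columns += c
        if op == "=":
            matches += c
        if op in "=XI":  # edlib: I consumes query, D consumes target
            query += c
    return matches, columns, query


def global_identity(a: str, b: str) -> float:
    """Identity of the optimal global alignment of two strings."""
    if not a or not b:
        return 0.0
    res = edlib.align(a, b, mode="NW", task="path")
    matches, columns, _ = _cigar_stats(res["cigar"])
    return matches / columns if columns else 0.0


def locate(query: str, target: str, max_edits: int) -> list[tuple[int, int, float, float]]:
    """Find the best infix placements of query in target.

    Returns a list of (start, end, identity, coverage) for every optimal-score
    location, end exclusive.  coverage is the fraction of query bases that are
    aligned (matched or mismatched) in the placement.  Empty if the best edit
    distance exceeds max_edits.
    """
    if not query or not target:
        return []
    res = edlib.align(query, target, mode="HW", task="locations", k=max_edits)
    if res["editDistance"] < 0:
        return []
    out = []
    seen = set()
    for start, end in res["locations"]:
        start = max(0, start)
        if start in seen:
            continue
        seen.add(start)
        window = target[start : end + 1]
        path = edlib.align(query, window, mode="NW", task="path")
        matches, columns, _ = _cigar_stats(path["cigar"])
        identity = matches / columns if columns else 0.0
        aligned_query = sum(
            int(c) for c, op in _CIGAR_RE.findall(path["cigar"]) if op in "=X"
        )
        coverage = aligned_query / len(query)
        out.append((start, end + 1, identity, coverage))
    return out
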