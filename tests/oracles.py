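"""Independent exhaustive oracles used only by the test suite.

The inverted-repeat oracle enumerates every exact substring pair via a
dynamic-programming run-length matrix on the doubled sequence - an
exhaustive comparison of all substring pairs, independent of the package's
seed-and-extend detector.
"""

import numpy as np

from plastopipe.model import reverse_complement


def exhaustive_inverted_repeats(s: str, min_length: int = 1) -> list[tuple[int, int, int]]:
    """All maximal exact inverted pairs (start_a, start_b, length), longest first.

    Positions are circular (mod len(s)); copies overlapping on the circle
    (palindromes) are excluded, as is any pair longer than half the circle.
    """
    L = len(s)
    n2 = 2 * L
    A = np.frombuffer((s + s).encode(), dtype=np.uint8)
    B = np.frombuffer((reverse_complement(s) * 2).encode(), dtype=np.uint8)
    M = A[:, None] == B[None, :]

    R = np.zeros((n2 + 1, n2 + 1), dtype=np.int32)
    for a in range(n2):
        R[a + 1, 1:] = (R[a, :-1] + 1) * M[a]

    # a run ends where the next diagonal cell does not match
    is_end = np.ones_like(M)
    is_end[:-1, :-1] = ~M[1:, 1:]
    ends = np.argwhere((R[1:, 1:] >= min_length) & is_end)

    found: dict[tuple[int, int], int] = {}
    for a, b in ends:
        n = int(R[a + 1, b + 1])
        if n > L // 2:
            n = L // 2  # cap: a pair cannot exceed half the circle
        i = (a - n + 1) % L
        j = (2 * L - (b - n + 1) - n) % L
        if (j - i) % L < n or (i - j) % L < n:
            continue  # overlapping copies (palindromic self-hit)
        lo, hi = (i, j) if i <= j else (j, i)
        if found.get((lo, hi), 0) < n:
            found[(lo, hi)] = n
    pairs = [(lo, hi, n) for (lo, hi), n in found.items()]
    pairs.sort(key=lambda p: (-p[2], p[0], p[1]))
    return pairs
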