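"""Standardize every isomer of a plastome to one canonical string.

An assembler can return the molecule rotated, on either strand, and in
either SSC orientation (the flip-flop isomers).  Canonicalization collapses
all of them to the same LSC-IRb-SSC-IRa linearization.
"""

from plastopipe import (
    canonicalize,
    find_inverted_repeats,
    generate_plastome,
    resolve_quadripartite,
)
from plastopipe.synthetic import transform

KW = {"min_length": 100, "min_identity": 0.95}
truth = generate_plastome(rng_seed=7)
canonical = truth.genome.bases

for rotation, flip, ssc_flip in [(0, False, False), (1234, False, False),
                                 (500, True, False), (2000, True, True)]:
    iso = transform(truth, rotation, flip, ssc_flip)
    structure = resolve_quadripartite(iso, find_inverted_repeats(iso, **KW))
    out = canonicalize(iso, structure, truth.annotation, **KW)
    print(
        f"input rot={rotation:>4} flip={flip!s:>5} ssc_flip={ssc_flip!s:>5} -> "
        f"recovered rotation={out.rotation_offset:>4} flip={out.flipped!s:>5} "
        f"ssc_flip={out.ssc_flipped!s:>5}  canonical={out.sequence.bases == canonical}"
    )
# Every line should end canonical=True: the provenance differs, the output
# byte string does not.  This is what makes downstream comparison of
# plastomes from different assembler runs meaningful.
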