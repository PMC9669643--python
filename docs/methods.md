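# Methods

This note records the models, algorithms, parameter choices and numerical
decisions behind `plastopipe`, and what the synthetic test substrate does and
does not demonstrate about real data.

## Coordinate conventions

All internal coordinates are 0-based half-open. Conversion to the 1-based
inclusive convention of GenBank and the NCBI feature table happens only in
the readers and writers (`formats`), so there is a single conversion boundary.
Intervals on the circular molecule store `start` in `[0, L)` with
`end = start + length`; `end > L` means the interval wraps the origin.
Circular searches run on the doubled sequence with results reduced modulo
`L` — the simplest correct wraparound handling.

## Inverted-repeat detection (`structure`)

The detector is seed-and-extend self-comparison: k-mers of the reverse
complement are indexed against the forward strand of the doubled sequence;
each seed pair is extended gaplessly in both directions. The default seed
size is 17 (scaled automatically to `min(17, min_length)` so kilobase-scale
fixtures with `min_length` ≈ 100 still seed densely). Seeds already covered
by a reported pair are skipped using the anti-diagonal invariant of gapless
inverted-pair extension (`start_a + start_b + length` is constant), which
keeps the search near-linear in practice.

Extension scoring is match +1, mismatch −2 with an X-drop of 8, and the end
is trimmed back to the *outermost* maximum-score point. Two properties drove
this choice over the more obvious "extend while running identity stays above
the threshold" rule:

* Running identity lets a long, near-perfect repeat interior subsidize
  extension through tens of bases of unrelated flanking sequence (a 400 bp
  repeat at 99% identity can absorb ~20 flanking mismatch-rich bases before
  the average dips below 0.95), destroying boundary accuracy.
* Trimming to the latest maximum means an isolated substitution at or near a
  repeat end costs at most the mismatch itself — the matching bases beyond
  it are kept — so boundaries stay within a couple of bases of the truth at
  ~1% divergence.

With `min_identity = 1.0` extension is exact-match-only; this mode is
directly comparable to exhaustive substring-pair enumeration, and the test
suite holds the detector to coordinate-level agreement with an independent
dynamic-programming oracle.

Pairs whose copies overlap on the circle (palindromic self-hits, common in
AT-rich plastome sequence) are discarded, as are pairs longer than half the
circle. Ambiguity codes never match anything, including themselves, so N-rich
regions cannot inflate identity. Defaults for real plastomes are
`min_length = 1000`, `min_identity = 0.99` (plastome IRs are 10–30 kb and
near-identical); the kilobase-scale fixtures in the tests pass
`min_length = 100`, `min_identity = 0.95`.

Quadripartite resolution takes the longest pair as the IRs; the longer
inter-copy arc is the LSC, the shorter the SSC, and IRb is by convention the
IR copy immediately clockwise of the LSC. Equal arcs are broken by alignment
identity of each arc against the reference LSC; without a reference the tie
is an error (`AmbiguousStructure`) rather than a silent guess.

## Standardization (`standardize`)

Canonicalization rotates the molecule to start at LSC base 1, choosing
between the two strands by which LSC aligns better to the reference LSC
(ties keep the forward strand, which makes the operation idempotent), then
reverse-complements exactly the SSC interval in place if the flipped SSC
matches the reference SSC better. Junction bases belong to the IRs and are
never touched. All identities are matched-columns over aligned-columns of a
global (Needleman–Wunsch, via edlib) alignment; ends-free alignment is
unnecessary because the compared segments are extracted exactly.

Isomer selection mirrors the two-candidate output convention of organelle
assemblers: each candidate is structure-resolved and strand-oriented, and the
candidate whose *native* SSC orientation has the higher forward identity to
the reference SSC wins. More than two candidates abort the sample
(`CandidateOverflow`) — an unresolved assembly needs human eyes, not a guess.

Ambiguous-base correction anchors reads by exact k-mer match (k = 21, both
strands of both mates) on the nearest clean k-mer within 30 bp of each side
of the ambiguous position — strictly adjacent flanks would fail whenever two
planted Ns fall within k bases of each other. Votes from both flanks are
pooled, one vote per read strand, and a read that votes inconsistently for a
position is dropped. A position is rewritten only when depth ≥ 5 and the
modal base reaches a 0.7 majority; anything else is reported, not changed,
and positions that are already A/C/G/T are never eligible. Base qualities
are carried through parsing but deliberately unused: at the coverage depths
where correction is sensible, the depth/majority rule dominates.

Per-sample order of operations is select → correct → resolve → canonicalize:
correcting before canonicalization keeps read-space coordinates stable for
the provenance log; the final sequence is unaffected by the order.

## Annotation transfer (`annotate`)

Templates are extracted per gene-level feature (CDS/tRNA/rRNA, plus bare
genes without a child feature); each IR-duplicated gene copy is its own
template. Segment sequences are stored strand-applied (sense), and a
trans-spliced flag is set for `order()` locations or mixed-strand segments.

Mapping is per-segment: each segment sequence is searched on both strands of
the doubled target with edlib's infix mode, and a placement counts in round
*r* only if its identity and query coverage clear that round's thresholds.
The default schedule (0.98, 1.00), (0.90, 0.95), (0.80, 0.90) applies rounds
in order to still-unmapped templates only — a decreasing-threshold rescue
ladder. Competing placements are scored by identity × coverage; ties are
resolved toward the circular shift implied by unambiguously placed templates.
Templates with *identical* query sequences (the IR duplicates) are assigned
jointly: each copy must claim a distinct placement, chosen by positional
consistency, because under asymmetric divergence the strictly-best hit for
both copies is the same spot. A post-check rejects placements whose relative
strand pattern contradicts the template. Boundaries come from alignment ends;
no codon-aware extension is attempted, and internal stops are *reported* by
QC, never silently "fixed" — explicit flags beat silent edits.

QC rebuilds each CDS in biological order (reverse textual order for
minus-strand multi-exon genes; as-given order for trans-spliced genes),
honors `codon_start`, translates with table 11, and flags internal stops,
frame-length violations and missing terminal stops.

## Formats (`formats`)

FASTA and FASTQ pass through strict validating readers (exact line numbers in
errors; gzip-transparent streaming for FASTQ); GenBank goes through
Biopython with the location grammar (`join`, `complement`, `order`, nesting)
converted at the boundary, minus-strand compound locations flipped between
GenBank's textual order and Biopython's biological order. All writers are
fixed points under read∘write on their own output. The feature-table writer
emits gene/CDS/tRNA/rRNA only — submission tables derive introns implicitly —
with minus-strand intervals written start > end and origin-wrapping segments
split into two intervals. Emitted GenBank qualifiers are gene, product,
codon_start, transl_table, note, with anything else from the reference
carried through verbatim. The external-assembler adapters write the
`key = value` config (type chloro, k-mer 29, read length 151 bp, insert
300 bp, paired-end, the user's genome range) and discover output by the
assembler's naming convention (one circularized assembly, or Option_1/2).

## Pipeline (`pipeline`)

Pre-assembled mode is first-class so the core algorithms run with no
external binaries; the trimmer/assembler adapters shell out only in reads
mode. The read trimmer is asked to subsample 10,000,000 reads. The batch
manifest (`fof.txt`) dialect is whitespace-separated fields with `#`
comments: `prefix forward reverse` (reads mode) or `prefix assembly`
(pre-assembled), a definition this package owns. Samples run independently;
each stage appends to its own log whose last line is `SUCCESS: ...` or
`ERROR: ...`; a sample is complete only if every declared output exists and
is non-empty. When no IR is found (IR-reduced lineages exist), the sample
falls back to whole-molecule orientation by locating the reference start on
both strands, warns, and proceeds to annotation. Exit codes: 0 all complete,
1 any sample failed, 2 configuration error.

## Synthetic data (`synthetic`)

The generator emulates what the pipeline consumes: a circular genome built
as LSC + IR + SSC + revcomp(IR) with a named planted gene set (single-exon
CDS, two-exon CDS with intron, trans-spliced two-segment CDS spanning LSC
and SSC on opposite strands, a tRNA, and an rRNA duplicated in both IRs),
plus isomer transformations, Bernoulli point mutations with feature-boundary
exclusion windows, exact-fraction divergence planting for threshold
fixtures, N injection, and uniform-coverage paired-end read simulation with
substitution errors. Four bases at each single-copy edge are pinned to 'A'
so the planted IR is maximal even under mismatch-tolerant extension —
without this, chance complementary flanking bases make "exact boundary
recovery" ill-posed. Every generator is a pure function of its arguments
including the RNG seed.

Default fixture dimensions (LSC 2000, IR 400, SSC 600 → 3400 bp; tests up to
LSC 4 kb / IR 800 / SSC 1 kb) are two orders of magnitude below real
plastomes, chosen so the full acceptance battery runs in seconds; the
algorithms are scale-free apart from the seed/length thresholds, which are
configuration. What the synthetic results do **not** show: real base
composition and codon usage, indels (substitutions only), sequencing-quality
error profiles, IR junction shift biology, or assembler failure modes —
conclusions about those need real reads and assemblies.

## Known limitations

* The repeat detector is gapless; an IR pair differing by indels would be
  reported as shorter flanking pairs.
* Annotation boundaries are pure alignment evidence; genes whose true
  boundaries moved (not just diverged) transfer at the reference's geometry.
* The whole-molecule fallback orientation anchors on the reference start; a
  reference starting inside a rearranged region would mis-rotate (the
  warning in the log is the signal to inspect).
* The feature-table writer targets BankIt/table2asn conventions only.
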