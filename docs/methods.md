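# Methods

## Data model and coordinate conventions

All coordinates are 0-based, half-open, on the forward strand of both
sequences; strandedness is a segment-level flag. Reverse-orientation
segments store the target range in forward coordinates with the block list
ordered by ascending query position (hence descending target position).
Formats that deviate are normalized only at the I/O boundary: UCSC chain
reverse-strand query coordinates (counted from the sequence end) are
flipped on ingest, and BLAST tabular / GFF3 1-based closed coordinates are
converted on read/write. An alignment's user-facing *length* is its query
span.

An `AlignmentSegment` carries its ungapped blocks plus match, mismatch and
gap totals. Two invariants are enforced everywhere: blocks are maximal
ungapped runs sorted and non-overlapping on both axes, and
`matches + mismatches == Σ block lengths`.

**Percent identity** is `100 · matches / (matches + mismatches + gap_bases)`
— the alignment-column convention, in which gapped columns count against
identity. The upstream viewer this library models reports identity, gaps
and mismatches jointly without publishing a formula, so the denominator
choice is ours; it is applied consistently in the info panel, GFF3 output
and ranking, and documented here because other tools (e.g. BLAST `pident`)
use the aligned-column denominator instead.

## Second-phase processing

Stages, in order: merge → gap split → overlap split → drop contained →
rank → reciprocity scans → per-class re-merge. The input is canonically
sorted first, so the result is independent of input order.

Parameter and rule choices that the recipe leaves open:

* **Gap at a junction** is `max(query-side gap, target-side gap)`; the
  split threshold is `min(gap_split_bp, gap_split_frac × alignment length)`
  with the *pre-split* query span as the alignment length. The absolute
  threshold is 50 bp (same-or-close species) or 50 kb (distant); the
  fractional one is 5%. Both criteria apply uniformly to every pair.
* **"Adjacent with no conflicting alignments"** (merge) is operationalized
  as: same sequence pair, same orientation, collinear, both intervening
  gaps ≤ `merge_max_gap`, and no third alignment overlapping either
  intervening interval. `merge_max_gap` defaults to the gap-split
  threshold so merge and split are mutually consistent.
* **Merged statistics are summed** (and intervening gaps added to
  `gap_bases`), never recomputed from sequence — phase two has no sequence
  access. **Split statistics** are apportioned: mismatches proportionally
  to each child's aligned length with cumulative rounding (so totals are
  conserved exactly, matched bases in particular), gap statistics
  recomputed from the junctions each child retains.
* **Overlap splitting** iterates to a fixpoint: each alignment is cut at
  every other alignment's endpoint strictly inside it, on either axis
  (target-axis cut points are mapped through the block structure; a point
  inside a block bisects it exactly, a point in a gap cuts at the
  junction). At the fixpoint, any two alignments overlapping on an axis
  are range-identical there, which is the precondition for the scans.
* **"Low-quality" in the containment drop** means strictly lower rank key;
  exact duplicates keep the first representative in rank order.
* **Ranking** is (both-chromosome > one > neither) by sequence role, then
  identity, then length, then (query seq, query start, target seq, target
  start) as a tie-break. The upstream system's additional common-component
  preference needs component-level assembly metadata that public alignments
  do not carry, and is omitted.
* **Reciprocity codes**: scan 1 walks the rank order and marks an alignment
  query-best iff no higher-ranked alignment overlaps it on the query; scan
  2 likewise on the target. Code 3 = best on both, **1 = query-side best
  only, 2 = target-side best only** (the convention is ours; the source
  material does not say which code is which side). Alignments best on
  neither are counted and discarded.
* **Re-merge** applies the merge rule independently within each
  reciprocity class, with conflicts evaluated against that class only.

Degenerate inputs: empty input yields empty output; single-segment sets
pass through unchanged; alignments referencing sequences absent from the
assembly catalogue (or overflowing them) raise a validation error naming
the offenders.

## Distance and recommendation

Bottom-s MinHash sketch of canonical k-mers (lexicographic min of k-mer and
reverse complement), k = 21, s = 1000 — the sketching tool's published
defaults, since the recipe names the tool but no parameters. K-mers with
non-ACGT characters are skipped. The hash is an 8-byte BLAKE2b digest of
the k-mer bytes keyed with a fixed seed (42), giving a deterministic,
platform-independent 64-bit hash from the standard library. Distances are
therefore reproducible across runs but not numerically identical to other
MinHash implementations, which use different hash functions; cross-tool
agreement is not a goal.

`d = −(1/k)·ln(2j/(1+j))` with `j` estimated on the merged bottom-s sketch;
`d = 0` at `j = 1` and saturates to 1.0 at `j = 0`. Recommendation
boundaries are left-closed: d = 0.05 → word_size 16, d = 0.1 → LASTZ,
d = 0.3 → still LASTZ (the "likely uninformative" advisory applies strictly
above 0.3). The HoxD55 substitution-matrix note is attached to LASTZ
recommendations above d = 0.2 ("most distant pairs" — the cutoff is ours).
PNG rasterization of the SVG output is not provided; the SVG 1.1 documents
render in any browser.

## Coverage

Genome and CDS coverage are computed on the union of **ungapped blocks**
(never segment envelopes), so internal gaps do not inflate coverage. CDS
intervals are unioned across isoforms before intersecting. Both an
all-alignments and a best-placed-only (reciprocity 3) filter are exposed,
since either could be the denominator of interest; the bundled report
prints both rows.

## Synthetic data

The generator emulates the structural patterns the viewer is designed to
expose — inversions (reverse-orientation alignment at the locus),
inter-chromosomal translocations, segmental duplications (one extra
non-best placement), within-chromosome scrambling of tiles (macrosynteny
with shuffled internal order), deletions — on top of uniform-composition
random chromosomes with planned SNP and small-indel rates. Defaults:
5 × 1 Mb chromosomes, SNP rate 0.002 and indel rate 1e-4 with geometric
sizes capped at 40 bp — a within-species-like divergence whose indel gaps
stay below the 50 bp split threshold, so gap splitting is exercised by the
fragmentation step rather than by mutation noise. `fragment_alignments`
then cuts the truth at random positions and injects overlapping redundant
pieces and contained duplicates, reproducing the fragmented, redundant
character of raw aligner output while staying consistent with the truth
mapping.

What the simulation does **not** model: repeats and paralogy (other than
the planted duplication), GC/composition structure, large indels, ploidy
differences, or alignment errors (every raw segment is consistent with the
truth). Passing the recovery tests therefore shows that the second phase
reconstructs best placements from fragmented, redundant, truth-consistent
input — not that any upstream aligner is accurate on real genomes.

The reference study conditions used by the end-to-end checks are a seeded
plan of 5 × 1 Mb chromosomes with one 100 kb inversion, one 100 kb
translocation, one 50 kb duplication and one chromosome scrambled into 20
tiles, fragmented with 200 cuts, 10% overlap injection and 10% duplicate
injection; the reciprocal-best set must recover ≥ 95% of truth bases with
the correct base-level mapping. These sizes make every stage's work
non-trivial (hundreds of segments, every event type present) while the
whole check runs in seconds.

## Rendering

Static SVG 1.1 only, built deterministically (fixed float formatting,
insertion-ordered attributes): the same scene always yields byte-identical
output, and flipping a chromosome twice restores the exact bytes. The
ideogram shows reciprocal-best alignments by default; the dotplot always
shows best and non-best placements, forward in green with positive slope
and reverse in purple with negative slope. Connector colors are keyed to
the target chromosome with a fixed 12-color categorical palette (the
upstream palette is unpublished; any fixed deterministic palette satisfies
the display contract). Chromosomes are laid out in natural sort order.

## Known limitations

* Chains and CIGAR-less PAF/BLAST rows carry no (or incomplete)
  substitution/block information; such segments get a synthesized one- or
  two-block structure, identity from the available counts, and
  whole-segment granularity in gap splitting (a warning is logged).
* The common-component merge/rank criterion is omitted (no public
  component metadata).
* Phase one (masking and running BLAST/LASTZ/chaining) is external; this
  package recommends its parameters and consumes its outputs.
* Sketching is pure Python and intended for the package's own test-scale
  inputs; multi-gigabase assemblies should be sketched with a dedicated
  tool.
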