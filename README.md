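# syntopy

Offline post-processing, ranking and rendering of **pairwise whole-genome
alignments**. `syntopy` takes the raw output of a whole-genome aligner
(PAF, UCSC chain, or BLAST tabular), cleans it into ranked
reciprocal-best / non-best alignment sets, and renders the result as synteny
ideograms and dotplots, GFF3/TSV/XLSX exports, and genome/CDS coverage
reports. It also estimates the MinHash (Mash) distance between two
assemblies and recommends which aligner and parameters to use for them, and
ships a rearrangement simulator so the whole pipeline can be exercised with
no downloads.

It is aimed at comparative genomicists who have (or are about to produce)
assembly-assembly alignments and want the "viewer-grade" cleaned alignment
sets and figures on their own machine.

## The method

Raw whole-genome alignments are fragmented and redundant: the same locus is
covered by overlapping, duplicated and broken segments. The second-phase
algorithm turns them into ranked placement sets:

1. **Merge** adjacent collinear alignments when both intervening gaps are at
   most `merge_max_gap` and no third alignment overlaps either gap.
2. **Split on gaps**: an alignment is cut at every internal junction whose
   gap `g = max(query-side, target-side)` reaches
   `min(gap_split_bp, 0.05 × alignment length)`, with `gap_split_bp` = 50 bp
   for the same or closer species and 50 kb for more distant ones.
3. **Split at overlaps**: alignments are cut wherever they intersect other
   alignments, so that on either genome any two alignments are
   range-identical or disjoint.
4. **Drop contained** duplicates: an alignment contained on both genomes
   within a single higher-ranked alignment of the same orientation is removed.
5. **Rank**: chromosome-to-chromosome placements first, then percent
   identity (`100·matches / (matches + mismatches + gap_bases)`), then
   alignment length, with coordinates as a deterministic tie-break.
6. **Two reciprocity scans**: in rank order, an alignment is *query-best* if
   no higher-ranked alignment overlaps it on the query, and *target-best*
   likewise on the target. Best on both ⇒ **reciprocity 3** (reciprocal
   best, the default display set); query-side best only ⇒ 1; target-side
   best only ⇒ 2; best on neither ⇒ discarded.
7. **Re-merge** within each reciprocity class into the longest
   representative stretches.

The Mash distance `d = −(1/k)·ln(2j/(1+j))` (bottom-s sketch of canonical
k-mers, k=21, s=1000) drives the aligner recommendation: BLAST megablast
with `word_size` 28 below d = 0.05 (or same species), 16 for 0.05 ≤ d < 0.1,
LASTZ above 0.1, and an "alignment likely uninformative" advisory above 0.3;
WindowMasker `t_thres_pct` is 99.5 / 98.5 / 97.5 for same-species BLAST /
cross-species BLAST / LASTZ pairs.

## Worked example

Simulate a 4 × 100 kb genome pair with a planted inversion, translocation
and duplication, fragment the truth into 61 raw overlapping segments, and
process them:

```sh
syntopy simulate --seed 7 --out-dir demo --n-chromosomes 4 \
    --chromosome-length 100000 --n-cuts 40 \
    --overlap-fraction 0.1 --duplicate-fraction 0.1
syntopy process demo/raw.paf \
    --query-report demo/query.report.tsv \
    --target-report demo/target.report.tsv \
    --out-gff3 demo/aln.gff3 --out-tsv demo/aln.tsv
```

The stage log (stderr) shows the pipeline at work — 61 raw segments are
merged to 29, atomized to 66 at overlap boundaries, deduplicated to 42 and
stitched back into 12 ranked alignments:

```
input	61
after_merge	29
after_gap_split	29
after_overlap_split	66
after_drop_contained	42
after_reciprocity	42
output	12
```

`demo/aln.gff3` anchors one `match` feature per alignment on the target
assembly; the planted inversion comes out as a single reverse-strand
reciprocal-best feature spanning exactly the inverted interval:

```
chr1  syntopy  match  30001  40001  99.77  -  .  ID=match2;Target=chr1 30001 40000 -;reciprocity=3;...
```

Coverage and distance reports:

```sh
$ syntopy coverage demo/aln.gff3 --target-report demo/target.report.tsv
query_assembly  target_assembly  mash_distance  reciprocity_filter  genome_coverage_pct  cds_coverage_pct
query           target           NA             all                 99.9869              NA
query           target           NA             best_placed         98.7523              NA

$ syntopy dist demo/query.fa demo/target.fa
0.002353
```

Best-placed coverage is lower than total coverage because the duplicated
region's second copy is a non-best placement (reciprocity 2). The Mash
distance 0.0024 reflects the 0.2% simulated SNP rate, and feeds the aligner
recommendation:

```sh
$ syntopy recommend --distance 0.07
mash_distance	0.0700
aligner	BLAST
windowmasker_t_thres_pct	98.5
word_size	16
command	blastn -evalue 0.0001 -gapextend 1 -gapopen 2 -max_target_seqs 250 -soft_masking true -task megablast -window_size 150 -word_size 16
```

Render the views with `syntopy ideogram demo/aln.gff3 --out ideo.svg`
(reciprocal-best connectors only by default; `--flip chr1` reverses a
chromosome, `--min-length` and `--orientation` filter the view) and
`syntopy dotplot demo/aln.gff3 --out dot.svg` (forward alignments green
with positive slope, reverse purple with negative slope; the dotplot always
shows best and non-best placements).

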