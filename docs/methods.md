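# Methods

## The calling model

`hervwha` decides, per sample and per proviral HERV locus, whether the locus
is transcribed above a reproducible detection floor. Reads are first aligned
(upstream, e.g. with BWA) to a catalog of proviral locus sequences; the
package consumes those alignments. Three filters are applied in order:

1. **Read selection.** For single-cell data, reads belonging to one cell
   cluster are selected by intersecting the alignment's `CB` cell-barcode
   tag with a plain-text barcode list. Untagged reads are dropped, as are
   unmapped, secondary and supplementary records, so each read contributes
   depth at most once per locus.
2. **Identity filter.** Percent identity is computed from the SAM `NM`
   edit distance over the reference-consuming aligned length (soft clips
   excluded; insertions and deletions count as edits). Reads below the
   threshold are discarded. The threshold is *inclusive*: at the default
   99%, a 100-bp read with exactly one mismatch (99.0%) is retained. Note
   the granularity interaction: for 90-bp reads, one mismatch already gives
   98.9%, so at 99% only perfect 90-bp reads survive.
3. **Window scoring.** Each locus is partitioned into sequential,
   non-overlapping windows of `window_length` bp (default 50); trailing
   bases shorter than one window belong to no window. For each window:
   - *usable* ⇔ every window position is covered by ≥ 1 filtered read. A
     window cannot be compared against the reference where there is no
     data, and identity is always divided by the full window length, so
     missing data can never inflate a score — it voids usability instead.
   - the *consensus* is the majority base per position, with ties broken
     toward the reference base (at a 1–1 tie there is no evidence of
     divergence).
   - *passed* ⇔ usable and consensus–reference identity ≥ `window_identity`
     (default 99%, i.e. at most 0 mismatching positions in a 50-bp window,
     since 49/50 = 98%).

The window similarity score (WSS) is the percentage of usable windows that
passed. The ternary locus call is:

- **positive** — mean per-base depth over the windowed span ≥ `min_depth`
  (default 3), usable windows ≥ `min_usable_windows` (default 9), and WSS
  = 100%, evaluated as the integer identity `n_passed == n_usable`
  (never a rounded float);
- **negative** — any criterion failed;
- **uncallable** — the locus hosts fewer than `min_usable_windows` full
  windows (< 450 bp at defaults) and is structurally incapable of a
  positive call; such loci are loaded and scored, not rejected.

Two boundary conventions deserve note. The depth criterion is inclusive
(mean depth exactly 3.0 satisfies it); "depth" defaults to mean per-base
coverage over the windowed span `[0, n_windows × 50)`, with raw read count
available via `depth_mode="reads"`. Usable windows need not be contiguous.
Scoring is a pure function of (reads, catalog, thresholds); the
`replicate_check` option runs the whole pass twice and raises if the two
call vectors differ, turning sample duplication into a determinism audit.

## Cohort comparison

A scored cohort is held as a presence matrix: loci × samples ternary calls
plus a parallel depth matrix (0.0, not missing, where a sample has no
coverage — so every per-locus depth vector has one entry per sample).

**Case-unique loci.** A locus is case-unique when it is non-positive in
*every* control sample and positive in ≥ 1 case sample. The control panel
is a set of individually scored samples, never a pooled read file.
Uncallable control cells count as non-positive by default
(`strict_negative=True` requires explicit negatives). The filter is
undefined without controls. Because adding a control can only remove loci
from the unique set, the saturation curve — the unique-locus count as
controls are added one at a time, indexed by cumulative control reads — is
monotone non-increasing, which is the formal statement of the curve
leveling off once the control pool is large enough.

**Depth rank tests.** Loci positive in ≥ 2 cases (configurable) are tested
for a depth difference between case and control samples with a two-sided
Mann–Whitney U test: exact null distribution when n + m ≤ 16 with no ties,
tie-corrected normal approximation (with continuity correction) otherwise;
the result records which branch ran. No multiple-testing correction alters
the `significant` flag (per-locus p < 0.05); a Benjamini–Hochberg column is
emitted alongside for transparency.

**Subsampling.** Uniform without replacement; indices are drawn from a
seeded generator and then sorted, so output order is input order and
identical (input, n, seed) gives byte-identical output.

## Figure-type exports

All figure-type results are data exports (TSV / Newick / BED6 / JSON) for
external rendering tools. PCA operates on the column-centered samples ×
loci 0/1 presence matrix (depths optional), constant loci dropped, full
SVD; the full-rank embedding preserves pairwise sample distances to 1e-9.
The sample tree is average-linkage agglomerative clustering on Euclidean
distances; "normalize" means per-locus z-scoring with zero-variance loci
dropped. Paired-sample similarity is Jaccard-style: 100 × |positive in
both| / |positive in either| (agreement over the union of positive loci).
Chromosome distributions report all catalog chromosomes including
zero-count ones, with a BED6 companion for ideogram tools.

Coordinates are 0-based half-open everywhere (BED convention); 1-based
locus tables are declared with `one_based=True` and converted on load.

## Synthetic data

The generator emulates the pipeline's assumed structure: a catalog of
random-sequence loci (default 40 loci of 450–800 bp scattered over 23
chromosomes), per-sample expressed subsets, 90-bp barcoded reads at a
target mean depth (default 30×, ten times the calling depth floor), i.i.d.
substitution errors, and optional per-locus dropout emulating the RNA
degradation of frozen samples. Read starts are drawn over
`[-(read_length-1), L-1]` and clipped at locus boundaries, so expected
coverage is uniform across the entire locus including its first and last
bases; boundary reads carry only their aligned part, as an aligner's
soft-clipping would leave them. Cohorts plant a baseline locus set in all
samples plus case-only loci (shared and/or per-case private), so the
expected output of the differential filter is known exactly.

Alignments are emitted directly from truth — positions and edit distances
are exact by construction — with optional FASTQ for users who want to run
a real aligner. The error model is substitution-only, so edit distance
equals mismatch count; indels, UMIs, quality-score error profiles, spliced
transcripts and multi-mapping ambiguity between near-identical loci are
*not* modeled. Passing tests on this generator therefore demonstrate the
pipeline's logic (filter semantics, threshold arithmetic, set algebra,
determinism), not robustness to the repetitive-sequence mapping ambiguity
that dominates real HERV data.

## Problem sizes and numerical choices

The test and acceptance workloads run at desk scale: 200 randomized loci
(≤ 600 bp, ≤ 50 reads) for brute-force cross-validation; a 21-control /
10-case cohort over a 40-locus catalog with 15 planted case-only loci at
30× error-free depth for end-to-end recovery; 100 random cohorts for
saturation monotonicity; 100 seeds of 50% subsampling on a saturated
12-locus sample for call stability. Headline counts from real cohort
studies depend on the specific deposited datasets and are not reproduced
here; the package verifies the method's properties, not those datasets.

Tie-breaks and degenerate inputs: empty alignment sets score all loci
negative or uncallable; an all-identical sample matrix yields a zero-length
star tree rather than an error; an all-constant presence matrix embeds
every sample at the origin; WSS with zero usable windows is reported as 0.
Exact float comparisons are avoided everywhere a count can be compared
instead (WSS, Venn compartments, window tallies).
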