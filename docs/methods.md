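# Methods

This note records the models, defaults and design choices behind cnvcurate,
and what the synthetic fixtures do and do not demonstrate.

## Data model and coordinates

Segments are 0-based half-open internally. SEG files are read and written
in either a 1-based inclusive dialect (the common convention, default) or
0-based half-open, selected by a flag; dialects in the wild vary, so the
convention is explicit rather than guessed. The index keeps per-chromosome
lists sorted by start, rejects overlaps at load time, and orders
chromosomes naturally (chr2 before chr10). The sample column is preserved
verbatim on round trip but otherwise ignored: a session is one tumor/normal
pair. Segment means are written at 6 decimal places, and index equality is
defined at that precision so a write/read round trip is an identity.

## Classification thresholds

A segment is a gain when mean logR ≥ `gain_thr` and a loss when ≤
`loss_thr` (boundaries inclusive — a deterministic tie rule). Defaults are
±0.2 logR, a conventional review threshold for bulk tumor data;
both are user-settable because the appropriate cutoff depends on purity and
ploidy.

## Tracks

Depth is extracted from bigWig in fixed-width bins (default 100 bp). The
bin statistic is the mean over *covered* bases only; bases without data do
not count as zeros, and a fully uncovered bin is missing (NaN). logR =
log2((T + c) / (s·(N + c))) with pseudocount c = 0.5 (stabilizes
low-coverage bins) and scale factor s = 1 by default; an optional
library-size normalizer `median_scale_factor` (median tumor / median normal
over non-missing bins) is available when libraries differ in depth. Note
the pseudocount biases logR slightly toward 0 in non-neutral regions
(≈0.017 at depth 30 for a half-copy loss); exact-recovery checks therefore
use c = 0. BAF arrives precomputed as a sparse bigWig with one value per
germline het SNV; values outside [0, 1] are rejected with the offending
position named. Interval means over logR use an unweighted mean of
non-missing bins, with bin membership decided by the bin midpoint — a
deterministic, order-free rule for partial bins.

## Breakpoint evidence

Reads are taken from indexed BAMs in a window of ±100 bp (default) around
each segment boundary; duplicates, secondary and supplementary alignments
are excluded everywhere. A soft clip of at least `min_clip` = 5 bp makes a
split read (shorter clips are routinely produced by adapter or quality
trimming); the clip/match junction contributes the record's reference start
(leading clip) or end (trailing clip), and `split_at_pos` counts junctions
within ±5 bp (default tolerance) of the breakpoint. Pair status takes the
first matching rule of: mate unmapped; mate on a different chromosome;
orientation not forward–reverse (which covers same-strand and everted
layouts — the display-level notion of "different strand"); insert size
outside mean ± k·sd. One category must win because each read gets one
color. The insert model is estimated per BAM from the first 10,000
forward-reverse pairs using the median and a MAD-derived sd (1.4826·MAD),
robust to the discordant pairs being screened for; k = 3.

The verdict rule is an explicit, configurable operationalization of a
reviewer's judgement: *supported* iff |segment mean logR| ≥ 0.2 and (BAF
divergence mean |BAF − 0.5| ≥ 0.1 over ≥ 10 SNVs, or clip support at both
breakpoints with ≥ 2 tumor reads and 0 normal reads); *spurious* iff no
line flags; *ambiguous* otherwise. These defaults are deliberately
conservative on the normal sample (`s_max` = 0) because any clip support in
the matched normal points to a germline or artifactual junction.

## Split-point search

"Minimizing the variation within the two segments" is implemented as
two-piece constant least squares: minimize total within-side SSE over the
boundary k. Total SSE rather than the sum of the two variances is used
because dividing by side size degenerately favors single-bin segments;
`min_seg_bins` (default 2) additionally keeps boundaries off the window
edges. Missing bins are excluded from both the sums and the size counts.
The production path uses prefix sums (O(n)); an exhaustive O(n²) scan
serves as the independent oracle in tests. Because the prefix-sum SSE is a
difference of large moments, its rounding noise scales with the total sum
of squares; boundaries whose SSEs differ by less than 1e-12·(1 + Σx²) are
treated as exact ties and broken toward the smallest k, and a suggestion
whose SSE reduction is negligible carries a low-confidence note. Multiple
breakpoints are handled by greedy binary segmentation — recursive
application of the single split — rather than a joint multi-break
optimizer, matching how a curator works sub-window by sub-window.

## Edit algebra

Splitting replaces a segment by [start, p) and [p, end); merging replaces
two adjacent segments by [left.start, right.end), absorbing any gap
between them (so per-chromosome footprint never decreases under merge and
is invariant under split). When a logR track is bound to the session,
split positions snap to bin boundaries and child/merged means are
recomputed from the track; without a track, split children inherit the
parent mean and a merge takes the length-weighted mean — except that two
parents with equal means merge to exactly that mean, so merging the
children of a split restores the parent bit-for-bit. Every edit pushes an
operation holding the removed segments and the inserted ids; undo is exact
restoration. Removing a false call is a merge into its neighbor; adding a
missed segment is two splits — there are no free-form insert/delete
primitives. The CLI persists sessions as the current SEG plus an audit log
(one timestamped record per edit with its inverse), writes atomically via
temp-file rename, and can undo across invocations.

## Simulator

The simulator emulates a paired tumor/normal whole-genome experiment on one
synthetic 2 Mb chromosome `chrS` at 100 bp bins, diploid depth 30, purity
0.8, read length 100, insert 350 ± 50 — defaults chosen once as realistic
desk-scale conditions. Expected logR per region is log2((p·c + 2(1−p))/2)
(floored at −8 for the c = 0, p = 1 singularity); expected BAF modes follow
the allele mixture of a (c−1, 1) tumor genotype. Depth noise is lognormal
per bin with the configured logR sd (default 0.15) split evenly between
tumor and normal, so the binned logR noise sd equals the configured value
exactly. BAF values are binomial draws at the local simulated depth, making
BAF noise depth-consistent. Reads are fixed-sequence pairs with valid flags
and CIGARs; at every true breakpoint the tumor BAM receives 6 reads
soft-clipped exactly at the breakpoint, 4 discordant-distance pairs
flanking the event, one same-strand pair and one mate-unmapped read, while
the normal BAM holds concordant background only. Background insert sizes
are drawn from a normal truncated at ±2.5 sd so the k = 3 concordance band
cleanly separates generated concordant from discordant pairs. The emitted
SEG is the truth tiling optionally corrupted by dropping a segment (means
length-weighted into the neighbors), shifting a boundary, or adding a
spurious call — yielding the four scenarios: supported, missed, spurious,
shifted. BAMs are emitted via sorted SAM text converted with
`samtools view --no-PG` and indexed, keeping every output byte-identical
for a fixed seed.

What the simulator does **not** model: sequencing error, GC and
mappability bias, subclonal mixtures, multi-chromosome genomes, realistic
breakpoint microhomology, or clipped reads arising from anything but the
simulated junctions. Passing tests therefore demonstrate the correctness of
the indexing, evidence and editing machinery under the stated signal
model — not calling accuracy on real tumors, where depth artifacts can
mimic or mask every signature used here.

## Rendering

Rendering is pure and deterministic: figures are built directly on Agg/SVG
canvases with fixed sizes and no timestamps (SVG uses a fixed hash salt and
a cleared date field), so identical inputs give byte-identical files. Read
stacking is greedy first-free-row over a stable ordering — determinism over
aesthetics — and wide windows draw a deterministic prefix of reads since
the visible rows are capped anyway. Default colors follow the reviewing
convention: loss blue, gain red, neutral black; tumor/normal depth
red/green; BAF red dots; split-read clips yellow on gray bodies; discordant
categories purple (mate unmapped), red (other chromosome), blue (strand),
orange (distance). A plain coordinate ruler stands in for a chromosome
ideogram, keeping the package free of any annotation download; transcript
annotation can be supplied as BED or GFF3.

## Problem sizes used in checks

The automated checks run the four scenarios at the default 2 Mb / depth 30
conditions; module tests use a 200 kb / depth 10 configuration of the same
generator. The split-search oracle comparison uses 1000 random windows of
up to 500 bins (steps, constants, noise, missing values), breakpoint
recovery uses 200 replicates of a unit step at bin 120 under σ = 0.3 noise,
and the edit algebra uses 500 randomized operation sequences.

## Known limitations

* Depth-only logR with no GC/mappability correction; apply upstream
  correction before deriving bigWigs if needed.
* BAF must arrive precomputed; the package does not pileup BAMs for allele
  counts.
* The verdict rule is a documented heuristic, not a calibrated classifier;
  treat *ambiguous* as "review by eye".
* Single tumor/normal pair per session; no cohort indexing.
* One split at a time; simultaneous multi-breakpoint optimization is out of
  scope.
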