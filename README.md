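# cnvcurate

Segment-central review and curation of somatic copy-number variation (CNV)
calls from tumor/normal sequencing, as a scriptable Python library and CLI.

Somatic CNV callers mis-segment routinely: they miss true breakpoints, place
boundaries off by hundreds of base pairs, and emit entirely spurious
segments. Analysts therefore review calls by eye against the underlying
evidence — read depth in tumor and matched normal, the logR ratio
(log2 tumor:normal depth), the B-allele frequency (BAF) of germline
heterozygous SNVs, and breakpoint-scale read signatures (soft-clipped split
reads, discordant pairs) — and then fix the segment list by hand. cnvcurate
makes that workflow reproducible and scriptable: it indexes calls segment by
segment, quantifies the three evidence lines per call, renders static
region and breakpoint images, and edits the segment list through
variance-minimizing splits, merges and undo, exporting curated SEG.

## The model in brief

* A tumor of purity *p* with a region at total copy number *c* has expected
  depth ratio (p·c + 2(1−p))/2, so expected logR = log2 of that; a
  one-allele event splits the het-SNV BAF into modes (1−p+m·p)/(p·c+2(1−p))
  for minor/major allele counts m.
* **Split-point search.** Within a window of binned logR values x₁…xₙ the
  suggested breakpoint is the boundary k minimizing the two-piece constant
  least-squares objective
  SSE(k) = Σ_{i<k}(xᵢ−μ_L)² + Σ_{i≥k}(xᵢ−μ_R)²,
  computed in O(n) with prefix sums and validated against an exhaustive
  O(n²) scan. Multiple breakpoints are found by applying the search
  recursively (greedy binary segmentation).
* **Breakpoint evidence.** Around each segment boundary (±100 bp by
  default) reads are classified: a soft clip ≥ 5 bp makes a split read
  whose clip/match junction coordinate is compared to the breakpoint;
  pair status is the first match of mate-unmapped → mate-on-other-chromosome
  → non-forward-reverse orientation → insert size outside median ± 3·(MAD-
  derived sd). A call is *supported* when the logR line flags together with
  the BAF line or clip support at both breakpoints (tumor-only), *spurious*
  when nothing flags, *ambiguous* otherwise.

A seeded simulator generates mutually consistent SEG + bigWig + BAM
fixtures (one synthetic chromosome `chrS`) for the classic curation
situations — supported call, missed call, spurious call, shifted
boundary — so everything here runs with no external data.

## Worked example

Generate a "missed call" dataset — a real one-copy loss at
chrS:800000–1100000 (purity 0.8) that the caller reported as a single
neutral segment — and recover the hidden breakpoints:

```python
from pathlib import Path
from cnvcurate import simulate, tracks, segio
from cnvcurate.editing import suggest_splits_recursive

truth = simulate.simulate_scenario("missed", Path("demo"), seed=42)
index = segio.read_seg(truth.paths["seg"])
for seg in index:
    print(f"{seg.id}  {seg.chrom}:{seg.start}-{seg.end}  "
          f"mean_logr={seg.mean_logr:+.3f}  {seg.state}")

tumor = tracks.fetch_depth(truth.paths["tumor_depth"], "chrS", 0, 2_000_000)
normal = tracks.fetch_depth(truth.paths["normal_depth"], "chrS", 0, 2_000_000)
logr = tracks.compute_logr(tumor, normal)
for sug in suggest_splits_recursive(logr.values, 2, bin_starts=logr.bin_starts):
    print(f"split at chrS:{sug.position}  sse_reduction={sug.sse_reduction:.1f}  "
          f"means {sug.left_mean:+.3f} | {sug.right_mean:+.3f}")
```

prints

```
seg00001  chrS:0-2000000  mean_logr=-0.111  neutral
split at chrS:800000  sse_reduction=1142.3  means +0.004 | -0.720
split at chrS:1100100  sse_reduction=178.3  means -0.194 | -0.004
```

The emitted call is one 2 Mb neutral segment (its −0.111 mean hides the
event). The recursive split search lands on 800000 exactly and on 1100100 —
one 100 bp bin from the second true breakpoint — and the per-side means
show the neutral flank (≈0) against the loss (≈−0.72, the expectation for a
one-copy loss at purity 0.8). The same workflow is available from the
shell: `cnvcurate simulate`, `list`, `evidence`, `suggest-split`, `split`,
`merge`, `undo`, `render`, `export` (see `cnvcurate --help`); edits are
journaled to an audit log so `undo` works across invocations.

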