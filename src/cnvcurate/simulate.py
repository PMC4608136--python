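"""Fully synthetic, mutually consistent CNV review fixtures.

Generates everything a review session needs — SEG calls, tumor/normal depth
bigWigs, a tumor BAF bigWig, and coordinate-sorted indexed tumor/normal
BAMs — for a single synthetic chromosome ``chrS``, from a seeded config.
The truth (copy numbers, breakpoints, expected logR and BAF) is returned
alongside, and the emitted SEG can be corrupted on purpose (dropped
segment, shifted boundary, added spurious call) to reproduce the classic
curation situations: a well-supported call, a missed call, a spurious call,
and a call with a misplaced breakpoint.

Signal model
------------
A tumor sample of purity p with a region at total copy number c mixes with
diploid normal cells, so the expected depth ratio is (p*c + 2*(1-p)) / 2
and the expected logR is its log2.  For a one-allele event the two germline
heterozygous alleles separate into BAF modes (1-p)/(2-p) and 1/(2-p) (loss)
or, generally, the allele-mixture fractions of a (c-1, 1) genotype.  Depth
noise is lognormal per bin, split evenly between tumor and normal so the
binned logR noise sd equals the configured value exactly.  Reads are
synthetic fixed-sequence pairs with valid flags and CIGARs: the evidence
logic needs flags, clips and positions, not base-level realism.  At every
true breakpoint the tumor BAM carries reads soft-clipped exactly at the
breakpoint, discordant-distance pairs spanning the event, and a sprinkling
of other discordant categories; the normal BAM carries concordant
background only.  Background insert sizes are truncated at +/-2.5 sd so the
k=3 concordance band separates the generated categories cleanly.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pyBigWig
import pysam

from . import segio
from .errors import ValidationError
from .segio import Segment, SegmentIndex, Thresholds, classify_state

CHROM = "chrS"
LOGR_FLOOR = -8.0   # stands in for -inf at copy number 0 in a pure tumor
DEFAULT_SPLIT_READS = 6       # soft-clipped reads placed at each true breakpoint
DEFAULT_DISCORDANT_PAIRS = 4  # discordant-distance pairs spanning each event


def expected_logr(copy_number: float, purity: float) -> float:
    """Expected log2 tumor:normal depth ratio of a region at total copy ``c``."""
    if copy_number < 0:
        raise ValueError("copy number must be >= 0")
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    mix = purity * copy_number + 2.0 * (1.0 - purity)
    if mix == 0:
        return LOGR_FLOOR
    return max(math.log2(mix / 2.0), LOGR_FLOOR)


def expected_baf(copy_number: int, purity: float) -> tuple[float, ...]:
    """Expected BAF modes at germline het SNVs inside a CNV region.

    Copy-neutral regions keep the single balanced mode 0.5.  Other copy
    numbers assume a single-allele event, i.e. a (c-1, 1) allele genotype in
    the tumor cells (for c = 1 that is (1, 0): loss of heterozygosity),
    mixed with the diploid (1, 1) normal at purity ``p``.
    """
    if not 0 < purity <= 1:
        raise ValueError("purity must be in (0, 1]")
    c = int(copy_number)
    if c == 2:
        return (0.5,)
    minor = 0 if c < 2 else 1
    major = max(c - minor, 0)
    total = purity * c + 2.0 * (1.0 - purity)
    if total == 0:
        return (0.5,)
    lo = (purity * minor + (1.0 - purity)) / total
    hi = (purity * major + (1.0 - purity)) / total
    return (lo, hi)


@dataclass(frozen=True)
class CnvEvent:
    """One somatic CNV: [start, end) at ``copy_number`` total copies."""

    start: int
    end: int
    copy_number: int


@dataclass(frozen=True)
class DropSegment:
    """SEG corruption: the caller misses segment ``index`` entirely."""

    index: int


@dataclass(frozen=True)
class ShiftBoundary:
    """SEG corruption: one boundary of segment ``index`` off by ``delta`` bp."""

    index: int
    side: str       # "left" or "right"
    delta: int


@dataclass(frozen=True)
class AddSpurious:
    """SEG corruption: an entirely false call with a fabricated mean."""

    start: int
    end: int
    mean: float


@dataclass
class SimConfig:
    """Study conditions for one synthetic tumor/normal pair."""

    ref_length: int = 2_000_000
    bin_size: int = 100
    diploid_depth: float = 30.0
    purity: float = 0.8
    cnv_events: tuple = (CnvEvent(800_000, 1_100_000, 1),)
    het_snv_spacing: int = 500
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    noise_sd: float = 0.15        # sd of binned logR noise, logR units
    seed: int = 0
    seg_errors: tuple = ()

    def validate(self) -> None:
        if not 0 < self.purity <= 1:
            raise ValidationError(f"purity must be in (0, 1], got {self.purity}")
        events = sorted(self.cnv_events, key=lambda e: e.start)
        prev_end = 0
        for ev in events:
            if not (0 <= ev.start < ev.end <= self.ref_length):
                raise ValidationError(f"event {ev} outside reference [0, {self.ref_length})")
            if ev.start < prev_end:
                raise ValidationError(f"overlapping CNV events at {ev}")
            if ev.copy_number < 0:
                raise ValidationError(f"negative copy number in {ev}")
            prev_end = ev.end


@dataclass
class TruthSegment:
    start: int
    end: int
    copy_number: int
    logr: float
    baf_modes: tuple


@dataclass
class TruthSet:
    """Ground truth plus the paths of every emitted file."""

    config: SimConfig
    segments: list            # TruthSegment tiling of the reference
    breakpoints: list         # interior true breakpoint coordinates
    emitted: list             # (start, end, mean) tuples actually written to SEG
    paths: dict               # name -> file path

    def to_json(self) -> str:
        payload = {
            "chrom": CHROM,
            "config": asdict(self.config),
            "segments": [asdict(s) for s in self.segments],
            "breakpoints": self.breakpoints,
            "emitted": self.emitted,
            "paths": {k: str(v) for k, v in self.paths.items()},
        }
        return json.dumps(payload, indent=2)


def truth_tiling(config: SimConfig) -> list[TruthSegment]:
    """Tile the reference into neutral and event segments, in order."""
    segs: list[TruthSegment] = []

    def push(start: int, end: int, cn: int) -> None:
        if start < end:
            segs.append(TruthSegment(start, end, cn,
                                     expected_logr(cn, config.purity),
                                     expected_baf(cn, config.purity)))

    cursor = 0
    for ev in sorted(config.cnv_events, key=lambda e: e.start):
        push(cursor, ev.start, 2)
        push(ev.start, ev.end, ev.copy_number)
        cursor = ev.end
    push(cursor, config.ref_length, 2)
    return segs


def _apply_seg_errors(segments: list[TruthSegment],
                      errors: Sequence) -> list[tuple[int, int, float]]:
    """Corrupt the truth tiling into the SEG the 'caller' emits."""
    rows: list[list] = [[s.start, s.end, s.logr] for s in segments]
    for err in errors:
        if isinstance(err, DropSegment):
            i = err.index
            lo = i - 1 if i > 0 else i
            hi = i + 1 if i + 1 < len(rows) else i
            group = rows[lo:hi + 1]
            total = sum(e - s for s, e, _ in group)
            mean = sum((e - s) * m for s, e, m in group) / total
            rows[lo:hi + 1] = [[group[0][0], group[-1][1], mean]]
        elif isinstance(err, ShiftBoundary):
            i = err.index
            if err.side == "left":
                rows[i][0] += err.delta
                if i > 0:
                    rows[i - 1][1] += err.delta
            else:
                rows[i][1] += err.delta
                if i + 1 < len(rows):
                    rows[i + 1][0] += err.delta
        elif isinstance(err, AddSpurious):
            for i, (s, e, m) in enumerate(rows):
                if s <= err.start and err.end <= e:
                    rows[i:i + 1] = [[s, err.start, m],
                                     [err.start, err.end, err.mean],
                                     [err.end, e, m]]
                    break
            else:
                raise ValidationError(
                    f"spurious call {err.start}-{err.end} not inside one segment"
                )
        else:
            raise ValidationError(f"unknown seg error {err!r}")
    return [(int(s), int(e), float(m)) for s, e, m in rows if e > s]


def _depth_ratio_per_bin(config: SimConfig,
                         segments: Sequence[TruthSegment]) -> np.ndarray:
    n_bins = config.ref_length // config.bin_size
    ratio = np.ones(n_bins)
    for seg in segments:
        b0, b1 = seg.start // config.bin_size, seg.end // config.bin_size
        ratio[b0:b1] = 2.0 ** seg.logr
    return ratio


def _write_bigwig(path, values=None, span=None, step=None,
                  positions=None, length: int = 0) -> None:
    bw = pyBigWig.open(str(path), "w")
    bw.addHeader([(CHROM, length)])
    if positions is not None:
        bw.addEntries(CHROM, [int(p) for p in positions],
                      values=[float(v) for v in values], span=1)
    elif values is not None and len(values):
        bw.addEntries(CHROM, 0, values=[float(v) for v in values],
                      span=span, step=step)
    bw.close()


def _sam_record(name: str, flag: int, pos0: int, cigar: str, pnext0: int,
                tlen: int, qlen: int, rnext: str = "=") -> tuple:
    seq = "A" * qlen
    qual = "I" * qlen
    line = (f"{name}\t{flag}\t{CHROM}\t{pos0 + 1}\t60\t{cigar}\t{rnext}"
            f"\t{pnext0 + 1}\t{tlen}\t{seq}\t{qual}")
    return (pos0, name, flag, line)


def _truncated_insert(rng: np.random.Generator, mean: float, sd: float) -> int:
    while True:
        val = rng.normal(mean, sd)
        if abs(val - mean) <= 2.5 * sd:
            return max(int(round(val)), 1)


def _background_pairs(records: list, rng: np.random.Generator, config: SimConfig,
                      start: int, end: int, depth: float, tag: str) -> None:
    rl = config.read_length
    length = end - start
    n_pairs = int(round(length * depth / (2 * rl)))
    for i in range(n_pairs):
        insert = _truncated_insert(rng, config.insert_mean, config.insert_sd)
        insert = max(insert, rl)
        p1 = int(rng.integers(start, max(start + 1, end - insert)))
        p2 = min(p1 + insert - rl, config.ref_length - rl)
        name = f"{tag}{start}_{i}"
        records.append(_sam_record(name, 99, p1, f"{rl}M", p2, insert, rl))
        records.append(_sam_record(name, 147, p2, f"{rl}M", p1, -insert, rl))


def _breakpoint_reads(records: list, config: SimConfig, bp_index: int,
                      pos: int) -> None:
    """Split reads clipped exactly at ``pos`` plus other discordant categories."""
    rl = config.read_length
    insert = int(config.insert_mean)
    for i in range(DEFAULT_SPLIT_READS):
        name = f"sp{bp_index}_{i}"
        matched = 50 + 4 * i
        clipped = rl - matched
        if i % 2 == 0:
            # clip on the right: alignment ends exactly at the breakpoint
            p1 = pos - matched
            mate = min(p1 + insert - rl, config.ref_length - rl)
            records.append(_sam_record(name, 99, p1, f"{matched}M{clipped}S",
                                       mate, insert, rl))
            records.append(_sam_record(name, 147, mate, f"{rl}M", p1, -insert, rl))
        else:
            # clip on the left: alignment starts exactly at the breakpoint
            mate = max(pos - insert + rl, 0)
            records.append(_sam_record(name, 83, pos, f"{clipped}S{matched}M",
                                       mate, -insert, matched + clipped))
            records.append(_sam_record(name, 163, mate, f"{rl}M", pos, insert, rl))
    # one pair in non-forward-reverse orientation
    records.append(_sam_record(f"ds{bp_index}", 65, pos + 20, f"{rl}M",
                               pos + 400, 380 + rl, rl))
    records.append(_sam_record(f"ds{bp_index}", 129, pos + 400, f"{rl}M",
                               pos + 20, -(380 + rl), rl))
    # one read whose mate failed to map
    records.append(_sam_record(f"du{bp_index}", 73, max(pos - 60, 0), f"{rl}M",
                               max(pos - 60, 0), 0, rl))


def _event_spanning_pairs(records: list, config: SimConfig, ev_index: int,
                          ev: CnvEvent) -> None:
    """Discordant-distance pairs whose mates flank the event on both sides."""
    rl = config.read_length
    for i in range(DEFAULT_DISCORDANT_PAIRS):
        name = f"dd{ev_index}_{i}"
        p1 = max(ev.start - 135 + 15 * i, 0)
        p2 = min(ev.end + 20 + 15 * i, config.ref_length - rl)
        tlen = p2 + rl - p1
        records.append(_sam_record(name, 97, p1, f"{rl}M", p2, tlen, rl))
        records.append(_sam_record(name, 145, p2, f"{rl}M", p1, -tlen, rl))


def _write_bam(records: list, sam_path: Path, bam_path: Path,
               ref_length: int) -> None:
    records.sort(key=lambda r: (r[0], r[1], r[2]))
    with open(sam_path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:coordinate\n")
        fh.write(f"@SQ\tSN:{CHROM}\tLN:{ref_length}\n")
        for rec in records:
            fh.write(rec[3] + "\n")
    pysam.samtools.view("-b", "--no-PG", "-o", str(bam_path), str(sam_path),
                        catch_stdout=False)
    os.remove(sam_path)
    pysam.index(str(bam_path))


def simulate_dataset(config: SimConfig, outdir) -> TruthSet:
    """Generate the full fixture set for one tumor/normal pair.

    Writes tumor/normal depth bigWigs, the tumor BAF bigWig, sorted and
    indexed tumor/normal BAMs, the (possibly corrupted) SEG, and a truth
    JSON into ``outdir``.  All randomness flows from ``config.seed``, and
    repeated runs with the same config are byte-identical.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)
    segments = truth_tiling(config)
    n_bins = config.ref_length // config.bin_size

    # --- depth tracks: lognormal noise split evenly between the two samples
    per_sample_sd = config.noise_sd / math.sqrt(2.0)
    ratio = _depth_ratio_per_bin(config, segments)
    normal_depth = config.diploid_depth * 2.0 ** rng.normal(0.0, per_sample_sd, n_bins)
    tumor_depth = config.diploid_depth * ratio \
        * 2.0 ** rng.normal(0.0, per_sample_sd, n_bins)
    paths = {
        "tumor_depth": outdir / "tumor_depth.bw",
        "normal_depth": outdir / "normal_depth.bw",
        "baf": outdir / "tumor_baf.bw",
        "tumor_bam": outdir / "tumor.bam",
        "normal_bam": outdir / "normal.bam",
        "seg": outdir / "calls.seg",
        "truth": outdir / "truth.json",
    }
    _write_bigwig(paths["normal_depth"], values=normal_depth,
                  span=config.bin_size, step=config.bin_size,
                  length=config.ref_length)
    _write_bigwig(paths["tumor_depth"], values=tumor_depth,
                  span=config.bin_size, step=config.bin_size,
                  length=config.ref_length)

    # --- BAF at evenly spaced germline het SNVs, binomial at local depth
    positions = np.arange(config.het_snv_spacing, config.ref_length,
                          config.het_snv_spacing, dtype=np.int64)
    baf_values = np.empty(len(positions))
    seg_iter = iter(segments)
    current = next(seg_iter)
    for i, pos in enumerate(positions):
        while pos >= current.end:
            current = next(seg_iter)
        modes = current.baf_modes
        mode = modes[0] if len(modes) == 1 else modes[int(rng.integers(0, 2))]
        local_depth = max(int(round(config.diploid_depth * 2.0 ** current.logr)), 1)
        baf_values[i] = rng.binomial(local_depth, mode) / local_depth
    _write_bigwig(paths["baf"], values=baf_values, positions=positions,
                  length=config.ref_length)

    # --- BAMs
    breakpoints = sorted({b for ev in config.cnv_events for b in (ev.start, ev.end)
                          if 0 < b < config.ref_length})
    tumor_records: list = []
    normal_records: list = []
    for seg in segments:
        _background_pairs(normal_records, rng, config, seg.start, seg.end,
                          config.diploid_depth, "bg")
        _background_pairs(tumor_records, rng, config, seg.start, seg.end,
                          config.diploid_depth * 2.0 ** seg.logr, "bg")
    for bi, pos in enumerate(breakpoints):
        _breakpoint_reads(tumor_records, config, bi, pos)
    for ei, ev in enumerate(sorted(config.cnv_events, key=lambda e: e.start)):
        _event_spanning_pairs(tumor_records, config, ei, ev)
    _write_bam(tumor_records, outdir / "tumor.sam", paths["tumor_bam"],
               config.ref_length)
    _write_bam(normal_records, outdir / "normal.sam", paths["normal_bam"],
               config.ref_length)

    # --- emitted SEG (possibly corrupted truth)
    emitted = _apply_seg_errors(segments, config.seg_errors)
    index = SegmentIndex()
    for start, end, mean in emitted:
        index.add(Segment(chrom=CHROM, start=start, end=end, mean_logr=mean,
                          n_bins=max(1, (end - start) // config.bin_size),
                          state=classify_state(mean), sample="sim"))
    segio.write_seg(index, paths["seg"])

    truth = TruthSet(config=config, segments=segments, breakpoints=breakpoints,
                     emitted=emitted, paths=paths)
    with open(paths["truth"], "w") as fh:
        fh.write(truth.to_json())
    return truth


SCENARIOS = ("supported", "missed", "spurious", "shifted")


def scenario_config(name: str, seed: int = 0, **overrides) -> SimConfig:
    """Study conditions for the four classic curation situations.

    ``supported``: a clean one-copy loss, correctly called.
    ``missed``: the same loss, but the caller reports one neutral segment.
    ``spurious``: flat data with a fabricated loss call.
    ``shifted``: the loss called with its left boundary 500 bp off.
    """
    event = CnvEvent(800_000, 1_100_000, 1)
    if name == "supported":
        cfg = SimConfig(cnv_events=(event,), seg_errors=(), seed=seed)
    elif name == "missed":
        cfg = SimConfig(cnv_events=(event,), seg_errors=(DropSegment(1),), seed=seed)
    elif name == "spurious":
        cfg = SimConfig(cnv_events=(),
                        seg_errors=(AddSpurious(900_000, 1_000_000, -0.6),),
                        seed=seed)
    elif name == "shifted":
        cfg = SimConfig(cnv_events=(event,),
                        seg_errors=(ShiftBoundary(1, "left", -500),), seed=seed)
    else:
        raise ValueError(f"unknown scenario {name!r}; expected one of {SCENARIOS}")
    for key, val in overrides.items():
        setattr(cfg, key, val)
    return cfg


def simulate_scenario(name: str, outdir, seed: int = 0, **overrides) -> TruthSet:
    """Generate one named scenario into ``outdir``."""
    return simulate_dataset(scenario_config(name, seed=seed, **overrides), outdir)
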