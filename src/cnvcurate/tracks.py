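"""Binned read-depth and BAF signal from bigWig, and the derived logR track.

The logR ratio is log2 of tumor over matched-normal read depth, computed on
a shared fixed-width binning; copy-neutral loci sit near 0.  B-allele
fractions (BAF) arrive precomputed as a sparse bigWig with one value per
germline heterozygous SNV position.

Missing data is explicit: bins with no covered bases are NaN, and every
downstream statistic skips NaN bins.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pyBigWig

from .errors import EmptyIntervalError, SegmentLookupError, ValidationError

DEFAULT_BIN_SIZE = 100
DEFAULT_PSEUDOCOUNT = 0.5


@dataclass
class DepthTrack:
    """Mean read depth per fixed-width bin over one interval of one chromosome.

    ``values[i]`` is the mean depth over the covered bases of bin
    ``[start + i*bin_size, start + (i+1)*bin_size)``; NaN marks bins with no
    coverage.  Uncovered bases inside a partially covered bin do not count as
    zeros: the statistic is the mean over covered bases only.
    """

    chrom: str
    start: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        finite = self.values[~np.isnan(self.values)]
        if finite.size and (finite < 0).any():
            raise ValidationError("depth values must be non-negative")

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) * self.bin_size

    @property
    def end(self) -> int:
        return self.start + len(self.values) * self.bin_size


@dataclass
class LogRTrack:
    """log2 tumor:normal depth ratio on the binning of its parent depth tracks."""

    chrom: str
    start: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)

    @property
    def bin_starts(self) -> np.ndarray:
        return self.start + np.arange(len(self.values)) * self.bin_size

    @property
    def end(self) -> int:
        return self.start + len(self.values) * self.bin_size


@dataclass
class BafPoints:
    """B-allele fractions at germline heterozygous SNV positions (0-based)."""

    chrom: str
    positions: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.values = np.asarray(self.values, dtype=float)
        if len(self.positions) != len(self.values):
            raise ValidationError("positions and values must have equal length")
        if len(self.positions) > 1 and not (np.diff(self.positions) > 0).all():
            raise ValidationError("BAF positions must be strictly increasing")
        bad = np.where((self.values < 0) | (self.values > 1))[0]
        if bad.size:
            raise ValidationError(
                f"BAF value {self.values[bad[0]]} at position "
                f"{self.chrom}:{self.positions[bad[0]]} outside [0, 1]"
            )

    def __len__(self) -> int:
        return len(self.positions)

    def in_interval(self, start: int, end: int) -> "BafPoints":
        mask = (self.positions >= start) & (self.positions < end)
        return BafPoints(self.chrom, self.positions[mask], self.values[mask])


def fetch_depth(bigwig_path, chrom: str, start: int, end: int,
                bin_size: int = DEFAULT_BIN_SIZE) -> DepthTrack:
    """Extract a binned depth track from a bigWig file.

    Each bin value is the exact mean of the base-level signal over the bin's
    covered bases; bins with no data are NaN.  The last bin may extend past
    ``end`` to keep all bins full width.
    """
    if bin_size < 1:
        raise ValueError(f"bin_size must be >= 1, got {bin_size}")
    if start < 0 or start >= end:
        raise ValueError(f"invalid interval {start}-{end}")
    with pyBigWig.open(str(bigwig_path)) as bw:
        chroms = bw.chroms()
        if chrom not in chroms:
            raise SegmentLookupError(
                f"chromosome {chrom!r} absent from {bigwig_path} "
                f"(has {sorted(chroms)})"
            )
        clen = chroms[chrom]
        n_bins = -(-(end - start) // bin_size)
        base = np.full(n_bins * bin_size, np.nan)
        hi = min(start + n_bins * bin_size, clen)
        if start < hi:
            base[:hi - start] = bw.values(chrom, start, hi, numpy=True)
    tiles = base.reshape(n_bins, bin_size)
    covered = (~np.isnan(tiles)).sum(axis=1)
    with np.errstate(invalid="ignore"):
        values = np.where(covered > 0, np.nansum(tiles, axis=1) / covered, np.nan)
    return DepthTrack(chrom=chrom, start=start, bin_size=bin_size, values=values)


def compute_logr(tumor: DepthTrack, normal: DepthTrack,
                 pseudocount: float = DEFAULT_PSEUDOCOUNT,
                 scale_factor: float = 1.0) -> LogRTrack:
    """Derive the logR track: log2((T + c) / (s * (N + c))).

    ``pseudocount`` c stabilizes low-depth bins; ``scale_factor`` s absorbs
    library-size differences (see :func:`median_scale_factor`).  Bins are NaN
    where either parent is NaN or the denominator is zero.
    """
    if (tumor.chrom, tumor.start, tumor.bin_size, len(tumor.values)) != \
            (normal.chrom, normal.start, normal.bin_size, len(normal.values)):
        raise ValidationError("tumor and normal depth tracks have mismatched binning")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    if scale_factor <= 0:
        raise ValueError("scale_factor must be > 0")
    num = tumor.values + pseudocount
    den = scale_factor * (normal.values + pseudocount)
    with np.errstate(divide="ignore", invalid="ignore"):
        values = np.where(den > 0, np.log2(num / den), np.nan)
    values[np.isnan(tumor.values) | np.isnan(normal.values)] = np.nan
    return LogRTrack(chrom=tumor.chrom, start=tumor.start,
                     bin_size=tumor.bin_size, values=values)


def median_scale_factor(tumor: DepthTrack, normal: DepthTrack) -> float:
    """Library-size normalizer: median(tumor) / median(normal) over non-missing bins."""
    t = np.nanmedian(tumor.values)
    n = np.nanmedian(normal.values)
    if not np.isfinite(t) or not np.isfinite(n) or n == 0:
        raise ValidationError("cannot derive a median scale factor from empty tracks")
    return float(t / n)


def fetch_baf(bigwig_path, chrom: str, start: int, end: int) -> BafPoints:
    """Read sparse per-base BAF values: one point per covered base in the interval."""
    with pyBigWig.open(str(bigwig_path)) as bw:
        if chrom not in bw.chroms():
            raise SegmentLookupError(f"chromosome {chrom!r} absent from {bigwig_path}")
        intervals = bw.intervals(chrom, start, min(end, bw.chroms()[chrom])) or ()
    positions: list[int] = []
    values: list[float] = []
    for ival_start, ival_end, value in intervals:
        for pos in range(max(ival_start, start), min(ival_end, end)):
            positions.append(pos)
            values.append(value)
    return BafPoints(chrom=chrom, positions=np.array(positions, dtype=np.int64),
                     values=np.array(values, dtype=float))


def interval_mean_logr(track: LogRTrack, start: int, end: int) -> float:
    """Unweighted mean logR over the track bins inside ``[start, end)``.

    A bin belongs to the interval iff its midpoint does (deterministic
    handling of partial bins); NaN bins are skipped.
    """
    midpoints = track.bin_starts + track.bin_size / 2.0
    mask = (midpoints >= start) & (midpoints < end) & ~np.isnan(track.values)
    if not mask.any():
        raise EmptyIntervalError(
            f"no usable logR bins in {track.chrom}:{start}-{end}"
        )
    return float(np.mean(track.values[mask]))
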