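"""Segment data model, SEG I/O, state classification and the segment-central index.

Somatic CNV callers report their results as a segmented-data (SEG) table:
one row per genomic interval with a mean log2 tumor:normal depth ratio
(``seg.mean``).  This module parses and writes that table, classifies each
segment as copy *gain*, *loss* or *neutral* against configurable logR
thresholds, and keeps segments in a per-chromosome ordered index so that a
review session can navigate call-by-call rather than locus-by-locus.

Coordinates are 0-based half-open internally.  On disk two dialects are
supported: ``one_based_inclusive`` (the common SEG convention, default) and
``zero_based_half_open``.
"""

from __future__ import annotations

import itertools
import re
from bisect import bisect_left, insort
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator, Optional

from .errors import ParseError, SegmentLookupError, ValidationError

GAIN = "gain"
LOSS = "loss"
NEUTRAL = "neutral"
STATES = (GAIN, LOSS, NEUTRAL)

DIALECTS = ("one_based_inclusive", "zero_based_half_open")


@dataclass(frozen=True)
class Thresholds:
    """LogR cutoffs separating gain/neutral/loss. ``loss_thr < 0 < gain_thr``."""

    gain_thr: float = 0.2
    loss_thr: float = -0.2

    def __post_init__(self) -> None:
        if not (self.loss_thr < 0.0 < self.gain_thr):
            raise ValidationError(
                f"invalid thresholds: need loss_thr < 0 < gain_thr, "
                f"got loss_thr={self.loss_thr}, gain_thr={self.gain_thr}"
            )


def classify_state(mean_logr: float, thresholds: Thresholds = Thresholds()) -> str:
    """Classify a segment mean logR as gain/loss/neutral.

    Boundary values are inclusive: ``mean_logr >= gain_thr`` is a gain and
    ``mean_logr <= loss_thr`` is a loss.
    """
    x = float(mean_logr)
    if x != x or x in (float("inf"), float("-inf")):
        raise ValidationError(f"cannot classify non-finite mean logR: {mean_logr!r}")
    if x >= thresholds.gain_thr:
        return GAIN
    if x <= thresholds.loss_thr:
        return LOSS
    return NEUTRAL


@dataclass
class Segment:
    """One called CNV interval, 0-based half-open, with its mean logR."""

    chrom: str
    start: int
    end: int
    mean_logr: float
    n_bins: Optional[int] = None
    state: str = NEUTRAL
    sample: str = "sample"
    id: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValidationError(
                f"segment {self.chrom}:{self.start}-{self.end}: start must be < end"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def key(self) -> tuple:
        """Identity-free field tuple used for index equality.

        Means compare at the 6-decimal precision of the on-disk format, so
        equality is preserved across a write/read round trip.
        """
        return (self.chrom, self.start, self.end, round(float(self.mean_logr), 6),
                self.n_bins, self.state, self.sample)

    def __str__(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}({self.state})"


def _natural_key(chrom: str) -> tuple:
    parts = re.split(r"(\d+)", chrom)
    return tuple(int(p) if p.isdigit() else p for p in parts)


class SegmentIndex:
    """Per-chromosome ordered, non-overlapping segment lists.

    Chromosomes iterate in natural sort order (chr2 before chr10); within a
    chromosome segments are sorted by start and pairwise non-overlapping.
    Every segment gets a stable string identifier on insertion.
    """

    def __init__(self, segments: Iterable[Segment] = ()) -> None:
        self._by_id: dict[str, Segment] = {}
        # chrom -> sorted list of (start, id)
        self._by_chrom: dict[str, list[tuple[int, str]]] = {}
        self._counter = itertools.count(1)
        for seg in segments:
            self.add(seg)

    def add(self, segment: Segment, seg_id: Optional[str] = None) -> str:
        """Insert a segment, validating non-overlap; returns its identifier."""
        if seg_id is None:
            seg_id = segment.id if segment.id is not None else f"seg{next(self._counter):05d}"
        if seg_id in self._by_id:
            raise ValidationError(f"duplicate segment id {seg_id!r}")
        entries = self._by_chrom.setdefault(segment.chrom, [])
        pos = bisect_left(entries, (segment.start, ""))
        for neighbor_pos in (pos - 1, pos):
            if 0 <= neighbor_pos < len(entries):
                other = self._by_id[entries[neighbor_pos][1]]
                if segment.start < other.end and other.start < segment.end:
                    raise ValidationError(
                        f"overlapping segments on {segment.chrom}: "
                        f"{other} and {segment.chrom}:{segment.start}-{segment.end}"
                    )
        segment = replace(segment, id=seg_id)
        self._by_id[seg_id] = segment
        insort(entries, (segment.start, seg_id))
        return seg_id

    def remove(self, seg_id: str) -> Segment:
        seg = self.get(seg_id)
        entries = self._by_chrom[seg.chrom]
        entries.remove((seg.start, seg_id))
        if not entries:
            del self._by_chrom[seg.chrom]
        del self._by_id[seg_id]
        return seg

    def get(self, seg_id: str) -> Segment:
        try:
            return self._by_id[seg_id]
        except KeyError:
            raise SegmentLookupError(f"unknown segment id {seg_id!r}") from None

    def __contains__(self, seg_id: str) -> bool:
        return seg_id in self._by_id

    def __len__(self) -> int:
        return len(self._by_id)

    @property
    def chromosomes(self) -> list[str]:
        return sorted(self._by_chrom, key=_natural_key)

    def segments(self, chrom: Optional[str] = None) -> list[Segment]:
        if chrom is not None:
            return [self._by_id[i] for _, i in self._by_chrom.get(chrom, [])]
        return [s for c in self.chromosomes for s in self.segments(c)]

    def __iter__(self) -> Iterator[Segment]:
        return iter(self.segments())

    def adjacent(self, seg_id: str) -> tuple[Optional[Segment], Optional[Segment]]:
        """Nearest same-chromosome neighbors of a segment, or None at the ends."""
        seg = self.get(seg_id)
        entries = self._by_chrom[seg.chrom]
        pos = entries.index((seg.start, seg_id))
        left = self._by_id[entries[pos - 1][1]] if pos > 0 else None
        right = self._by_id[entries[pos + 1][1]] if pos + 1 < len(entries) else None
        return left, right

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SegmentIndex):
            return NotImplemented
        return [s.key() for s in self] == [t.key() for t in other]

    def copy(self) -> "SegmentIndex":
        clone = SegmentIndex()
        for seg in self:
            clone.add(replace(seg))
        clone._counter = itertools.count(next(self._counter))
        return clone


def adjacent(index: SegmentIndex, segment_id: str):
    """Module-level alias for :meth:`SegmentIndex.adjacent`."""
    return index.adjacent(segment_id)


def display_window(segment: Segment, flank_fraction: float,
                   chrom_length: Optional[int] = None) -> tuple[int, int]:
    """Genomic window around a segment with fractional flanking context.

    The flank on each side is ``floor(flank_fraction * segment_length)``
    bases, clipped at 0 and at ``chrom_length`` when known.
    """
    if flank_fraction < 0:
        raise ValueError(f"flank_fraction must be >= 0, got {flank_fraction}")
    flank = int(flank_fraction * segment.length)
    lo = max(0, segment.start - flank)
    hi = segment.end + flank
    if chrom_length is not None:
        hi = min(hi, chrom_length)
    return lo, hi


def _to_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "one_based_inclusive":
        return start - 1, end
    return start, end


def _from_internal(start: int, end: int, dialect: str) -> tuple[int, int]:
    if dialect == "one_based_inclusive":
        return start + 1, end
    return start, end


def _check_dialect(dialect: str) -> None:
    if dialect not in DIALECTS:
        raise ValueError(f"unknown SEG dialect {dialect!r}; expected one of {DIALECTS}")


def read_seg(path, dialect: str = "one_based_inclusive",
             thresholds: Thresholds = Thresholds()) -> SegmentIndex:
    """Read a SEG table into a :class:`SegmentIndex`.

    Columns: sample, chrom, start, end, [n_bins], seg.mean — whitespace- or
    tab-delimited, 5 or 6 columns, optional header auto-detected.  States are
    assigned from ``thresholds``.  Overlapping records are rejected.
    """
    _check_dialect(dialect)
    path = Path(path)
    index = SegmentIndex()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) not in (5, 6):
                raise ParseError(
                    f"{path}:{lineno}: expected 5 or 6 columns, got {len(fields)}"
                )
            try:
                start, end = int(fields[2]), int(fields[3])
                n_bins = int(fields[4]) if len(fields) == 6 else None
                mean = float(fields[-1])
            except ValueError:
                if lineno == 1 and len(index) == 0:
                    continue  # tolerated header line
                raise ParseError(f"{path}:{lineno}: malformed record: {line!r}") from None
            istart, iend = _to_internal(start, end, dialect)
            try:
                seg = Segment(chrom=fields[1], start=istart, end=iend,
                              mean_logr=mean, n_bins=n_bins,
                              state=classify_state(mean, thresholds),
                              sample=fields[0])
                index.add(seg)
            except ValidationError as exc:
                raise ValidationError(f"{path}:{lineno}: {exc}") from None
    return index


def write_seg(index: SegmentIndex, path, dialect: str = "one_based_inclusive") -> None:
    """Write a SEG table; ``read_seg`` of the result reproduces the index."""
    _check_dialect(dialect)
    with open(path, "w") as fh:
        fh.write("ID\tchrom\tloc.start\tloc.end\tnum.mark\tseg.mean\n")
        for seg in index:
            start, end = _from_internal(seg.start, seg.end, dialect)
            n_bins = "" if seg.n_bins is None else str(seg.n_bins)
            row = [seg.sample, seg.chrom, str(start), str(end)]
            if n_bins:
                row.append(n_bins)
            row.append(f"{seg.mean_logr:.6f}")
            fh.write("\t".join(row) + "\n")
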