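"""Curation engine: split-point suggestion, split/merge edits, undo, save/reload.

Mis-segmentation — missed breakpoints, spurious breakpoints, wrong
boundaries — is fixed by splitting and merging segments.  The split-point
search fits a two-piece constant model to the logR bins of a window and
returns the boundary minimizing the total within-segment sum of squared
errors (SSE); this is the "minimize the variation on both sides" criterion
of classical least-squares change-point detection.  SSE rather than a sum
of variances is used deliberately: dividing each side's squared error by its
size degenerately rewards single-bin segments.

Every edit records enough inverse information to be undone exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np

from . import segio
from .errors import (AdjacencyError, EmptyIntervalError, InsufficientDataError,
                     NothingToUndoError, ValidationError)
from .segio import Segment, SegmentIndex, Thresholds, classify_state
from .tracks import LogRTrack, interval_mean_logr

DEFAULT_MIN_SEG_BINS = 2


@dataclass(frozen=True)
class SplitSuggestion:
    """Best two-piece constant split of a window of logR bins.

    ``index`` is the bin boundary k (between bins k-1 and k); ``position``
    is that boundary mapped to a genomic coordinate when the window carries
    coordinates, else equal to ``index``.  ``sse_reduction`` is the drop in
    total squared error relative to the no-split fit; a value near zero
    means the window gives no real support for a breakpoint, flagged in
    ``note``.
    """

    index: int
    position: int
    sse_reduction: float
    left_mean: float
    right_mean: float
    note: str = ""


def _sse_from_moments(total: float, total_sq: float, n: int) -> float:
    if n == 0:
        return 0.0
    return total_sq - total * total / n


def suggest_split(values: Sequence[float],
                  min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
                  bin_starts: Optional[Sequence[int]] = None) -> SplitSuggestion:
    """Find the split index minimizing total within-side SSE.

    NaN values are missing: they contribute to neither the sums nor the
    per-side size counts.  Candidate boundaries k require at least
    ``min_seg_bins`` non-missing bins on each side; ties break toward the
    smallest k.  Runs in O(n) via prefix sums.
    """
    x = np.asarray(values, dtype=float)
    if min_seg_bins < 1:
        raise ValueError("min_seg_bins must be >= 1")
    present = ~np.isnan(x)
    n_present = int(present.sum())
    if n_present < 2 * min_seg_bins:
        raise InsufficientDataError(
            f"need >= {2 * min_seg_bins} non-missing bins, got {n_present}"
        )
    filled = np.where(present, x, 0.0)
    csum = np.concatenate([[0.0], np.cumsum(filled)])
    csq = np.concatenate([[0.0], np.cumsum(filled * filled)])
    cnt = np.concatenate([[0], np.cumsum(present)])

    grand_sse = _sse_from_moments(csum[-1], csq[-1], n_present)

    # tie tolerance scales with the total sum of squares: SSE values are
    # differences of moments of that magnitude, so their rounding noise is
    # proportional to it; anything closer than this is a tie, broken toward
    # the smallest k
    tol = 1e-12 * (1.0 + csq[-1])
    best_k = -1
    best_sse = np.inf
    for k in range(1, len(x)):
        n_left = int(cnt[k])
        n_right = n_present - n_left
        if n_left < min_seg_bins or n_right < min_seg_bins:
            continue
        sse = (_sse_from_moments(csum[k], csq[k], n_left)
               + _sse_from_moments(csum[-1] - csum[k], csq[-1] - csq[k], n_right))
        if sse < best_sse - tol:
            best_sse, best_k = sse, k
    if best_k < 0:
        raise InsufficientDataError("no admissible split boundary")

    left_mean = csum[best_k] / cnt[best_k]
    right_mean = (csum[-1] - csum[best_k]) / (n_present - cnt[best_k])
    reduction = max(grand_sse - best_sse, 0.0)
    note = ""
    if reduction <= 1e-9 * max(1.0, grand_sse):
        note = "low confidence: split barely reduces within-segment variation"
    position = int(bin_starts[best_k]) if bin_starts is not None else best_k
    return SplitSuggestion(index=best_k, position=position,
                           sse_reduction=float(reduction),
                           left_mean=float(left_mean), right_mean=float(right_mean),
                           note=note)


def suggest_splits_recursive(values: Sequence[float], n_splits: int,
                             min_seg_bins: int = DEFAULT_MIN_SEG_BINS,
                             bin_starts: Optional[Sequence[int]] = None
                             ) -> list[SplitSuggestion]:
    """Greedy binary segmentation: apply the single-split search recursively.

    At each round the sub-window whose best split gives the largest SSE
    reduction is split, until ``n_splits`` boundaries are placed or no
    sub-window admits one.  This mirrors a curator recursively applying the
    split function inside each sub-window to resolve multiple breakpoints.
    """
    x = np.asarray(values, dtype=float)
    pieces: list[tuple[int, int]] = [(0, len(x))]
    out: list[SplitSuggestion] = []
    for _ in range(n_splits):
        best: Optional[tuple[float, int, SplitSuggestion]] = None
        for pi, (lo, hi) in enumerate(pieces):
            try:
                sug = suggest_split(x[lo:hi], min_seg_bins=min_seg_bins)
            except InsufficientDataError:
                continue
            if best is None or sug.sse_reduction > best[0]:
                best = (sug.sse_reduction, pi, sug)
        if best is None:
            break
        _, pi, sug = best
        lo, hi = pieces.pop(pi)
        k = lo + sug.index
        pieces.extend([(lo, k), (k, hi)])
        position = int(bin_starts[k]) if bin_starts is not None else k
        out.append(replace(sug, index=k, position=position))
    return sorted(out, key=lambda s: s.index)


@dataclass
class EditOp:
    """One undoable edit: the replaced segments and their replacements."""

    kind: str                       # "split" or "merge"
    removed: list[Segment]          # segments (with ids) present before
    added_ids: list[str]            # ids of segments inserted by the op
    params: dict = field(default_factory=dict)


@dataclass
class EditSession:
    """A segment index under curation, with an undo history and optional logR track.

    When a track is bound, split/merge recompute child means from the data;
    otherwise children inherit (split) or length-weight (merge) the parent
    means.  Split positions snap to track bin boundaries when a track is
    bound.
    """

    index: SegmentIndex
    track: Optional[LogRTrack] = None
    thresholds: Thresholds = field(default_factory=Thresholds)
    history: list[EditOp] = field(default_factory=list)

    def _mean_for(self, start: int, end: int, fallback: float) -> float:
        if self.track is None:
            return fallback
        try:
            return interval_mean_logr(self.track, start, end)
        except EmptyIntervalError:
            return fallback

    def _snap(self, position: int) -> int:
        if self.track is None:
            return position
        offset = (position - self.track.start) / self.track.bin_size
        return int(self.track.start + round(offset) * self.track.bin_size)


def split_segment(session: EditSession, segment_id: str,
                  position: int) -> tuple[Segment, Segment]:
    """Split a segment in two at ``position`` (strictly inside it).

    With a bound track the position snaps to the nearest bin boundary and
    each child's mean is recomputed from the track; otherwise both children
    inherit the parent mean.  States are reclassified and the edit is pushed
    onto the undo history.
    """
    parent = session.index.get(segment_id)
    position = session._snap(int(position))
    if not (parent.start < position < parent.end):
        raise ValueError(
            f"split position {position} not strictly inside "
            f"{parent.chrom}:{parent.start}-{parent.end}"
        )
    session.index.remove(segment_id)
    children = []
    for start, end in ((parent.start, position), (position, parent.end)):
        mean = session._mean_for(start, end, parent.mean_logr)
        n_bins = None
        if session.track is not None:
            n_bins = max(1, round((end - start) / session.track.bin_size))
        elif parent.n_bins is not None:
            n_bins = max(1, round(parent.n_bins * (end - start) / parent.length))
        child = Segment(chrom=parent.chrom, start=start, end=end, mean_logr=mean,
                        n_bins=n_bins, state=classify_state(mean, session.thresholds),
                        sample=parent.sample)
        child_id = session.index.add(child)
        children.append(session.index.get(child_id))
    session.history.append(EditOp(kind="split", removed=[parent],
                                  added_ids=[c.id for c in children],
                                  params={"position": position}))
    return children[0], children[1]


def merge_segments(session: EditSession, left_id: str, right_id: str) -> Segment:
    """Merge two adjacent same-chromosome segments into one.

    The merged interval spans ``[left.start, right.end)``, absorbing any gap
    between the parents.  The mean comes from the bound track when present;
    otherwise it is the length-weighted mean of the parents (their shared
    value when equal, so that merging the children of a split restores the
    parent exactly).
    """
    left = session.index.get(left_id)
    right = session.index.get(right_id)
    if left.chrom != right.chrom:
        raise AdjacencyError(f"{left} and {right} are on different chromosomes")
    if left.start > right.start:
        left, right, left_id, right_id = right, left, right_id, left_id
    _, neighbor = session.index.adjacent(left_id)
    if neighbor is None or neighbor.id != right_id:
        raise AdjacencyError(
            f"{left} and {right} are not adjacent in the index"
        )
    if session.track is not None:
        fallback = (left.mean_logr * left.length + right.mean_logr * right.length) \
            / (left.length + right.length)
        mean = session._mean_for(left.start, right.end, fallback)
    elif left.mean_logr == right.mean_logr:
        mean = left.mean_logr
    else:
        mean = (left.mean_logr * left.length + right.mean_logr * right.length) \
            / (left.length + right.length)
    n_bins = None
    if left.n_bins is not None and right.n_bins is not None:
        n_bins = left.n_bins + right.n_bins
    session.index.remove(left_id)
    session.index.remove(right_id)
    merged = Segment(chrom=left.chrom, start=left.start, end=right.end,
                     mean_logr=mean, n_bins=n_bins,
                     state=classify_state(mean, session.thresholds),
                     sample=left.sample)
    merged_id = session.index.add(merged)
    merged = session.index.get(merged_id)
    session.history.append(EditOp(kind="merge", removed=[left, right],
                                  added_ids=[merged_id], params={}))
    return merged


def undo(session: EditSession) -> None:
    """Reverse the most recent edit, restoring the index to its prior state."""
    if not session.history:
        raise NothingToUndoError("edit history is empty; nothing to undo")
    op = session.history.pop()
    for seg_id in op.added_ids:
        session.index.remove(seg_id)
    for seg in op.removed:
        session.index.add(seg, seg_id=seg.id)


def save_session(session: EditSession, path,
                 dialect: str = "one_based_inclusive") -> None:
    """Persist the curated segment list as SEG (history is not persisted)."""
    segio.write_seg(session.index, path, dialect=dialect)


def reload_session(path, dialect: str = "one_based_inclusive",
                   thresholds: Thresholds = Thresholds(),
                   track: Optional[LogRTrack] = None) -> EditSession:
    """Load a saved segment list into a fresh session with empty history."""
    index = segio.read_seg(path, dialect=dialect, thresholds=thresholds)
    return EditSession(index=index, track=track, thresholds=thresholds)
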