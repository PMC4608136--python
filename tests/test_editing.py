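"""Split-point search against a brute-force oracle, and the edit algebra."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from cnvcurate.editing import (EditSession, merge_segments, reload_session,
                               save_session, split_segment, suggest_split,
                               suggest_splits_recursive, undo)
from cnvcurate.errors import (AdjacencyError, InsufficientDataError,
                              NothingToUndoError, ValidationError)
from cnvcurate.segio import Segment, SegmentIndex, classify_state
from cnvcurate.tracks import LogRTrack


def brute_force_split(values, min_seg_bins):
    """Independent O(n^2) scan over every boundary.

    Shares the documented tie rule: boundaries whose SSEs differ by less
    than 1e-12 of the total sum of squares are ties, broken toward the
    smallest k.
    """
    x = np.asarray(values, dtype=float)
    present = ~np.isnan(x)
    tol = 1e-12 * (1.0 + float(np.nansum(x * x)))
    best = None
    for k in range(1, len(x)):
        left = x[:k][present[:k]]
        right = x[k:][present[k:]]
        if len(left) < min_seg_bins or len(right) < min_seg_bins:
            continue
        sse = float(((left - left.mean()) ** 2).sum()
                    + ((right - right.mean()) ** 2).sum())
        if best is None or sse < best[0] - tol:
            best = (sse, k, left.mean(), right.mean())
    return best


def session_with(intervals, chrom="chr1", means=None, track=None):
    idx = SegmentIndex()
    means = means or [0.0] * len(intervals)
    for (start, end), mean in zip(intervals, means):
        idx.add(Segment(chrom=chrom, start=start, end=end, mean_logr=mean,
                        state=classify_state(mean)))
    return EditSession(index=idx, track=track)


class TestSuggestSplit:
    def test_clean_step(self):
        sug = suggest_split([1, 1, 1, 5, 5, 5], min_seg_bins=1)
        assert sug.index == 3
        assert sug.sse_reduction == pytest.approx(24.0)
        assert (sug.left_mean, sug.right_mean) == (1.0, 5.0)
        assert sug.note == ""

    def test_constant_window_ties_to_first_admissible_boundary(self):
        sug = suggest_split([2.0, 2.0, 2.0, 2.0], min_seg_bins=1)
        assert sug.index == 1
        assert sug.sse_reduction == pytest.approx(0.0, abs=1e-12)
        assert "low confidence" in sug.note

    def test_min_seg_bins_constrains_candidates(self):
        # k=3 gives left SSE 0, right SSE 0.5; k=2 gives right SSE 2/3
        sug = suggest_split([0, 0, 0, 0, 1], min_seg_bins=2)
        assert sug.index == 3

    def test_missing_bins_excluded_from_sums_and_counts(self):
        values = [1.0, np.nan, 1.0, 5.0, np.nan, 5.0]
        sug = suggest_split(values, min_seg_bins=2)
        assert sug.index == 3
        assert (sug.left_mean, sug.right_mean) == (1.0, 5.0)

    def test_position_maps_to_bin_start(self):
        sug = suggest_split([1, 1, 5, 5], min_seg_bins=1,
                            bin_starts=[1000, 1100, 1200, 1300])
        assert sug.position == 1200

    def test_too_few_bins_raises(self):
        with pytest.raises(InsufficientDataError):
            suggest_split([1.0, 2.0, np.nan], min_seg_bins=2)

    @given(st.lists(st.one_of(st.floats(-3, 3, allow_nan=False), st.just(np.nan)),
                    min_size=4, max_size=60),
           st.integers(1, 3))
    def test_matches_brute_force_oracle(self, values, min_seg_bins):
        oracle = brute_force_split(values, min_seg_bins)
        if oracle is None:
            with pytest.raises(InsufficientDataError):
                suggest_split(values, min_seg_bins=min_seg_bins)
            return
        sug = suggest_split(values, min_seg_bins=min_seg_bins)
        assert sug.index == oracle[1]
        assert sug.left_mean == pytest.approx(oracle[2])
        assert sug.right_mean == pytest.approx(oracle[3])

    def test_recursive_search_finds_both_steps(self):
        values = [0.0] * 30 + [-1.0] * 30 + [0.0] * 30
        rng = np.random.default_rng(3)
        noisy = np.asarray(values) + rng.normal(0, 0.1, len(values))
        found = sorted(s.index for s in suggest_splits_recursive(noisy, 2))
        assert found == [30, 60]


class TestSplitMerge:
    def test_split_partitions_interval(self):
        session = session_with([(1000, 2000)], means=[0.4])
        (parent,) = session.index
        left, right = split_segment(session, parent.id, 1400)
        assert (left.start, left.end, right.start, right.end) == (1000, 1400, 1400, 2000)
        assert left.mean_logr == right.mean_logr == 0.4

    def test_split_with_bound_track_recomputes_means(self):
        track = LogRTrack("chr1", 1000, 100,
                          np.array([1.0] * 4 + [0.0] * 6, dtype=float))
        session = session_with([(1000, 2000)], means=[0.4], track=track)
        (parent,) = session.index
        left, right = split_segment(session, parent.id, 1400)
        assert left.mean_logr == pytest.approx(1.0)
        assert right.mean_logr == pytest.approx(0.0)
        assert left.state == "gain" and right.state == "neutral"

    def test_split_position_snaps_to_bin_boundary(self):
        track = LogRTrack("chr1", 1000, 100, np.zeros(10))
        session = session_with([(1000, 2000)], track=track)
        (parent,) = session.index
        left, _ = split_segment(session, parent.id, 1449)
        assert left.end == 1400

    def test_split_at_boundary_rejected(self):
        session = session_with([(1000, 2000)])
        (parent,) = session.index
        with pytest.raises(ValueError):
            split_segment(session, parent.id, 1000)
        with pytest.raises(ValueError):
            split_segment(session, parent.id, 2000)

    def test_merge_length_weighted_mean(self):
        session = session_with([(0, 100), (100, 400)], means=[1.0, 0.0])
        a, b = session.index
        merged = merge_segments(session, a.id, b.id)
        assert merged.mean_logr == pytest.approx(0.25)
        assert (merged.start, merged.end) == (0, 400)

    def test_merge_absorbs_gap(self):
        session = session_with([(0, 100), (200, 300)], means=[0.1, 0.1])
        a, b = session.index
        merged = merge_segments(session, a.id, b.id)
        assert (merged.start, merged.end) == (0, 300)

    def test_merge_of_split_children_restores_parent(self):
        session = session_with([(1000, 2000)], means=[0.37])
        (parent,) = session.index
        left, right = split_segment(session, parent.id, 1301)
        merged = merge_segments(session, left.id, right.id)
        assert merged.key() == parent.key()

    def test_merge_non_adjacent_rejected(self):
        session = session_with([(0, 100), (100, 200), (200, 300)])
        a, _, c = session.index
        with pytest.raises(AdjacencyError):
            merge_segments(session, a.id, c.id)

    def test_merge_across_chromosomes_rejected(self):
        idx = SegmentIndex([Segment("chr1", 0, 10, 0.0), Segment("chr2", 0, 10, 0.0)])
        session = EditSession(index=idx)
        a, b = idx
        with pytest.raises(AdjacencyError):
            merge_segments(session, a.id, b.id)

    def test_footprint_invariant_under_split_and_merge(self):
        session = session_with([(0, 100), (150, 400)], means=[0.3, -0.3])
        total = sum(s.length for s in session.index)
        a, b = session.index
        split_segment(session, b.id, 200)
        assert sum(s.length for s in session.index) == total
        segs = session.index.segments("chr1")
        merge_segments(session, segs[0].id, segs[1].id)
        assert sum(s.length for s in session.index) >= total


class TestUndo:
    def test_split_then_undo(self):
        session = session_with([(0, 100), (100, 300)], means=[0.5, -0.5])
        snapshot = session.index.copy()
        (a, b) = session.index
        split_segment(session, b.id, 180)
        undo(session)
        assert session.index == snapshot

    def test_merge_then_undo_restores_means(self):
        session = session_with([(0, 100), (100, 400)], means=[1.0, 0.0])
        snapshot = session.index.copy()
        a, b = session.index
        merge_segments(session, a.id, b.id)
        undo(session)
        assert session.index == snapshot

    def test_two_splits_then_two_undos(self):
        session = session_with([(0, 1000)], means=[0.2])
        snapshot = session.index.copy()
        (seg,) = session.index
        left, right = split_segment(session, seg.id, 400)
        split_segment(session, right.id, 700)
        undo(session)
        undo(session)
        assert session.index == snapshot
        assert session.history == []

    def test_empty_history_raises(self):
        session = session_with([(0, 10)])
        with pytest.raises(NothingToUndoError):
            undo(session)

    @given(st.lists(st.integers(0, 2), min_size=1, max_size=12))
    def test_random_edit_sequences_fully_reversible(self, choices):
        session = session_with([(0, 2_000), (2_000, 5_000), (5_000, 6_000)],
                               means=[0.4, -0.6, 0.0])
        snapshot = session.index.copy()
        rng = np.random.default_rng(sum(choices) + len(choices))
        applied = 0
        for choice in choices:
            segs = session.index.segments("chr1")
            if choice <= 1:
                seg = segs[int(rng.integers(0, len(segs)))]
                if seg.length < 2:
                    continue
                pos = int(rng.integers(seg.start + 1, seg.end))
                split_segment(session, seg.id, pos)
                applied += 1
            elif len(segs) >= 2:
                i = int(rng.integers(0, len(segs) - 1))
                merge_segments(session, segs[i].id, segs[i + 1].id)
                applied += 1
        for _ in range(applied):
            undo(session)
        assert session.index == snapshot


class TestSessionPersistence:
    def test_edit_save_reload_round_trip(self, tmp_path):
        session = session_with([(0, 1_000), (1_000, 3_000)], means=[0.3, -0.4])
        (a, b) = session.index
        split_segment(session, b.id, 2_000)
        path = tmp_path / "curated.seg"
        save_session(session, path)
        reloaded = reload_session(path)
        assert reloaded.index == session.index
        assert reloaded.history == []

    def test_save_without_edits_matches_plain_write(self, tmp_path):
        from cnvcurate.segio import write_seg

        session = session_with([(0, 500)], means=[0.1])
        p1, p2 = tmp_path / "a.seg", tmp_path / "b.seg"
        save_session(session, p1)
        write_seg(session.index, p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_reload_of_overlapping_file_rejected(self, tmp_path):
        path = tmp_path / "bad.seg"
        path.write_text("S chr1 1 100 0.1\nS chr1 50 150 0.2\n")
        with pytest.raises(ValidationError):
            reload_session(path)
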