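"""IOU similarity and the per-alpha one-to-one matching."""

import math

import numpy as np
import pytest
from _oracle import hota_alpha_bruteforce

from cellhota import (
    GROUND_TRUTH,
    TRACKER,
    Sequence,
    TrackRecord,
    compute_similarity,
    evaluate,
    global_alignment,
    match_at_alpha,
)
from conftest import as_ground_truth, as_tracker, random_division_free


def _seq(frames, tracks, role=GROUND_TRUTH):
    return Sequence(np.asarray(frames, dtype=np.int64), tracks, role)


class TestComputeSimilarity:
    def test_identical_masks_have_iou_one(self):
        img = np.zeros((6, 6), dtype=np.int64)
        img[1:4, 1:4] = 1
        gt = _seq([img], [TrackRecord(1, 0, 0, 0)])
        res = _seq([img], [TrackRecord(1, 0, 0, 0)], TRACKER)
        sim = compute_similarity(gt, res)
        assert sim.pair_iou[0] == {(1, 1): 1.0}

    def test_disjoint_masks_yield_empty_table(self):
        a = np.zeros((6, 6), dtype=np.int64); a[0:2, 0:2] = 1
        b = np.zeros((6, 6), dtype=np.int64); b[4:6, 4:6] = 1
        sim = compute_similarity(
            _seq([a], [TrackRecord(1, 0, 0, 0)]),
            _seq([b], [TrackRecord(1, 0, 0, 0)], TRACKER),
        )
        assert sim.pair_iou[0] == {}

    def test_partial_overlap_jaccard(self):
        # 10-pixel gt cell overlapping 5 pixels of a 10-pixel tracker cell
        g = np.zeros((4, 10), dtype=np.int64); g[0, 0:10] = 1
        r = np.zeros((4, 10), dtype=np.int64); r[0, 5:10] = 2; r[1, 0:5] = 2
        sim = compute_similarity(
            _seq([g], [TrackRecord(1, 0, 0, 0)]),
            _seq([r], [TrackRecord(2, 0, 0, 0)], TRACKER),
        )
        assert sim.pair_iou[0][(1, 2)] == pytest.approx(5 / 15)

    def test_shape_mismatch_rejected(self):
        g = np.zeros((1, 4, 4), dtype=np.int64)
        r = np.zeros((1, 5, 5), dtype=np.int64)
        with pytest.raises(ValueError, match="shape"):
            compute_similarity(_seq(g, []), _seq(r, [], TRACKER))


class TestGlobalAlignment:
    def test_fully_aligned_pair_scores_one(self):
        img = np.zeros((6, 6), dtype=np.int64); img[1:4, 1:4] = 1
        gt = _seq([img] * 5, [TrackRecord(1, 0, 4, 0)])
        res = as_tracker(gt)
        sim = compute_similarity(gt, res)
        assert global_alignment(sim, gt, res) == {(1, 1): 1.0}

    def test_partial_overlap_formula(self):
        # gt exists 4 frames, tracker 2 frames, overlapping in those 2
        img = np.zeros((6, 6), dtype=np.int64); img[1:4, 1:4] = 1
        img7 = np.zeros((6, 6), dtype=np.int64); img7[1:4, 1:4] = 7
        empty = np.zeros((6, 6), dtype=np.int64)
        gt = _seq([img] * 4, [TrackRecord(1, 0, 3, 0)])
        res = _seq([empty, empty, img7, img7], [TrackRecord(7, 2, 3, 0)], TRACKER)
        sim = compute_similarity(gt, res)
        assert global_alignment(sim, gt, res)[(1, 7)] == pytest.approx(
            2 / (4 + 2 - 2)
        )

    def test_never_overlapping_pair_absent(self):
        a = np.zeros((6, 6), dtype=np.int64); a[0:2, 0:2] = 1
        b = np.zeros((6, 6), dtype=np.int64); b[4:6, 4:6] = 3
        gt = _seq([a], [TrackRecord(1, 0, 0, 0)])
        res = _seq([b], [TrackRecord(3, 0, 0, 0)], TRACKER)
        assert global_alignment(compute_similarity(gt, res), gt, res) == {}


class TestMatchAtAlpha:
    def _single_pair(self, iou_num, iou_den):
        g = np.zeros((2, iou_den), dtype=np.int64)
        g[0, :iou_den] = 1
        r = np.zeros((2, iou_den), dtype=np.int64)
        r[0, :iou_num] = 2
        gt = _seq([g], [TrackRecord(1, 0, 0, 0)])
        res = _seq([r], [TrackRecord(2, 0, 0, 0)], TRACKER)
        sim = compute_similarity(gt, res)
        return sim, global_alignment(sim, gt, res)

    def test_iou_above_alpha_matches(self):
        sim, align = self._single_pair(6, 10)  # nested, iou 0.6
        m = match_at_alpha(sim, align, 0.5)
        assert m.matches[0] == [(1, 2, 0.6)]
        assert m.unmatched_gt[0] == [] and m.unmatched_res[0] == []

    def test_iou_below_alpha_leaves_both_unmatched(self):
        sim, align = self._single_pair(4, 10)
        m = match_at_alpha(sim, align, 0.5)
        assert m.matches[0] == []
        assert m.unmatched_gt[0] == [1] and m.unmatched_res[0] == [2]

    def test_iou_exactly_alpha_is_not_a_match(self):
        # strict inequality: IOU must exceed alpha
        sim, align = self._single_pair(5, 10)
        m = match_at_alpha(sim, align, 0.5)
        assert m.matches[0] == []

    def test_invalid_alpha_rejected(self):
        sim, align = self._single_pair(6, 10)
        with pytest.raises(ValueError):
            match_at_alpha(sim, align, 1.0)

    def test_crossing_pairs_resolve_to_oracle_score(self):
        """Two gt and two tracker cells all overlapping above alpha: the
        chosen pairing must reach the brute-force HOTA maximum."""
        H, W = 8, 20
        g = np.zeros((H, W), dtype=np.int64)
        g[2:6, 2:8] = 1
        g[2:6, 9:15] = 2
        r = np.zeros((H, W), dtype=np.int64)
        r[2:6, 4:10] = 11   # overlaps both gt cells
        r[2:6, 11:17] = 12
        # a second frame where the tracker follows gt 1 with label 11 exactly,
        # making the swap-free pairing globally consistent
        g2 = np.zeros((H, W), dtype=np.int64)
        g2[2:6, 2:8] = 1
        g2[2:6, 9:15] = 2
        r2 = np.zeros((H, W), dtype=np.int64)
        r2[2:6, 2:8] = 11
        r2[2:6, 9:15] = 12
        gt = _seq([g, g2], [TrackRecord(1, 0, 1, 0), TrackRecord(2, 0, 1, 0)])
        res = _seq([r, r2], [TrackRecord(11, 0, 1, 0), TrackRecord(12, 0, 1, 0)],
                   TRACKER)
        report = evaluate(gt, res)
        for row in report.per_alpha:
            expected = hota_alpha_bruteforce(gt, res, row.alpha)
            assert row.hota == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("seed", range(20))
    def test_tp_count_non_increasing_in_alpha(self, seed):
        gt, res = random_division_free(seed)
        sim = compute_similarity(gt, res)
        align = global_alignment(sim, gt, res)
        counts = [
            match_at_alpha(sim, align, a).total_matches()
            for a in (0.05, 0.25, 0.5, 0.75, 0.95)
        ]
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    @pytest.mark.parametrize("seed", range(10))
    def test_matching_is_symmetric_under_role_swap(self, seed):
        gt, res = random_division_free(seed)
        sim = compute_similarity(gt, res)
        align = global_alignment(sim, gt, res)
        gt2, res2 = as_ground_truth(res), as_tracker(gt)
        sim2 = compute_similarity(gt2, res2)
        align2 = global_alignment(sim2, gt2, res2)
        for alpha in (0.3, 0.6):
            m = match_at_alpha(sim, align, alpha)
            m2 = match_at_alpha(sim2, align2, alpha)
            for f in range(m.n_frames):
                fwd = {(g, r) for g, r, _ in m.matches[f]}
                rev = {(r, g) for g, r, _ in m2.matches[f]}
                assert fwd == rev
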