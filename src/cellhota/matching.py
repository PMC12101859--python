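"""Frame-level matching of tracker cells to ground-truth cells.

The similarity between two cells in one frame is the Jaccard index (IOU) of
their pixel sets.  At a similarity threshold alpha, cells may only be matched
when their IOU strictly exceeds alpha ("IOU > alpha"; at alpha = 0.95 an IOU
of exactly 0.95 is not a match).  Matching is one-to-one within each frame
and is recomputed independently at every alpha.

To make per-frame assignments globally consistent — i.e. to approximate the
matching that maximizes the final tracking score rather than per-frame
overlap alone — each candidate pair is scored by a track-level alignment
term (a Jaccard index over the frames in which the two tracks coexist and
overlap) plus a small epsilon times the per-frame IOU, and the Hungarian
algorithm maximizes that score frame by frame.  On small instances this
two-pass scheme reproduces the score found by exhaustively enumerating all
per-frame matchings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .ctc_io import Sequence

__all__ = [
    "SimilarityTable",
    "AlphaMatching",
    "compute_similarity",
    "global_alignment",
    "match_at_alpha",
]

#: weight of the per-frame IOU relative to the track alignment score
EPSILON_IOU = 1e-6
#: deterministic tie-break bias toward low (gt, tracker) label ranks
_TIE_BIAS = 1e-12


@dataclass
class SimilarityTable:
    """Per-frame sparse IOU map plus the label inventory of both sequences."""

    n_frames: int
    pair_iou: list[dict[tuple[int, int], float]]  # frame -> {(gt, res): iou}
    gt_labels: list[list[int]]  # labels present per frame
    res_labels: list[list[int]]

    def iou(self, frame: int, gt_label: int, res_label: int) -> float:
        return self.pair_iou[frame].get((gt_label, res_label), 0.0)


@dataclass
class AlphaMatching:
    """One-to-one per-frame matching at a single similarity threshold."""

    alpha: float
    matches: list[list[tuple[int, int, float]]]  # frame -> [(gt, res, iou)]
    unmatched_gt: list[list[int]]
    unmatched_res: list[list[int]]

    @property
    def n_frames(self) -> int:
        return len(self.matches)

    def total_matches(self) -> int:
        return sum(len(m) for m in self.matches)

    def matched_gt_at(self, frame: int) -> dict[int, tuple[int, float]]:
        return {g: (r, iou) for g, r, iou in self.matches[frame]}

    def matched_res_at(self, frame: int) -> dict[int, tuple[int, float]]:
        return {r: (g, iou) for g, r, iou in self.matches[frame]}


def compute_similarity(gt: Sequence, res: Sequence) -> SimilarityTable:
    """Exact pixel-set Jaccard for every overlapping (gt, tracker) pair.

    Pairs with zero pixel overlap are absent from the table.  Sequences must
    share frame count and image shape; masks are compared on the identical
    grid, never resampled.
    """
    if gt.n_frames != res.n_frames:
        raise ValueError(
            f"frame count mismatch: gt has {gt.n_frames}, tracker {res.n_frames}"
        )
    if gt.image_shape != res.image_shape:
        raise ValueError(
            f"image shape mismatch: gt {gt.image_shape}, tracker {res.image_shape}"
        )
    pair_iou: list[dict[tuple[int, int], float]] = []
    gt_labels: list[list[int]] = []
    res_labels: list[list[int]] = []
    for f in range(gt.n_frames):
        g = gt.frames[f].ravel()
        r = res.frames[f].ravel()
        g_lab, g_area = np.unique(g[g > 0], return_counts=True)
        r_lab, r_area = np.unique(r[r > 0], return_counts=True)
        gt_labels.append([int(x) for x in g_lab])
        res_labels.append([int(x) for x in r_lab])
        g_area_map = dict(zip(g_lab.tolist(), g_area.tolist()))
        r_area_map = dict(zip(r_lab.tolist(), r_area.tolist()))
        both = (g > 0) & (r > 0)
        table: dict[tuple[int, int], float] = {}
        if both.any():
            pairs, inter = np.unique(
                np.stack([g[both], r[both]]), axis=1, return_counts=True
            )
            for (gl, rl), i in zip(pairs.T.tolist(), inter.tolist()):
                union = g_area_map[gl] + r_area_map[rl] - i
                table[(gl, rl)] = i / union
        pair_iou.append(table)
    return SimilarityTable(gt.n_frames, pair_iou, gt_labels, res_labels)


def global_alignment(
    sim: SimilarityTable, gt: Sequence, res: Sequence
) -> dict[tuple[int, int], float]:
    """Track-pair alignment scores biasing per-frame assignment.

    For tracks i (gt) and j (tracker), the score is a Jaccard index over
    frames: ``o / (|i| + |j| - o)`` where ``o`` counts frames in which both
    exist and their masks overlap, and ``|i|``, ``|j|`` are the tracks' frame
    counts.  Never-overlapping pairs score 0 and are omitted.
    """
    overlap: dict[tuple[int, int], int] = {}
    for table in sim.pair_iou:
        for pair in table:
            overlap[pair] = overlap.get(pair, 0) + 1
    gt_len = {t.label: t.n_frames for t in gt.tracks}
    res_len = {t.label: t.n_frames for t in res.tracks}
    return {
        (gl, rl): o / (gt_len[gl] + res_len[rl] - o)
        for (gl, rl), o in overlap.items()
    }


def match_at_alpha(
    sim: SimilarityTable,
    align: dict[tuple[int, int], float],
    alpha: float,
) -> AlphaMatching:
    """Maximum-score one-to-one assignment per frame among pairs with IOU > alpha.

    The assignment score of a candidate pair is its global alignment score
    plus ``EPSILON_IOU`` times the per-frame IOU; ties are broken toward the
    lowest (gt label, tracker label) ranks.
    """
    if not (0.0 < alpha < 1.0):
        raise ValueError(f"alpha must lie strictly in (0, 1), got {alpha}")
    matches: list[list[tuple[int, int, float]]] = []
    unmatched_gt: list[list[int]] = []
    unmatched_res: list[list[int]] = []
    for f in range(sim.n_frames):
        cands = [
            (gl, rl, iou)
            for (gl, rl), iou in sim.pair_iou[f].items()
            if iou > alpha
        ]
        frame_matches: list[tuple[int, int, float]] = []
        if cands:
            g_order = sorted({gl for gl, _, _ in cands})
            r_order = sorted({rl for _, rl, _ in cands})
            g_idx = {gl: i for i, gl in enumerate(g_order)}
            r_idx = {rl: j for j, rl in enumerate(r_order)}
            score = np.full((len(g_order), len(r_order)), -1.0)
            for gl, rl, iou in cands:
                i, j = g_idx[gl], r_idx[rl]
                score[i, j] = (
                    align.get((gl, rl), 0.0)
                    + EPSILON_IOU * iou
                    - _TIE_BIAS * (i + j)
                )
            rows, cols = linear_sum_assignment(score, maximize=True)
            for i, j in zip(rows, cols):
                if score[i, j] >= 0.0:
                    gl, rl = g_order[i], r_order[j]
                    frame_matches.append((gl, rl, sim.pair_iou[f][(gl, rl)]))
        frame_matches.sort()
        matches.append(frame_matches)
        got_g = {g for g, _, _ in frame_matches}
        got_r = {r for _, r, _ in frame_matches}
        unmatched_gt.append([g for g in sim.gt_labels[f] if g not in got_g])
        unmatched_res.append([r for r in sim.res_labels[f] if r not in got_r])
    return AlphaMatching(alpha, matches, unmatched_gt, unmatched_res)
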