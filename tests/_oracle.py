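"""Independent brute-force HOTA oracle for small division-free instances.

Recomputes per-frame IOUs from the pixel arrays with its own loop, then
enumerates EVERY combination of per-frame one-to-one matchings over the
candidate pairs with IOU > alpha, scores each joint matching with the
published detection/association formulas, and returns the maximum HOTA.
Nothing here touches the package's matching or scoring code paths.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np

#: safety cap on the joint-matching search space
MAX_COMBINATIONS = 500_000


def frame_ious(gt_img: np.ndarray, res_img: np.ndarray) -> dict:
    """IOU for every overlapping (gt label, res label) pair in one frame."""
    out = {}
    for gl in np.unique(gt_img[gt_img > 0]):
        gmask = gt_img == gl
        for rl in np.unique(res_img[gmask]):
            if rl == 0:
                continue
            rmask = res_img == rl
            inter = np.count_nonzero(gmask & rmask)
            union = np.count_nonzero(gmask | rmask)
            out[(int(gl), int(rl))] = inter / union
    return out


def _all_matchings(pairs: list[tuple[int, int]]):
    """Every one-to-one sub-matching of a candidate pair list (incl. empty)."""
    if not pairs:
        yield ()
        return
    head, *rest = pairs
    for m in _all_matchings(rest):
        yield m
        if all(head[0] != g and head[1] != r for g, r in m):
            yield m + (head,)


def hota_alpha_bruteforce(gt_seq, res_seq, alpha: float) -> float:
    """Max HOTA_alpha over all joint per-frame matchings of two sequences."""
    n_frames = gt_seq.n_frames
    per_frame_options = []
    n_gt = n_res = 0
    gt_det = Counter()  # every detection of every track, matched or not
    res_det = Counter()
    for f in range(n_frames):
        gt_img, res_img = gt_seq.frames[f], res_seq.frames[f]
        gt_labels = np.unique(gt_img[gt_img > 0])
        res_labels = np.unique(res_img[res_img > 0])
        n_gt += len(gt_labels)
        n_res += len(res_labels)
        gt_det.update(int(x) for x in gt_labels)
        res_det.update(int(x) for x in res_labels)
        cands = [p for p, iou in frame_ious(gt_img, res_img).items() if iou > alpha]
        per_frame_options.append(list(_all_matchings(sorted(cands))))

    total = 1
    for opts in per_frame_options:
        total *= len(opts)
        if total > MAX_COMBINATIONS:
            raise RuntimeError("instance too large for the brute-force oracle")

    best = 0.0
    for joint in itertools.product(*per_frame_options):
        tp = sum(len(m) for m in joint)
        if tp == 0:
            continue  # AssA is 0 with no detected TPs, so HOTA is 0
        det_a = tp / (n_gt + n_res - tp)
        tpa = Counter()
        for m in joint:
            for g, r in m:
                tpa[(g, r)] += 1
        acc = 0.0
        for m in joint:
            for g, r in m:
                t = tpa[(g, r)]
                # FPA/FNA span the tracks' whole detection sets, incl.
                # unmatched detections
                acc += t / (gt_det[g] + res_det[r] - t)
        ass_a = acc / tp
        best = max(best, math.sqrt(det_a * ass_a))
    return best
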