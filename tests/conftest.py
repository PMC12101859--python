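"""Shared fixture builders: seeded random scenarios for property tests."""

from __future__ import annotations

import numpy as np
import pytest

from cellhota import (
    GROUND_TRUTH,
    Perturbation,
    ScenarioConfig,
    ScenarioError,
    Sequence,
    generate,
    perturb,
)
from cellhota.ctc_io import TRACKER


def as_ground_truth(seq: Sequence) -> Sequence:
    out = seq.copy()
    out.role = GROUND_TRUTH
    return out


def as_tracker(seq: Sequence) -> Sequence:
    out = seq.copy()
    out.role = TRACKER
    return out


def random_division_free(seed: int) -> tuple[Sequence, Sequence]:
    """A small division-free (gt, tracker) pair with 0-3 random errors.

    Sized for the brute-force oracle: at most 4 cells per frame (3 tracked
    plus possibly a spurious one) and at most 4 frames.
    """
    rng = np.random.default_rng(seed)
    n_cells = int(rng.integers(1, 4))
    n_frames = int(rng.integers(2, 5))
    gt = generate(ScenarioConfig(
        mode="mother_machine_1d",
        n_initial_cells=n_cells,
        n_frames=n_frames,
        cell_size=(8, 6),
        seed=seed,
    ))
    res = as_tracker(gt)
    for _ in range(int(rng.integers(0, 3))):
        labels = sorted(t.label for t in res.tracks)
        if not labels:
            break
        kind = rng.choice(
            ["erode", "dilate", "translate", "drop_detection",
             "add_spurious", "id_swap"]
        )
        label = int(rng.choice(labels))
        rec = res.track_map[label]
        frame = int(rng.integers(rec.begin, rec.end + 1))
        try:
            if kind == "erode":
                p = Perturbation(kind, {
                    "label": label,
                    "keep_fraction": float(rng.uniform(0.4, 0.95)),
                })
            elif kind == "dilate":
                p = Perturbation(kind, {
                    "label": label, "grow": int(rng.integers(2, 10)),
                })
            elif kind == "translate":
                p = Perturbation(kind, {
                    "label": label,
                    "dy": int(rng.integers(-3, 4)),
                    "dx": int(rng.integers(-3, 4)),
                })
            elif kind == "drop_detection":
                p = Perturbation(kind, {"label": label, "frame": frame})
            elif kind == "add_spurious":
                p = Perturbation(kind, {
                    "frame": frame, "size": (3, 3),
                })
            else:  # id_swap needs two live tracks and a mid-span frame
                if len(labels) < 2:
                    continue
                a, b = (int(x) for x in rng.choice(labels, 2, replace=False))
                lo = max(res.track_map[a].begin, res.track_map[b].begin) + 1
                hi = min(res.track_map[a].end, res.track_map[b].end)
                if lo > hi:
                    continue
                p = Perturbation(kind, {
                    "labels": (a, b),
                    "frame": int(rng.integers(lo, hi + 1)),
                })
            res = perturb(res, p)
        except ScenarioError:
            continue
    return gt, res


def random_division_scenario(seed: int) -> tuple[Sequence, ScenarioConfig]:
    """A lineage scenario with one division placed away from the boundaries,
    so both division-shift perturbations apply."""
    rng = np.random.default_rng(seed)
    n_frames = int(rng.integers(5, 8))
    div_frame = int(rng.integers(2, n_frames - 1))
    config = ScenarioConfig(
        mode="mother_machine_1d",
        n_initial_cells=int(rng.integers(1, 3)),
        n_frames=n_frames,
        division_schedule=((1, div_frame),),
        seed=seed,
    )
    return generate(config), config


@pytest.fixture
def perfect_pair():
    from cellhota import build_scenario

    return build_scenario("perfect", 0)
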