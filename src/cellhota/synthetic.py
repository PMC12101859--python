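"""Synthetic cell-tracking scenarios with exactly computable scores.

The generator emulates the two data regimes the metric is aimed at:
bacteria confined to mother-machine growth channels (one channel per
lineage, cells stacked along the channel axis) and cells growing freely in
two dimensions.  Masks are static between divisions and different lineages
are separated by background, so every IOU in a perturbed scenario is an
exact ratio of pixel counts that can be written down by hand.

At a scheduled division the parent's mask is split into two daughter masks
of (near) equal area whose pixel union is exactly the parent mask.  The
daughters therefore touch each other, while distinct lineages never do.
This makes the division-shift perturbations exact inverses of each other:
``shift_division_early`` replaces the parent mask one frame before the
division by the two daughter masks, and ``shift_division_late`` replaces
the daughter masks at the division frame by their union under the parent
label, preserving all other pixels bit for bit.

Perturbations map one-to-one onto the metric's error families: ``erode`` /
``dilate`` / ``translate`` (localization), ``drop_detection`` (FN),
``add_spurious`` (FP), ``id_swap`` (association), ``shift_division_early``
/ ``shift_division_late`` (division timing), ``merge_cells`` (detection).
``id_swap`` emulates a tracker losing both identities where two tracks
cross: the affected tracks end at the swap frame and two fresh identities
continue the trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .ctc_io import GROUND_TRUTH, TRACKER, Sequence, TrackRecord, validate_sequence

__all__ = [
    "ScenarioConfig",
    "Perturbation",
    "ScenarioError",
    "generate",
    "perturb",
    "apply_perturbations",
    "SCENARIOS",
    "build_scenario",
]


class ScenarioError(ValueError):
    """Raised for infeasible scenario configs or inapplicable perturbations."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Ground-truth scenario description.

    ``division_schedule`` lists ``(track_label, frame)`` pairs; ``frame`` is
    the daughters' first frame.  Daughter labels are assigned sequentially
    in schedule order.  The generator is deterministic for a fixed seed.
    """

    mode: str = "mother_machine_1d"  # or "open_2d"
    n_initial_cells: int = 1
    n_frames: int = 4
    division_schedule: tuple[tuple[int, int], ...] = ()
    cell_shape: str = "rectangle"  # or "ellipse"
    cell_size: tuple[int, int] = (16, 10)  # (height, width) in pixels
    image_shape: tuple[int, int] | None = None
    seed: int = 0


@dataclass(frozen=True)
class Perturbation:
    """One controlled tracker error: a kind plus its parameters."""

    kind: str
    params: dict = field(default_factory=dict)
    seed: int = 0


# ---------------------------------------------------------------------------
# ground-truth generation
# ---------------------------------------------------------------------------


def _base_mask(config: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    h, w = config.cell_size
    if config.cell_shape == "rectangle":
        return np.ones((h, w), dtype=bool)
    if config.cell_shape == "ellipse":
        yy, xx = np.mgrid[0:h, 0:w]
        cy, cx = (h - 1) / 2, (w - 1) / 2
        return ((yy - cy) / (h / 2)) ** 2 + ((xx - cx) / (w / 2)) ** 2 <= 1.0
    raise ScenarioError(f"unknown cell shape {config.cell_shape!r}")


def _split_mask(pixels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Split a pixel set (N x 2 coordinates) into two near-equal halves.

    The split is along the axis of larger extent; the union of the halves is
    exactly the input.
    """
    spans = pixels.max(axis=0) - pixels.min(axis=0)
    axis = int(np.argmax(spans))
    order = np.lexsort((pixels[:, 1 - axis], pixels[:, axis]))
    half = len(pixels) // 2
    return pixels[order[:half]], pixels[order[half:]]


def generate(config: ScenarioConfig) -> Sequence:
    """Generate a valid ground-truth sequence from a scenario config."""
    if config.n_frames < 1:
        raise ScenarioError("a scenario needs at least one frame")
    if config.n_initial_cells < 1:
        raise ScenarioError("a scenario needs at least one initial cell")
    rng = np.random.default_rng(config.seed)
    h, w = config.cell_size
    gap = 4
    n = config.n_initial_cells
    if config.image_shape is None:
        if config.mode == "mother_machine_1d":
            shape = (h * 4 + 2 * gap, n * (w + gap) + gap)
        elif config.mode == "open_2d":
            side = int(np.ceil(np.sqrt(n)))
            shape = (side * (h + 3 * gap) + gap, side * (w + 3 * gap) + gap)
        else:
            raise ScenarioError(f"unknown mode {config.mode!r}")
    else:
        shape = tuple(config.image_shape)

    # place initial cells: pixel coordinate arrays per label
    pix: dict[int, np.ndarray] = {}
    base = _base_mask(config, rng)
    coords = np.argwhere(base)
    for i in range(n):
        if config.mode == "mother_machine_1d":
            r0, c0 = gap, gap + i * (w + gap)
        elif config.mode == "open_2d":
            side = int(np.ceil(np.sqrt(n)))
            gy, gx = divmod(i, side)
            jy, jx = rng.integers(-2, 3, size=2)
            r0 = gap + gy * (h + 3 * gap) + int(jy)
            c0 = gap + gx * (w + 3 * gap) + int(jx)
        else:
            raise ScenarioError(f"unknown mode {config.mode!r}")
        p = coords + np.array([r0, c0])
        if (p < 0).any() or (p[:, 0] >= shape[0]).any() or (p[:, 1] >= shape[1]).any():
            raise ScenarioError(
                f"cell {i + 1} does not fit in image shape {shape}"
            )
        pix[i + 1] = p

    tracks: dict[int, TrackRecord] = {
        lab: TrackRecord(lab, 0, config.n_frames - 1, 0) for lab in pix
    }
    next_label = n + 1
    for lab, frame in config.division_schedule:
        if lab not in tracks:
            raise ScenarioError(f"division schedule names unknown track {lab}")
        rec = tracks[lab]
        if not (rec.begin + 1 <= frame <= config.n_frames - 1):
            raise ScenarioError(
                f"track {lab} cannot divide at frame {frame} "
                f"(alive [{rec.begin}, {rec.end}], movie has "
                f"{config.n_frames} frames)"
            )
        if rec.end != config.n_frames - 1:
            raise ScenarioError(f"track {lab} has already divided or ended")
        pa, pb = _split_mask(pix[lab])
        if len(pa) == 0 or len(pb) == 0:
            raise ScenarioError(f"track {lab} is too small to divide")
        tracks[lab] = replace(rec, end=frame - 1)
        da, db = next_label, next_label + 1
        next_label += 2
        tracks[da] = TrackRecord(da, frame, config.n_frames - 1, lab)
        tracks[db] = TrackRecord(db, frame, config.n_frames - 1, lab)
        pix[da], pix[db] = pa, pb

    frames = np.zeros((config.n_frames,) + shape, dtype=np.int64)
    for lab, rec in tracks.items():
        p = pix[lab]
        for t in range(rec.begin, rec.end + 1):
            frames[t, p[:, 0], p[:, 1]] = lab
    seq = Sequence(frames, sorted(tracks.values()), GROUND_TRUTH)
    bad = [d for d in validate_sequence(seq) if d.severity == "error"]
    if bad:  # pragma: no cover - generator contract
        raise ScenarioError("generator produced an invalid sequence: "
                            + "; ".join(map(str, bad)))
    return seq


# ---------------------------------------------------------------------------
# perturbations
# ---------------------------------------------------------------------------


def _as_tracker(seq: Sequence) -> Sequence:
    out = seq.copy()
    out.role = TRACKER
    return out


def _next_label(tracks: list[TrackRecord]) -> int:
    return max(t.label for t in tracks) + 1


def _track_frames(seq: Sequence, label: int, frames) -> list[int]:
    rec = seq.track_map[label]
    if frames is None:
        return list(range(rec.begin, rec.end + 1))
    frames = [frames] if isinstance(frames, int) else list(frames)
    for f in frames:
        if not (rec.begin <= f <= rec.end):
            raise ScenarioError(
                f"track {label} does not exist at frame {f}"
            )
    return frames


def perturb(seq: Sequence, p: Perturbation) -> Sequence:
    """Apply one controlled error; returns a tracker-role sequence."""
    out = _as_tracker(seq)
    handler = _PERTURBATIONS.get(p.kind)
    if handler is None:
        raise ScenarioError(f"unknown perturbation kind {p.kind!r}")
    handler(out, p)
    bad = [d for d in validate_sequence(out) if d.severity == "error"]
    if bad:
        raise ScenarioError(
            f"perturbation {p.kind} produced an invalid sequence: "
            + "; ".join(map(str, bad))
        )
    return out


def apply_perturbations(seq: Sequence, perturbations) -> Sequence:
    """Apply a list of perturbations in order; an empty list is the identity
    (up to the role switching to tracker)."""
    out = _as_tracker(seq)
    for p in perturbations:
        out = perturb(out, p)
    return out


def _p_erode(seq: Sequence, p: Perturbation) -> None:
    label = p.params["label"]
    keep_fraction = p.params.get("keep_fraction")
    keep = p.params.get("keep")
    for f in _track_frames(seq, label, p.params.get("frames")):
        pix = np.argwhere(seq.frames[f] == label)
        n = len(pix)
        k = keep if keep is not None else int(round(keep_fraction * n))
        if not (1 <= k <= n):
            raise ScenarioError(
                f"erode would leave {k} of {n} pixels for label {label}"
            )
        drop = pix[k:]
        seq.frames[f, drop[:, 0], drop[:, 1]] = 0


def _p_dilate(seq: Sequence, p: Perturbation) -> None:
    label = p.params["label"]
    grow = int(p.params["grow"])
    for f in _track_frames(seq, label, p.params.get("frames")):
        img = seq.frames[f]
        need = grow
        while need > 0:
            mask = img == label
            ring = np.zeros_like(mask)
            ring[1:, :] |= mask[:-1, :]
            ring[:-1, :] |= mask[1:, :]
            ring[:, 1:] |= mask[:, :-1]
            ring[:, :-1] |= mask[:, 1:]
            ring &= img == 0
            cand = np.argwhere(ring)
            if len(cand) == 0:
                raise ScenarioError(
                    f"no background left to dilate label {label} into"
                )
            take = cand[:need]
            img[take[:, 0], take[:, 1]] = label
            need -= len(take)


def _p_translate(seq: Sequence, p: Perturbation) -> None:
    label = p.params["label"]
    dy, dx = int(p.params.get("dy", 0)), int(p.params.get("dx", 0))
    h, w = seq.image_shape
    for f in _track_frames(seq, label, p.params.get("frames")):
        img = seq.frames[f]
        pix = np.argwhere(img == label)
        img[pix[:, 0], pix[:, 1]] = 0
        moved = pix + np.array([dy, dx])
        inside = (
            (moved[:, 0] >= 0) & (moved[:, 0] < h)
            & (moved[:, 1] >= 0) & (moved[:, 1] < w)
        )
        moved = moved[inside]
        if len(moved) == 0:
            raise ScenarioError(f"translate moved label {label} off the image")
        img[moved[:, 0], moved[:, 1]] = label


def _split_track_around(seq: Sequence, label: int, frame: int) -> None:
    """Remove ``label`` from one frame, splitting its track if mid-span.

    The continuation after the removed frame gets a fresh identity (no parent
    link); children beginning after the split follow the new identity.
    """
    rec = seq.track_map[label]
    tracks = [t for t in seq.tracks if t.label != label]
    if rec.begin == rec.end:
        pass  # track vanishes entirely
    elif frame == rec.begin:
        tracks.append(replace(rec, begin=frame + 1, parent=0))
    elif frame == rec.end:
        tracks.append(replace(rec, end=frame - 1))
    else:
        new = _next_label(seq.tracks)
        tracks.append(replace(rec, end=frame - 1))
        tracks.append(TrackRecord(new, frame + 1, rec.end, 0))
        for t in range(frame + 1, rec.end + 1):
            seq.frames[t][seq.frames[t] == label] = new
        tracks = [
            replace(t, parent=new)
            if t.parent == label and t.begin > frame else t
            for t in tracks
        ]
    if rec.begin == rec.end or frame == rec.begin:
        # children lose their (now shortened/removed) parent's link validity
        tracks = [
            replace(t, parent=0)
            if t.parent == label and (rec.begin == rec.end) else t
            for t in tracks
        ]
    seq.tracks = sorted(tracks)
    seq._track_map = None


def _p_drop_detection(seq: Sequence, p: Perturbation) -> None:
    label = p.params["label"]
    frame = int(p.params["frame"])
    rec = seq.track_map.get(label)
    if rec is None or not (rec.begin <= frame <= rec.end):
        raise ScenarioError(f"track {label} does not exist at frame {frame}")
    seq.frames[frame][seq.frames[frame] == label] = 0
    _split_track_around(seq, label, frame)


def _p_add_spurious(seq: Sequence, p: Perturbation) -> None:
    frame = int(p.params["frame"])
    if not (0 <= frame < seq.n_frames):
        raise ScenarioError(f"frame {frame} outside the movie")
    size = tuple(p.params.get("size", (4, 4)))
    pos = p.params.get("position")
    img = seq.frames[frame]
    h, w = seq.image_shape
    sh, sw = size
    if pos is None:
        pos = None
        for r0 in range(1, h - sh):
            for c0 in range(1, w - sw):
                if not img[r0 - 1 : r0 + sh + 1, c0 - 1 : c0 + sw + 1].any():
                    pos = (r0, c0)
                    break
            if pos:
                break
        if pos is None:
            raise ScenarioError("no free background for a spurious cell")
    r0, c0 = pos
    if img[r0 : r0 + sh, c0 : c0 + sw].any():
        raise ScenarioError("spurious cell would overlap an existing cell")
    new = _next_label(seq.tracks)
    img[r0 : r0 + sh, c0 : c0 + sw] = new
    seq.tracks = sorted(seq.tracks + [TrackRecord(new, frame, frame, 0)])
    seq._track_map = None


def _p_id_swap(seq: Sequence, p: Perturbation) -> None:
    a, b = p.params["labels"]
    frame = int(p.params["frame"])
    ra, rb = seq.track_map.get(a), seq.track_map.get(b)
    for lab, rec in ((a, ra), (b, rb)):
        if rec is None or not (rec.begin < frame <= rec.end):
            raise ScenarioError(
                f"track {lab} cannot hand over its identity at frame {frame}"
            )
    new_a = _next_label(seq.tracks)
    new_b = new_a + 1
    tracks = [t for t in seq.tracks if t.label not in (a, b)]
    tracks += [
        replace(ra, end=frame - 1),
        replace(rb, end=frame - 1),
        TrackRecord(new_a, frame, ra.end, 0),
        TrackRecord(new_b, frame, rb.end, 0),
    ]
    for t in range(frame, max(ra.end, rb.end) + 1):
        img = seq.frames[t]
        ma = img == a
        mb = img == b
        img[ma] = new_a
        img[mb] = new_b
    tracks = [
        replace(t, parent={a: new_a, b: new_b}[t.parent])
        if t.parent in (a, b) and t.begin > frame else t
        for t in tracks
    ]
    seq.tracks = sorted(tracks)
    seq._track_map = None


def _division_of(seq: Sequence, parent: int) -> tuple[int, int, int]:
    """Return (frame, daughter_a, daughter_b) of the division of ``parent``."""
    daughters = sorted(
        t for t in seq.tracks if t.parent == parent and t.label != parent
    )
    if len(daughters) != 2 or daughters[0].begin != daughters[1].begin:
        raise ScenarioError(f"track {parent} has no binary division")
    return daughters[0].begin, daughters[0].label, daughters[1].label


def _p_shift_division_early(seq: Sequence, p: Perturbation) -> None:
    parent = p.params["label"]
    f, da, db = _division_of(seq, parent)
    rec = seq.track_map[parent]
    if f - 1 <= rec.begin:
        raise ScenarioError(
            f"division of {parent} at frame {f} cannot shift earlier: "
            "the parent would not exist before it"
        )
    # at f-1: parent pixels give way to the daughters' masks from frame f
    img = seq.frames[f - 1]
    img[img == parent] = 0
    for d in (da, db):
        pix = np.argwhere(seq.frames[f] == d)
        img[pix[:, 0], pix[:, 1]] = d
    seq.tracks = sorted(
        replace(t, end=f - 2) if t.label == parent
        else replace(t, begin=f - 1) if t.label in (da, db)
        else t
        for t in seq.tracks
    )
    seq._track_map = None


def _p_shift_division_late(seq: Sequence, p: Perturbation) -> None:
    parent = p.params["label"]
    f, da, db = _division_of(seq, parent)
    for d in (da, db):
        if seq.track_map[d].end < f + 1:
            raise ScenarioError(
                f"division of {parent} at frame {f} cannot shift later: "
                f"daughter {d} ends at frame {seq.track_map[d].end}"
            )
    if f + 1 >= seq.n_frames:
        raise ScenarioError(
            f"division of {parent} at the final frame cannot shift later"
        )
    img = seq.frames[f]
    both = np.isin(img, (da, db))
    img[both] = parent
    seq.tracks = sorted(
        replace(t, end=f) if t.label == parent
        else replace(t, begin=f + 1) if t.label in (da, db)
        else t
        for t in seq.tracks
    )
    seq._track_map = None


def _p_merge_cells(seq: Sequence, p: Perturbation) -> None:
    a, b = p.params["labels"]
    frame = int(p.params["frame"])
    for lab in (a, b):
        rec = seq.track_map.get(lab)
        if rec is None or not (rec.begin <= frame <= rec.end):
            raise ScenarioError(f"track {lab} does not exist at frame {frame}")
    img = seq.frames[frame]
    img[img == b] = a
    _split_track_around(seq, b, frame)


_PERTURBATIONS = {
    "erode": _p_erode,
    "dilate": _p_dilate,
    "translate": _p_translate,
    "drop_detection": _p_drop_detection,
    "add_spurious": _p_add_spurious,
    "id_swap": _p_id_swap,
    "shift_division_early": _p_shift_division_early,
    "shift_division_late": _p_shift_division_late,
    "merge_cells": _p_merge_cells,
}


# ---------------------------------------------------------------------------
# named scenario catalog
# ---------------------------------------------------------------------------


def _sc_perfect(seed: int):
    gt = generate(ScenarioConfig(
        n_initial_cells=2, n_frames=5,
        division_schedule=((1, 2),), seed=seed,
    ))
    return gt, apply_perturbations(gt, [])


def _sc_id_swap(seed: int):
    gt = generate(ScenarioConfig(n_initial_cells=2, n_frames=4, seed=seed))
    res = perturb(gt, Perturbation("id_swap", {"labels": (1, 2), "frame": 2}))
    return gt, res


def _sc_erosion(seed: int):
    gt = generate(ScenarioConfig(
        n_initial_cells=1, n_frames=3, cell_size=(10, 10), seed=seed,
    ))
    res = perturb(gt, Perturbation("erode", {"label": 1, "keep_fraction": 0.6}))
    return gt, res


def _sc_shift_early(seed: int):
    gt = generate(ScenarioConfig(
        n_initial_cells=1, n_frames=6, division_schedule=((1, 3),), seed=seed,
    ))
    res = perturb(gt, Perturbation("shift_division_early", {"label": 1}))
    return gt, res


def _sc_shift_late(seed: int):
    gt = generate(ScenarioConfig(
        n_initial_cells=1, n_frames=6, division_schedule=((1, 3),), seed=seed,
    ))
    res = perturb(gt, Perturbation("shift_division_late", {"label": 1}))
    return gt, res


def _sc_shift_early_boundary(seed: int):
    gt = generate(ScenarioConfig(
        n_initial_cells=1, n_frames=4, division_schedule=((1, 1),), seed=seed,
    ))
    res = perturb(gt, Perturbation("shift_division_early", {"label": 1}))
    return gt, res  # pragma: no cover - perturb raises first


def _sc_drop(seed: int):
    gt = generate(ScenarioConfig(n_initial_cells=2, n_frames=4, seed=seed))
    res = perturb(gt, Perturbation("drop_detection", {"label": 2, "frame": 1}))
    return gt, res


def _sc_spurious(seed: int):
    gt = generate(ScenarioConfig(n_initial_cells=2, n_frames=4, seed=seed))
    res = perturb(gt, Perturbation("add_spurious", {"frame": 2}))
    return gt, res


SCENARIOS = {
    "perfect": _sc_perfect,
    "id_swap": _sc_id_swap,
    "erosion": _sc_erosion,
    "shift_early": _sc_shift_early,
    "shift_late": _sc_shift_late,
    "shift_early_boundary": _sc_shift_early_boundary,
    "drop": _sc_drop,
    "spurious": _sc_spurious,
}


def build_scenario(name: str, seed: int = 0) -> tuple[Sequence, Sequence]:
    """Build a named (ground truth, tracker) scenario pair."""
    if name not in SCENARIOS:
        raise ScenarioError(
            f"unknown scenario {name!r}; known: {', '.join(sorted(SCENARIOS))}"
        )
    return SCENARIOS[name](seed)
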