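"""Reading, writing and validating Cell Tracking Challenge sequences.

A sequence is a movie of 2-D integer label masks (one image per frame,
background 0) together with a lineage table.  The table is plain text, one
record per line, four whitespace-separated integers ``L B E P``: track label,
first frame, last frame (inclusive) and parent label (0 for none).  Ground
truth sequences carry ``man_trackNNN.tif`` masks and a ``man_track.txt``
table; tracker results carry ``maskNNN.tif`` and ``res_track.txt``.

Frame numbers are normalised to contiguous 0-based indices on read, whatever
zero-padded numbering the files carry on disk.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import tifffile

__all__ = [
    "TrackRecord",
    "Sequence",
    "Diagnostic",
    "CTCFormatError",
    "read_sequence",
    "write_sequence",
    "validate_sequence",
]

GROUND_TRUTH = "ground_truth"
TRACKER = "tracker"


class CTCFormatError(ValueError):
    """Raised when an on-disk sequence violates the CTC format contract."""


@dataclass(frozen=True, order=True)
class TrackRecord:
    """One lineage-table row: a track's label, frame span and parent link."""

    label: int
    begin: int
    end: int
    parent: int = 0

    @property
    def n_frames(self) -> int:
        return self.end - self.begin + 1


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding.  ``severity`` is ``"error"`` or ``"warning"``."""

    kind: str
    severity: str
    message: str
    frame: int | None = None
    label: int | None = None

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        loc = []
        if self.frame is not None:
            loc.append(f"frame {self.frame}")
        if self.label is not None:
            loc.append(f"label {self.label}")
        where = f" ({', '.join(loc)})" if loc else ""
        return f"[{self.severity}] {self.kind}{where}: {self.message}"


@dataclass
class Sequence:
    """A label-mask movie plus its lineage table.

    ``frames`` is a ``(T, H, W)`` integer array; ``tracks`` one
    :class:`TrackRecord` per label; ``role`` either ``"ground_truth"`` or
    ``"tracker"``.
    """

    frames: np.ndarray
    tracks: list[TrackRecord]
    role: str = GROUND_TRUTH
    _track_map: dict[int, TrackRecord] | None = field(
        default=None, repr=False, compare=False
    )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def image_shape(self) -> tuple[int, int]:
        return self.frames.shape[1], self.frames.shape[2]

    @property
    def track_map(self) -> dict[int, TrackRecord]:
        if self._track_map is None or len(self._track_map) != len(self.tracks):
            self._track_map = {t.label: t for t in self.tracks}
        return self._track_map

    def labels_at(self, frame: int) -> np.ndarray:
        """Sorted labels present in the mask of one frame."""
        img = self.frames[frame]
        labels = np.unique(img)
        return labels[labels > 0]

    def mask_of(self, frame: int, label: int) -> np.ndarray:
        return self.frames[frame] == label

    def copy(self) -> "Sequence":
        return Sequence(self.frames.copy(), list(self.tracks), self.role)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

_FRAME_RE = re.compile(r"(\d+)\D*$")


def _frame_number(path: Path) -> int | None:
    m = _FRAME_RE.search(path.stem)
    return int(m.group(1)) if m else None


def read_sequence(mask_dir: str | Path, track_file: str | Path, role: str) -> Sequence:
    """Read and validate a CTC sequence from disk.

    ``mask_dir`` must hold one integer-label image per frame, ordered by the
    zero-padded frame number in the file name; ``track_file`` is the four
    column lineage table.  Frame numbers are remapped to 0-based contiguous
    indices; labels are preserved verbatim.
    """
    mask_dir = Path(mask_dir)
    track_file = Path(track_file)
    if role not in (GROUND_TRUTH, TRACKER):
        raise CTCFormatError(f"unknown sequence role {role!r}")
    if not mask_dir.is_dir():
        raise CTCFormatError(f"mask directory {mask_dir} does not exist")

    mask_paths = sorted(
        (p for p in mask_dir.iterdir() if p.suffix.lower() in (".tif", ".tiff")),
        key=lambda p: p.name,
    )
    if not mask_paths:
        raise CTCFormatError(f"no TIFF mask images found in {mask_dir}")

    numbers = [_frame_number(p) for p in mask_paths]
    if any(n is None for n in numbers):
        bad = mask_paths[numbers.index(None)]
        raise CTCFormatError(f"mask file name {bad.name} carries no frame number")
    if sorted(numbers) != list(range(min(numbers), min(numbers) + len(numbers))):
        raise CTCFormatError(
            f"mask frame numbers in {mask_dir} are not contiguous: {sorted(numbers)}"
        )
    offset = min(numbers)

    frames = []
    shape = None
    for path, num in sorted(zip(mask_paths, numbers), key=lambda x: x[1]):
        img = np.asarray(tifffile.imread(path))
        if img.ndim != 2:
            raise CTCFormatError(f"{path.name}: expected a 2-D label image")
        if not np.issubdtype(img.dtype, np.integer):
            raise CTCFormatError(
                f"{path.name}: non-integer pixel type {img.dtype}"
            )
        if shape is None:
            shape = img.shape
        elif img.shape != shape:
            raise CTCFormatError(
                f"{path.name}: image shape {img.shape} differs from {shape}"
            )
        frames.append(img.astype(np.int64))

    tracks = _parse_track_table(track_file, frame_offset=offset)
    seq = Sequence(np.stack(frames), tracks, role)
    errors = [d for d in validate_sequence(seq) if d.severity == "error"]
    if errors:
        raise CTCFormatError(
            "invalid sequence:\n" + "\n".join(str(d) for d in errors)
        )
    return seq


def _parse_track_table(track_file: Path, frame_offset: int = 0) -> list[TrackRecord]:
    if not track_file.is_file():
        raise CTCFormatError(f"track table {track_file} does not exist")
    tracks: list[TrackRecord] = []
    seen: set[int] = set()
    for i, line in enumerate(track_file.read_text().splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        parts = line.split()
        if len(parts) != 4:
            raise CTCFormatError(
                f"{track_file.name}:{i}: expected 4 integers 'L B E P', got {line!r}"
            )
        try:
            label, begin, end, parent = (int(p) for p in parts)
        except ValueError:
            raise CTCFormatError(
                f"{track_file.name}:{i}: non-integer field in {line!r}"
            ) from None
        if label in seen:
            raise CTCFormatError(
                f"{track_file.name}:{i}: duplicate track label {label}"
            )
        seen.add(label)
        tracks.append(
            TrackRecord(label, begin - frame_offset, end - frame_offset, parent)
        )
    return tracks


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_sequence(seq: Sequence, out_dir: str | Path) -> Path:
    """Write a sequence to ``out_dir`` in CTC layout; returns ``out_dir``.

    Masks are emitted as 16-bit TIFF named ``man_trackNNN.tif`` (ground truth)
    or ``maskNNN.tif`` (tracker), plus the matching ``man_track.txt`` /
    ``res_track.txt`` table.  ``read_sequence`` on the result reproduces the
    input bit-exactly.
    """
    if seq.n_frames < 1:
        raise CTCFormatError("cannot write an empty sequence (0 frames)")
    max_label = max((t.label for t in seq.tracks), default=0)
    if max_label > np.iinfo(np.uint16).max:
        raise CTCFormatError(
            f"label {max_label} exceeds the 16-bit range of CTC mask images"
        )
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = "man_track" if seq.role == GROUND_TRUTH else "mask"
    table = "man_track.txt" if seq.role == GROUND_TRUTH else "res_track.txt"
    width = max(3, len(str(seq.n_frames - 1)))
    for t in range(seq.n_frames):
        tifffile.imwrite(
            out_dir / f"{stem}{t:0{width}d}.tif",
            seq.frames[t].astype(np.uint16),
        )
    lines = [f"{t.label} {t.begin} {t.end} {t.parent}" for t in seq.tracks]
    (out_dir / table).write_text("\n".join(lines) + "\n")
    return out_dir


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------


def validate_sequence(seq: Sequence) -> list[Diagnostic]:
    """Check every sequence invariant; returns one diagnostic per violation.

    Errors: malformed records, dangling/cyclic/overlapping parent links,
    labels in masks without a covering track record (or vice versa), >=3
    daughters at one frame, daughters not starting right after the parent
    ends.  A parent with a single child (CTC gap-closing link) is legal but
    flagged as a warning; see the evaluation config for how it is scored.
    """
    diags: list[Diagnostic] = []
    if seq.n_frames < 1:
        return [Diagnostic("empty-movie", "error", "sequence has no frames")]

    tmap: dict[int, TrackRecord] = {}
    for t in seq.tracks:
        if t.label in tmap:
            diags.append(
                Diagnostic("duplicate-label", "error",
                           f"track label {t.label} defined twice", label=t.label)
            )
            continue
        tmap[t.label] = t
        if t.label < 1:
            diags.append(
                Diagnostic("bad-label", "error",
                           f"track label {t.label} must be >= 1", label=t.label)
            )
        if t.begin > t.end:
            diags.append(
                Diagnostic("bad-span", "error",
                           f"track {t.label} begins at {t.begin} after its end {t.end}",
                           label=t.label)
            )
        if t.begin < 0 or t.end >= seq.n_frames:
            diags.append(
                Diagnostic("span-outside-movie", "error",
                           f"track {t.label} span [{t.begin}, {t.end}] leaves the "
                           f"movie [0, {seq.n_frames - 1}]", label=t.label)
            )
        if t.parent == t.label:
            diags.append(
                Diagnostic("self-parent", "error",
                           f"track {t.label} lists itself as parent", label=t.label)
            )

    for t in seq.tracks:
        if t.parent != 0 and t.parent != t.label:
            p = tmap.get(t.parent)
            if p is None:
                diags.append(
                    Diagnostic("dangling-parent", "error",
                               f"track {t.label} references missing parent "
                               f"{t.parent}", label=t.parent)
                )
            elif p.end >= t.begin:
                diags.append(
                    Diagnostic("parent-overlap", "error",
                               f"parent {t.parent} ends at {p.end}, not before "
                               f"child {t.label} begins at {t.begin}",
                               label=t.label)
                )

    # children grouped by first frame: pairs are divisions, singletons are
    # gap-closing links, triples and up are rejected
    children: dict[int, dict[int, list[TrackRecord]]] = {}
    for t in seq.tracks:
        if t.parent != 0 and t.parent in tmap and t.parent != t.label:
            children.setdefault(t.parent, {}).setdefault(t.begin, []).append(t)
    for parent, groups in sorted(children.items()):
        for begin, group in sorted(groups.items()):
            if len(group) == 1:
                diags.append(
                    Diagnostic("single-child-parent-link", "warning",
                               f"parent {parent} has a single child "
                               f"{group[0].label} (gap-closing link)",
                               frame=begin, label=parent)
                )
            elif len(group) >= 3:
                diags.append(
                    Diagnostic("polytomy", "error",
                               f"parent {parent} has {len(group)} simultaneous "
                               "daughters; binary divisions only",
                               frame=begin, label=parent)
                )
            else:
                if tmap[parent].end != begin - 1:
                    diags.append(
                        Diagnostic("division-gap", "error",
                                   f"daughters of {parent} begin at {begin} but "
                                   f"the parent ends at {tmap[parent].end}",
                                   frame=begin, label=parent)
                    )

    # mask <-> table consistency
    present: dict[int, set[int]] = {}
    for f in range(seq.n_frames):
        for lab in seq.labels_at(f):
            lab = int(lab)
            present.setdefault(lab, set()).add(f)
            rec = tmap.get(lab)
            if rec is None:
                diags.append(
                    Diagnostic("unknown-label", "error",
                               f"label {lab} appears in the masks but not in "
                               "the track table", frame=f, label=lab)
                )
            elif not (rec.begin <= f <= rec.end):
                diags.append(
                    Diagnostic("label-outside-track-span", "error",
                               f"label {lab} appears at frame {f} outside its "
                               f"span [{rec.begin}, {rec.end}]", frame=f,
                               label=lab)
                )
    for t in seq.tracks:
        if 0 <= t.begin <= t.end < seq.n_frames:
            missing = set(range(t.begin, t.end + 1)) - present.get(t.label, set())
            for f in sorted(missing):
                diags.append(
                    Diagnostic("label-missing-from-frame", "error",
                               f"track {t.label} spans frame {f} but has no "
                               "pixels there", frame=f, label=t.label)
                )
    return diags
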