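"""Lineage forests and cell-division events.

A lineage forest is the set of track trees induced by parent links in a
CTC track table.  A division is an internal node with exactly two daughters;
its event time is the first frame in which the daughters coexist (the parent
last appears one frame earlier).  Single-child parent links (CTC gap-closing)
are not divisions; they are kept aside as gap links so the evaluation can
either sever them (default) or treat the child as a continuation of the
parent identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .ctc_io import TrackRecord

__all__ = ["DivisionEvent", "LineageForest", "build_forest", "divisions_at",
           "gap_aliases"]


class LineageError(ValueError):
    """Raised for structurally invalid lineage tables (cycles, polytomies)."""


@dataclass(frozen=True, order=True)
class DivisionEvent:
    """One binary division: parent track splitting into two daughters.

    ``frame`` is the daughters' first frame; the parent's last frame is
    ``frame - 1``.
    """

    frame: int
    parent_label: int
    daughter_labels: tuple[int, int]


@dataclass
class LineageForest:
    nodes: list[int]
    edges: dict[int, tuple[int, ...]]  # parent -> daughters (division links only)
    divisions: list[DivisionEvent]
    gap_links: list[tuple[int, int]] = field(default_factory=list)  # (parent, child)

    def divisions_by_frame(self) -> dict[int, list[DivisionEvent]]:
        out: dict[int, list[DivisionEvent]] = {}
        for ev in self.divisions:
            out.setdefault(ev.frame, []).append(ev)
        return out


def build_forest(tracks: list[TrackRecord]) -> LineageForest:
    """Build the lineage forest and enumerate division events.

    Parents with exactly two daughters starting at the same frame yield one
    :class:`DivisionEvent`; single children are recorded as gap links.
    Cyclic parent references or >=3 simultaneous daughters raise
    :class:`LineageError`.
    """
    tmap = {t.label: t for t in tracks}
    # cycle check by walking parent chains
    for t in tracks:
        seen = {t.label}
        cur = t
        while cur.parent != 0 and cur.parent in tmap:
            if cur.parent in seen:
                raise LineageError(
                    f"cycle in parent links involving track {cur.parent}"
                )
            seen.add(cur.parent)
            cur = tmap[cur.parent]

    children: dict[int, dict[int, list[int]]] = {}
    for t in tracks:
        if t.parent != 0 and t.parent in tmap:
            children.setdefault(t.parent, {}).setdefault(t.begin, []).append(t.label)

    divisions: list[DivisionEvent] = []
    gap_links: list[tuple[int, int]] = []
    edges: dict[int, tuple[int, ...]] = {}
    for parent, groups in sorted(children.items()):
        for begin, labels in sorted(groups.items()):
            if len(labels) == 1:
                gap_links.append((parent, labels[0]))
            elif len(labels) == 2:
                pair = tuple(sorted(labels))
                divisions.append(DivisionEvent(begin, parent, pair))
                edges[parent] = pair
            else:
                raise LineageError(
                    f"parent {parent} has {len(labels)} simultaneous daughters"
                )
    divisions.sort()
    return LineageForest(
        nodes=sorted(tmap),
        edges=edges,
        divisions=divisions,
        gap_links=gap_links,
    )


def divisions_at(forest: LineageForest, frame: int) -> list[DivisionEvent]:
    """All divisions whose daughters first appear at ``frame``, by parent label."""
    evs = [ev for ev in forest.divisions if ev.frame == frame]
    evs.sort(key=lambda ev: ev.parent_label)
    return evs


def gap_aliases(forest: LineageForest) -> dict[int, int]:
    """Map each gap-linked child label to its root ancestor identity.

    Used when single-child parent links are scored as identity continuations
    (``link_gaps``): the child track then inherits the parent's identity for
    association counting.
    """
    parent_of = {child: parent for parent, child in forest.gap_links}
    alias: dict[int, int] = {}
    for child in parent_of:
        root = child
        while root in parent_of:
            root = parent_of[root]
        alias[child] = root
    return alias
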