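"""Cell-HOTA scores: detection, association, division accuracy and their
geometric combinations, swept over similarity thresholds.

At a threshold alpha:

* ``DetA = TP / (TP + FP + FN)`` — Jaccard index of detection;
* ``A(c) = TPA(c) / (TPA(c) + FPA(c) + FNA(c))`` for each detected true
  positive c, where TPA counts detections in which c's track pair is
  matched, FPA detections of the same tracker track that are matched to a
  different ground-truth track or left unmatched, and FNA detections of
  the same ground-truth track matched to a different tracker track or left
  unmatched — equivalently a Jaccard index over the union of the two
  tracks' detections; ``AssA`` is the mean of A(c) over all detected true
  positives;
* ``DivA = TPD / (TPD + FPD + FND)`` — Jaccard index of divisions
  (undefined when no divisions exist on either side);
* ``AssDivA = sqrt(AssA * DivA)``, ``Cell-HOTA = sqrt(DetA * AssDivA)`` and
  ``HOTA = sqrt(DetA * AssA)``.

The final scores average the per-alpha values over the 19-point grid
alpha = 0.05, 0.10, ..., 0.95.  On data without divisions AssDivA is defined
as AssA, so Cell-HOTA reduces exactly to HOTA.  Internally all scores live
in [0, 1]; reports multiply by 100.
"""

from __future__ import annotations

import csv
import json
import math
import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

from .ctc_io import Sequence
from .division_scoring import (
    AdjustedTallies,
    DivisionVerdict,
    apply_flex_adjustments,
    classify_divisions,
    detect_flexible,
)
from .lineage import build_forest, gap_aliases
from .matching import compute_similarity, global_alignment, match_at_alpha

__all__ = [
    "DEFAULT_ALPHA_GRID",
    "EvalConfig",
    "AssociationCounts",
    "AlphaCounts",
    "AlphaScores",
    "MetricReport",
    "detection_accuracy",
    "association_accuracy",
    "division_accuracy",
    "combine_alpha",
    "integrate",
    "evaluate",
]

#: alpha = 0.05, 0.10, ..., 0.95 — 19 thresholds
DEFAULT_ALPHA_GRID: tuple[float, ...] = tuple(
    round(0.05 * i, 2) for i in range(1, 20)
)


@dataclass(frozen=True)
class EvalConfig:
    """Evaluation settings.

    ``flex`` enables the one-frame early/late division tolerance (on by
    default); ``link_gaps`` scores single-child parent links as identity
    continuations instead of new identities (off by default).
    """

    alpha_grid: tuple[float, ...] = DEFAULT_ALPHA_GRID
    flex: bool = True
    link_gaps: bool = False

    def __post_init__(self):
        grid = tuple(self.alpha_grid)
        if not grid:
            raise ValueError("alpha grid must not be empty")
        if any(not (0.0 < a < 1.0) for a in grid):
            raise ValueError("alpha values must lie strictly in (0, 1)")
        if any(b <= a for a, b in zip(grid, grid[1:])):
            raise ValueError("alpha grid must be strictly increasing")
        object.__setattr__(self, "alpha_grid", grid)


@dataclass
class AssociationCounts:
    """Per track-pair TPA plus each track's total detection count.

    ``gt_total`` / ``res_total`` count every detection of a track — matched
    or not — so ``A(c)`` is the Jaccard index of the pair's matched
    detections over the union of the two tracks' detections.
    """

    tpa: Counter = field(default_factory=Counter)  # (gt, res) -> matched dets
    gt_total: Counter = field(default_factory=Counter)  # gt -> all detections
    res_total: Counter = field(default_factory=Counter)

    @classmethod
    def from_instances(
        cls,
        instances: list[tuple[int, int]],
        unmatched_gt: list[int] = (),
        unmatched_res: list[int] = (),
    ) -> "AssociationCounts":
        c = cls()
        for pair in instances:
            c.tpa[pair] += 1
            c.gt_total[pair[0]] += 1
            c.res_total[pair[1]] += 1
        for g in unmatched_gt:
            c.gt_total[g] += 1
        for r in unmatched_res:
            c.res_total[r] += 1
        return c

    def a_score(self, pair: tuple[int, int]) -> float:
        tpa = self.tpa[pair]
        # FPA = res detections outside the pair; FNA = gt detections outside
        fpa = self.res_total[pair[1]] - tpa
        fna = self.gt_total[pair[0]] - tpa
        return tpa / (tpa + fpa + fna)


@dataclass
class AlphaCounts:
    alpha: float
    tp: int
    fp: int
    fn: int
    tpd: int
    fpd: int
    fnd: int
    assoc: AssociationCounts
    instances: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class AlphaScores:
    alpha: float
    det_a: float
    ass_a: float
    div_a: float | None
    ass_div_a: float
    cell_hota: float
    hota: float


@dataclass
class MetricReport:
    """Per-alpha scores plus their means over the alpha grid."""

    alpha_grid: tuple[float, ...]
    per_alpha: list[AlphaScores]
    counts_per_alpha: list[AlphaCounts]
    flex_enabled: bool
    link_gaps: bool

    def _mean(self, attr: str) -> float | None:
        vals = [getattr(s, attr) for s in self.per_alpha]
        vals = [v for v in vals if v is not None]
        return sum(vals) / len(vals) if vals else None

    @property
    def cell_hota(self) -> float:
        return self._mean("cell_hota")

    @property
    def hota(self) -> float:
        return self._mean("hota")

    @property
    def det_a(self) -> float:
        return self._mean("det_a")

    @property
    def ass_a(self) -> float:
        return self._mean("ass_a")

    @property
    def ass_div_a(self) -> float:
        return self._mean("ass_div_a")

    @property
    def div_a(self) -> float | None:
        """Mean DivA over the alphas where it is defined; None if never."""
        return self._mean("div_a")

    # -- serialization (scores x100, rounded to 2 decimals only here) -------

    def to_dict(self) -> dict:
        def pct(v):
            return None if v is None else round(100.0 * v, 2)

        return {
            "config": {
                "flex": self.flex_enabled,
                "link_gaps": self.link_gaps,
                "alpha_grid": list(self.alpha_grid),
            },
            "alpha_grid": list(self.alpha_grid),
            "per_alpha": [
                {
                    "alpha": s.alpha,
                    "DetA": pct(s.det_a),
                    "AssA": pct(s.ass_a),
                    "DivA": pct(s.div_a),
                    "AssDivA": pct(s.ass_div_a),
                    "CellHOTA": pct(s.cell_hota),
                    "HOTA": pct(s.hota),
                }
                for s in self.per_alpha
            ],
            "integrated": {
                "DetA": pct(self.det_a),
                "AssA": pct(self.ass_a),
                "DivA": pct(self.div_a),
                "AssDivA": pct(self.ass_div_a),
                "CellHOTA": pct(self.cell_hota),
                "HOTA": pct(self.hota),
                "DivA_defined": self.div_a is not None,
            },
            "counts_per_alpha": [
                {
                    "alpha": c.alpha,
                    "TP": c.tp, "FP": c.fp, "FN": c.fn,
                    "TPD": c.tpd, "FPD": c.fpd, "FND": c.fnd,
                }
                for c in self.counts_per_alpha
            ],
        }

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")
        return path

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        d = self.to_dict()
        cols = ["alpha", "DetA", "AssA", "DivA", "AssDivA", "CellHOTA", "HOTA"]
        with open(path, "w", newline="") as fh:
            w = csv.DictWriter(fh, fieldnames=cols)
            w.writeheader()
            for row in d["per_alpha"]:
                w.writerow(row)
        return path


# ---------------------------------------------------------------------------
# the published formulas
# ---------------------------------------------------------------------------


def detection_accuracy(counts: AlphaCounts) -> float:
    """``TP / (TP + FP + FN)``; an empty universe scores 1 with a warning."""
    denom = counts.tp + counts.fp + counts.fn
    if denom == 0:
        warnings.warn(
            "no cells in either sequence; detection accuracy defined as 1",
            stacklevel=2,
        )
        return 1.0
    return counts.tp / denom


def association_accuracy(counts: AlphaCounts) -> float:
    """Mean of A(c) over all detected true positives; 0 if there are none."""
    if not counts.instances:
        warnings.warn(
            "no detected true positives; association accuracy defined as 0",
            stacklevel=2,
        )
        return 0.0
    assoc = counts.assoc
    return sum(assoc.a_score(pair) for pair in counts.instances) / len(
        counts.instances
    )


def division_accuracy(counts: AlphaCounts) -> float | None:
    """``TPD / (TPD + FPD + FND)``; None when no divisions exist at all."""
    denom = counts.tpd + counts.fpd + counts.fnd
    if denom == 0:
        return None
    return counts.tpd / denom


def combine_alpha(
    alpha: float, det_a: float, ass_a: float, div_a: float | None
) -> AlphaScores:
    """Geometric combinations at one alpha.

    ``AssDivA = sqrt(AssA * DivA)`` when DivA is defined, else AssA (so
    Cell-HOTA reduces to HOTA on division-free data); ``Cell-HOTA =
    sqrt(DetA * AssDivA)``; ``HOTA = sqrt(DetA * AssA)``.
    """
    ass_div_a = ass_a if div_a is None else math.sqrt(ass_a * div_a)
    return AlphaScores(
        alpha=alpha,
        det_a=det_a,
        ass_a=ass_a,
        div_a=div_a,
        ass_div_a=ass_div_a,
        cell_hota=math.sqrt(det_a * ass_div_a),
        hota=math.sqrt(det_a * ass_a),
    )


def integrate(
    per_alpha: list[AlphaScores],
    counts_per_alpha: list[AlphaCounts],
    config: EvalConfig,
) -> MetricReport:
    """Assemble the report; integrated scores are plain means over the grid."""
    if len(per_alpha) != len(config.alpha_grid):
        raise ValueError(
            f"{len(per_alpha)} score rows for a grid of "
            f"{len(config.alpha_grid)} alphas"
        )
    return MetricReport(
        alpha_grid=config.alpha_grid,
        per_alpha=per_alpha,
        counts_per_alpha=counts_per_alpha,
        flex_enabled=config.flex,
        link_gaps=config.link_gaps,
    )


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------


def _alias_instances(
    instances: list[tuple[int, int]],
    gt_alias: dict[int, int],
    res_alias: dict[int, int],
) -> list[tuple[int, int]]:
    if not gt_alias and not res_alias:
        return instances
    return [
        (gt_alias.get(g, g), res_alias.get(r, r)) for g, r in instances
    ]


def counts_at_alpha(
    tallies: AdjustedTallies,
    verdicts: list[DivisionVerdict],
    alpha: float,
    gt_alias: dict[int, int] | None = None,
    res_alias: dict[int, int] | None = None,
) -> AlphaCounts:
    gt_alias = gt_alias or {}
    res_alias = res_alias or {}
    instances = _alias_instances(tallies.instances, gt_alias, res_alias)
    if len(instances) != tallies.tp:
        raise AssertionError(
            "internal inconsistency: detected TP count "
            f"{tallies.tp} != association instances {len(instances)}"
        )
    tpd = sum(1 for v in verdicts if v.is_tp)
    fpd = sum(1 for v in verdicts if v.kind == "FPD")
    fnd = sum(1 for v in verdicts if v.kind == "FND")
    return AlphaCounts(
        alpha=alpha,
        tp=tallies.tp, fp=tallies.fp, fn=tallies.fn,
        tpd=tpd, fpd=fpd, fnd=fnd,
        assoc=AssociationCounts.from_instances(
            instances,
            [gt_alias.get(g, g) for g in tallies.unmatched_gt],
            [res_alias.get(r, r) for r in tallies.unmatched_res],
        ),
        instances=instances,
    )


def evaluate(
    gt: Sequence, res: Sequence, config: EvalConfig | None = None
) -> MetricReport:
    """Score a tracker sequence against ground truth.

    Runs similarity -> per-alpha matching -> division classification (with
    the flexible one-frame tolerance unless disabled) -> counts -> scores ->
    integration over the alpha grid.  Deterministic for fixed inputs.
    """
    config = config or EvalConfig()
    sim = compute_similarity(gt, res)
    align = global_alignment(sim, gt, res)
    gt_forest = build_forest(gt.tracks)
    res_forest = build_forest(res.tracks)
    gt_alias = gap_aliases(gt_forest) if config.link_gaps else {}
    res_alias = gap_aliases(res_forest) if config.link_gaps else {}

    per_alpha: list[AlphaScores] = []
    per_counts: list[AlphaCounts] = []
    for alpha in config.alpha_grid:
        matching = match_at_alpha(sim, align, alpha)
        verdicts = classify_divisions(gt_forest, res_forest, matching, alpha)
        adjustments = []
        if config.flex:
            verdicts, adjustments = detect_flexible(
                gt, res, gt_forest, res_forest, matching, verdicts, alpha
            )
        tallies = apply_flex_adjustments(matching, adjustments)
        counts = counts_at_alpha(tallies, verdicts, alpha, gt_alias, res_alias)
        det_a = detection_accuracy(counts)
        ass_a = association_accuracy(counts)
        div_a = division_accuracy(counts)
        per_alpha.append(combine_alpha(alpha, det_a, ass_a, div_a))
        per_counts.append(counts)
    return integrate(per_alpha, per_counts, config)
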