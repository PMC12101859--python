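# Methods

## Scope and data model

`cellhota` scores a tracker-produced sequence against a ground-truth
sequence. Both are Cell Tracking Challenge (CTC) layouts: one 2-D integer
label image per frame (background 0, 16-bit on disk) and a lineage table of
`label begin end parent` rows. Internally frames are contiguous 0-based
indices whatever numbering the files carry; labels are preserved verbatim.
Only 2-D masks are supported, and non-contiguous pixel blobs sharing one
label in a frame are a single detection (IOU is defined on pixel sets, not
connected components).

A division is a parent track with exactly two daughters beginning at the
same frame; the event is timestamped at the daughters' first frame, with
the parent required to end one frame earlier. Parents with three or more
simultaneous daughters are rejected. A parent with a single child is a CTC
gap-closing link, which is legal but flagged: by default the child is a
*new identity* for association (no division credit); with `link_gaps` the
child inherits the parent's identity through the whole alias chain.

## Matching

Per frame, IOUs are exact pixel-set Jaccard indices computed on the
identical image grid (no resampling). At each threshold α, matching is a
one-to-one maximum-score Hungarian assignment restricted to pairs with
**IOU strictly greater than α** — at α = 0.95 an IOU of exactly 0.95 is not
a match, and an IOU of 1 passes all 19 thresholds. The assignment score of
a candidate pair is a track-level alignment term (Jaccard index of the two
tracks' overlapping frames over their pooled frames) plus `1e-6 ×` the
per-frame IOU, with a `1e-12` bias toward low label ranks so that ties
resolve deterministically. Matching is recomputed independently at every α:
counts at high stringency never inherit low-stringency pairings.

The alignment-biased per-frame assignment is a heuristic for the matching
that maximizes the final score. With the association formula below, each
pair's A(c) denominator depends only on the tracks' detection inventories,
not on the matching, so adding a valid match never lowers the score and the
per-frame optimum composes to the global one; the test suite verifies, on
several hundred random small instances, that the heuristic reproduces the
score of an exhaustive enumeration of all per-frame matchings to 1e-9.

## Scores

At each α, with TP/FP/FN the matched / unmatched-tracker /
unmatched-ground-truth detection counts:

- `DetA = TP / (TP + FP + FN)`.
- For each detected true positive c with track pair (i, j):
  `A(c) = TPA / (TPA + FPA + FNA)` where TPA is the number of detections on
  which i and j are matched to each other, FPA the remaining detections of
  tracker track j (matched elsewhere or unmatched) and FNA the remaining
  detections of ground-truth track i. Equivalently
  `A(c) = TPA / (|dets(i)| + |dets(j)| − TPA)`. `AssA` is the mean of A(c)
  over all detected true positives; the per-pair weighted form is used
  internally for speed.
- `DivA = TPD / (TPD + FPD + FND)`, with TPD defined by the three-criteria
  test (daughter set matched at the division frame, parents matched one
  frame earlier, mean daughter IOU > α). When several candidate pairings
  exist at one frame they are taken greedily by highest mean daughter IOU,
  ties by lowest parent labels; each division on either side is consumed at
  most once.
- `AssDivA = sqrt(AssA × DivA)`, `Cell-HOTA = sqrt(DetA × AssDivA)`,
  `HOTA = sqrt(DetA × AssA)`; final scores are arithmetic means over the
  19-point grid α = 0.05 … 0.95.

Degenerate cases: with no cells anywhere DetA is reported as 1 with a
warning (empty agreement); with no detected true positives AssA is 0 with a
warning; with no divisions on either side DivA is undefined and
`AssDivA := AssA`, so Cell-HOTA reduces *exactly* to HOTA on division-free
data — a testable limit. The integrated DivA averages only the α values
where DivA is defined (definedness does not actually vary with α: the
denominator `gt divisions + tracker divisions − TPD` is zero only when
neither side divides); the report flags whether DivA was ever defined.
Reports multiply by 100 and round to 2 decimals at serialization only.

## Flexible divisions

A division predicted exactly one frame before (*early*) or after (*late*)
the ground truth can optionally be scored as correct (`flex`, on by
default). Only divisions left unmatched by the strict same-frame
classification are considered. For a tracker division at t1 whose parent
matched, at t0 = t1 − 1, a ground-truth cell that divides at t2 = t1 + 1
(early; mirrored for late), the upgrade requires the daughters to match at
t2 with mean IOU > α. The counts are then adjusted as if the division were
on time:

- **Detection** — at t1 the two cells of the divided side are merged into
  one object; its IOU against the single cell on the other side replaces
  the individual outcomes. For a late division this merged IOU is counted
  twice, because the merged object stands for two ground-truth cells; this
  equal per-ground-truth-cell weighting is what makes the score identical
  whether the tracker divided on time, early or late.
- **Association** — at t1 the match list is rewired to the ground-truth
  lineage: early adds (ground-truth cell, tracker parent) and removes the
  ground-truth cell's match with a tracker daughter; late adds both
  (ground-truth daughter, tracker daughter) pairs as matched at t2 and
  removes the match between one daughter and the undivided tracker cell.

One design point was genuinely open: whether a flexible upgrade survives
when the *merged* IOU at t1 fails the α test even though the daughter IOUs
at t2 pass. Here the whole upgrade is reverted in that case — verdict back
to FPD + FND, no detection or association adjustment — which keeps the
detected-TP count equal to the number of association match instances (the
normalization of AssA) at every α. On perfect-mask fixtures the merged IOU
is exactly 1, so the gate is inert there. Likewise unspecified was *which*
daughter match to remove for an early division; since the matching is
one-to-one, at most one daughter can hold the ground-truth cell's match at
t1, and that one is removed — the symmetric perfect-mask property tests
confirm A(c) values do not depend on this choice.

Divisions at the movie boundary cannot flex (no t0 or no t2), and the
window is fixed at one frame in this version.

## Synthetic scenarios

The generator emulates the two target regimes: `mother_machine_1d` places
each lineage in its own channel column with cells stacked along the channel
axis, and `open_2d` scatters rectangular or elliptical cells on a jittered
grid. Masks are static between divisions and distinct lineages are
separated by background, so every perturbed IOU is an exact pixel-count
ratio (an eroded cell keeping 60 of 100 pixels has IOU 60/100 at every
affected frame). At a scheduled division the parent mask is split along its
longer axis into two halves whose union is exactly the parent mask; the
daughters touch each other (the background-separation rule applies between
lineages), which makes the division-shift perturbations exact: shifting
early replaces the parent mask by the daughter masks one frame sooner, and
shifting late replaces the daughter masks by their union, so the flexible
merged IOU is exactly 1 and the flex-invariance property holds with
equality rather than within tolerance.

Perturbation kinds map one-to-one onto error families: `erode`/`dilate`/
`translate` (localization), `drop_detection` (FN; a mid-track drop splits
the identity, as a real tracker restart would), `add_spurious` (FP),
`id_swap` (association: both identities end at the swap frame and fresh
identities continue the crossed trajectories), `shift_division_early`/
`shift_division_late` (division timing), `merge_cells` (detection). All
generation is deterministic for a fixed seed.

What the fixtures do *not* emulate: cell growth and shape change, touching
cells from different lineages, intensity noise, segmentation masks with
ragged borders, and dense fields where many cells overlap many others.
Passing the suite therefore demonstrates the correctness of the counting
and score algebra under controlled conditions, not robustness of any
tracker, and real microscopy data will exercise matching ambiguity far more
than these fixtures do.

## Problem sizes and verification

The oracle-equivalence checks run the evaluator against an independent
brute-force implementation that enumerates every combination of per-frame
matchings and keeps the score-maximal one; this is only tractable on small
instances, so those tests use 1-3 cells over 2-4 frames (up to 4 cells per
frame after a spurious detection), 200 seeded instances at all 19
thresholds. The acceptance script uses 60 random division-free instances
plus the named catalog; all randomness derives from the single `--seed`
argument.
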