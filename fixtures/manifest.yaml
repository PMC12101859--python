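# Named synthetic scenarios with hand-computed expected scores.
#
# All scenarios are built programmatically (seed 0) by
# cellhota.build_scenario(name); scores are integrated over the default
# 19-point alpha grid, x100, 2 decimals.  Derivations:
#
# perfect     identity tracker: every IOU is 1 > alpha at all 19 thresholds.
# id_swap     2 cells x 4 frames, both identities lost and re-initialized at
#             frame 2: each track pair has TPA=2 matched of 4+2-2=4 pooled
#             detections, so every A(c)=0.5; masks perfect so DetA=100.
# erosion     one 100-px cell kept at 60 px in all 3 frames: IOU=0.6 exactly,
#             a match at the 11 thresholds 0.05..0.55 (strict IOU>alpha) and
#             a FP+FN at the 8 thresholds 0.60..0.95 -> means 11/19=57.89.
# drop        2 cells x 4 frames, one detection dropped mid-track (track 2,
#             frame 1; the continuation is a new identity): TP=7 FN=1 ->
#             DetA=7/8; A(c)=1 (x4), 1/4 (x1), 1/2 (x2) -> AssA=5.25/7=75;
#             CellHOTA=sqrt(0.875*0.75)=81.01.
# spurious    2 cells x 4 frames + one 16-px spurious cell in one frame:
#             TP=8 FP=1 -> DetA=8/9=88.89, AssA=100, CellHOTA=sqrt(8/9)=94.28.
# shift_early/late  one lineage, division moved one frame, perfect masks:
#             with flexible divisions the score equals the error-free 100.
perfect:     {CellHOTA: 100.00, DetA: 100.00, AssA: 100.00, DivA: 100.00}
id_swap:     {CellHOTA: 70.71,  DetA: 100.00, AssA: 50.00,  DivA: null}
erosion:     {CellHOTA: 57.89,  DetA: 57.89,  AssA: 57.89,  DivA: null}
drop:        {CellHOTA: 81.01,  DetA: 87.50,  AssA: 75.00,  DivA: null}
spurious:    {CellHOTA: 94.28,  DetA: 88.89,  AssA: 100.00, DivA: null}
shift_early: {CellHOTA: 100.00, DetA: 100.00, AssA: 100.00, DivA: 100.00}
shift_late:  {CellHOTA: 100.00, DetA: 100.00, AssA: 100.00, DivA: 100.00}
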