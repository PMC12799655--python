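"""Close the diagnostic loop: simulate each affected side, observe the prone
step of a rightward roll, and feed that observation into the prone-step
lateralization rule.
"""

from canalith import RollPlan, lateralize_from_prone, make_canal, predict_roll

for side in ("right", "left"):
    preds, _ = predict_roll(make_canal(side), RollPlan(direction="rightward"))
    prone = next(p for p in preds if p.pose == "prone")
    (observed,) = prone.outcome_set
    result = lateralize_from_prone("rightward", observed)
    print(f"true side: {side:5s}  prone observation: {observed:10s}")
    print(f"  -> inferred side: {result.affected_side}, "
          f"treating correct side: {result.treating_correct_side}")
    print(f"     {result.note}")
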