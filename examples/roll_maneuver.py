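"""Simulate a rightward logroll for each affected side and print the
per-pose nystagmus predictions.

The clinically decisive observation is the prone step: the right canal
produces right-beat nystagmus there, the left canal none (the otolith has
already fallen into the utricle), so prone alone lateralizes the side.
"""

from canalith import RollPlan, make_canal, predict_roll

for side in ("right", "left"):
    canal = make_canal(side, "true_posteromedial")
    preds, report = predict_roll(canal, RollPlan(direction="rightward"))
    print(f"\n{side}-sided horizontal canal, rightward roll from supine:")
    for step in preds:
        outcomes = ", ".join(sorted(step.outcome_set))
        print(f"  {step.pose:>16s} (gravity {step.gravity:3.0f} deg): {outcomes}")

print(
    "\nSets with more than one entry enumerate branch alternatives (the"
    "\notolith may or may not escape the utricle, or leave an unstable"
    "\nequilibrium); single entries are deterministic predictions."
)
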