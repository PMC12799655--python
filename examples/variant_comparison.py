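"""Where the true (posteromedial) and hypothetical (anteromedial) canal
anatomies predict different nystagmus during a rightward roll.
"""

from canalith import compare_variants

for side in ("right", "left"):
    rep = compare_variants(side)
    print(f"\n{side}-sided canal, rightward roll from supine:")
    for pt, ph in zip(rep.true_predictions, rep.hypothetical_predictions):
        mark = "  <-- diverges" if pt.outcome_set != ph.outcome_set else ""
        print(
            f"  {pt.pose:>16s}: true {sorted(pt.outcome_set)} "
            f"vs hypothetical {sorted(ph.outcome_set)}{mark}"
        )

print(
    "\nEvery diverging pose is an observation that could empirically"
    "\ndistinguish the two anatomical models at the bedside."
)
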