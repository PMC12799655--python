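"""Instantaneous bow/lean predictions for a right canal modeled with an
anteromedial segment, at the six canonical configurations: canalith in the
lateral (p=270 deg) or anteromedial (p=80 deg) segment, head neutral, leaned
back 60 deg, or bowed forward 90 deg.
"""

from canalith import BowLeanConfig, bow_lean_predict, make_canal

canal = make_canal("right", "hypothetical_anteromedial")
cases = [
    ("lateral segment, neutral", 270, 0),
    ("lateral segment, lean -60", 270, -60),
    ("lateral segment, bow +90", 270, 90),
    ("anteromedial segment, neutral", 80, 0),
    ("anteromedial segment, lean -60", 80, -60),
    ("anteromedial segment, bow +90", 80, 90),
]
for label, p, pitch in cases:
    ev = bow_lean_predict(canal, p, BowLeanConfig(pitch))
    print(f"{label:32s} -> {ev.qualifier:6s} {ev.direction:10s} (|F| = {ev.intensity:.2f})")

print(
    "\n|F| is the in-plane tangential gravity component on the canalith;"
    "\nclockwise force (viewed from below) predicts right-beat nystagmus."
)
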