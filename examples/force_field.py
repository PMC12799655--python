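"""Render the (p, d) force field as Cartesian and polar plots with the
rightward-roll trajectory of a right-sided canal overlaid.

Writes field_cartesian.png and field_polar.png to the working directory.
Red cells = clockwise force (right-beat nystagmus), blue = counterclockwise
(left-beat); the black diagonal is the stable-equilibrium locus d = p, the
white diagonal the unstable locus; in polar coordinates the stable locus
appears as a single-armed spiral.
"""

from canalith import (
    RollPlan,
    compute_field,
    make_canal,
    overlay_from_report,
    predict_roll,
    render_cartesian,
    render_polar,
)

grid = compute_field(resolution=360)
_, report = predict_roll(make_canal("right"), RollPlan())
overlay = overlay_from_report(report, start_gravity=180)

render_cartesian(grid, overlay, "field_cartesian.png")
render_polar(grid, overlay, "field_polar.png")
print("wrote field_cartesian.png and field_polar.png")
print(f"overlay waypoints (label, p, d): {overlay.waypoints}")
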