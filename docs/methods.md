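# Methods

## Model and assumptions

The package models a single free-floating otoconial mass in the horizontal
semicircular canal as a point particle on a circle, moving quasi-statically
under gravity. "Quasi-static" means each maneuver step holds one head pose
long enough for the particle to reach a terminal configuration; gravity
changes as a discrete jump between steps, and there is no inertia, no
endolymph fluid dynamics, and no cupular time constant. The model is purely
positional: the observable it predicts per step is the direction and peak
strength of otolith motion, mapped onto nystagmus direction (clockwise
motion, viewed from inferior to superior, → right-beat; counterclockwise →
left-beat; no in-lumen motion → no nystagmus). Slow-phase velocity in °/s is
*not* modeled; |F| is exposed only as a relative intensity proxy, because
nothing in the model fixes a linear mapping from tangential force to eye
velocity.

Key assumptions, each a deliberate simplification:

* **The canal plane is vertical** for all lying poses, so gravity's in-plane
  direction is a single angle d. The bow/lean operation is the one place a
  third dimension enters, reduced analytically (below).
* **The ampulla is impassable** (the cupula seals it); an otolith pressed
  against it generates no nystagmus, because only motion is scored —
  sustained cupular deflection is explicitly out of scope.
* **The utricle is a positionless sac**, not a traversable arc. Exit through
  the opening is deterministic and silent at the moment of crossing;
  re-entry is offered as a branch exactly when the tangential force at the
  opening points into the lumen. This branch structure is what produces the
  "either/or" rows of the roll predictions.
* **Cupulolithiasis** (debris adherent to the cupula) and multi-particle
  interactions are out of scope.

## Equilibria and branching

F = sin(d − p) vanishes at separations 0° (stable) and 180° (unstable);
classification uses an angular tolerance of 1e−6° (poses are multiples of
90°, so collinear cases arise exactly, and the tolerance only needs to
absorb floating-point wrap error). At an unstable equilibrium the simulator
emits three branches (stay, clockwise nudge, counterclockwise nudge); in the
utricle it emits one or two (stay; re-enter when the opening force points
inward, judged with a 1e−12 zero tolerance on sin so that exactly collinear
gravity never opens a spurious branch). Branches are deduplicated by final
compartment, final angle rounded to 0.01°, and nystagmus direction, and the
sequence simulator caps the live branch count at 64 (never approached by the
four-step rolls, which stay ≤ 3). Because branch enumeration is exhaustive
and ordered, the package needs no randomness anywhere.

The deterministic settle endpoint is computed analytically (first stopping
event among stable point, ampulla, opening along the motion direction); a
brute-force fine-step descent (`integrate_descent`, default 0.05° steps)
serves as an independent oracle and is required to agree within 2 steps.
Every reported motion segment is monotonically downhill in the potential
h = −cos(p − d), which the tests verify at 0.1° sampling.

## Anatomy parameters

No published endpoint angles exist for the canal arc abstraction, so the
defaults are the package's own choice, constrained by anatomy and exposed as
overridable parameters (degrees):

| side/variant        | ampulla | opening | orientation | span |
|---------------------|--------:|--------:|:-----------:|-----:|
| right / true        |  20     | 140     | ccw         | 240  |
| left / true         | 340     | 220     | cw          | 240  |
| right / hypothetical| 315     |  75     | ccw         | 240  |
| left / hypothetical |  45     | 285     | cw          | 240  |
| right / arc180      |   0     | 180     | ccw         | 180  |
| left / arc180       |   0     | 180     | cw          | 180  |

Constraints realized: the true variant's opening is posteromedial and the
hypothetical variant's anteromedial for the correct ear; both named variants
span 240° so comparisons isolate the opening's location (the literature's
180°-arc model is the third variant; the hypothetical minus 180° spans give
the "extra" 60° attributed to the anteromedial segment); and the true
ampulla sits slightly medial of straight anterior, since both canal ends
attach to the medially placed utricle — this offset is what makes the
left-side-lying step of a rightward roll produce right-beat on the right
side. The true variant's span is itself unpublished; 240° is adopted for
symmetry and is configurable. The roll predictions are insensitive to all
of these choices within ±10° per endpoint (tested exhaustively over the
3 × 3 perturbation grid).

Mirror symmetry (x → 360 − x, side and orientation swapped) is an involution
that maps each left default onto the corresponding right default, and the
simulator is equivariant under it with right/left beat swapped — a strong
internal consistency check on the sign conventions.

## Bow and lean

In the neutral upright head the horizontal canal plane is tilted about
τ = 30° backward. Pitching the head by θ (positive = bow forward, negative =
lean back) leaves an in-plane gravity component along the canal's anterior
axis of signed magnitude m = sin(θ − τ); the instantaneous tangential force
on a canalith at p is F = m·sin(0° − p). The prediction is momentary (the
otolith is not stepped), matching how the bedside test is read at onset. The
panel defaults are θ = +90° for bow (the canal roughly vertical, utricle
above ampulla) and θ = −60° for lean (canal near vertical the other way);
both are configurable. The modest/robust intensity grading threshold is
|F| = 0.6, chosen to separate the neutral-position stimuli (|F| ≈ 0.48–0.50)
from the pitched ones (|F| ≈ 0.85–1.0); it is a label boundary, not a
physiological constant.

## Visualization conventions

The field plots sample F on cell-centered grids (default 360 × 360; minimum
36). Hue encodes only sign(F) (red = clockwise/right-beat, blue =
counterclockwise/left-beat), saturation only |F|; the stable locus d = p is
drawn black and the unstable locus white, each one grid cell wide, overriding
the field color. The polar rendering maps p to the angular coordinate
(clockwise from anterior, matching the compass) and d linearly onto
[0.15, 1.0] of the plot radius — the inner hole keeps the d = 0 circle
visible and "d increases outward" is a convention, not a claim. Both
renderings share one RGB mapping function, so their colors agree exactly at
every cell. Trajectory overlays draw held-pose motion as horizontal
displacement, pose changes as vertical displacement, branch alternatives
translucent, and pieces touching the 0° = 360° seam dashed; waypoints are
lettered in event order. Rendering is deterministic (fixed SVG hash salt, no
timestamps), so identical inputs give byte-identical vector output.

## Numerical choices and degenerate inputs

* Angles wrap to [0, 360); trig is evaluated in radians internally, degrees
  everywhere in the API.
* Compartment boundaries use a 1e−9° tolerance; canal spans outside
  (90°, 350°) are rejected as non-physical.
* A descent that starts at a boundary and is pushed outward resolves without
  a motion segment (silent exit or pinned at the seal).
* An otolith whose stable point falls exactly on the opening rests there
  (the stable case wins the tie).
* Step-sequence reports of held identical poses are idempotent: settling a
  settled state yields one motionless branch.

## What the packaged scenarios do and do not show

The packaged fixtures are configurations, not data: they encode the
canonical study conditions (rightward roll from the supine settled state,
p = 180°, for each side and variant; the six bow/lean cases). Passing tests
show the model's internal consistency and that these configurations
reproduce the expected categorical outcome sets — they cannot show that real
patients' canals match the default endpoint angles, that debris behaves as a
single point mass, or that nystagmus intensity tracks |F|; those remain
empirical questions the model is designed to sharpen, not settle.

## Known limitations

Prone-position nystagmus is hard to observe without video-oculography, so
the model's key diagnostic step may require instrumentation in practice.
The model offers no treatment-maneuver optimization, no Gufoni/Appiani
maneuvers, and no apogeotropic cupulolithiasis variants.
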