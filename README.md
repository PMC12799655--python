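# canalith

Quasi-static canalith dynamics and nystagmus prediction for horizontal canal
benign paroxysmal positional vertigo (BPPV).

In horizontal canal BPPV, free-floating otoconial debris (a "canalith" or
"otolith") inside the horizontal semicircular canal slides under gravity when
the head is repositioned; the resulting endolymph displacement produces
horizontal positional nystagmus. Diagnosis requires *lateralizing* the
affected ear, because the therapeutic logroll (Lempert) maneuver must roll
away from it — and lateralization is notoriously hard. `canalith` is a small
library (plus a thin CLI) for clinicians and vestibular researchers that
models this system explicitly and turns anatomical assumptions into testable
bedside predictions.

## The model

Work in the plane of the horizontal canal, viewed from inferior to superior,
with a compass in degrees: 0° anterior, 90° toward the patient's left, 180°
posterior, 270° toward the patient's right. Two variables describe any
positional test on a lying patient: the otolith position *p* on the canal
circle and the gravity direction *d* (prone → 0°, left side-lying → 90°,
supine → 180°, right side-lying → 270°). The component of gravity tangential
to the lumen is

```
F = sin(d − p)
```

with *F* > 0 a clockwise push (right-beat nystagmus) and *F* < 0
counterclockwise (left-beat). *F* vanishes when *p* and *d* are collinear:
separation 0° is a stable equilibrium, 180° an unstable one. Motion is
quasi-static — each held pose lets the otolith slide downhill in the
potential *h* = −cos(*p* − *d*) until it rests at *p* = *d*, is pressed
against the sealed ampulla, or exits into the utricle through the canal's
utricular opening. At unstable equilibria and at the utricular opening the
outcome is indeterminate, so the simulator enumerates *branches* (stay /
escape clockwise / escape counterclockwise; stay in the utricle / re-enter
the lumen) and reports the full set of possible nystagmus outcomes per pose.

The canal itself is an arc with a sealed ampulla at one end and a permeable
utricular opening at the other. Three anatomy variants are built in: the
**true** anatomy, whose medial limb is *posteromedial* (opening in the
posteromedial quadrant); the **hypothetical** anatomy assumed by much of the
bow-and-lean literature, with an *anteromedial* limb; and a simple 180° arc.
Both named variants span 240° of arc, so their differing predictions isolate
the location of the opening.

## Worked example

```
$ python examples/roll_maneuver.py

right-sided horizontal canal, rightward roll from supine:
  right_side_lying (gravity 270 deg): right_beat
             prone (gravity   0 deg): right_beat
   left_side_lying (gravity  90 deg): right_beat
            supine (gravity 180 deg): none

left-sided horizontal canal, rightward roll from supine:
  right_side_lying (gravity 270 deg): right_beat
             prone (gravity   0 deg): none
   left_side_lying (gravity  90 deg): left_beat, none
            supine (gravity 180 deg): left_beat, none, right_beat
```

The prone step separates the sides: with right-sided involvement every
branch produces right-beat nystagmus (the otolith slides clockwise to the
new dependent position), while with left-sided involvement the otolith has
already fallen into the utricle and the step is silent. Feeding that
observation into the prone-step rule (`lateralize_from_prone`) recovers the
affected ear and tells you whether the roll under way is treating the
correct side. Sets with several entries enumerate branch alternatives — for
example at left side-lying the left-canal otolith may stay in the utricle
(no nystagmus) or re-enter the lumen (left-beat).

Other examples, one per capability:

* `examples/bow_lean.py` — the six bow/lean stimulus predictions for a canal
  modeled with an anteromedial segment,
* `examples/lateralization.py` — the closed diagnostic loop,
* `examples/variant_comparison.py` — poses where the true and hypothetical
  anatomies disagree,
* `examples/force_field.py` — Cartesian and polar force-field plots with the
  roll trajectory overlaid.

The same operations are available from the shell:

```
canalith simulate --fixture table5_right_true --out-json report.json
canalith lateralize --roll rightward --observed none
canalith field --cartesian field.png --polar polar.png
```

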