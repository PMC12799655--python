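"""Quasi-static branching simulation of otolith motion under held gravity.

The model is purely positional: each step of a maneuver holds one gravity
direction ``d``, and the otolith slides along the lumen in the direction of
the tangential force ``F = sin(d - p)`` until it reaches the stable point
``p = d``, is pressed against the sealed ampulla, or exits through the
utricular opening into the utricle.  There is no inertia and no time axis;
what is reported per step is the direction and peak strength of the motion,
which maps directly onto nystagmus (clockwise → right-beat, counterclockwise
→ left-beat, viewed from inferior to superior).

Branching.  At an unstable equilibrium the outcome is indeterminate: the
otolith may stay, or a perturbation may send it clockwise or counterclockwise.
Likewise an otolith resting in the utricle (a positionless sac in this model)
may or may not re-enter the lumen when the force at the opening points inward.
:func:`settle` therefore returns a *list* of branches, and
:func:`simulate_sequence` expands every live branch at every step,
deduplicating identical outcomes, so a maneuver report enumerates every
qualitatively distinct course of events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .anatomy import CanalSpec, Compartment, locate
from .geometry import (
    EquilibriumKind,
    classify_equilibrium,
    directional_distance,
    gravity_to_pose,
    tangential_force,
    wrap_angle,
)

__all__ = [
    "OtolithState",
    "MotionSegment",
    "NystagmusEvent",
    "Branch",
    "StepRecord",
    "ManeuverReport",
    "settle",
    "integrate_descent",
    "nystagmus_of",
    "simulate_sequence",
    "MODEST_ROBUST_THRESHOLD",
    "BRANCH_CAP",
]

#: |F| above which an evoked nystagmus is graded "robust" rather than
#: "modest".  Chosen to separate the weak neutral-position bow/lean stimuli
#: (|F| ≈ 0.48-0.50) from the strong pitched ones (|F| ≈ 0.85-1.0).
MODEST_ROBUST_THRESHOLD = 0.6

#: Safety cap on live branches during sequence simulation.
BRANCH_CAP = 64

_DEDUP_DECIMALS = 2  # dedup key rounds p to 0.01°


@dataclass(frozen=True)
class OtolithState:
    """Where the otolith is: in the lumen at angle ``p``, or in the utricle.

    The utricle is modeled as a positionless sac, so ``p`` is ``None`` there.
    An otolith pressed against the sealed ampulla is in the lumen with
    ``p = ampulla_angle``.
    """

    compartment: str  # "in_lumen" | "in_utricle"
    p: float | None = None

    def __post_init__(self) -> None:
        if self.compartment == "in_lumen":
            if self.p is None:
                raise ValueError("in_lumen state requires a position angle p")
            object.__setattr__(self, "p", wrap_angle(self.p))
        elif self.compartment == "in_utricle":
            if self.p is not None:
                raise ValueError("in_utricle state carries no position")
        else:
            raise ValueError(
                f"compartment must be 'in_lumen' or 'in_utricle', got {self.compartment!r}"
            )

    @classmethod
    def in_lumen(cls, p: float) -> "OtolithState":
        return cls("in_lumen", p)

    @classmethod
    def in_utricle(cls) -> "OtolithState":
        return cls("in_utricle")

    def to_dict(self) -> dict:
        return {"compartment": self.compartment, "p": self.p}


@dataclass(frozen=True)
class MotionSegment:
    """One continuous arc of motion at a held gravity direction."""

    start: float
    end: float
    rotation_sense: str  # "cw" | "ccw" | "none"
    in_lumen: bool
    peak_force: float  # max |sin(d - p)| along the arc, in [0, 1]

    def to_dict(self) -> dict:
        return {
            "start": self.start,
            "end": self.end,
            "rotation_sense": self.rotation_sense,
            "in_lumen": self.in_lumen,
            "peak_force": self.peak_force,
        }


@dataclass(frozen=True)
class NystagmusEvent:
    """Predicted nystagmus for one branch of one maneuver step.

    Direction follows the rotation sense of in-lumen otolith motion (motion
    inside the utricle is clinically silent); intensity is the peak |F| of
    that motion, graded modest below :data:`MODEST_ROBUST_THRESHOLD` and
    robust at or above it.
    """

    direction: str  # "right_beat" | "left_beat" | "none"
    intensity: float = 0.0
    qualifier: str = "none"  # "modest" | "robust" | "none"
    biphasic: bool = False

    def to_dict(self) -> dict:
        d = {
            "direction": self.direction,
            "intensity": self.intensity,
            "qualifier": self.qualifier,
        }
        if self.biphasic:
            d["biphasic"] = True
        return d


NO_NYSTAGMUS = NystagmusEvent("none", 0.0, "none")


@dataclass(frozen=True)
class Branch:
    """One possible course of events for a single held gravity direction."""

    label: str
    segments: tuple[MotionSegment, ...]
    final: OtolithState
    nystagmus: NystagmusEvent

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "segments": [s.to_dict() for s in self.segments],
            "final": self.final.to_dict(),
            "nystagmus": self.nystagmus.to_dict(),
        }


_BRANCH_LABELS = {
    "deterministic",
    "unstable_stay",
    "unstable_cw",
    "unstable_ccw",
    "utricle_stay",
    "utricle_reenter",
}


def _grade(intensity: float) -> str:
    return "modest" if intensity < MODEST_ROBUST_THRESHOLD else "robust"


def _event_from_segments(segments: tuple[MotionSegment, ...]) -> NystagmusEvent:
    senses = []
    peak = 0.0
    for seg in segments:
        if seg.in_lumen and seg.rotation_sense in ("cw", "ccw"):
            senses.append(seg.rotation_sense)
            peak = max(peak, seg.peak_force)
    if not senses:
        return NO_NYSTAGMUS
    direction = "right_beat" if senses[0] == "cw" else "left_beat"
    biphasic = len(set(senses)) > 1
    return NystagmusEvent(direction, peak, _grade(peak), biphasic)


def nystagmus_of(branch: Branch) -> NystagmusEvent:
    """Map a branch's motion segments to the nystagmus they would evoke."""
    return _event_from_segments(branch.segments)


def _peak_force_on_arc(p0: float, p1: float, d: float, sense: str) -> float:
    """max |sin(d - p)| for p travelling from p0 to p1 in the given sense.

    |F| = 1 exactly where the separation wrap(d - p) is 90° or 270°; if
    neither such point lies on the arc the maximum is at an endpoint.
    """
    arc = directional_distance(p0, p1, sense)
    for q in (wrap_angle(d - 90.0), wrap_angle(d + 90.0)):
        if directional_distance(p0, q, sense) <= arc:
            return 1.0
    return max(abs(tangential_force(p0, d)), abs(tangential_force(p1, d)))


def _descend(p0: float, d: float, sense: str, canal: CanalSpec) -> tuple[
    tuple[MotionSegment, ...], OtolithState
]:
    """Slide from ``p0`` in ``sense`` until the first stopping event.

    Stopping events, in order of encounter along the arc: the stable point
    ``p = d`` (rest), the ampulla (rest, pressed against the seal), or the
    utricular opening travelling outward (exit into the utricle).
    """
    here = locate(canal, p0)
    # At a boundary, motion may be impossible before it starts.
    if here is Compartment.AMPULLA_BOUNDARY and sense != canal.lumen_orientation:
        # pushed into the seal: no motion
        return (), OtolithState.in_lumen(p0)
    if here is Compartment.OPENING_BOUNDARY and sense == canal.lumen_orientation:
        # pushed outward through the opening: immediate silent exit
        return (), OtolithState.in_utricle()

    dist_stable = directional_distance(p0, d, sense)
    if sense == canal.lumen_orientation:
        boundary = canal.opening_angle
        boundary_kind = "opening"
    else:
        boundary = canal.ampulla_angle
        boundary_kind = "ampulla"
    dist_boundary = directional_distance(p0, boundary, sense)
    if dist_boundary == 0.0:  # starting at that boundary, moving away from it
        dist_boundary = 360.0

    if 0.0 < dist_stable <= dist_boundary:
        end = wrap_angle(d)
        seg = MotionSegment(p0, end, sense, True, _peak_force_on_arc(p0, end, d, sense))
        return (seg,), OtolithState.in_lumen(end)
    seg = MotionSegment(
        p0, boundary, sense, True, _peak_force_on_arc(p0, boundary, d, sense)
    )
    if boundary_kind == "ampulla":
        return (seg,), OtolithState.in_lumen(boundary)
    return (seg,), OtolithState.in_utricle()


def _dedup_key(branch: Branch) -> tuple:
    st = branch.final
    p_key = None if st.p is None else round(st.p, _DEDUP_DECIMALS) % 360.0
    return (st.compartment, p_key, branch.nystagmus.direction)


def _merge(branches: list[Branch]) -> list[Branch]:
    seen: dict[tuple, Branch] = {}
    out: list[Branch] = []
    for b in branches:
        k = _dedup_key(b)
        if k not in seen:
            seen[k] = b
            out.append(b)
    return out


def settle(state: OtolithState, d: float, canal: CanalSpec, tol: float = 1e-6) -> list[Branch]:
    """Enumerate every possible outcome of holding gravity at ``d``.

    * In-lumen, off equilibrium: one deterministic branch sliding in the
      direction of the force until rest or exit.
    * In-lumen at an unstable equilibrium: three branches — stay put, or
      settle after a clockwise / counterclockwise nudge.
    * In the utricle: always a stay branch; additionally a re-entry branch
      (otolith appears at the opening and settles) exactly when the force at
      the opening points into the lumen.

    Branches with identical final state and nystagmus are merged.
    """
    d = wrap_angle(d)
    if state.compartment == "in_utricle":
        branches = [Branch("utricle_stay", (), state, NO_NYSTAGMUS)]
        f_open = tangential_force(canal.opening_angle, d)
        if abs(f_open) < 1e-12:  # collinear cases: sin noise must not open a branch
            f_open = 0.0
        inward = canal.into_lumen_sense
        if (f_open > 0 and inward == "cw") or (f_open < 0 and inward == "ccw"):
            segs, final = _descend(canal.opening_angle, d, inward, canal)
            branches.append(
                Branch("utricle_reenter", segs, final, _event_from_segments(segs))
            )
        return _merge(branches)

    p = state.p
    where = locate(canal, p)
    if where is Compartment.UTRICLE_GAP:
        raise ValueError(
            f"otolith position {p:.3f}° lies in the utricle gap of this canal; "
            "an in-lumen state must be on the lumen arc"
        )

    eq = classify_equilibrium(p, d, tol)
    if eq is EquilibriumKind.STABLE:
        return [Branch("deterministic", (), state, NO_NYSTAGMUS)]
    if eq is EquilibriumKind.UNSTABLE:
        branches = [Branch("unstable_stay", (), state, NO_NYSTAGMUS)]
        for sense, label in (("cw", "unstable_cw"), ("ccw", "unstable_ccw")):
            segs, final = _descend(p, d, sense, canal)
            branches.append(Branch(label, segs, final, _event_from_segments(segs)))
        return _merge(branches)

    f = tangential_force(p, d)
    sense = "cw" if f > 0 else "ccw"
    segs, final = _descend(p, d, sense, canal)
    return [Branch("deterministic", segs, final, _event_from_segments(segs))]


def integrate_descent(
    p0: float, d: float, canal: CanalSpec, step: float = 0.05
) -> float:
    """Brute-force fine-step descent; the independent oracle for ``settle``.

    Repeatedly moves ``p`` by ``step`` degrees in the direction of the
    tangential force, stopping at the stable point, the ampulla seal, or the
    utricular opening (outward), and returns the final angle.  Must agree
    with the deterministic :func:`settle` branch endpoint within ``2 * step``.
    """
    if step > 0.1 or step <= 0:
        raise ValueError("step must be in (0, 0.1] degrees")
    p0 = wrap_angle(p0)
    d = wrap_angle(d)
    if classify_equilibrium(p0, d) is EquilibriumKind.UNSTABLE:
        raise ValueError("descent from an unstable equilibrium is branch-dependent")
    if locate(canal, p0) is Compartment.UTRICLE_GAP:
        raise ValueError("p0 must lie on the lumen arc")

    p = p0
    max_iter = int(360.0 / step) * 4
    for _ in range(max_iter):
        f = tangential_force(p, d)
        if f == 0.0:
            return p
        sense = "cw" if f > 0 else "ccw"
        here = locate(canal, p)
        if here is Compartment.AMPULLA_BOUNDARY and sense != canal.lumen_orientation:
            return p
        if here is Compartment.OPENING_BOUNDARY and sense == canal.lumen_orientation:
            return p
        if directional_distance(p, d, sense) <= step:
            return d
        if sense == canal.lumen_orientation:
            dist_b = directional_distance(p, canal.opening_angle, sense)
            bnd = canal.opening_angle
        else:
            dist_b = directional_distance(p, canal.ampulla_angle, sense)
            bnd = canal.ampulla_angle
        if 0.0 < dist_b <= step:
            return bnd
        p = wrap_angle(p + step if sense == "cw" else p - step)
    raise RuntimeError(f"descent oracle failed to converge after {max_iter} iterations")


@dataclass(frozen=True)
class BranchRecord:
    """A branch within a maneuver step, with its parent in the previous step."""

    branch: Branch
    parent: int  # index into previous step's branches; -1 for the first step

    def to_dict(self) -> dict:
        d = self.branch.to_dict()
        d["parent"] = self.parent
        return d


@dataclass(frozen=True)
class StepRecord:
    index: int
    gravity: float
    pose: str | None
    branches: tuple[BranchRecord, ...]

    @property
    def outcome_set(self) -> frozenset[str]:
        return frozenset(b.branch.nystagmus.direction for b in self.branches)

    def to_dict(self) -> dict:
        return {
            "index": self.index,
            "gravity": self.gravity,
            "pose": self.pose,
            "branches": [b.to_dict() for b in self.branches],
        }


@dataclass(frozen=True)
class ManeuverReport:
    """Branch-enumerated record of a full pose sequence."""

    canal: CanalSpec
    initial: OtolithState
    steps: tuple[StepRecord, ...]

    def to_dict(self) -> dict:
        return {
            "canal": self.canal.to_dict(),
            "initial": self.initial.to_dict(),
            "steps": [s.to_dict() for s in self.steps],
        }


def simulate_sequence(
    initial: OtolithState,
    gravity_seq: list[float],
    canal: CanalSpec,
    cap: int = BRANCH_CAP,
) -> ManeuverReport:
    """Breadth-first branch expansion of a held-pose gravity sequence.

    Each held direction expands every live branch of the previous step via
    :func:`settle`; branches with identical (final state, nystagmus direction)
    within a step are merged.  Raises if the branch count ever exceeds ``cap``.
    """
    if not gravity_seq:
        raise ValueError("gravity sequence must be non-empty")
    steps: list[StepRecord] = []
    live: list[OtolithState] = [initial]
    for i, d in enumerate(gravity_seq):
        d = wrap_angle(d)
        records: list[BranchRecord] = []
        seen: set[tuple] = set()
        for parent, st in enumerate(live):
            for br in settle(st, d, canal):
                k = _dedup_key(br)
                if k in seen:
                    continue
                seen.add(k)
                records.append(BranchRecord(br, parent if i > 0 else -1))
        if len(records) > cap:
            raise RuntimeError(
                f"branch cap {cap} exceeded at step {i} (gravity {d:.1f}°)"
            )
        pose = gravity_to_pose(d)
        steps.append(
            StepRecord(i, d, pose.value if pose else None, tuple(records))
        )
        live = [r.branch.final for r in records]
    return ManeuverReport(canal, initial, tuple(steps))
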