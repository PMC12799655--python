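"""Canonical roll maneuvers, bow/lean predictions, and lateralization logic.

The logroll (Lempert, "barbecue") maneuver rotates the supine patient in 90°
steps through a full turn.  Rolling *away* from the affected ear is
therapeutic, so lateralizing the affected side correctly is the clinically
decisive question this module's prone-step rule answers: during a rightward
roll begun supine, right-beat nystagmus in the prone position indicates
right-sided involvement (and that the roll is treating the wrong side),
whereas absence of nystagmus in prone indicates left-sided involvement (and a
correctly-directed roll).

The bow and lean test instead pitches the upright patient forward (bow) or
backward (lean).  Because the horizontal canal plane is tilted about 30°
backward from the axial plane in a neutral upright head, a pitch of θ leaves
an in-plane gravity component of signed magnitude m = sin(θ − τ) along the
canal's anterior axis (τ = canal tilt, default 30°); the instantaneous
tangential force on a canalith at position p is then m·sin(0° − p).
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .anatomy import CanalSpec, Compartment, locate, make_canal
from .dynamics import (
    MODEST_ROBUST_THRESHOLD,
    ManeuverReport,
    NystagmusEvent,
    OtolithState,
    simulate_sequence,
)
from .geometry import Pose, directional_distance, pose_to_gravity, wrap_angle
import math

__all__ = [
    "RollPlan",
    "roll_positions",
    "StepPrediction",
    "predict_roll",
    "settled_state",
    "BowLeanConfig",
    "bow_lean_predict",
    "LateralizationResult",
    "lateralize_from_prone",
    "DivergenceReport",
    "compare_variants",
]


@dataclass(frozen=True)
class RollPlan:
    """A four-step 90°-increment roll returning to the start pose."""

    start_pose: Pose = Pose.SUPINE
    direction: str = "rightward"  # "rightward" | "leftward"

    def __post_init__(self) -> None:
        object.__setattr__(self, "start_pose", Pose(self.start_pose))
        if self.direction not in ("rightward", "leftward"):
            raise ValueError(
                f"direction must be 'rightward' or 'leftward', got {self.direction!r}"
            )


def roll_positions(plan: RollPlan) -> list[float]:
    """Gravity directions of the four held poses of a roll plan.

    A rightward roll advances gravity by +90° per step (the dependent ear
    moves rightward around the compass); leftward by −90°.  From supine a
    rightward roll gives [270, 0, 90, 180]: right side-lying, prone, left
    side-lying, and back to supine.
    """
    d0 = pose_to_gravity(plan.start_pose)
    delta = 90.0 if plan.direction == "rightward" else -90.0
    return [wrap_angle(d0 + delta * k) for k in range(1, 5)]


def settled_state(canal: CanalSpec, start_pose: Pose | str = Pose.SUPINE) -> OtolithState:
    """The otolith at rest in the lumen under the start pose's gravity.

    Placed at the stable point ``p = d`` when that angle lies in the lumen,
    otherwise at the nearest lumen endpoint.  For every default variant and a
    supine start this is the posterior lumen, p = 180° — the canonical
    geotropic canalolithiasis starting condition.
    """
    d = pose_to_gravity(start_pose)
    if locate(canal, d) is not Compartment.UTRICLE_GAP:
        return OtolithState.in_lumen(d)
    # nearest lumen point is the closer of the two endpoints
    best = min(
        (canal.ampulla_angle, canal.opening_angle),
        key=lambda a: min(wrap_angle(d - a), wrap_angle(a - d)),
    )
    return OtolithState.in_lumen(best)


@dataclass(frozen=True)
class StepPrediction:
    """Per-pose branch outcomes of a simulated roll step."""

    pose: str | None
    gravity: float
    outcome_set: frozenset[str]
    events: tuple[NystagmusEvent, ...]

    def to_dict(self) -> dict:
        return {
            "pose": self.pose,
            "gravity": self.gravity,
            "outcome_set": sorted(self.outcome_set),
            "events": [e.to_dict() for e in self.events],
        }


def predict_roll(
    canal: CanalSpec,
    plan: RollPlan,
    initial: OtolithState | str = "settled",
) -> tuple[list[StepPrediction], ManeuverReport]:
    """Simulate a roll plan and summarize the per-pose nystagmus outcome sets."""
    if initial == "settled":
        initial = settled_state(canal, plan.start_pose)
    elif not isinstance(initial, OtolithState):
        raise ValueError("initial must be an OtolithState or the string 'settled'")
    report = simulate_sequence(initial, roll_positions(plan), canal)
    preds = [
        StepPrediction(
            step.pose,
            step.gravity,
            step.outcome_set,
            tuple(b.branch.nystagmus for b in step.branches),
        )
        for step in report.steps
    ]
    return preds, report


@dataclass(frozen=True)
class BowLeanConfig:
    """Upright pitch test configuration.

    ``pitch`` θ in degrees: positive = bow (forward flexion), negative = lean
    (backward extension).  ``canal_tilt`` τ is the backward tilt of the
    horizontal canal plane relative to the axial plane in the neutral upright
    head, about 30°.  The in-plane gravity component along the canal's
    anterior (0°) axis has signed magnitude ``m = sin(θ − τ)``; m vanishes
    when the pitch brings the canal plane horizontal (θ = τ).
    """

    pitch: float = 0.0
    canal_tilt: float = 30.0

    @property
    def in_plane_magnitude(self) -> float:
        return math.sin(math.radians(self.pitch - self.canal_tilt))


def bow_lean_predict(
    canal: CanalSpec, p: float, cfg: BowLeanConfig
) -> NystagmusEvent:
    """Instantaneous bow/lean nystagmus prediction for a canalith at ``p``.

    The in-plane gravity of signed magnitude m points anteriorly (0°) for
    m > 0, posteriorly for m < 0; the tangential force is F = m·sin(0° − p).
    Clockwise (F > 0) predicts right-beat, counterclockwise left-beat.  The
    otolith is not stepped — this is the momentary stimulus at test onset.
    """
    p = wrap_angle(p)
    if locate(canal, p) is Compartment.UTRICLE_GAP:
        return NystagmusEvent("none", 0.0, "none")
    m = cfg.in_plane_magnitude
    force = m * math.sin(math.radians(-p))
    if force == 0.0:
        return NystagmusEvent("none", 0.0, "none")
    direction = "right_beat" if force > 0 else "left_beat"
    intensity = abs(force)
    qualifier = "modest" if intensity < MODEST_ROBUST_THRESHOLD else "robust"
    return NystagmusEvent(direction, intensity, qualifier)


@dataclass(frozen=True)
class LateralizationResult:
    affected_side: str  # "left" | "right" | "indeterminate"
    treating_correct_side: bool | None
    note: str = ""

    def to_dict(self) -> dict:
        return {
            "affected_side": self.affected_side,
            "treating_correct_side": self.treating_correct_side,
            "note": self.note,
        }


def lateralize_from_prone(direction: str, observed: str) -> LateralizationResult:
    """Apply the prone-step rule of a roll begun supine.

    An ipsiversive beat (fast phase toward the roll direction) implicates the
    canal on the roll side — and means the ongoing roll is treating the
    incorrect side.  No nystagmus implicates the contralateral canal, and the
    roll is treating the correct side.  A contraversive beat is not predicted
    by the model.
    """
    if direction not in ("rightward", "leftward"):
        raise ValueError(f"direction must be 'rightward' or 'leftward', got {direction!r}")
    if observed not in ("right_beat", "left_beat", "none"):
        raise ValueError(
            f"observed must be 'right_beat', 'left_beat' or 'none', got {observed!r}"
        )
    roll_side = "right" if direction == "rightward" else "left"
    other_side = "left" if roll_side == "right" else "right"
    ipsiversive = f"{roll_side}_beat"
    if observed == ipsiversive:
        return LateralizationResult(
            roll_side,
            False,
            "ipsiversive prone nystagmus: the roll is treating the incorrect side",
        )
    if observed == "none":
        return LateralizationResult(
            other_side,
            True,
            "no prone nystagmus: the otolith is already in the utricle of the "
            f"{other_side} canal; the roll is treating the correct side",
        )
    return LateralizationResult(
        "indeterminate", None, "contraversive prone nystagmus: not predicted by model"
    )


@dataclass(frozen=True)
class DivergenceReport:
    """Where the true and hypothetical anatomies predict differently."""

    side: str
    plan: RollPlan
    true_predictions: tuple[StepPrediction, ...]
    hypothetical_predictions: tuple[StepPrediction, ...]
    diverging_poses: tuple[str, ...]

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "direction": self.plan.direction,
            "start_pose": self.plan.start_pose.value,
            "true": [p.to_dict() for p in self.true_predictions],
            "hypothetical": [p.to_dict() for p in self.hypothetical_predictions],
            "diverging_poses": list(self.diverging_poses),
        }


def compare_variants(
    side: str,
    plan: RollPlan | None = None,
    canal_true: CanalSpec | None = None,
    canal_hyp: CanalSpec | None = None,
) -> DivergenceReport:
    """Roll-maneuver predictions of the true vs. hypothetical anatomy.

    Both canals start from the settled state of the plan's start pose; the
    report lists each pose where the per-branch nystagmus outcome sets differ
    between the posteromedial (true) and anteromedial (hypothetical) models.
    """
    plan = plan or RollPlan()
    canal_true = canal_true or make_canal(side, "true_posteromedial")
    canal_hyp = canal_hyp or make_canal(side, "hypothetical_anteromedial")
    preds_t, _ = predict_roll(canal_true, plan)
    preds_h, _ = predict_roll(canal_hyp, plan)
    diverging = tuple(
        (pt.pose or f"{pt.gravity:g}°")
        for pt, ph in zip(preds_t, preds_h)
        if pt.outcome_set != ph.outcome_set
    )
    return DivergenceReport(side, plan, tuple(preds_t), tuple(preds_h), diverging)
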