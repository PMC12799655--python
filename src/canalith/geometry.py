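"""Angle conventions, the tangential force law, and equilibrium classification.

All angles are in degrees on the circle of the horizontal semicircular canal's
plane, wrapped to [0, 360).  The compass convention (viewed from below the
supine patient, i.e. from inferior to superior):

* 0° (= 360°) points anteriorly (toward the nose),
* 90° points toward the patient's left,
* 180° points posteriorly,
* 270° points toward the patient's right.

The same compass serves both the otolith position ``p`` within the canal lumen
and the direction of gravity ``d`` (the direction in which gravity pulls, for a
patient lying down with the canal plane vertical).  The component of gravity
tangential to the lumen at ``p`` is

    F = sin(d - p)

with ``F > 0`` meaning a clockwise push (increasing ``p``) and ``F < 0``
counterclockwise.  Clockwise otolith motion in this frame manifests as
right-beat nystagmus, counterclockwise as left-beat.
"""

from __future__ import annotations

import enum
import math

__all__ = [
    "wrap_angle",
    "Pose",
    "pose_to_gravity",
    "tangential_force",
    "height",
    "EquilibriumKind",
    "classify_equilibrium",
    "directional_distance",
]


def wrap_angle(x: float) -> float:
    """Wrap an angle in degrees to the half-open interval [0, 360)."""
    w = math.fmod(float(x), 360.0)
    if w < 0.0:
        w += 360.0
    # fmod of a tiny negative can round to 360.0 exactly
    return 0.0 if w == 360.0 else w


class Pose(str, enum.Enum):
    """The four canonical lying-down head/body poses of a roll maneuver."""

    PRONE = "prone"
    LEFT_SIDE_LYING = "left_side_lying"
    SUPINE = "supine"
    RIGHT_SIDE_LYING = "right_side_lying"


_POSE_GRAVITY = {
    Pose.PRONE: 0.0,
    Pose.LEFT_SIDE_LYING: 90.0,
    Pose.SUPINE: 180.0,
    Pose.RIGHT_SIDE_LYING: 270.0,
}

_GRAVITY_POSE = {v: k for k, v in _POSE_GRAVITY.items()}


def pose_to_gravity(pose: Pose | str) -> float:
    """Gravity direction (degrees) for a canonical pose.

    Prone → 0, left side-lying → 90, supine → 180, right side-lying → 270:
    gravity pulls toward the dependent (lowermost) aspect of the head.
    """
    try:
        pose = Pose(pose)
    except ValueError:
        valid = ", ".join(p.value for p in Pose)
        raise ValueError(f"unknown pose {pose!r}; valid poses: {valid}") from None
    return _POSE_GRAVITY[pose]


def gravity_to_pose(d: float) -> Pose | None:
    """Inverse of :func:`pose_to_gravity`; ``None`` for non-canonical angles."""
    return _GRAVITY_POSE.get(wrap_angle(d))


def tangential_force(p: float, d: float) -> float:
    """Tangential (along-lumen) component of gravity on an otolith.

    Parameters
    ----------
    p : otolith position on the canal circle, degrees.
    d : direction of gravity, degrees.

    Returns
    -------
    Dimensionless force in [-1, 1]: ``sin(d - p)``.  Positive is clockwise
    (viewed from inferior to superior), i.e. ``p`` increasing.
    """
    return math.sin(math.radians(wrap_angle(d) - wrap_angle(p)))


def height(p: float, d: float) -> float:
    """Gravitational height of the otolith, ``-cos(p - d)``, in canal radii.

    Minimal (-1) at the stable point ``p = d``, maximal (+1) at the unstable
    point opposite gravity.  Quasi-static motion is strictly downhill in this
    potential, which makes it the monotone-descent oracle for trajectories.
    """
    return -math.cos(math.radians(wrap_angle(p) - wrap_angle(d)))


class EquilibriumKind(str, enum.Enum):
    STABLE = "stable"
    UNSTABLE = "unstable"
    NONE = "none"


def classify_equilibrium(p: float, d: float, tol: float = 1e-6) -> EquilibriumKind:
    """Classify the configuration (p, d) as a collinear equilibrium or not.

    Gravity aligned with the otolith position (separation 0°) pins it at a
    point of stable equilibrium; gravity opposite (separation 180°) holds it
    at an unstable one, where any tangential perturbation accelerates it away.

    ``tol`` is the angular tolerance in degrees, ``0 <= tol < 90``.
    """
    if not 0.0 <= tol < 90.0:
        raise ValueError(f"tolerance must satisfy 0 <= tol < 90 degrees, got {tol}")
    sep = wrap_angle(d - p)
    if sep <= tol or sep >= 360.0 - tol:
        return EquilibriumKind.STABLE
    if abs(sep - 180.0) <= tol:
        return EquilibriumKind.UNSTABLE
    return EquilibriumKind.NONE


def directional_distance(a: float, b: float, sense: str) -> float:
    """Arc length in degrees from ``a`` to ``b`` travelling in ``sense``.

    ``sense`` is ``"cw"`` (increasing angle) or ``"ccw"``.  Result in [0, 360).
    """
    if sense == "cw":
        return wrap_angle(b - a)
    if sense == "ccw":
        return wrap_angle(a - b)
    raise ValueError(f"sense must be 'cw' or 'ccw', got {sense!r}")
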