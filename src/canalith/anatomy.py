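"""Arc geometry of the left/right horizontal semicircular canal.

The canal is modeled as an arc of the unit circle with two distinguished
endpoints: the ampulla (sealed by the cupula — impassable) and the utricular
opening (permeable — the lumen communicates with the utricle there).  The
complement of the lumen arc is the "utricle gap": angles occupied by the
utricle rather than by canal lumen.

Three named anatomical variants are built in:

``true_posteromedial``
    The real anatomy: the canal's medial limb reaches posteromedially, so the
    utricular opening sits in the posteromedial quadrant of the ear.
``hypothetical_anteromedial``
    The configuration assumed by much of the bow-and-lean literature, with an
    anteromedial limb: the opening sits in the anteromedial quadrant.
``arc180``
    The simplest textbook abstraction in which the canal subtends only half
    the circle.

Both named 240° variants span 240° of arc (the 180° variant spans 180°), so
comparisons between the true and hypothetical variants isolate the location
of the opening rather than arc length.  All endpoint angles are overridable.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace

from .geometry import directional_distance, wrap_angle

__all__ = ["CanalSpec", "Compartment", "make_canal", "locate", "mirror_canal"]

_BOUNDARY_TOL = 1e-9


class Compartment(str, enum.Enum):
    LUMEN = "lumen"
    UTRICLE_GAP = "utricle_gap"
    AMPULLA_BOUNDARY = "ampulla_boundary"
    OPENING_BOUNDARY = "opening_boundary"


@dataclass(frozen=True)
class CanalSpec:
    """Geometry of one horizontal canal.

    ``lumen_orientation`` is the rotational sense of travel from the ampulla
    to the utricular opening *along the lumen* ("cw" = increasing angle when
    viewed from inferior to superior).
    """

    side: str  # "left" | "right"
    variant: str
    ampulla_angle: float
    opening_angle: float
    lumen_orientation: str  # "cw" | "ccw"

    def __post_init__(self) -> None:
        object.__setattr__(self, "ampulla_angle", wrap_angle(self.ampulla_angle))
        object.__setattr__(self, "opening_angle", wrap_angle(self.opening_angle))
        if self.side not in ("left", "right"):
            raise ValueError(f"side must be 'left' or 'right', got {self.side!r}")
        if self.lumen_orientation not in ("cw", "ccw"):
            raise ValueError(
                f"lumen_orientation must be 'cw' or 'ccw', got {self.lumen_orientation!r}"
            )
        if self.ampulla_angle == self.opening_angle:
            raise ValueError("ampulla and opening angles must differ")

    @property
    def span(self) -> float:
        """Arc length of the lumen, degrees, travelling ampulla → opening."""
        return directional_distance(
            self.ampulla_angle, self.opening_angle, self.lumen_orientation
        )

    @property
    def into_lumen_sense(self) -> str:
        """Rotational sense that leads from the opening into the lumen."""
        return "ccw" if self.lumen_orientation == "cw" else "cw"

    def to_dict(self) -> dict:
        return {
            "side": self.side,
            "variant": self.variant,
            "ampulla_angle": self.ampulla_angle,
            "opening_angle": self.opening_angle,
            "lumen_orientation": self.lumen_orientation,
        }


# Default endpoint angles per (side, variant).  Chosen so the true variant's
# opening is posteromedial and the hypothetical variant's opening anteromedial
# for the correct ear, both named variants span 240°, and the true ampulla
# sits slightly medial of straight anterior (both canal ends attach to the
# medially placed utricle).
_DEFAULTS: dict[tuple[str, str], tuple[float, float, str]] = {
    ("right", "true_posteromedial"): (20.0, 140.0, "ccw"),
    ("left", "true_posteromedial"): (340.0, 220.0, "cw"),
    ("right", "hypothetical_anteromedial"): (315.0, 75.0, "ccw"),
    ("left", "hypothetical_anteromedial"): (45.0, 285.0, "cw"),
    ("right", "arc180"): (0.0, 180.0, "ccw"),
    ("left", "arc180"): (0.0, 180.0, "cw"),
}

_VARIANT_ALIASES = {
    "true": "true_posteromedial",
    "true_posteromedial": "true_posteromedial",
    "hypothetical": "hypothetical_anteromedial",
    "hypothetical_anteromedial": "hypothetical_anteromedial",
    "arc180": "arc180",
    "custom": "custom",
}

MIN_SPAN = 90.0
MAX_SPAN = 350.0


def make_canal(
    side: str,
    variant: str = "true_posteromedial",
    *,
    ampulla_angle: float | None = None,
    opening_angle: float | None = None,
    lumen_orientation: str | None = None,
) -> CanalSpec:
    """Build a :class:`CanalSpec` from variant defaults plus overrides.

    Raises ``ValueError`` for unknown side/variant, for a ``custom`` variant
    missing explicit angles, or for a lumen span outside (90°, 350°), which
    is rejected as non-physical.
    """
    try:
        variant = _VARIANT_ALIASES[variant]
    except KeyError:
        raise ValueError(
            f"unknown variant {variant!r}; valid: true_posteromedial, "
            "hypothetical_anteromedial, arc180, custom"
        ) from None
    if variant == "custom":
        if ampulla_angle is None or opening_angle is None or lumen_orientation is None:
            raise ValueError(
                "custom variant requires ampulla_angle, opening_angle and "
                "lumen_orientation"
            )
        amp, opn, orient = ampulla_angle, opening_angle, lumen_orientation
    else:
        if (side, variant) not in _DEFAULTS:
            raise ValueError(f"side must be 'left' or 'right', got {side!r}")
        amp, opn, orient = _DEFAULTS[(side, variant)]
        if ampulla_angle is not None:
            amp = ampulla_angle
        if opening_angle is not None:
            opn = opening_angle
        if lumen_orientation is not None:
            orient = lumen_orientation
    spec = CanalSpec(side, variant, amp, opn, orient)
    if not MIN_SPAN < spec.span < MAX_SPAN:
        raise ValueError(
            f"lumen span {spec.span:.1f}° outside the physical range "
            f"({MIN_SPAN:.0f}°, {MAX_SPAN:.0f}°)"
        )
    return spec


def locate(canal: CanalSpec, p: float) -> Compartment:
    """Which compartment the angle ``p`` falls in for this canal.

    The circle is partitioned exactly: the two endpoint angles map to their
    boundary kinds, angles strictly between them (travelling ampulla →
    opening in the lumen's sense) are lumen, the complement is utricle gap.
    """
    p = wrap_angle(p)
    t = directional_distance(canal.ampulla_angle, p, canal.lumen_orientation)
    span = canal.span
    if t <= _BOUNDARY_TOL or t >= 360.0 - _BOUNDARY_TOL:
        return Compartment.AMPULLA_BOUNDARY
    if abs(t - span) <= _BOUNDARY_TOL:
        return Compartment.OPENING_BOUNDARY
    if t < span:
        return Compartment.LUMEN
    return Compartment.UTRICLE_GAP


def mirror_canal(canal: CanalSpec) -> CanalSpec:
    """Reflect a canal across the sagittal plane (left ↔ right).

    Angles map ``x → 360 − x``, the side flips, and the lumen orientation
    reverses.  The operation is an involution and preserves the span.
    """
    return replace(
        canal,
        side="left" if canal.side == "right" else "right",
        ampulla_angle=wrap_angle(-canal.ampulla_angle),
        opening_angle=wrap_angle(-canal.opening_angle),
        lumen_orientation="ccw" if canal.lumen_orientation == "cw" else "cw",
    )
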