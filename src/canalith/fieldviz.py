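"""The (p, d) tangential-force field and its Cartesian and polar renderings.

Iterating F = sin(d - p) over all otolith positions p and gravity directions
d yields a two-dimensional field that summarizes every positional test at a
glance.  The Cartesian rendering puts p on the x-axis and d on the y-axis;
red encodes clockwise otolith motion (right-beat nystagmus), blue
counterclockwise (left-beat), color saturation encodes |F| (the strength of
the stimulus and hence of the nystagmus), the stable-equilibrium locus d = p
is drawn black and the unstable locus |d - p| = 180° white.  The polar
rendering maps p to the angular coordinate and d to the radius; the stable
locus then appears as a single-armed spiral (the "grand design spiral
galaxy" pattern).  Both renderings are produced from the identical grid and
share one color-mapping function.

Maneuver reports overlay onto the field as paths: motion at a held gravity
direction is horizontal displacement, a pose change is vertical displacement,
paths that cross 0° = 360° wrap around (drawn dashed), and branch
alternatives are drawn translucent.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field

import numpy as np

from .dynamics import ManeuverReport
from .geometry import wrap_angle

__all__ = [
    "FieldGrid",
    "OverlayPath",
    "OverlaySpec",
    "compute_field",
    "force_to_rgb",
    "render_cartesian",
    "render_polar",
    "overlay_from_report",
    "export_field_csv",
]

_INNER_RADIUS = 0.15  # polar plot: radial fraction where d = 0 sits


@dataclass(frozen=True)
class FieldGrid:
    """Sampled force field F[p_i, d_j] = sin(d_j - p_i) with locus masks."""

    resolution: int
    p: np.ndarray  # (resolution,) cell-center angles
    d: np.ndarray  # (resolution,)
    values: np.ndarray  # (resolution, resolution), rows = p, cols = d
    stable_mask: np.ndarray  # True where the d = p locus crosses the cell
    unstable_mask: np.ndarray


def compute_field(resolution: int = 360) -> FieldGrid:
    """Sample the force law on a square grid of cell-center angles.

    The locus masks are one grid cell wide: a cell is marked when the exact
    locus passes within half a cell spacing of its center.
    """
    if resolution < 36:
        raise ValueError(f"resolution must be >= 36, got {resolution}")
    spacing = 360.0 / resolution
    centers = (np.arange(resolution) + 0.5) * spacing
    p = centers[:, None]
    d = centers[None, :]
    values = np.sin(np.radians(d - p))
    sep = np.mod(d - p, 360.0)
    circ = np.minimum(sep, 360.0 - sep)  # circular distance to the 0 locus
    stable = circ <= spacing / 2.0
    unstable = np.abs(sep - 180.0) <= spacing / 2.0
    return FieldGrid(resolution, centers.copy(), centers.copy(), values, stable, unstable)


def force_to_rgb(grid: FieldGrid) -> np.ndarray:
    """Shared color mapping for both renderings.

    Hue from the sign of F alone (positive red, negative blue), saturation
    from |F| alone, loci override both (stable black, unstable white).
    """
    f = grid.values
    rgb = np.ones(f.shape + (3,))
    pos = f > 0
    neg = f < 0
    rgb[pos, 1] = 1.0 - f[pos]
    rgb[pos, 2] = 1.0 - f[pos]
    rgb[neg, 0] = 1.0 + f[neg]
    rgb[neg, 1] = 1.0 + f[neg]
    rgb[grid.unstable_mask] = 1.0
    rgb[grid.stable_mask] = 0.0
    return rgb


@dataclass(frozen=True)
class OverlayPath:
    points: tuple[tuple[float, float], ...]  # (p, d) vertices
    translucent: bool = False
    dashed: bool = False  # wrap-around pieces


@dataclass(frozen=True)
class OverlaySpec:
    waypoints: tuple[tuple[str, float, float], ...] = ()  # (label, p, d)
    paths: tuple[OverlayPath, ...] = ()


def _split_wrap(p0: float, p1: float, sense: str, d: float) -> list[tuple[list, bool]]:
    """Horizontal displacement p0 → p1 in ``sense`` at held d, split at 0/360.

    Returns a list of (vertex list, is_wrap_piece).
    """
    p0, p1 = wrap_angle(p0), wrap_angle(p1)
    if sense == "cw":
        if p1 > p0:
            return [([(p0, d), (p1, d)], False)]
        pieces = [([(p0, d), (360.0, d)], True), ([(0.0, d), (p1, d)], True)]
    else:
        if p1 < p0:
            return [([(p0, d), (p1, d)], False)]
        pieces = [([(p0, d), (0.0, d)], True), ([(360.0, d), (p1, d)], True)]
    # motion touching or crossing the 0 = 360 seam: dashed, degenerate bits dropped
    return [(verts, True) for verts, _ in pieces if verts[0][0] != verts[1][0]]


class _Labeler:
    def __init__(self) -> None:
        self._seen: dict[tuple[float, float], str] = {}
        self._n = 0
        self.waypoints: list[tuple[str, float, float]] = []

    def mark(self, p: float, d: float) -> None:
        key = (round(p, 2), round(d, 2))
        if key in self._seen:
            return
        letters = string.ascii_lowercase
        n, label = self._n, ""
        while True:
            label = letters[n % 26] + label
            n = n // 26 - 1
            if n < 0:
                break
        self._seen[key] = label
        self._n += 1
        self.waypoints.append((label, p, d))


def overlay_from_report(
    report: ManeuverReport, start_gravity: float | None = None
) -> OverlaySpec:
    """Trajectory overlay for a maneuver report.

    Waypoints are labeled alphabetically in event order.  Pose changes are
    vertical displacements at fixed p, in-lumen motion horizontal at the
    held d; branches other than deterministic ones are translucent, and
    pieces crossing 0° = 360° are dashed.  States in the utricle have no
    position and draw nothing.
    """
    labeler = _Labeler()
    paths: list[OverlayPath] = []
    # final positions of the previous step's branches, index-aligned
    prev_finals: list[float | None] = [
        report.initial.p if report.initial.compartment == "in_lumen" else None
    ]
    prev_d = start_gravity
    for step in report.steps:
        d = step.gravity
        finals: list[float | None] = []
        for rec in step.branches:
            parent_p = prev_finals[rec.parent] if rec.parent >= 0 else prev_finals[0]
            translucent = rec.branch.label != "deterministic"
            if parent_p is not None:
                if prev_d is not None and wrap_angle(prev_d) != wrap_angle(d):
                    labeler.mark(parent_p, wrap_angle(prev_d))
                    paths.append(
                        OverlayPath(
                            ((parent_p, wrap_angle(prev_d)), (parent_p, d)),
                            translucent=translucent,
                        )
                    )
                labeler.mark(parent_p, d)
            segs = rec.branch.segments
            if not segs and rec.branch.label in ("unstable_stay", "utricle_stay"):
                if parent_p is not None:
                    paths.append(
                        OverlayPath(((parent_p, d), (parent_p, d)), translucent=True)
                    )
            for seg in segs:
                for verts, is_wrap in _split_wrap(seg.start, seg.end, seg.rotation_sense, d):
                    paths.append(
                        OverlayPath(tuple(verts), translucent=translucent, dashed=is_wrap)
                    )
                labeler.mark(seg.end, d)
            finals.append(
                rec.branch.final.p if rec.branch.final.compartment == "in_lumen" else None
            )
        prev_finals = finals
        prev_d = d
    return OverlaySpec(tuple(labeler.waypoints), tuple(paths))


def _setup_matplotlib():
    import matplotlib

    matplotlib.use("Agg", force=False)
    matplotlib.rcParams["svg.hashsalt"] = "canalith"
    import matplotlib.pyplot as plt

    return plt


def _savefig(fig, out_path: str) -> None:
    kwargs = {}
    if str(out_path).lower().endswith(".svg"):
        kwargs["metadata"] = {"Date": None}
    fig.savefig(out_path, dpi=100, **kwargs)


_GUIDE_ANGLES = (0.0, 90.0, 180.0, 270.0, 360.0)


def render_cartesian(
    grid: FieldGrid, overlays: OverlaySpec | None = None, out_path: str | None = None
):
    """Render the Cartesian field plot (x = p, y = d) with overlays.

    Yellow vertical guide lines mark otolith positions at the compass
    quadrants, green horizontal lines the gravity directions.  Returns the
    figure; writes it to ``out_path`` when given.
    """
    plt = _setup_matplotlib()
    rgb = force_to_rgb(grid)
    fig, ax = plt.subplots(figsize=(8, 8))
    # imshow rows are y: transpose so that axis 0 of rgb (p) becomes x
    ax.imshow(
        np.transpose(rgb, (1, 0, 2)),
        origin="lower",
        extent=(0, 360, 0, 360),
        interpolation="nearest",
    )
    for a in _GUIDE_ANGLES:
        ax.axvline(a, color="gold", lw=0.8)
        ax.axhline(a, color="green", lw=0.8)
    _draw_overlays(ax, overlays, lambda p, d: (p, d))
    ax.set_xlim(0, 360)
    ax.set_ylim(0, 360)
    ax.set_xticks(_GUIDE_ANGLES)
    ax.set_yticks(_GUIDE_ANGLES)
    ax.set_xlabel("otolith position p (deg)")
    ax.set_ylabel("gravity direction d (deg)")
    ax.set_title("Tangential force on the otolith: red = CW (right beat), blue = CCW (left beat)")
    if out_path is not None:
        _savefig(fig, out_path)
        plt.close(fig)
        return None
    return fig


def _polar_radius(d: float) -> float:
    return _INNER_RADIUS + (1.0 - _INNER_RADIUS) * (d / 360.0)


def render_polar(
    grid: FieldGrid, overlays: OverlaySpec | None = None, out_path: str | None = None
):
    """Render the polar field plot (angle = p, radius = d) with overlays.

    The radius maps d linearly from [0, 360] onto [0.15, 1.0] of the plot
    radius (a small inner hole keeps the d = 0 circle visible).  Colors are
    identical to the Cartesian rendering; the stable locus traces a
    single-armed spiral.
    """
    plt = _setup_matplotlib()
    rgb = force_to_rgb(grid)
    res = grid.resolution
    theta_edges = np.radians(np.linspace(0.0, 360.0, res + 1))
    r_edges = _INNER_RADIUS + (1.0 - _INNER_RADIUS) * np.linspace(0.0, 1.0, res + 1)
    fig, ax = plt.subplots(figsize=(8, 8), subplot_kw={"projection": "polar"})
    ax.set_theta_zero_location("N")
    ax.set_theta_direction(-1)  # p increases clockwise, matching the compass
    mesh = ax.pcolormesh(
        theta_edges, r_edges, np.zeros((res, res)), shading="flat", rasterized=True
    )
    # quad (i, j) spans r_edges[i:i+2] x theta_edges[j:j+2] -> d index i, p index j
    mesh.set_array(None)
    mesh.set_facecolor(np.transpose(rgb, (1, 0, 2)).reshape(-1, 3))
    mesh.set_edgecolor("face")
    for a in (0.0, 90.0, 180.0, 270.0):
        ax.plot(
            [np.radians(a), np.radians(a)], [_INNER_RADIUS, 1.0], color="gold", lw=0.8
        )
        ax.plot(
            np.radians(np.linspace(0, 360, 181)),
            np.full(181, _polar_radius(a)),
            color="green",
            lw=0.8,
        )
    _draw_overlays(ax, overlays, lambda p, d: (np.radians(p), _polar_radius(d)))
    ax.set_rlim(0, 1.0)
    ax.set_xticks(np.radians([0, 90, 180, 270]))
    ax.set_xticklabels(["0° (ant)", "90° (left)", "180° (post)", "270° (right)"])
    ax.set_yticks([])
    ax.set_title("Polar force field: angle = p, radius = d")
    if out_path is not None:
        _savefig(fig, out_path)
        plt.close(fig)
        return None
    return fig


def _draw_overlays(ax, overlays: OverlaySpec | None, to_xy) -> None:
    if overlays is None:
        return
    for path in overlays.paths:
        # densify in (p, d) space so arcs stay arcs under the polar mapping
        dense: list[tuple[float, float]] = [path.points[0]]
        for (p0, d0), (p1, d1) in zip(path.points, path.points[1:]):
            n = max(2, int(max(abs(p1 - p0), abs(d1 - d0)) / 2.0) + 1)
            for t in np.linspace(0.0, 1.0, n)[1:]:
                dense.append((p0 + t * (p1 - p0), d0 + t * (d1 - d0)))
        xs, ys = zip(*(to_xy(p, d) for p, d in dense))
        ax.plot(
            xs,
            ys,
            color="dimgray",
            lw=2.5,
            alpha=0.35 if path.translucent else 1.0,
            linestyle=(0, (2, 2)) if path.dashed else "-",
            solid_capstyle="round",
            zorder=5,
        )
    for label, p, d in overlays.waypoints:
        x, y = to_xy(p, d)
        ax.plot([x], [y], marker="o", color="black", ms=4, zorder=6)
        ax.annotate(
            label,
            (x, y),
            textcoords="offset points",
            xytext=(5, 5),
            fontsize=9,
            color="black",
            zorder=6,
        )


def export_field_csv(grid: FieldGrid, path: str) -> None:
    """Write the sampled field as CSV columns p, d, F, locus."""
    import csv

    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["p", "d", "F", "locus"])
        for i in range(grid.resolution):
            for j in range(grid.resolution):
                locus = (
                    "stable"
                    if grid.stable_mask[i, j]
                    else "unstable" if grid.unstable_mask[i, j] else ""
                )
                writer.writerow(
                    [f"{grid.p[i]:.4f}", f"{grid.d[j]:.4f}", f"{grid.values[i, j]:.9f}", locus]
                )
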