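"""Scenario configuration, validation, and packaged scenario fixtures.

A scenario couples a canal specification, an initial otolith state and
exactly one maneuver (a roll plan, an explicit gravity sequence, or a set of
bow/lean cases), plus optional output paths.  Configurations load from YAML
or JSON; unknown keys are rejected by name so typos fail loudly.

The packaged fixtures encode the canonical study scenarios: the rightward
roll with right- and left-sided true anatomy (the prone-step dichotomy), the
six bow/lean panel cases on the hypothetical right canal, and the true-vs-
hypothetical divergence comparison for each side.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Any

import yaml

from .anatomy import CanalSpec, make_canal
from .dynamics import OtolithState
from .maneuvers import (
    BowLeanConfig,
    RollPlan,
    bow_lean_predict,
    compare_variants,
    predict_roll,
)

__all__ = ["ScenarioConfig", "load_config", "scenario_from_dict", "run_scenario",
           "FIXTURES", "fixture_config", "run_fixture"]

_CANAL_KEYS = {"side", "variant", "ampulla_angle", "opening_angle", "lumen_orientation"}
_ROLL_KEYS = {"direction", "start_pose"}
_BOWLEAN_KEYS = {"canal_tilt", "cases"}
_CASE_KEYS = {"label", "position", "pitch"}
_OUTPUT_KEYS = {"report_json", "report_csv", "cartesian", "polar", "resolution"}
_TOP_KEYS = {"canal", "initial", "roll", "gravity_sequence", "bow_lean", "compare", "output"}


@dataclass(frozen=True)
class ScenarioConfig:
    canal: CanalSpec
    initial: OtolithState | str  # OtolithState or "settled"
    maneuver_kind: str  # "roll" | "gravity_sequence" | "bow_lean" | "compare"
    roll: RollPlan | None = None
    gravity_sequence: tuple[float, ...] | None = None
    bow_lean_tilt: float = 30.0
    bow_lean_cases: tuple[dict, ...] = ()
    output: dict = field(default_factory=dict)


def _reject_unknown(d: dict, allowed: set[str], where: str) -> None:
    for k in d:
        if k not in allowed:
            raise ValueError(f"unknown key {k!r} in {where}; allowed: {sorted(allowed)}")


def _check_angle(value: Any, name: str) -> float:
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValueError(f"{name} must be a number in [0, 360), got {value!r}") from None
    if not 0.0 <= v < 360.0:
        raise ValueError(f"{name} must lie in [0, 360), got {v}")
    return v


def scenario_from_dict(doc: dict) -> ScenarioConfig:
    """Validate a raw mapping and build a :class:`ScenarioConfig`."""
    if not isinstance(doc, dict):
        raise ValueError("scenario config must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "scenario")

    canal_doc = dict(doc.get("canal", {}))
    _reject_unknown(canal_doc, _CANAL_KEYS, "canal")
    side = canal_doc.pop("side", "right")
    variant = canal_doc.pop("variant", "true_posteromedial")
    for key in ("ampulla_angle", "opening_angle"):
        if key in canal_doc:
            canal_doc[key] = _check_angle(canal_doc[key], f"canal.{key}")
    canal = make_canal(side, variant, **canal_doc)

    initial_raw = doc.get("initial", "settled")
    initial: OtolithState | str
    if initial_raw == "settled":
        initial = "settled"
    elif initial_raw == "utricle":
        initial = OtolithState.in_utricle()
    else:
        initial = OtolithState.in_lumen(_check_angle(initial_raw, "initial"))

    kinds = [k for k in ("roll", "gravity_sequence", "bow_lean", "compare") if k in doc]
    if len(kinds) != 1:
        raise ValueError(
            "scenario must specify exactly one maneuver: roll, gravity_sequence, "
            f"bow_lean or compare (got {kinds or 'none'})"
        )
    kind = kinds[0]

    roll = None
    gravity_sequence = None
    tilt = 30.0
    cases: tuple[dict, ...] = ()
    if kind == "roll" or kind == "compare":
        roll_doc = dict(doc[kind] if isinstance(doc[kind], dict) else {})
        _reject_unknown(roll_doc, _ROLL_KEYS, kind)
        roll = RollPlan(
            start_pose=roll_doc.get("start_pose", "supine"),
            direction=roll_doc.get("direction", "rightward"),
        )
    elif kind == "gravity_sequence":
        seq = doc[kind]
        if not isinstance(seq, list) or not seq:
            raise ValueError("gravity_sequence must be a non-empty list of angles")
        gravity_sequence = tuple(_check_angle(a, "gravity_sequence entry") for a in seq)
    else:  # bow_lean
        bl = dict(doc[kind])
        _reject_unknown(bl, _BOWLEAN_KEYS, "bow_lean")
        tilt = float(bl.get("canal_tilt", 30.0))
        raw_cases = bl.get("cases", [])
        if not raw_cases:
            raise ValueError("bow_lean requires at least one case")
        checked = []
        for c in raw_cases:
            c = dict(c)
            _reject_unknown(c, _CASE_KEYS, "bow_lean case")
            checked.append(
                {
                    "label": str(c.get("label", "")),
                    "position": _check_angle(c["position"], "bow_lean position"),
                    "pitch": float(c["pitch"]),
                }
            )
        cases = tuple(checked)

    output = dict(doc.get("output", {}))
    _reject_unknown(output, _OUTPUT_KEYS, "output")
    return ScenarioConfig(canal, initial, kind, roll, gravity_sequence, tilt, cases, output)


def load_config(path: str) -> ScenarioConfig:
    """Load and validate a YAML (or JSON) scenario file."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return scenario_from_dict(doc)


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Execute a scenario and return its result document.

    Roll and gravity-sequence scenarios yield a maneuver report; bow/lean
    yields per-case instantaneous predictions; compare yields a divergence
    report.  Output files listed in the config are written as a side effect.
    """
    from .dynamics import simulate_sequence
    from .maneuvers import settled_state

    if cfg.maneuver_kind == "roll":
        _, report = predict_roll(cfg.canal, cfg.roll, cfg.initial)
        result = report.to_dict()
    elif cfg.maneuver_kind == "gravity_sequence":
        initial = (
            settled_state(cfg.canal) if cfg.initial == "settled" else cfg.initial
        )
        report = simulate_sequence(initial, list(cfg.gravity_sequence), cfg.canal)
        result = report.to_dict()
    elif cfg.maneuver_kind == "bow_lean":
        result = {
            "canal": cfg.canal.to_dict(),
            "canal_tilt": cfg.bow_lean_tilt,
            "cases": [
                {
                    **case,
                    "prediction": bow_lean_predict(
                        cfg.canal,
                        case["position"],
                        BowLeanConfig(case["pitch"], cfg.bow_lean_tilt),
                    ).to_dict(),
                }
                for case in cfg.bow_lean_cases
            ],
        }
    else:  # compare
        result = compare_variants(cfg.canal.side, cfg.roll).to_dict()

    _write_outputs(cfg, result)
    return result


def _write_outputs(cfg: ScenarioConfig, result: dict) -> None:
    out = cfg.output
    if not out:
        return
    from .reporting import write_report

    if "report_json" in out:
        write_report(result, out["report_json"], "json")
    if "report_csv" in out and "steps" in result:
        write_report(result, out["report_csv"], "csv")
    if "cartesian" in out or "polar" in out:
        from .dynamics import ManeuverReport  # noqa: F401
        from .fieldviz import compute_field, overlay_from_report, render_cartesian, render_polar
        from .maneuvers import settled_state as _settled

        grid = compute_field(int(out.get("resolution", 360)))
        overlays = None
        if cfg.maneuver_kind in ("roll", "gravity_sequence"):
            if cfg.maneuver_kind == "roll":
                _, report = predict_roll(cfg.canal, cfg.roll, cfg.initial)
                from .geometry import pose_to_gravity

                start_d = pose_to_gravity(cfg.roll.start_pose)
            else:
                initial = _settled(cfg.canal) if cfg.initial == "settled" else cfg.initial
                from .dynamics import simulate_sequence

                report = simulate_sequence(initial, list(cfg.gravity_sequence), cfg.canal)
                start_d = None
            overlays = overlay_from_report(report, start_gravity=start_d)
        if "cartesian" in out:
            render_cartesian(grid, overlays, out["cartesian"])
        if "polar" in out:
            render_polar(grid, overlays, out["polar"])


# ---------------------------------------------------------------------------
# Packaged fixtures

_FIG1_CASES = [
    {"label": "A", "position": 270.0, "pitch": 0.0},
    {"label": "B", "position": 270.0, "pitch": -60.0},
    {"label": "C", "position": 270.0, "pitch": 90.0},
    {"label": "D", "position": 80.0, "pitch": 0.0},
    {"label": "E", "position": 80.0, "pitch": -60.0},
    {"label": "F", "position": 80.0, "pitch": 90.0},
]

FIXTURES: dict[str, dict] = {
    "table5_right_true": {
        "canal": {"side": "right", "variant": "true_posteromedial"},
        "initial": "settled",
        "roll": {"direction": "rightward", "start_pose": "supine"},
    },
    "table5_left_true": {
        "canal": {"side": "left", "variant": "true_posteromedial"},
        "initial": "settled",
        "roll": {"direction": "rightward", "start_pose": "supine"},
    },
    "fig1_panels": {
        "canal": {"side": "right", "variant": "hypothetical_anteromedial"},
        "bow_lean": {"canal_tilt": 30.0, "cases": _FIG1_CASES},
    },
    "divergence_right": {
        "canal": {"side": "right", "variant": "true_posteromedial"},
        "compare": {"direction": "rightward", "start_pose": "supine"},
    },
    "divergence_left": {
        "canal": {"side": "left", "variant": "true_posteromedial"},
        "compare": {"direction": "rightward", "start_pose": "supine"},
    },
}


def fixture_config(name: str) -> ScenarioConfig:
    try:
        doc = FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; available: {sorted(FIXTURES)}"
        ) from None
    return scenario_from_dict(copy.deepcopy(doc))


def run_fixture(name: str) -> dict:
    """Execute a packaged fixture (without file outputs) and return its result."""
    return run_scenario(fixture_config(name))
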