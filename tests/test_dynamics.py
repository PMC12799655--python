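"""Branching settle simulation against the fine-step descent oracle."""

import numpy as np
import pytest

from canalith import (
    Compartment,
    EquilibriumKind,
    OtolithState,
    classify_equilibrium,
    height,
    integrate_descent,
    locate,
    make_canal,
    mirror_canal,
    nystagmus_of,
    settle,
    simulate_sequence,
    tangential_force,
    wrap_angle,
)
from canalith.dynamics import _descend  # internal, used to sample trajectories


def _random_lumen_angle(rng, canal):
    while True:
        p = rng.uniform(0, 360)
        if locate(canal, p) is Compartment.LUMEN:
            return p


class TestSettle:
    def test_geotropic_step_right_true(self, right_true):
        """From the posterior lumen with gravity to the right, the otolith
        slides clockwise to the dependent position: right-beat nystagmus."""
        branches = settle(OtolithState.in_lumen(180), 270, right_true)
        assert len(branches) == 1
        (b,) = branches
        assert b.label == "deterministic"
        assert b.final == OtolithState.in_lumen(270)
        seg = b.segments[0]
        assert (seg.start, seg.end, seg.rotation_sense) == (180, 270, "cw")
        assert b.nystagmus.direction == "right_beat"
        assert b.nystagmus.intensity == pytest.approx(1.0)
        assert b.nystagmus.qualifier == "robust"

    def test_stable_rest_is_single_silent_branch(self, default_canals):
        for canal in default_canals:
            p = 180.0 if locate(canal, 180.0) is Compartment.LUMEN else canal.opening_angle
            branches = settle(OtolithState.in_lumen(p), p, canal)
            assert len(branches) == 1
            assert branches[0].segments == ()
            assert branches[0].nystagmus.direction == "none"

    def test_utricle_stay_when_force_points_outward(self, left_true):
        branches = settle(OtolithState.in_utricle(), 0, left_true)
        assert [b.label for b in branches] == ["utricle_stay"]
        assert branches[0].nystagmus.direction == "none"

    def test_utricle_reentry_branch_pair(self, left_true):
        """With gravity toward the patient's left the force at the left
        canal's opening points into the lumen: escape is offered as a branch."""
        branches = settle(OtolithState.in_utricle(), 90, left_true)
        labels = {b.label for b in branches}
        assert labels == {"utricle_stay", "utricle_reenter"}
        reenter = next(b for b in branches if b.label == "utricle_reenter")
        assert reenter.final == OtolithState.in_lumen(90)
        assert reenter.nystagmus.direction == "left_beat"

    def test_unstable_equilibrium_three_branches(self, right_true):
        branches = settle(OtolithState.in_lumen(0), 180, right_true)
        labels = {b.label for b in branches}
        assert labels == {"unstable_stay", "unstable_cw", "unstable_ccw"}
        by_label = {b.label: b for b in branches}
        assert by_label["unstable_stay"].segments == ()
        # clockwise nudge runs into the ampulla seal at 20°
        assert by_label["unstable_cw"].final == OtolithState.in_lumen(20)
        # counterclockwise nudge settles at the stable point 180°
        assert by_label["unstable_ccw"].final == OtolithState.in_lumen(180)
        assert by_label["unstable_ccw"].nystagmus.direction == "left_beat"

    def test_unstable_labels_only_at_unstable_equilibria(self, default_canals):
        rng = np.random.default_rng(7)
        for _ in range(100):
            canal = default_canals[rng.integers(len(default_canals))]
            p = _random_lumen_angle(rng, canal)
            d = rng.uniform(0, 360)
            labels = {b.label for b in settle(OtolithState.in_lumen(p), d, canal)}
            if labels & {"unstable_stay", "unstable_cw", "unstable_ccw"}:
                assert classify_equilibrium(p, d) is EquilibriumKind.UNSTABLE

    def test_gap_position_rejected(self, right_true):
        with pytest.raises(ValueError, match="utricle gap"):
            settle(OtolithState.in_lumen(80), 0, right_true)


class TestDescentOracle:
    @pytest.mark.parametrize(
        "p0,d,expected",
        [(270, 0, 0.0), (0, 90, 20.0), (199, 200, 200.0)],
    )
    def test_examples_right_true(self, right_true, p0, d, expected):
        assert integrate_descent(p0, d, right_true) == pytest.approx(expected, abs=0.2)

    def test_settle_matches_oracle_on_500_random_cases(self, default_canals):
        """The analytic settle endpoint equals brute-force 0.05°-step descent
        within 0.2° over random non-branching configurations."""
        rng = np.random.default_rng(2024)
        n = 0
        while n < 500:
            canal = default_canals[rng.integers(len(default_canals))]
            p0 = _random_lumen_angle(rng, canal)
            d = rng.uniform(0, 360)
            if classify_equilibrium(p0, d, tol=0.5) is not EquilibriumKind.NONE:
                continue
            (branch,) = settle(OtolithState.in_lumen(p0), d, canal)
            assert branch.label == "deterministic"
            oracle_end = integrate_descent(p0, d, canal)
            if branch.final.compartment == "in_utricle":
                settle_end = canal.opening_angle
            else:
                settle_end = branch.final.p
            diff = min(
                wrap_angle(settle_end - oracle_end), wrap_angle(oracle_end - settle_end)
            )
            assert diff <= 0.2
            n += 1

    def test_rejects_unstable_start_and_coarse_step(self, right_true):
        with pytest.raises(ValueError):
            integrate_descent(0, 180, right_true)
        with pytest.raises(ValueError):
            integrate_descent(100, 200, right_true, step=0.5)


class TestHeightMonotonicity:
    def test_height_nonincreasing_along_segments(self, default_canals):
        """Quasi-static motion is strictly downhill in h = -cos(p - d),
        checked at 0.1° sampling along every reported segment."""
        rng = np.random.default_rng(11)
        for _ in range(100):
            canal = default_canals[rng.integers(len(default_canals))]
            p0 = _random_lumen_angle(rng, canal)
            d = rng.uniform(0, 360)
            for branch in settle(OtolithState.in_lumen(p0), d, canal):
                for seg in branch.segments:
                    arc = (
                        wrap_angle(seg.end - seg.start)
                        if seg.rotation_sense == "cw"
                        else wrap_angle(seg.start - seg.end)
                    )
                    ts = np.append(np.arange(0, arc, 0.1), arc)
                    sign = 1 if seg.rotation_sense == "cw" else -1
                    hs = [height(seg.start + sign * t, d) for t in ts]
                    assert all(b <= a + 1e-12 for a, b in zip(hs, hs[1:]))


class TestIdempotence:
    def test_settling_twice_is_settling_once(self, default_canals):
        rng = np.random.default_rng(5)
        for _ in range(50):
            canal = default_canals[rng.integers(len(default_canals))]
            p0 = _random_lumen_angle(rng, canal)
            d = rng.uniform(0, 360)
            for branch in settle(OtolithState.in_lumen(p0), d, canal):
                if branch.final.compartment != "in_lumen":
                    continue
                again = settle(branch.final, d, canal)
                resettled = [b for b in again if b.label != "unstable_stay"]
                for b in again:
                    if b.label in ("deterministic", "unstable_stay"):
                        assert b.segments == ()


class TestMirrorEquivariance:
    def test_mirrored_canal_reflected_gravity_swaps_beats(self, default_canals):
        """Reflecting the anatomy and the gravity sequence across the sagittal
        plane reflects every trajectory and swaps right/left beat."""
        seq = [270, 0, 90, 180]
        refl_seq = [wrap_angle(-d) for d in seq]
        swap = {"right_beat": "left_beat", "left_beat": "right_beat", "none": "none"}
        for canal in default_canals:
            p0 = 180.0 if locate(canal, 180.0) is Compartment.LUMEN else canal.opening_angle
            rep = simulate_sequence(OtolithState.in_lumen(p0), seq, canal)
            mrep = simulate_sequence(
                OtolithState.in_lumen(wrap_angle(-p0)), refl_seq, mirror_canal(canal)
            )
            for step, mstep in zip(rep.steps, mrep.steps):
                assert {swap[o] for o in step.outcome_set} == mstep.outcome_set
                finals = sorted(
                    round(b.branch.final.p, 6) % 360
                    for b in step.branches
                    if b.branch.final.p is not None
                )
                mfinals = sorted(
                    round(wrap_angle(-b.branch.final.p), 6) % 360
                    for b in mstep.branches
                    if b.branch.final.p is not None
                )
                assert finals == pytest.approx(mfinals)


class TestSimulateSequence:
    def test_holding_the_same_pose_changes_nothing(self, right_true):
        rep = simulate_sequence(OtolithState.in_lumen(90 + 90), [180, 180, 180], right_true)
        for step in rep.steps:
            assert step.outcome_set == {"none"}
            assert len(step.branches) == 1

    def test_empty_sequence_rejected(self, right_true):
        with pytest.raises(ValueError):
            simulate_sequence(OtolithState.in_lumen(180), [], right_true)

    def test_pose_names_recorded(self, right_true):
        rep = simulate_sequence(OtolithState.in_lumen(180), [270, 0, 45], right_true)
        assert [s.pose for s in rep.steps] == ["right_side_lying", "prone", None]

    def test_report_roundtrip_dict(self, left_true):
        rep = simulate_sequence(OtolithState.in_lumen(180), [270, 0, 90, 180], left_true)
        doc = rep.to_dict()
        assert doc["canal"]["side"] == "left"
        assert len(doc["steps"]) == 4
        assert all("branches" in s for s in doc["steps"])


class TestNystagmusGrading:
    def test_peak_force_of_full_quarter_arc_is_robust(self, right_true):
        (b,) = settle(OtolithState.in_lumen(180), 270, right_true)
        ev = nystagmus_of(b)
        assert (ev.direction, ev.qualifier) == ("right_beat", "robust")

    def test_short_shallow_arc_is_modest(self, right_true):
        # from 150° with gravity at 180°: peak |F| = sin(30°) = 0.5 < 0.6
        (b,) = settle(OtolithState.in_lumen(150), 180, right_true)
        ev = nystagmus_of(b)
        assert ev.direction == "right_beat"
        assert ev.intensity == pytest.approx(0.5)
        assert ev.qualifier == "modest"

    def test_utricle_motion_is_silent(self, left_true):
        branches = settle(OtolithState.in_utricle(), 0, left_true)
        assert all(b.nystagmus.direction == "none" for b in branches)
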