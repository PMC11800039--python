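"""Spring steering: geometry, tension ramp, state machine, toy pulling."""

import numpy as np
import pytest

from dnaunwind.duplex import build_duplex, parse_sequence
from dnaunwind.protocol import (SteeringController, activate_pair,
                                cm_separation, protocol_advance,
                                pull_two_bead_toy, spring_force)


@pytest.fixture()
def model():
    return build_duplex(parse_sequence("TTGCG"))


class TestCmSeparation:
    def test_built_geometry_near_5_8(self, model):
        for i in range(model.n_pairs):
            assert cm_separation(model.positions, model, i) == pytest.approx(
                5.8, abs=0.1)

    def test_rigid_translation_along_pair_axis(self, model):
        x = model.positions.copy()
        a, b = model.pairs[0]
        axis = (x[a] - x[b]) / np.linalg.norm(x[a] - x[b])
        before = cm_separation(x, model, 0)
        x[a] += 2.4 * axis
        assert cm_separation(x, model, 0) == pytest.approx(before + 2.4,
                                                           abs=1e-12)

    def test_symmetric_under_base_swap(self, model):
        x = model.positions.copy()
        a, b = model.pairs[2]
        d0 = cm_separation(x, model, 2)
        x[[a, b]] = x[[b, a]]
        assert cm_separation(x, model, 2) == pytest.approx(d0, abs=1e-12)


class TestActivatePair:
    def test_zero_force_at_activation(self, model):
        sp = activate_pair(model, model.positions, 0, 100.0, 0.002, 0.0)
        a, b = model.pairs[0]
        f_a, f_b, tension = spring_force(sp, model.positions[a],
                                         model.positions[b], 0.0)
        assert np.abs(f_a).max() == 0.0
        assert np.abs(f_b).max() == 0.0
        assert tension == 0.0

    def test_action_lines_rotate_with_helix_twist(self, model):
        lines = []
        for i in range(model.n_pairs):
            sp = activate_pair(model, model.positions, i, 100.0, 0.002, 0.0)
            lines.append(sp.action_line)
        for l0, l1 in zip(lines, lines[1:]):
            cosang = np.dot(l0[:2], l1[:2]) / (
                np.linalg.norm(l0[:2]) * np.linalg.norm(l1[:2]))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            assert ang == pytest.approx(model.helix.twist_deg, abs=1e-6)

    def test_action_line_is_unit(self, model):
        sp = activate_pair(model, model.positions, 3, 100.0, 0.002, 5.0)
        assert np.linalg.norm(sp.action_line) == pytest.approx(1.0, abs=1e-12)

    def test_coincident_pull_beads_rejected(self, model):
        x = model.positions.copy()
        a, b = model.pairs[1]
        x[a] = x[b]
        with pytest.raises(ValueError, match="coincident"):
            activate_pair(model, x, 1, 100.0, 0.002, 0.0)


class TestSpringForce:
    def test_pinned_bead_tension_after_1000_fs(self, model):
        """A bead held at its tip origin sees tension k v Δt = 200 pN."""
        sp = activate_pair(model, model.positions, 0, 100.0, 0.002, 0.0)
        a, b = model.pairs[0]
        _, _, tension = spring_force(sp, model.positions[a],
                                     model.positions[b], 1000.0)
        assert tension == pytest.approx(200.0, rel=1e-12)

    def test_pinned_bead_growth_rate_is_pulling_rate(self, model):
        sp = activate_pair(model, model.positions, 0, 100.0, 0.002, 0.0)
        a, b = model.pairs[0]
        tensions = [spring_force(sp, model.positions[a], model.positions[b],
                                 t)[2] for t in (0.0, 1.0, 500.0)]
        assert tensions[1] - tensions[0] == pytest.approx(0.20, rel=1e-9)
        assert tensions[2] / 500.0 == pytest.approx(0.20, rel=1e-9)

    def test_bead_at_moving_tip_feels_no_force(self, model):
        sp = activate_pair(model, model.positions, 0, 100.0, 0.002, 0.0)
        a, b = model.pairs[0]
        t = 700.0
        tip_a, tip_b = sp.tips(t)
        f_a, f_b, tension = spring_force(sp, tip_a, tip_b, t)
        assert np.abs(f_a).max() == 0.0 and tension == 0.0

    def test_mirror_symmetric_beads_get_opposite_forces(self, model):
        sp = activate_pair(model, model.positions, 0, 100.0, 0.002, 0.0)
        mid = 0.5 * (sp.tip_origin_a + sp.tip_origin_b)
        offset = np.array([0.3, -0.2, 0.15])
        t = 400.0
        tip_a, tip_b = sp.tips(t)
        pos_a = tip_a + offset
        pos_b = tip_b - offset
        f_a, f_b, _ = spring_force(sp, pos_a, pos_b, t)
        assert np.allclose(f_a, -f_b, atol=1e-14)

    def test_time_before_activation_rejected(self, model):
        sp = activate_pair(model, model.positions, 0, 100.0, 0.002, 100.0)
        a, b = model.pairs[0]
        with pytest.raises(ValueError, match="activation"):
            spring_force(sp, model.positions[a], model.positions[b], 50.0)


class TestControllerStateMachine:
    def drive(self, model, controller, opening_rate=0.002, dt=1.0,
              n_steps=10_000):
        """Advance the controller with scripted positions in which the
        active pair's bases separate linearly along their axis."""
        x = model.positions.copy()
        t = 0.0
        active_counts = []
        for _ in range(n_steps):
            protocol_advance(controller, x, t)
            active_counts.append(0 if controller.active is None else 1)
            if controller.done:
                break
            sp = controller.active
            if sp is not None:   # may be None during a relaxation gap
                axis = sp.action_line
                x[sp.bead_a] += 0.5 * opening_rate * dt * axis
                x[sp.bead_b] -= 0.5 * opening_rate * dt * axis
            t += dt
        return x, t, active_counts

    def test_five_pairs_give_five_activations_and_deactivations(self, model):
        ctl = SteeringController(model)
        self.drive(model, ctl)
        kinds = [e.kind for e in ctl.events]
        assert kinds.count("activate") == 5
        assert kinds.count("deactivate") == 5
        order = [e.pair_index for e in ctl.events if e.kind == "activate"]
        assert order == [0, 1, 2, 3, 4]

    def test_at_most_one_active_pair(self, model):
        ctl = SteeringController(model)
        _, _, counts = self.drive(model, ctl)
        assert set(counts) <= {0, 1}

    def test_deactivation_at_threshold_crossing_time(self, model):
        """With a scripted linear opening the crossing time is analytic."""
        ctl = SteeringController(model)
        self.drive(model, ctl, opening_rate=0.002)
        first_deact = next(e for e in ctl.events if e.kind == "deactivate")
        start_sep = cm_separation(model.positions, model, 0)
        expected = np.ceil((8.2 - start_sep) / 0.002)
        assert first_deact.t == pytest.approx(expected, abs=1.0)
        assert first_deact.cm >= 8.2

    def test_every_deactivation_at_or_above_threshold(self, model):
        ctl = SteeringController(model)
        self.drive(model, ctl)
        for e in ctl.events:
            if e.kind == "deactivate":
                assert e.cm >= 8.2

    def test_immediate_handover_same_step(self, model):
        ctl = SteeringController(model)
        self.drive(model, ctl)
        deacts = [e for e in ctl.events if e.kind == "deactivate"]
        acts = [e for e in ctl.events if e.kind == "activate"]
        for d, a_next in zip(deacts[:-1], acts[1:]):
            assert a_next.t == d.t

    def test_relaxation_gap_delays_next_activation(self, model):
        ctl = SteeringController(model, gap_fs=50.0)
        self.drive(model, ctl)
        deacts = [e for e in ctl.events if e.kind == "deactivate"]
        acts = [e for e in ctl.events if e.kind == "activate"]
        for d, a_next in zip(deacts[:-1], acts[1:]):
            assert a_next.t >= d.t + 50.0

    def test_stuck_pair_raises_naming_pair(self, model):
        from dnaunwind.protocol import ProtocolStuckError

        ctl = SteeringController(model, max_fs_per_pair=100.0)
        with pytest.raises(ProtocolStuckError, match="pair 1"):
            self.drive(model, ctl, opening_rate=0.0)

    def test_tension_log_starts_at_zero_per_pair(self, model):
        ctl = SteeringController(model)
        self.drive(model, ctl)
        for log in ctl.pair_logs.values():
            assert log.tension[0] == 0.0
            assert log.t_deactivate is not None


class TestTwoBeadToy:
    def test_gc_rupture_force_exceeds_at(self):
        """Deterministic zero-temperature pulling: three bridges resist a
        strictly larger peak tension than two."""
        _, tension_at, sep_at = pull_two_bead_toy(2)
        _, tension_gc, sep_gc = pull_two_bead_toy(3)
        assert sep_at[-1] >= 8.2 and sep_gc[-1] >= 8.2
        assert tension_gc.max() > tension_at.max() > 0
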