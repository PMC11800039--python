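"""Sequential helicoidal spring steering — the helicase-mimicking protocol.

Each base pair carries two opposed harmonic springs attached to the pull
beads of its two bases.  The spring tips move apart at constant speed along
the pair's action line (the instantaneous hydrogen-bridge direction, frozen
at activation), so the tension on a held bead grows linearly at the pulling
rate k·v.  Pairs are pulled one at a time in sequence order; a pair is
considered separated — and its springs switched off — the first step its
base-base centre-of-mass distance reaches the separation threshold
(default 8.2 Å), at which point the next pair's springs switch on at the
same step.  Because consecutive pairs sit rotated by the helix twist, the
successive action lines rotate around the axis and the duplex unwinds
without entanglement, like a twisted ladder being unzipped rung by rung.

Defaults follow the study conditions: k = 0.01 N/cm (100 pN/Å),
tip speed v = 0.002 Å/fs, threshold 8.2 Å, pulling rate k·v = 0.20 pN/fs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .duplex import DuplexModel
from .units import KCAL_MOL_A_TO_PN, convert_units

__all__ = [
    "SpringPair",
    "Event",
    "ProtocolStuckError",
    "cm_separation",
    "activate_pair",
    "spring_force",
    "SteeringController",
    "protocol_advance",
    "pull_two_bead_toy",
]


class ProtocolStuckError(RuntimeError):
    """Raised when a pair fails to separate within the per-pair step budget."""


@dataclass
class SpringPair:
    """The two moving-tip springs acting on one base pair.

    Tips start at the pull beads' positions at activation (zero initial
    extension, force ramps from 0) and move in exactly opposite directions
    along the frozen action line.  ``k_pn_per_a`` is the stiffness after
    conversion from N/cm; tensions are reported in pN.
    """

    pair_index: int
    bead_a: int
    bead_b: int
    k_pn_per_a: float
    tip_speed: float                 # Å/fs
    action_line: np.ndarray          # unit vector b -> a
    t_activate: float                # fs
    tip_origin_a: np.ndarray
    tip_origin_b: np.ndarray
    active: bool = True

    def tips(self, t: float) -> tuple[np.ndarray, np.ndarray]:
        if t < self.t_activate:
            raise ValueError(
                f"t = {t} fs precedes activation at {self.t_activate} fs")
        s = self.tip_speed * (t - self.t_activate)
        return (self.tip_origin_a + s * self.action_line,
                self.tip_origin_b - s * self.action_line)


def cm_separation(positions: np.ndarray, model: DuplexModel, pair_index: int) -> float:
    """Distance between the centres of mass of the two bases of a pair.

    In this coarse-grained model each base is a single bead, so the base
    CM is the base-bead position; an all-atom backend would use the true
    mass-weighted base centre here.
    """
    i, j = model.pairs[pair_index]
    return float(np.linalg.norm(positions[i] - positions[j]))


def activate_pair(
    model: DuplexModel,
    positions: np.ndarray,
    pair_index: int,
    k_pn_per_a: float,
    tip_speed: float,
    t_now: float,
) -> SpringPair:
    """Attach the opposed springs of a pair along its current bridge line.

    The action line is the unit vector from the strand-two pull bead to the
    strand-one pull bead at activation time, then frozen; both spring
    extensions are zero at activation.
    """
    bead_a, bead_b = model.pairs[pair_index]
    line = positions[bead_a] - positions[bead_b]
    norm = np.linalg.norm(line)
    if norm < 1e-9:
        raise ValueError(
            f"pull beads of pair {pair_index} are coincident: action line undefined")
    return SpringPair(
        pair_index=pair_index, bead_a=bead_a, bead_b=bead_b,
        k_pn_per_a=k_pn_per_a, tip_speed=tip_speed,
        action_line=line / norm, t_activate=t_now,
        tip_origin_a=positions[bead_a].copy(),
        tip_origin_b=positions[bead_b].copy(),
    )


def spring_force(
    sp: SpringPair, position_a: np.ndarray, position_b: np.ndarray, t: float
) -> tuple[np.ndarray, np.ndarray, float]:
    """Spring forces (kcal/(mol Å)) on the two pull beads and the tension (pN).

    Each bead is pulled toward its moving tip: F = -k (r - tip).  The
    reported tension is the magnitude of the strand-one (bead_a) spring
    force — the two forces mirror two people pulling a rope at opposite
    ends, and the rope carries a single tension.
    """
    if not sp.active:
        raise ValueError(f"spring pair {sp.pair_index} is not active")
    tip_a, tip_b = sp.tips(t)
    k_int = sp.k_pn_per_a / KCAL_MOL_A_TO_PN
    d_a = position_a - tip_a
    d_b = position_b - tip_b
    f_a = -k_int * d_a
    f_b = -k_int * d_b
    tension = sp.k_pn_per_a * float(np.linalg.norm(d_a))
    return f_a, f_b, tension


@dataclass(frozen=True)
class Event:
    kind: str          # "activate" | "deactivate"
    pair_index: int
    t: float           # fs
    cm: float          # Å at the event


@dataclass
class PairLog:
    """Per-step record of one pair's active window."""

    pair_index: int
    t_activate: float
    t_deactivate: float | None = None
    times: list[float] = field(default_factory=list)
    tension: list[float] = field(default_factory=list)
    cm: list[float] = field(default_factory=list)

    def arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (np.array(self.times), np.array(self.tension), np.array(self.cm))


class SteeringController:
    """State machine driving the sequential spring protocol (stage 2).

    At most one pair is active at any time; pairs activate in sequence
    order; a pair deactivates at the first step its CM separation reaches
    the threshold, and its successor activates at that same step (an
    optional relaxation gap can delay the handover).  Tension and CM
    separation of the active pair are logged every step.
    """

    def __init__(
        self,
        model: DuplexModel,
        stiffness_n_per_cm: float = 0.01,
        tip_speed: float = 0.002,
        threshold: float = 8.2,
        gap_fs: float = 0.0,
        max_fs_per_pair: float | None = None,
    ):
        self.model = model
        self.k_pn_per_a = convert_units(stiffness_n_per_cm, "N/cm", "pN/A")
        self.tip_speed = tip_speed
        self.threshold = threshold
        self.gap_fs = gap_fs
        self.max_fs_per_pair = max_fs_per_pair
        self.queue: list[int] = list(range(model.n_pairs))
        self.active: SpringPair | None = None
        self.spring_history: list[SpringPair] = []
        self.events: list[Event] = []
        self.pair_logs: dict[int, PairLog] = {}
        self._next_activation_time: float | None = None

    @property
    def done(self) -> bool:
        return self.active is None and not self.queue

    def spring_energy_forces(self, t: float, positions: np.ndarray):
        """Spring potential (kcal/mol) and per-bead forces for the stepper."""
        forces = np.zeros_like(positions)
        if self.active is None:
            return 0.0, forces
        sp = self.active
        f_a, f_b, _ = spring_force(sp, positions[sp.bead_a], positions[sp.bead_b], t)
        forces[sp.bead_a] = f_a
        forces[sp.bead_b] = f_b
        tip_a, tip_b = sp.tips(t)
        k_int = sp.k_pn_per_a / KCAL_MOL_A_TO_PN
        energy = 0.5 * k_int * (
            float(np.sum((positions[sp.bead_a] - tip_a) ** 2))
            + float(np.sum((positions[sp.bead_b] - tip_b) ** 2)))
        return energy, forces

    def tension(self, t: float, positions: np.ndarray) -> float:
        if self.active is None:
            return float("nan")
        sp = self.active
        _, _, tension = spring_force(sp, positions[sp.bead_a],
                                     positions[sp.bead_b], t)
        return tension

    def advance(self, positions: np.ndarray, t: float) -> list[Event]:
        """Advance the state machine one step at time ``t``.

        Logs the active pair, deactivates it if separated, and activates
        the next queued pair when none is active (respecting the gap).
        Returns the events emitted this step.
        """
        emitted: list[Event] = []

        if self.active is not None:
            sp = self.active
            sep = cm_separation(positions, self.model, sp.pair_index)
            log = self.pair_logs[sp.pair_index]
            log.times.append(t)
            log.tension.append(self.tension(t, positions))
            log.cm.append(sep)
            if sep >= self.threshold:
                log.t_deactivate = t
                sp.active = False
                self.active = None
                ev = Event("deactivate", sp.pair_index, t, sep)
                self.events.append(ev)
                emitted.append(ev)
                self._next_activation_time = t + self.gap_fs
            elif (self.max_fs_per_pair is not None
                  and t - sp.t_activate > self.max_fs_per_pair):
                raise ProtocolStuckError(
                    f"pair {sp.pair_index + 1} still below threshold "
                    f"({sep:.2f} < {self.threshold} Å) after "
                    f"{self.max_fs_per_pair} fs of pulling")

        if self.active is None and self.queue:
            if (self._next_activation_time is None
                    or t >= self._next_activation_time):
                idx = self.queue.pop(0)
                sp = activate_pair(self.model, positions, idx,
                                   self.k_pn_per_a, self.tip_speed, t)
                self.active = sp
                self.spring_history.append(sp)
                sep = cm_separation(positions, self.model, idx)
                self.pair_logs[idx] = PairLog(pair_index=idx, t_activate=t)
                log = self.pair_logs[idx]
                log.times.append(t)
                log.tension.append(0.0)
                log.cm.append(sep)
                ev = Event("activate", idx, t, sep)
                self.events.append(ev)
                emitted.append(ev)
        return emitted


def protocol_advance(
    controller: SteeringController, positions: np.ndarray, t: float
) -> list[Event]:
    """Functional alias for :meth:`SteeringController.advance`."""
    return controller.advance(positions, t)


def pull_two_bead_toy(
    multiplicity: int,
    *,
    bridge_depth: float = 6.0,
    bridge_width: float = 0.8,
    rest: float = 5.8,
    stiffness_n_per_cm: float = 0.01,
    tip_speed: float = 0.002,
    threshold: float = 8.2,
    gamma_per_ps: float = 4.0,
    mass: float = 125.0,
    dt_fs: float = 1.0,
    max_steps: int = 200_000,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Deterministic (T = 0) pulling of an isolated two-bead base pair.

    The two beads interact through ``multiplicity`` Morse bridges and are
    pulled apart by the standard opposed moving-tip springs under damped
    zero-temperature dynamics.  Returns (times, tension pN, separation Å)
    up to and including the first threshold crossing.  With three bridges
    versus two (G·C versus A·T at equal per-bridge depth) the measured
    rupture force is strictly larger.
    """
    from .units import KCAL_MOL_TO_AKMA

    k_pn = convert_units(stiffness_n_per_cm, "N/cm", "pN/A")
    k_int = k_pn / KCAL_MOL_A_TO_PN
    depth = multiplicity * bridge_depth
    gamma = gamma_per_ps * 1e-3

    x = np.array([-rest / 2.0, rest / 2.0])   # 1-D positions on the pull axis
    v = np.zeros(2)
    c1 = np.exp(-gamma * dt_fs)

    def forces(t: float, x: np.ndarray) -> np.ndarray:
        r = x[1] - x[0]
        e = np.exp(-bridge_width * (r - rest))
        dv_dr = 2.0 * depth * bridge_width * e * (1.0 - e)
        f_bridge = np.array([dv_dr, -dv_dr])   # -dV/dx_i with r = x1 - x0
        tip = tip_speed * t + rest / 2.0
        f_spring = np.array([-k_int * (x[0] + tip), -k_int * (x[1] - tip)])
        return f_bridge + f_spring

    times, tension, sep = [], [], []
    f = forces(0.0, x)
    t = 0.0
    for _ in range(max_steps):
        times.append(t)
        tip = tip_speed * t + rest / 2.0
        tension.append(k_pn * abs(x[1] - tip))
        sep.append(x[1] - x[0])
        if sep[-1] >= threshold:
            break
        v = v + 0.5 * dt_fs * f * KCAL_MOL_TO_AKMA / mass
        x = x + 0.5 * dt_fs * v
        v = c1 * v
        x = x + 0.5 * dt_fs * v
        t += dt_fs
        f = forces(t, x)
        v = v + 0.5 * dt_fs * f * KCAL_MOL_TO_AKMA / mass
    else:
        raise ProtocolStuckError(
            f"toy pair (multiplicity {multiplicity}) did not separate "
            f"within {max_steps} steps")
    return np.array(times), np.array(tension), np.array(sep)
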