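"""Langevin dynamics: BAOAB integration and kinetic-temperature measurement.

Each bead obeys  m r̈ = F_sys + F_spring − γ m ṙ + G(t), with systematic
forces from a :class:`~dnaunwind.forcefield.ForceBackend`, optional steering
spring forces, viscous drag with friction coefficient γ and Gaussian
stochastic kicks G satisfying fluctuation–dissipation at the set-point
temperature.  The friction and noise stand in for the dissipative and
agitating sides of the implicit helicase + solvent environment.

The integrator is the BAOAB splitting (half kick, half drift,
Ornstein–Uhlenbeck velocity update, half drift, half kick).  In the
γ → 0, T → 0 limit it reduces exactly to velocity Verlet, which makes
energy conservation a direct correctness oracle.  Defaults follow the
study conditions: T = 300 K, γ = 4.0 ps⁻¹, dt = 1 fs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np

from .trajectory import Trajectory
from .units import KB_KCAL_MOL_K, KCAL_MOL_TO_AKMA

__all__ = [
    "LangevinParams",
    "SimState",
    "kinetic_energy",
    "kinetic_temperature",
    "maxwell_velocities",
    "init_state",
    "langevin_step",
    "run_segment",
]

#: force_fn(t, positions) -> (potential kcal/mol, forces kcal/(mol Å))
ForceFn = Callable[[float, np.ndarray], tuple[float, np.ndarray]]


@dataclass(frozen=True)
class LangevinParams:
    """Thermostat and integration parameters.

    temperature in K, gamma in 1/ps, dt in fs, seed for the noise stream.
    """

    temperature: float = 300.0
    gamma_per_ps: float = 4.0
    dt_fs: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if self.gamma_per_ps < 0:
            raise ValueError("friction must be >= 0")
        if self.dt_fs <= 0:
            raise ValueError("time step must be > 0")

    @property
    def gamma_per_fs(self) -> float:
        return self.gamma_per_ps * 1e-3


@dataclass
class SimState:
    """Instantaneous mechanical state of the bead system."""

    t: float                      # fs
    positions: np.ndarray         # (n, 3) Å
    velocities: np.ndarray        # (n, 3) Å/fs
    forces: np.ndarray            # (n, 3) kcal/(mol Å), systematic + spring
    potential: float              # kcal/mol
    kinetic: float                # kcal/mol
    temperature: float            # K


def kinetic_energy(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Σ ½ m v² in kcal/mol (velocities in Å/fs, masses in amu)."""
    ke_akma = 0.5 * float(np.sum(masses[:, None] * velocities**2))
    return ke_akma / KCAL_MOL_TO_AKMA


def kinetic_temperature(masses: np.ndarray, velocities: np.ndarray) -> float:
    """Equipartition temperature T = 2 KE / (3N k_B), all 3N dof counted."""
    n = len(masses)
    if n == 0 or np.any(masses <= 0):
        raise ValueError("need at least one bead with positive mass")
    return 2.0 * kinetic_energy(masses, velocities) / (3 * n * KB_KCAL_MOL_K)


def maxwell_velocities(
    masses: np.ndarray, temperature: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw Maxwell–Boltzmann velocities (Å/fs) at the given temperature."""
    sigma = np.sqrt(KB_KCAL_MOL_K * temperature * KCAL_MOL_TO_AKMA / masses)
    return sigma[:, None] * rng.standard_normal((len(masses), 3))


def init_state(
    masses: np.ndarray,
    positions: np.ndarray,
    force_fn: ForceFn,
    velocities: np.ndarray | None = None,
    t: float = 0.0,
) -> SimState:
    if velocities is None:
        velocities = np.zeros_like(positions)
    potential, forces = force_fn(t, positions)
    return SimState(
        t=t, positions=positions.astype(float).copy(),
        velocities=velocities.astype(float).copy(), forces=forces,
        potential=potential, kinetic=kinetic_energy(masses, velocities),
        temperature=kinetic_temperature(masses, velocities),
    )


def langevin_step(
    state: SimState,
    masses: np.ndarray,
    force_fn: ForceFn,
    params: LangevinParams,
    rng: np.random.Generator,
) -> SimState:
    """One BAOAB step; returns a new :class:`SimState` at t + dt.

    The noise draw happens unconditionally so trajectories with different
    temperatures but the same seed stay sample-aligned.
    """
    dt = params.dt_fs
    m = masses[:, None]
    inv_m = KCAL_MOL_TO_AKMA / m   # (kcal/mol/Å) -> Å/fs² per amu

    v = state.velocities + 0.5 * dt * state.forces * inv_m
    x = state.positions + 0.5 * dt * v

    c1 = np.exp(-params.gamma_per_fs * dt)
    c2 = np.sqrt(max(0.0, 1.0 - c1 * c1))
    sigma = np.sqrt(KB_KCAL_MOL_K * params.temperature * KCAL_MOL_TO_AKMA / m)
    xi = rng.standard_normal(x.shape)
    v = c1 * v + c2 * sigma * xi

    x = x + 0.5 * dt * v
    t_new = state.t + dt
    potential, forces = force_fn(t_new, x)
    if not (np.all(np.isfinite(forces)) and np.all(np.isfinite(x))):
        bead = int(np.argwhere(~np.isfinite(forces).all(axis=1) |
                               ~np.isfinite(x).all(axis=1))[0, 0])
        raise FloatingPointError(
            f"non-finite position/force at t = {t_new} fs, bead {bead}: "
            "integration blew up")
    v = v + 0.5 * dt * forces * inv_m

    return SimState(
        t=t_new, positions=x, velocities=v, forces=forces,
        potential=potential, kinetic=kinetic_energy(masses, v),
        temperature=kinetic_temperature(masses, v),
    )


def run_segment(
    state: SimState,
    masses: np.ndarray,
    backend,
    params: LangevinParams,
    n_steps: int,
    rng: np.random.Generator,
    *,
    controller=None,
    pairs: list[tuple[int, int]] | None = None,
    stride: int = 1,
    positions_stride: int = 0,
    stage: int = 0,
) -> tuple[SimState, Trajectory]:
    """Integrate ``n_steps`` Langevin steps, steering and recording.

    ``backend`` supplies systematic forces; ``controller`` (a
    :class:`~dnaunwind.protocol.SteeringController` or None) adds moving-tip
    spring forces and is advanced once per step after the positions update.
    ``pairs`` lists the base-bead index pairs whose CM separations are
    recorded (defaults to the controller's model pairs, else none).
    Observables are sampled every ``stride`` steps (the initial state is
    always sample 0); coordinates every ``positions_stride`` steps if > 0.
    Returns the final state and the recorded :class:`Trajectory`.  Stops
    early once the controller reports all pairs separated.
    """
    if pairs is None:
        pairs = list(controller.model.pairs) if controller is not None else []
    pair_arr = np.array(pairs, dtype=int).reshape(-1, 2)

    if controller is None:
        force_fn: ForceFn = lambda t, x: backend.evaluate(x)
    else:
        def force_fn(t, x):
            e, f = backend.evaluate(x)
            es, fs = controller.spring_energy_forces(t, x)
            return e + es, f + fs

    if controller is not None and not controller.done:
        # activates the first queued pair (and logs) at the segment start
        controller.advance(state.positions, state.t)

    # re-evaluate so cached forces include current spring state
    potential, forces = force_fn(state.t, state.positions)
    state = replace(state, potential=potential, forces=forces)

    times, temps, pots, kins = [], [], [], []
    cms, tens, act = [], [], []
    pos_frames, pos_times = [], []

    def cm_row(x):
        if len(pair_arr) == 0:
            return np.zeros(0)
        return np.linalg.norm(x[pair_arr[:, 0]] - x[pair_arr[:, 1]], axis=1)

    def record(st):
        times.append(st.t)
        temps.append(st.temperature)
        pots.append(st.potential)
        kins.append(st.kinetic)
        cms.append(cm_row(st.positions))
        if controller is not None and controller.active is not None:
            tens.append(controller.tension(st.t, st.positions))
            act.append(controller.active.pair_index)
        else:
            tens.append(np.nan)
            act.append(-1)

    record(state)
    if positions_stride > 0:
        pos_frames.append(state.positions.copy())
        pos_times.append(state.t)

    for step in range(1, n_steps + 1):
        state = langevin_step(state, masses, force_fn, params, rng)
        if controller is not None:
            controller.advance(state.positions, state.t)
        if step % stride == 0:
            record(state)
        if positions_stride > 0 and step % positions_stride == 0:
            pos_frames.append(state.positions.copy())
            pos_times.append(state.t)
        if controller is not None and controller.done:
            if step % stride != 0:
                record(state)
            break

    traj = Trajectory(
        times=np.array(times),
        cm=np.array(cms).reshape(len(times), len(pair_arr)),
        tension=np.array(tens), active_pair=np.array(act, dtype=int),
        temperature=np.array(temps), potential=np.array(pots),
        kinetic=np.array(kins),
        positions=np.array(pos_frames) if pos_frames else None,
        position_times=np.array(pos_times) if pos_times else None,
        stage=np.full(len(times), stage, dtype=int),
    )
    return state, traj
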