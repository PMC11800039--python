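"""Classical coarse-grained force field supplying the systematic forces.

The equation of motion needs a systematic force for every bead.  In the
ab initio picture that force comes from the electronic ground-state energy
surface; here a classical surrogate stands behind the same seam (the
:class:`ForceBackend` contract) so the dynamics, steering protocol and
analysis are agnostic to where forces come from.

Terms (energies in kcal/mol, lengths in Å):

- harmonic bonds and angles holding each strand's backbone together,
- a Morse well between stacked (adjacent same-strand) base beads,
- a Morse well per hydrogen bridge between paired base beads — a G·C pair
  carries three bridges, an A·T pair two, so at equal per-bridge depth GC
  pairs are 1.5× harder to open,
- a soft-core ``eps * (sigma/r)^12`` repulsion between all remaining bead
  pairs.

Rest lengths/angles live on the topology (measured in the freshly built
geometry); stiffnesses and well depths live here.  All parameter values
are choices of this package: the surrogate is calibrated so that pairs are
thermally stable at 300 K yet open quasi-statically under the standard
0.20 pN/fs pulling rate.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import Protocol, runtime_checkable

import numpy as np

from .duplex import DuplexModel

__all__ = [
    "ForceFieldParams",
    "ForceBackend",
    "ClassicalBackend",
    "evaluate_forcefield",
]


@dataclass(frozen=True)
class ForceFieldParams:
    """Surrogate force-field parameters (kcal/mol, Å, radians)."""

    bond_k: float = 400.0          # kcal/(mol Å²)
    angle_k: float = 80.0          # kcal/(mol rad²)
    stack_depth: float = 6.0       # kcal/mol per stack
    stack_width: float = 2.0       # 1/Å
    bridge_depth: float = 6.0      # kcal/mol per hydrogen bridge
    bridge_width: float = 0.8      # 1/Å
    excl_epsilon: float = 1.0      # kcal/mol
    excl_sigma: float = 2.5        # Å

    def __post_init__(self) -> None:
        for name in ("bond_k", "angle_k", "stack_depth", "bridge_depth",
                     "excl_epsilon", "excl_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.stack_width <= 0 or self.bridge_width <= 0:
            raise ValueError("Morse widths must be positive")

    def to_dict(self) -> dict[str, float]:
        return asdict(self)

    def replace(self, **kw) -> "ForceFieldParams":
        d = self.to_dict()
        d.update(kw)
        return ForceFieldParams(**d)


@runtime_checkable
class ForceBackend(Protocol):
    """Contract for anything that supplies systematic forces.

    ``evaluate(positions)`` returns (potential energy in kcal/mol, forces in
    kcal/(mol Å) with one 3-vector per bead); forces must be the negative
    gradient of the energy.  ``partial_charges`` is ``None`` for backends
    that cannot provide electronic charges (the classical surrogate cannot;
    a quantum backend would populate it).
    """

    name: str
    units: dict[str, str]
    partial_charges: np.ndarray | None

    def evaluate(self, positions: np.ndarray) -> tuple[float, np.ndarray]: ...


def _morse(r: np.ndarray, depth, width, r0):
    """Morse well with minimum -depth at r0 and 0 at infinity.

    Returns (energy per term, dV/dr per term)."""
    e = np.exp(-width * (r - r0))
    v = depth * ((1.0 - e) ** 2 - 1.0)
    dv = 2.0 * depth * width * e * (1.0 - e)
    return v, dv


class ClassicalBackend:
    """Vectorized evaluator of the coarse-grained surrogate potential."""

    name = "cg-surrogate"
    units = {"energy": "kcal/mol", "force": "kcal/(mol*A)", "length": "A"}
    partial_charges = None  # electronic observable; not available classically

    def __init__(self, model: DuplexModel, params: ForceFieldParams | None = None):
        self.model = model
        self.params = params or ForceFieldParams()
        b = np.array([(i, j) for i, j, _ in model.bonds], dtype=int).reshape(-1, 2)
        self._bond_ij = b
        self._bond_r0 = np.array([r0 for *_, r0 in model.bonds])
        a = np.array([(i, j, k) for i, j, k, _ in model.angles], dtype=int).reshape(-1, 3)
        self._angle_ijk = a
        self._angle_t0 = np.array([t0 for *_, t0 in model.angles])
        s = np.array([(i, j) for i, j, _ in model.stacks], dtype=int).reshape(-1, 2)
        self._stack_ij = s
        self._stack_r0 = np.array([r0 for *_, r0 in model.stacks])
        br = np.array([(i, j) for i, j, _, _ in model.bridges], dtype=int).reshape(-1, 2)
        self._bridge_ij = br
        self._bridge_mult = np.array([m for _, _, m, _ in model.bridges], dtype=float)
        self._bridge_r0 = np.array([r0 for *_, r0 in model.bridges])
        self._nb_ij = model.nonbonded

    def evaluate(self, positions: np.ndarray) -> tuple[float, np.ndarray]:
        x = np.asarray(positions, dtype=float)
        if x.shape != (self.model.n_beads, 3):
            raise ValueError(
                f"positions must have shape {(self.model.n_beads, 3)}, got {x.shape}")
        p = self.params
        energy = 0.0
        forces = np.zeros_like(x)

        def pair_term(ij, v, neg_dv_dr, rij, r):
            """Accumulate forces for a radial pair term; returns energy.

            ``neg_dv_dr`` is -dV/dr per term; with r̂ pointing i→j the force
            on j is -dV/dr · r̂ and on i the opposite."""
            f = (neg_dv_dr / r)[:, None] * rij
            np.add.at(forces, ij[:, 1], f)
            np.add.at(forces, ij[:, 0], -f)
            return float(np.sum(v))

        # bonds: V = 1/2 k (r - r0)^2
        if len(self._bond_ij):
            rij = x[self._bond_ij[:, 1]] - x[self._bond_ij[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            dr = r - self._bond_r0
            energy += pair_term(self._bond_ij, 0.5 * p.bond_k * dr**2,
                                -p.bond_k * dr, rij, r)

        # stacking / bridges: Morse
        if len(self._stack_ij):
            rij = x[self._stack_ij[:, 1]] - x[self._stack_ij[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            v, dv = _morse(r, p.stack_depth, p.stack_width, self._stack_r0)
            energy += pair_term(self._stack_ij, v, -dv, rij, r)
        if len(self._bridge_ij):
            rij = x[self._bridge_ij[:, 1]] - x[self._bridge_ij[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            v, dv = _morse(r, p.bridge_depth * self._bridge_mult,
                           p.bridge_width, self._bridge_r0)
            energy += pair_term(self._bridge_ij, v, -dv, rij, r)

        # soft-core repulsion: V = eps (sigma/r)^12
        if len(self._nb_ij):
            rij = x[self._nb_ij[:, 1]] - x[self._nb_ij[:, 0]]
            r = np.linalg.norm(rij, axis=1)
            bad = r < 1e-3
            if np.any(bad):
                i, j = self._nb_ij[np.argmax(bad)]
                raise ValueError(
                    f"beads {i} and {j} are coincident (r < 1e-3 Å): "
                    "soft-core repulsion is singular")
            sr6 = (p.excl_sigma / r) ** 6
            v = p.excl_epsilon * sr6**2
            dv = -12.0 * v / r
            energy += pair_term(self._nb_ij, v, -dv, rij, r)

        # angles: V = 1/2 k (theta - theta0)^2
        if len(self._angle_ijk):
            i, j, k = (self._angle_ijk[:, 0], self._angle_ijk[:, 1],
                       self._angle_ijk[:, 2])
            u = x[i] - x[j]
            v = x[k] - x[j]
            nu = np.linalg.norm(u, axis=1)
            nv = np.linalg.norm(v, axis=1)
            cos_t = np.clip(np.einsum("ij,ij->i", u, v) / (nu * nv), -1.0, 1.0)
            theta = np.arccos(cos_t)
            sin_t = np.sqrt(np.clip(1.0 - cos_t**2, 1e-12, None))
            dt = theta - self._angle_t0
            energy += float(np.sum(0.5 * p.angle_k * dt**2))
            dv_dt = p.angle_k * dt
            uhat = u / nu[:, None]
            vhat = v / nv[:, None]
            dth_di = (cos_t[:, None] * uhat - vhat) / (nu * sin_t)[:, None]
            dth_dk = (cos_t[:, None] * vhat - uhat) / (nv * sin_t)[:, None]
            np.add.at(forces, i, -dv_dt[:, None] * dth_di)
            np.add.at(forces, k, -dv_dt[:, None] * dth_dk)
            np.add.at(forces, j, dv_dt[:, None] * (dth_di + dth_dk))

        return energy, forces


def evaluate_forcefield(
    model: DuplexModel,
    positions: np.ndarray,
    params: ForceFieldParams | None = None,
) -> tuple[float, np.ndarray]:
    """One-shot evaluation of the surrogate potential and forces.

    For repeated evaluation build a :class:`ClassicalBackend` once and call
    its ``evaluate`` (the backend precomputes index arrays).
    """
    return ClassicalBackend(model, params).evaluate(positions)
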