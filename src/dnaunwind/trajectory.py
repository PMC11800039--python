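"""Trajectory container and scripted synthetic trajectories.

A :class:`Trajectory` is the tidy record of a run segment: per-sample time,
thermodynamic observables, the tension on the currently active spring and
the centre-of-mass separation of every base pair.  Bead coordinates are
optionally kept at a coarser stride.

:func:`scripted_trajectory` emits trajectories whose pair separations follow
prescribed analytic functions of time — the fixtures on which the rupture
detectors are validated against closed-form answers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence as TSeq

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "scripted_trajectory"]


@dataclass
class Trajectory:
    times: np.ndarray                     # (S,), fs
    cm: np.ndarray                        # (S, n_pairs), Å
    tension: np.ndarray                   # (S,), pN; NaN when no spring active
    active_pair: np.ndarray               # (S,), pair index; -1 when none
    temperature: np.ndarray | None = None  # (S,), K
    potential: np.ndarray | None = None    # (S,), kcal/mol
    kinetic: np.ndarray | None = None      # (S,), kcal/mol
    positions: np.ndarray | None = None    # (P, n_beads, 3)
    position_times: np.ndarray | None = None  # (P,), fs
    stage: np.ndarray | None = None        # (S,), int stage id

    @property
    def n_pairs(self) -> int:
        return self.cm.shape[1]

    def __post_init__(self) -> None:
        s = len(self.times)
        if self.cm.shape[0] != s or len(self.tension) != s or len(self.active_pair) != s:
            raise ValueError("trajectory arrays have inconsistent lengths")

    def to_frame(self) -> pd.DataFrame:
        """Tidy one-row-per-sample table (cm separations as cm_1..cm_N)."""
        data: dict[str, np.ndarray] = {"t_fs": self.times}
        if self.stage is not None:
            data["stage"] = self.stage
        if self.temperature is not None:
            data["temperature_K"] = self.temperature
        if self.potential is not None:
            data["potential_kcal_mol"] = self.potential
        if self.kinetic is not None:
            data["kinetic_kcal_mol"] = self.kinetic
        data["active_pair"] = self.active_pair
        data["tension_pN"] = self.tension
        for j in range(self.n_pairs):
            data[f"cm_{j + 1}_A"] = self.cm[:, j]
        return pd.DataFrame(data)

    def pair_window(self, t0: float, t1: float) -> np.ndarray:
        """Boolean mask of samples with t0 <= t <= t1."""
        return (self.times >= t0) & (self.times <= t1)

    @staticmethod
    def concatenate(parts: TSeq["Trajectory"]) -> "Trajectory":
        def cat(attr):
            vals = [getattr(p, attr) for p in parts]
            if any(v is None for v in vals):
                return None
            return np.concatenate(vals)

        return Trajectory(
            times=cat("times"), cm=np.concatenate([p.cm for p in parts]),
            tension=cat("tension"), active_pair=cat("active_pair"),
            temperature=cat("temperature"), potential=cat("potential"),
            kinetic=cat("kinetic"), positions=cat("positions"),
            position_times=cat("position_times"), stage=cat("stage"),
        )


def scripted_trajectory(
    cm_functions: TSeq[Callable[[float], float]],
    dt: float,
    duration: float,
    tension_function: Callable[[float], float] | None = None,
    active_pair: Callable[[float], int] | None = None,
) -> Trajectory:
    """Build a synthetic trajectory from per-pair CM-distance time functions.

    Samples are taken on the grid ``0, dt, ..., duration`` (inclusive).
    Placeholder coordinates put the two base beads of pair ``j`` on the x
    axis at ``±cm_j(t)/2``, offset by 10 Å in y per pair, so any
    coordinate-based CM recomputation reproduces the prescribed separations
    exactly.  Bead order is pair-major: beads ``2j`` and ``2j+1`` belong to
    pair ``j``.

    Parameters
    ----------
    cm_functions
        One callable per pair, defined on [0, duration], returning Å.
    tension_function
        Optional spring tension in pN as a function of time; defaults to 0.
    active_pair
        Optional callable giving the active pair index at each time
        (default: pair 0 throughout).
    """
    if dt <= 0 or duration <= 0:
        raise ValueError("dt and duration must be positive")
    if not cm_functions:
        raise ValueError("at least one pair function is required")
    n_steps = int(round(duration / dt))
    times = np.arange(n_steps + 1) * dt
    n_pairs = len(cm_functions)
    cm = np.empty((len(times), n_pairs))
    for j, f in enumerate(cm_functions):
        cm[:, j] = [float(f(t)) for t in times]
    if not np.all(np.isfinite(cm)):
        raise ValueError("a CM-distance function returned a non-finite value")
    tension = (np.zeros(len(times)) if tension_function is None
               else np.array([float(tension_function(t)) for t in times]))
    active = (np.zeros(len(times), dtype=int) if active_pair is None
              else np.array([int(active_pair(t)) for t in times]))

    positions = np.zeros((len(times), 2 * n_pairs, 3))
    for j in range(n_pairs):
        positions[:, 2 * j, 0] = -cm[:, j] / 2.0
        positions[:, 2 * j + 1, 0] = +cm[:, j] / 2.0
        positions[:, 2 * j, 1] = 10.0 * j
        positions[:, 2 * j + 1, 1] = 10.0 * j

    return Trajectory(
        times=times, cm=cm, tension=tension, active_pair=active,
        positions=positions, position_times=times.copy(),
    )
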