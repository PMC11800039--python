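import numpy as np
import pytest

from dnaunwind.duplex import (DuplexModel, HelixParams, Sequence,
                              build_duplex, parse_sequence)
from dnaunwind.forcefield import ClassicalBackend, ForceFieldParams


@pytest.fixture(scope="session")
def ttgcg_model() -> DuplexModel:
    return build_duplex(parse_sequence("TTGCG"))


@pytest.fixture(scope="session")
def ttgcg_backend(ttgcg_model) -> ClassicalBackend:
    return ClassicalBackend(ttgcg_model)


def toy_model(positions, masses, *, bonds=(), angles=(), stacks=(),
              bridges=(), nonbonded=(), pairs=()) -> DuplexModel:
    """Hand-assembled bead system for isolating single force-field terms."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    return DuplexModel(
        sequence=Sequence(("A", "T")), helix=HelixParams(),
        positions=positions, masses=np.asarray(masses, dtype=float),
        labels=[(0, i, "base") for i in range(n)],
        bonds=list(bonds), angles=list(angles), stacks=list(stacks),
        bridges=list(bridges),
        pull_beads=np.arange(n), pairs=list(pairs),
        nonbonded=np.asarray(nonbonded, dtype=int).reshape(-1, 2),
    )


def finite_difference_forces(backend, x, h=1e-6):
    fd = np.zeros_like(x)
    for i in range(x.shape[0]):
        for d in range(3):
            xp, xm = x.copy(), x.copy()
            xp[i, d] += h
            xm[i, d] -= h
            fd[i, d] = -(backend.evaluate(xp)[0] - backend.evaluate(xm)[0]) / (2 * h)
    return fd
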