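"""Sequence handling and coarse-grained B-DNA duplex construction.

The duplex is represented with three beads per nucleotide — phosphate,
sugar and base — laid out on two antiparallel helical strands.  The base
bead stands in for the pull atom of the all-atom picture (C4 of thymine,
C6 of adenine, C5 of cytosine, C5 of guanine): it carries the spring
attachment and defines the line of action along the hydrogen bridges of
its pair.

Lumped bead masses (amu), from standard atomic masses:

====================  ========  =========================
bead                  mass      composition
====================  ========  =========================
phosphate             78.971    PO3 (P + 3 O)
sugar                 99.108    C5H7O2 (deoxyribose residue)
base A (adenine)      134.122   C5H4N5
base G (guanine)      150.121   C5H4N5O
base C (cytosine)     110.096   C4H4N3O
base T (thymine)      125.107   C5H5N2O2
====================  ========  =========================
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Sequence",
    "HelixParams",
    "DuplexModel",
    "parse_sequence",
    "hbond_count",
    "build_duplex",
    "WATSON_CRICK",
    "PULL_ATOM",
]

WATSON_CRICK = {"A": "T", "T": "A", "G": "C", "C": "G"}

#: All-atom pull atom represented by the base bead of each nucleotide.
PULL_ATOM = {"T": "C4", "A": "C6", "C": "C5", "G": "C5"}

PHOSPHATE_MASS = 78.971
SUGAR_MASS = 99.108
BASE_MASS = {"A": 134.122, "G": 150.121, "C": 110.096, "T": 125.107}

ROLES = ("phosphate", "sugar", "base")


@dataclass(frozen=True)
class Sequence:
    """A duplex sequence: strand one 5'→3' plus its Watson–Crick complement.

    ``bases[i]`` pairs with ``complement[i]``; base pairs are labelled
    ``1TA``, ``2TA``, ``3GC``, ... in strand-one order.
    """

    bases: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.bases) < 2:
            raise ValueError("a duplex needs at least two base pairs")
        for i, b in enumerate(self.bases):
            if b not in WATSON_CRICK:
                raise ValueError(f"invalid base {b!r} at position {i + 1}")

    @property
    def complement(self) -> tuple[str, ...]:
        return tuple(WATSON_CRICK[b] for b in self.bases)

    @property
    def pair_labels(self) -> tuple[str, ...]:
        """Labels like ``("1TA", "2TA", "3GC", ...)`` in strand-one order."""
        return tuple(
            f"{i + 1}{b}{c}" for i, (b, c) in enumerate(zip(self.bases, self.complement))
        )

    def __len__(self) -> int:
        return len(self.bases)

    def __str__(self) -> str:
        return "".join(self.bases)


def parse_sequence(text: str) -> Sequence:
    """Parse a base string (case-insensitive; whitespace and hyphens ignored).

    >>> parse_sequence("T-T-G-C-G").pair_labels
    ('1TA', '2TA', '3GC', '4CG', '5GC')
    """
    cleaned = []
    for ch in text:
        if ch.isspace() or ch == "-":
            continue
        cleaned.append(ch.upper())
    if not cleaned:
        raise ValueError("empty sequence")
    for pos, b in enumerate(cleaned, start=1):
        if b not in WATSON_CRICK:
            raise ValueError(f"invalid base {b!r} at position {pos}")
    return Sequence(tuple(cleaned))


def hbond_count(base1: str, base2: str) -> int:
    """Hydrogen-bridge multiplicity of a Watson–Crick pair: G·C → 3, A·T → 2."""
    pair = {base1.upper(), base2.upper()}
    if pair == {"G", "C"}:
        return 3
    if pair == {"A", "T"}:
        return 2
    raise ValueError(f"{base1}·{base2} is not a Watson–Crick pair")


@dataclass(frozen=True)
class HelixParams:
    """Idealized B-DNA helix geometry (helix axis = z).

    rise/twist are the canonical B-DNA 3.4 Å and 36° per base pair;
    ``pair_target`` is the equilibrated centre-of-mass distance between
    paired bases (5.8 Å).  ``phase_deg`` rotates the whole frame about z.
    """

    rise: float = 3.4
    twist_deg: float = 36.0
    pair_target: float = 5.8
    phase_deg: float = 0.0
    sugar_radius: float = 6.5
    phosphate_radius: float = 9.0
    sugar_offset_deg: float = 20.0
    phosphate_offset_deg: float = 35.0

    def __post_init__(self) -> None:
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if not 0.0 < self.twist_deg <= 90.0:
            raise ValueError("twist must be in (0, 90] degrees")
        if self.pair_target <= 0:
            raise ValueError("pair CM target must be positive")


def _unit(theta: float) -> np.ndarray:
    return np.array([np.cos(theta), np.sin(theta), 0.0])


@dataclass
class DuplexModel:
    """Coarse-grained duplex: bead coordinates, masses and topology.

    Topology term lists carry index tuples plus the rest value measured in
    the freshly built geometry, so the built structure sits at (or very
    near) the minimum of the surrogate potential:

    - ``bonds``: (i, j, r0)
    - ``angles``: (i, j, k, theta0)  with j the vertex
    - ``stacks``: (i, j, r0)  adjacent base beads on one strand
    - ``bridges``: (i, j, multiplicity, r0)  paired base beads
    """

    sequence: Sequence
    helix: HelixParams
    positions: np.ndarray            # (n_beads, 3), Å
    masses: np.ndarray               # (n_beads,), amu
    labels: list[tuple[int, int, str]]   # (strand, residue, role)
    bonds: list[tuple[int, int, float]]
    angles: list[tuple[int, int, int, float]]
    stacks: list[tuple[int, int, float]]
    bridges: list[tuple[int, int, int, float]]
    pull_beads: np.ndarray           # (2 * n_pairs,) one bead per base
    pairs: list[tuple[int, int]]     # base beads (strand1, strand2), 5'→3'
    nonbonded: np.ndarray = field(default=None)  # (m, 2) soft-core pair list

    @property
    def n_beads(self) -> int:
        return len(self.masses)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def bead_names(self) -> list[str]:
        return [{"phosphate": "P", "sugar": "S", "base": "B"}[role]
                for (_, _, role) in self.labels]

    def bead_index(self, strand: int, residue: int, role: str) -> int:
        n = len(self.sequence)
        return (strand * n + residue) * 3 + ROLES.index(role)


def build_duplex(seq: Sequence, helix: HelixParams | None = None) -> DuplexModel:
    """Lay a coarse-grained duplex on two antiparallel helical strands.

    Pair ``i`` sits at height ``i * rise`` and azimuth ``phase + i * twist``;
    the two base beads of a pair face each other across the helix axis at
    half the pair CM target each, so their built separation equals the
    target exactly.  Strand two is stored in pairing order (its chemical
    5'→3' direction runs opposite to strand one).
    """
    if helix is None:
        helix = HelixParams()
    n = len(seq)
    twist = np.deg2rad(helix.twist_deg)
    phase = np.deg2rad(helix.phase_deg)
    d_s = np.deg2rad(helix.sugar_offset_deg)
    d_p = np.deg2rad(helix.phosphate_offset_deg)

    positions = np.zeros((2 * n * 3, 3))
    masses = np.zeros(2 * n * 3)
    labels: list[tuple[int, int, str]] = []

    strand_bases = (seq.bases, seq.complement)
    for strand in (0, 1):
        sign = 1.0 if strand == 0 else -1.0
        for i in range(n):
            theta = phase + i * twist
            z = i * helix.rise
            base = strand_bases[strand][i]
            # beads: phosphate, sugar, base
            if strand == 0:
                th_s, th_p = theta + d_s, theta + d_p
                u_b = _unit(theta)
            else:
                th_s, th_p = theta + np.pi - d_s, theta + np.pi - d_p
                u_b = -_unit(theta)
            k0 = (strand * n + i) * 3
            positions[k0 + 0] = helix.phosphate_radius * _unit(th_p) + [0, 0, z]
            positions[k0 + 1] = helix.sugar_radius * _unit(th_s) + [0, 0, z]
            positions[k0 + 2] = (helix.pair_target / 2.0) * u_b + [0, 0, z]
            masses[k0 + 0] = PHOSPHATE_MASS
            masses[k0 + 1] = SUGAR_MASS
            masses[k0 + 2] = BASE_MASS[base]
            labels += [(strand, i, "phosphate"), (strand, i, "sugar"),
                       (strand, i, "base")]

    model = DuplexModel(
        sequence=seq, helix=helix, positions=positions, masses=masses,
        labels=labels, bonds=[], angles=[], stacks=[], bridges=[],
        pull_beads=np.zeros(2 * n, dtype=int), pairs=[],
    )

    def dist(i: int, j: int) -> float:
        return float(np.linalg.norm(positions[i] - positions[j]))

    def ang(i: int, j: int, k: int) -> float:
        u = positions[i] - positions[j]
        v = positions[k] - positions[j]
        c = np.dot(u, v) / (np.linalg.norm(u) * np.linalg.norm(v))
        return float(np.arccos(np.clip(c, -1.0, 1.0)))

    for strand in (0, 1):
        for i in range(n):
            p = model.bead_index(strand, i, "phosphate")
            s = model.bead_index(strand, i, "sugar")
            b = model.bead_index(strand, i, "base")
            model.bonds.append((p, s, dist(p, s)))
            model.bonds.append((s, b, dist(s, b)))
            model.angles.append((p, s, b, ang(p, s, b)))
            model.pull_beads[strand * n + i] = b
            if i + 1 < n:
                p1 = model.bead_index(strand, i + 1, "phosphate")
                s1 = model.bead_index(strand, i + 1, "sugar")
                b1 = model.bead_index(strand, i + 1, "base")
                model.bonds.append((s, p1, dist(s, p1)))
                model.angles.append((s, p1, s1, ang(s, p1, s1)))
                model.stacks.append((b, b1, dist(b, b1)))

    for i in range(n):
        b1 = model.bead_index(0, i, "base")
        b2 = model.bead_index(1, i, "base")
        mult = hbond_count(seq.bases[i], seq.complement[i])
        model.pairs.append((b1, b2))
        model.bridges.append((b1, b2, mult, dist(b1, b2)))

    model.nonbonded = _nonbonded_pairs(model)
    return model


def _nonbonded_pairs(model: DuplexModel) -> np.ndarray:
    """Soft-core repulsion pair list: all bead pairs except those already
    coupled through a bonded/angle/stack/bridge term or sitting in the same
    or an adjacent residue of one strand."""
    n_beads = model.n_beads
    excluded: set[tuple[int, int]] = set()

    def exc(i: int, j: int) -> None:
        excluded.add((min(i, j), max(i, j)))

    for i, j, _ in model.bonds:
        exc(i, j)
    for i, j, k, _ in model.angles:
        exc(i, j), exc(j, k), exc(i, k)
    for i, j, _ in model.stacks:
        exc(i, j)
    for i, j, _, _ in model.bridges:
        exc(i, j)
    # same / adjacent residue on the same strand
    for a in range(n_beads):
        sa, ra, _ = model.labels[a]
        for b in range(a + 1, n_beads):
            sb, rb, _ = model.labels[b]
            if sa == sb and abs(ra - rb) <= 1:
                exc(a, b)

    pairs = [(i, j) for i in range(n_beads) for j in range(i + 1, n_beads)
             if (i, j) not in excluded]
    return np.array(pairs, dtype=int).reshape(-1, 2)
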