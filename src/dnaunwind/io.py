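"""File I/O: XYZ trajectories, PDB snapshots, schedules and events.

The XYZ reader/writer is deliberately minimal: frames of coarse-grained
beads with role names (P/S/B) rather than chemical elements, a fixed
``%.8f`` coordinate format so identical runs produce byte-identical files,
and the frame time carried in the comment line as ``t= <fs>``.  PDB
snapshots go through biotite.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Iterable, Sequence as TSeq

import numpy as np
import pandas as pd

from .duplex import DuplexModel
from .protocol import Event, SpringPair

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_pdb",
    "write_schedule",
    "read_schedule",
    "write_events",
]


def write_xyz(
    path: str | Path,
    names: TSeq[str],
    frames: np.ndarray,
    times: np.ndarray | None = None,
) -> None:
    """Write frames (F, n, 3) as multi-frame XYZ with times in the comments."""
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    n = frames.shape[1]
    if len(names) != n:
        raise ValueError("one name per bead is required")
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            t = 0.0 if times is None else float(times[fi])
            fh.write(f"{n}\nt= {t:.4f} fs\n")
            for name, (x, y, z) in zip(names, frame):
                fh.write(f"{name} {x:.8f} {y:.8f} {z:.8f}\n")


def read_xyz(path: str | Path) -> tuple[list[str], np.ndarray, np.ndarray]:
    """Read a (possibly multi-frame) XYZ file → (names, frames, times)."""
    names: list[str] = []
    frames: list[np.ndarray] = []
    times: list[float] = []
    with open(path) as fh:
        while True:
            header = fh.readline()
            if not header.strip():
                break
            n = int(header)
            comment = fh.readline()
            t = 0.0
            for tok in comment.split():
                try:
                    t = float(tok)
                    break
                except ValueError:
                    continue
            times.append(t)
            coords = np.empty((n, 3))
            frame_names = []
            for i in range(n):
                parts = fh.readline().split()
                frame_names.append(parts[0])
                coords[i] = [float(v) for v in parts[1:4]]
            if not names:
                names = frame_names
            frames.append(coords)
    if not frames:
        raise ValueError(f"{path}: no frames found")
    return names, np.array(frames), np.array(times)


_RESNAME = {"A": "DA", "T": "DT", "G": "DG", "C": "DC"}
_ATOMNAME = {"phosphate": "P", "sugar": "S", "base": "B"}


def write_pdb(path: str | Path, model: DuplexModel,
              positions: np.ndarray | None = None) -> None:
    """Write the coarse-grained duplex as a PDB snapshot (one chain per strand)."""
    import biotite.structure as struc
    from biotite.structure.io.pdb import PDBFile

    x = model.positions if positions is None else positions
    n = model.n_beads
    atoms = struc.AtomArray(n)
    atoms.coord = np.asarray(x, dtype=np.float32)
    strand_bases = (model.sequence.bases, model.sequence.complement)
    for i, (strand, resi, role) in enumerate(model.labels):
        atoms.chain_id[i] = "AB"[strand]
        atoms.res_id[i] = resi + 1
        atoms.res_name[i] = _RESNAME[strand_bases[strand][resi]]
        atoms.atom_name[i] = _ATOMNAME[role]
        atoms.element[i] = "P" if role == "phosphate" else "C"
    pdb = PDBFile()
    pdb.set_structure(atoms)
    pdb.write(str(path))


_SCHEDULE_COLS = [
    "pair", "bead_a", "bead_b", "t_activate_fs", "t_deactivate_fs",
    "k_pN_per_A", "tip_speed_A_per_fs", "threshold_A",
    "line_x", "line_y", "line_z",
    "origin_a_x", "origin_a_y", "origin_a_z",
    "origin_b_x", "origin_b_y", "origin_b_z",
]


def write_schedule(path: str | Path, springs: Iterable[SpringPair],
                   deactivations: dict[int, float], threshold: float) -> None:
    """Persist the spring schedule (one row per pair, sequence order)."""
    rows = []
    for sp in springs:
        rows.append({
            "pair": sp.pair_index + 1,
            "bead_a": sp.bead_a, "bead_b": sp.bead_b,
            "t_activate_fs": sp.t_activate,
            "t_deactivate_fs": deactivations.get(sp.pair_index, np.nan),
            "k_pN_per_A": sp.k_pn_per_a,
            "tip_speed_A_per_fs": sp.tip_speed,
            "threshold_A": threshold,
            "line_x": sp.action_line[0], "line_y": sp.action_line[1],
            "line_z": sp.action_line[2],
            "origin_a_x": sp.tip_origin_a[0], "origin_a_y": sp.tip_origin_a[1],
            "origin_a_z": sp.tip_origin_a[2],
            "origin_b_x": sp.tip_origin_b[0], "origin_b_y": sp.tip_origin_b[1],
            "origin_b_z": sp.tip_origin_b[2],
        })
    pd.DataFrame(rows, columns=_SCHEDULE_COLS).to_csv(path, index=False)


def read_schedule(path: str | Path) -> list[SpringPair]:
    """Rebuild :class:`SpringPair` records (inactive) from a schedule CSV."""
    df = pd.read_csv(path)
    springs = []
    for _, row in df.iterrows():
        springs.append(SpringPair(
            pair_index=int(row["pair"]) - 1,
            bead_a=int(row["bead_a"]), bead_b=int(row["bead_b"]),
            k_pn_per_a=float(row["k_pN_per_A"]),
            tip_speed=float(row["tip_speed_A_per_fs"]),
            action_line=np.array([row["line_x"], row["line_y"], row["line_z"]]),
            t_activate=float(row["t_activate_fs"]),
            tip_origin_a=np.array([row["origin_a_x"], row["origin_a_y"],
                                   row["origin_a_z"]]),
            tip_origin_b=np.array([row["origin_b_x"], row["origin_b_y"],
                                   row["origin_b_z"]]),
            active=False,
        ))
    return springs


def schedule_threshold(path: str | Path) -> float:
    df = pd.read_csv(path)
    return float(df["threshold_A"].iloc[0])


def write_events(path_csv: str | Path, path_json: str | Path,
                 events: TSeq[Event]) -> None:
    rows = [{"kind": e.kind, "pair": e.pair_index + 1, "t_fs": e.t,
             "cm_A": e.cm} for e in events]
    pd.DataFrame(rows, columns=["kind", "pair", "t_fs", "cm_A"]).to_csv(
        path_csv, index=False)
    with open(path_json, "w") as fh:
        json.dump(rows, fh, indent=1)
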