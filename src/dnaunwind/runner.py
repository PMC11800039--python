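"""Run configuration and orchestration of the three-stage protocol.

A run proceeds in three stages, mirroring how the enzymatic unwinding is
simulated:

1. the linked duplex is equilibrated at the thermostat temperature with no
   external forces;
2. the sequential spring protocol pulls the base pairs apart one at a time
   until every pair has passed the separation threshold;
3. the two separated strands relax with the springs switched off.

Every run directory contains the fully resolved configuration, the
trajectory (XYZ), tidy observable series (CSV), the spring schedule and
events, the per-pair rupture report and a log; identical configuration and
seed reproduce the outputs byte for byte.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from . import __version__
from .analysis import detect_fmax, detect_rupture, rupture_report
from .duplex import DuplexModel, HelixParams, build_duplex, parse_sequence
from .dynamics import LangevinParams, init_state, maxwell_velocities, run_segment
from .forcefield import ClassicalBackend, ForceFieldParams
from .io import (read_schedule, read_xyz, schedule_threshold, write_events,
                 write_pdb, write_schedule, write_xyz)
from .protocol import SteeringController
from .trajectory import Trajectory

__all__ = ["RunConfig", "run_protocol", "analyze_only", "load_sequence"]


class RunConfig(BaseModel):
    """Fully specified run; defaults are the study conditions."""

    model_config = ConfigDict(extra="forbid")

    sequence: str = "TTGCG"
    temperature_K: float = 300.0
    gamma_per_ps: float = 4.0
    dt_fs: float = 1.0
    spring_stiffness_N_per_cm: float = 0.01
    tip_speed_A_per_fs: float = 0.002
    threshold_A: float = 8.2
    stage1_ps: float = 10.0
    stage3_ps: float = 10.0
    stride: int = 1
    xyz_stride: int = 50
    seed: int = 0
    max_fs_per_pair: float = 20000.0
    relaxation_gap_fs: float = 0.0
    smooth_window_fs: float = 500.0
    rise_A: float = 3.4
    twist_deg: float = 36.0
    pair_target_A: float = 5.8
    forcefield: dict[str, float] = Field(default_factory=dict)
    outdir: str = "runs/run"

    @field_validator("dt_fs", "stage1_ps", "stage3_ps", "tip_speed_A_per_fs",
                     "spring_stiffness_N_per_cm", "threshold_A",
                     "max_fs_per_pair")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be positive")
        return v

    @field_validator("temperature_K", "gamma_per_ps", "relaxation_gap_fs",
                     "smooth_window_fs")
    @classmethod
    def _nonneg(cls, v, info):
        if v < 0:
            raise ValueError(f"{info.field_name} must be >= 0")
        return v

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.model_dump(), fh, sort_keys=True)

    def helix_params(self) -> HelixParams:
        return HelixParams(rise=self.rise_A, twist_deg=self.twist_deg,
                           pair_target=self.pair_target_A)

    def forcefield_params(self) -> ForceFieldParams:
        return ForceFieldParams().replace(**self.forcefield)

    def langevin_params(self) -> LangevinParams:
        return LangevinParams(temperature=self.temperature_K,
                              gamma_per_ps=self.gamma_per_ps,
                              dt_fs=self.dt_fs, seed=self.seed)


def load_sequence(spec: str):
    """Resolve a sequence given as a base string or a FASTA file path."""
    p = Path(spec)
    if p.suffix.lower() in {".fa", ".fasta", ".fna"} or p.is_file():
        import biotite.sequence.io.fasta as fasta

        ff = fasta.FastaFile.read(str(p))
        records = list(ff.items())
        if not records:
            raise ValueError(f"{spec}: FASTA file contains no record")
        return parse_sequence(records[0][1])
    return parse_sequence(spec)


def run_protocol(config: RunConfig) -> Path:
    """Execute the three-stage protocol and write the run directory."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    seq = load_sequence(config.sequence)
    model = build_duplex(seq, config.helix_params())
    backend = ClassicalBackend(model, config.forcefield_params())
    params = config.langevin_params()
    rng = np.random.default_rng(config.seed)

    write_pdb(outdir / "duplex_initial.pdb", model)
    write_xyz(outdir / "duplex_initial.xyz", model.bead_names, model.positions)

    velocities = maxwell_velocities(model.masses, config.temperature_K, rng)
    state = init_state(model.masses, model.positions,
                       lambda t, x: backend.evaluate(x), velocities)

    n1 = int(round(config.stage1_ps * 1000.0 / config.dt_fs))
    n3 = int(round(config.stage3_ps * 1000.0 / config.dt_fs))

    state, traj1 = run_segment(
        state, model.masses, backend, params, n1, rng,
        pairs=model.pairs, stride=config.stride,
        positions_stride=config.xyz_stride, stage=1)
    write_pdb(outdir / "duplex_stage1_end.pdb", model, state.positions)

    controller = SteeringController(
        model,
        stiffness_n_per_cm=config.spring_stiffness_N_per_cm,
        tip_speed=config.tip_speed_A_per_fs,
        threshold=config.threshold_A,
        gap_fs=config.relaxation_gap_fs,
        max_fs_per_pair=config.max_fs_per_pair,
    )
    n2_max = int(np.ceil(
        model.n_pairs * (config.max_fs_per_pair + config.relaxation_gap_fs)
        / config.dt_fs)) + 10
    state, traj2 = run_segment(
        state, model.masses, backend, params, n2_max, rng,
        controller=controller, pairs=model.pairs, stride=config.stride,
        positions_stride=config.xyz_stride, stage=2)
    if not controller.done:
        raise RuntimeError("stage 2 ended with pairs still queued")
    write_pdb(outdir / "duplex_stage2_end.pdb", model, state.positions)

    state, traj3 = run_segment(
        state, model.masses, backend, params, n3, rng,
        pairs=model.pairs, stride=config.stride,
        positions_stride=config.xyz_stride, stage=3)
    write_pdb(outdir / "duplex_stage3_end.pdb", model, state.positions)

    traj = Trajectory.concatenate([traj1, traj2, traj3])

    config.to_yaml(outdir / "config_resolved.yaml")
    traj.to_frame().to_csv(outdir / "observables.csv", index=False)
    if traj.positions is not None:
        write_xyz(outdir / "trajectory.xyz", model.bead_names,
                  traj.positions, traj.position_times)
    deact = {log.pair_index: log.t_deactivate
             for log in controller.pair_logs.values()
             if log.t_deactivate is not None}
    write_schedule(outdir / "schedule.csv", controller.spring_history,
                   deact, config.threshold_A)
    write_events(outdir / "events.csv", outdir / "events.json",
                 controller.events)

    report = rupture_report(controller.pair_logs, seq.pair_labels,
                            config.threshold_A, config.smooth_window_fs)
    report.to_csv(outdir / "rupture_report.csv", index=False)
    report.to_json(outdir / "rupture_report.json", orient="records", indent=1)

    _write_log(outdir / "run.log", config, model, traj, controller, report)
    return outdir


def _write_log(path: Path, config: RunConfig, model: DuplexModel,
               traj: Trajectory, controller, report: pd.DataFrame) -> None:
    from .units import pulling_rate_pn_per_fs

    lines = [
        f"dnaunwind {__version__} (numpy {np.__version__})",
        f"sequence: {model.sequence} ({model.n_pairs} bp, "
        f"{model.n_beads} beads)",
        f"seed: {config.seed}",
        "resolved parameters:",
    ]
    for k, v in sorted(config.model_dump().items()):
        lines.append(f"  {k}: {v}")
    rate = pulling_rate_pn_per_fs(config.spring_stiffness_N_per_cm,
                                  config.tip_speed_A_per_fs)
    lines.append(f"pulling rate k*v: {rate:.4f} pN/fs")
    for stage in (1, 2, 3):
        mask = traj.stage == stage
        if mask.any():
            lines.append(
                f"stage {stage}: {mask.sum()} samples, "
                f"t = {traj.times[mask][0]:.0f}..{traj.times[mask][-1]:.0f} fs, "
                f"<T> = {np.mean(traj.temperature[mask]):.1f} K")
    lines.append(f"events: {len(controller.events)}")
    lines.append("rupture report:")
    lines.append(report.to_string(index=False))
    path.write_text("\n".join(lines) + "\n")


def analyze_only(
    trajectory_path: str | Path,
    schedule_path: str | Path,
    config: RunConfig | None = None,
    sequence: str | None = None,
) -> pd.DataFrame:
    """Recompute the rupture report from a trajectory plus spring schedule.

    The CM separations and spring tensions are rebuilt from the XYZ
    coordinates and the persisted spring parameters alone — no
    re-simulation.  The bead layout is taken from the configured sequence
    (full duplex, 3 beads per nucleotide) or, for scripted fixture files,
    recognized as the pair-major two-beads-per-pair layout.
    """
    config = config or RunConfig()
    if sequence is not None:
        config = config.model_copy(update={"sequence": sequence})
    names, frames, times = read_xyz(trajectory_path)
    springs = read_schedule(schedule_path)
    threshold = schedule_threshold(schedule_path)
    n_atoms = frames.shape[1]

    seq = load_sequence(config.sequence)
    if n_atoms == 2 * len(springs):
        labels = tuple(f"{i + 1}" for i in range(len(springs)))
    else:
        model = build_duplex(seq, config.helix_params())
        if model.n_beads != n_atoms:
            raise ValueError(
                f"trajectory has {n_atoms} beads but sequence "
                f"{seq} implies {model.n_beads}")
        labels = seq.pair_labels

    rows = []
    for sp in springs:
        if not np.isfinite(sp.t_activate):
            raise ValueError(f"pair {sp.pair_index + 1}: no activation time")
        mask = times >= sp.t_activate - 1e-9
        if times[0] > sp.t_activate + 1e-9:
            raise ValueError(
                f"pair {sp.pair_index + 1}: schedule starts at "
                f"{sp.t_activate} fs but trajectory begins at {times[0]} fs "
                "(timestamp mismatch)")
        t = times[mask]
        cm = np.linalg.norm(frames[mask, sp.bead_a] - frames[mask, sp.bead_b],
                            axis=1)
        # restrict the window to the pair's own activity: cut at the first
        # threshold crossing
        hits = np.nonzero(cm >= threshold)[0]
        if len(hits) == 0:
            raise ValueError(
                f"pair {sp.pair_index + 1}: CM separation never reaches "
                f"{threshold} Å — trajectory truncated before the crossing")
        end = int(hits[0])
        t = t[: end + 1]
        cm = cm[: end + 1]
        window_frames = frames[mask]
        tension = np.array([
            sp.k_pn_per_a * np.linalg.norm(
                window_frames[i, sp.bead_a] - sp.tips(ti)[0])
            for i, ti in enumerate(t)])
        rup = detect_rupture(t, tension, cm, threshold,
                             config.smooth_window_fs)
        fmax, t_max = detect_fmax(t, tension, cm, threshold)
        rows.append({
            "pair": sp.pair_index + 1,
            "label": labels[sp.pair_index],
            "F_rup_pN": rup.force, "t_rup_fs": rup.t,
            "F_max_pN": fmax, "t_max_fs": t_max,
            "t_activate_fs": sp.t_activate, "t_deactivate_fs": t_max,
            "rupture_found": rup.found, "bound_ok": fmax >= rup.force,
        })
    return pd.DataFrame(rows)
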