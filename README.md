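# dnaunwind

Steered Langevin molecular dynamics of helicase-style DNA unwinding.

A helicase separates double-stranded DNA one base pair at a time, following
the helical twist of the molecule.  `dnaunwind` reproduces the mechanics of
that process on a coarse-grained duplex: the enzyme's grip and thermal
agitation enter implicitly through Langevin friction (γ = 4.0 ps⁻¹) and
noise at 300 K, and the strand-separating force is applied by two opposed
harmonic springs (k = 0.01 N/cm) per base pair whose tips move apart at
constant speed (v = 0.002 Å/fs) along the hydrogen-bridge direction of that
pair.  Pairs are pulled sequentially: when the centre-of-mass (CM) distance
between the two bases of the active pair first reaches 8.2 Å the pair
counts as separated, its springs switch off and the next pair's switch on
— rotated by the helix twist, so the duplex unwinds like a twisted ladder
being unzipped rung by rung.

The package is aimed at people studying force-induced nucleic-acid
dissociation (single-molecule pulling, unzipping simulations) who want a
fast, fully reproducible sandbox for the *protocol* — sequential helicoidal
steering, rupture detection, force–extension analysis — rather than a
quantitative model of hydrogen-bond chemistry.

## What it computes

For each base pair the protocol yields two forces from the spring tension
F(t) = k·|r(t) − tip(t)| (the tension ramps at the pulling rate
k·v = 0.20 pN/fs when a bead is held):

- **rupture force, F_rup** — the tension at the moment the pair's CM
  separation ceases to decrease (last local minimum of the smoothed
  separation series before the threshold crossing);
- **maximum force, F_max** — the tension when the separation first reaches
  the 8.2 Å threshold.  Under quasi-static pulling F_max ≥ F_rup, because
  the pair lets go before the threshold is reached.

A run also records temperature and energy time series (separation events
leave the thermostat temperature unaffected while the potential energy
responds to every opening), spring activation/deactivation events, the
stage-averaged energy change between the linked and the fully separated
duplex, and force–extension curves.

Systematic forces come from a classical coarse-grained surrogate potential
(three beads per nucleotide; Morse hydrogen bridges with G·C = 3 and
A·T = 2 bridges per pair) behind a documented backend seam — see
`docs/methods.md` for the model, its calibration and its limits.

## Worked example

```python
import dnaunwind as dw

cfg = dw.RunConfig(sequence="TTGCG", seed=1, outdir="runs/ttgcg")
outdir = dw.run_protocol(cfg)
```

or equivalently `dnaunwind run -s TTGCG --seed 1 -o runs/ttgcg` from the
shell (`examples/ttgcg.yaml` holds the same configuration as a file).  The
run directory contains the trajectory (XYZ), tidy observables (CSV), the
spring schedule and events, and `rupture_report.csv`:

```
 pair label  F_rup_pN  t_rup_fs  F_max_pN  t_max_fs  bound_ok
    1   1TA     413.6   12029.0     643.2   13293.0      True
    2   2TA     113.7   13896.0     370.4   15907.0      True
    3   3GC     645.5   19460.0     839.2   20527.0      True
    4   4CG     360.8   22262.0     589.4   23949.0      True
    5   5GC     450.9   26476.0     560.1   27339.0      True
```

Pairs are labelled `1TA` … `5GC` in strand-one order.  Forces are in the
hundreds-of-pN range; the G·C pairs (three hydrogen bridges) resist larger
rupture forces than the T·A pairs (two bridges), F_max bounds F_rup for
every pair, and the five pairs separate strictly in sequence.  `run.log`
summarizes the stages of the same run:

```
pulling rate k*v: 0.2000 pN/fs
stage 1: 10001 samples, t = 0..10000 fs, <T> = 304.8 K
stage 2: 17340 samples, t = 10000..27339 fs, <T> = 295.9 K
stage 3: 10001 samples, t = 27339..37339 fs, <T> = 295.4 K
```

Stage 1 equilibrates the linked duplex with no external forces, stage 2 is
the sequential unwinding, stage 3 relaxes the separated strands.  Identical
configuration and seed reproduce every output file byte for byte.
`dw.analyze_only(...)` (CLI verb `analyze`) recomputes the report from a
trajectory plus spring schedule without re-simulation, and `dnaunwind
fixtures` emits scripted trajectories with closed-form rupture values for
validating the detectors.

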