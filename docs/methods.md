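# Methods

`dnaunwind` simulates the mechanical opening of a short DNA duplex the way a
helicase performs it: base pair by base pair, following the helical twist,
with the enzyme's grip and agitation represented implicitly by friction and
thermal noise.  This note records the model, the numerical choices, and what
the package's synthetic conditions can and cannot say about real DNA.

## The model

### Coarse-grained duplex

Each nucleotide is three beads — phosphate, sugar, base — with lumped group
masses from standard atomic masses (see the mass table in
`dnaunwind.duplex`).  The two strands are laid on an idealized B-DNA helix:
rise 3.4 Å and twist 36° per base pair, with the paired base beads facing
each other across the helix axis at the calibrated centre-of-mass (CM)
distance of 5.8 Å — the value an equilibrated, still-linked duplex shows.
The base bead carries the spring attachment, standing in for the pull atoms
of the all-atom picture (C4 of thymine, C6 of adenine, C5 of cytosine and
C5 of guanine), whose purpose is to define a line of action along the
hydrogen bridges and minimize torsional moments while pulling.  The initial
helix parameters are not critical: stage-1 thermalization relaxes the
structure before any force is applied.

### Surrogate potential

Systematic forces come from a classical coarse-grained potential behind the
`ForceBackend` seam (an ab initio backend could be plugged into the same
seam; the electronic-structure level of description, including partial
charges, is out of scope here and `partial_charges` is `None`):

| term | form | default |
|---|---|---|
| backbone bonds | ½ k (r − r₀)² | k = 400 kcal mol⁻¹ Å⁻² |
| backbone/base angles | ½ k (θ − θ₀)² | k = 80 kcal mol⁻¹ rad⁻² |
| stacking (adjacent bases, same strand) | Morse | depth 6.0 kcal/mol, width 2.0 Å⁻¹ |
| hydrogen bridges (paired bases) | multiplicity × Morse | depth 6.0 kcal/mol per bridge, width 0.8 Å⁻¹ |
| excluded volume (all other pairs) | ε (σ/r)¹² | ε = 1 kcal/mol, σ = 2.5 Å |

Rest lengths and angles are measured on the freshly built geometry, so the
built duplex sits at the potential minimum and stage-1 equilibration
fluctuates around it.  A G·C pair couples through three hydrogen bridges and
an A·T pair through two, at equal per-bridge well depth — this 3:2 ratio is
the only sequence dependence of the surrogate and reproduces the
qualitative ordering that GC pairs resist larger opening forces than AT
pairs.  There is no electrostatics, no solvent, no sequence-dependent
stacking library; the parameters are this package's own choices, and none
of its energies or forces should be compared numerically to ab initio
values.

### Langevin dynamics

Beads obey m r̈ = F_sys + F_spring − γ m ṙ + G(t) with γ = 4.0 ps⁻¹ —
deliberately higher than a pure-water value, accounting for the mechanical
grip of the implicit enzyme — and Gaussian noise G satisfying
fluctuation–dissipation at 300 K.  The original formulation draws kicks
from a bivariate position–velocity distribution; this package instead uses
the BAOAB splitting integrator with standard Gaussian noise, which targets
the same stationary (canonical) distribution.  Equivalence is therefore
enforced at the level of stationary statistics, not per-step arithmetic.
The time step is 1 fs.  Kinetic temperature uses all 3N degrees of freedom
(no centre-of-mass or constraint correction: the springs break momentum
conservation during stage 2 anyway).

In the γ → 0, T → 0 limit BAOAB reduces exactly to velocity Verlet, which
the test suite uses as an energy-conservation oracle (dt = 0.1 fs there,
purely as a discretization-error control).

### Spring protocol

Stage 2 attaches two opposed harmonic springs (k = 0.01 N/cm = 100 pN/Å) to
the pull beads of the active pair.  The tips move apart at v = 0.002 Å/fs
along the action line — the unit vector between the two pull beads, frozen
at activation — starting from the beads' own positions, so the spring force
ramps from zero at the pulling rate k·v = 0.20 pN/fs.  The reported tension
is the magnitude of the strand-one spring force (the two springs are the
two ends of one rope).  A pair is separated when its base–base CM distance
first reaches 8.2 Å, sampled at the integration step (no sub-step
interpolation; at dt = 1 fs the induced error in crossing times is a
fraction of a femtosecond).  Its springs then switch off and the next
pair's switch on at the same step (a configurable relaxation gap, default
0, can delay the handover).  Successive action lines rotate with the helix
twist, so the duplex unwinds helicoidally.

### Observables

- **F_rup** — tension at the last local minimum of the smoothed CM series
  before the threshold crossing (the point where the separation ceases to
  decrease and the runaway begins).  Rupture is not an abrupt observable;
  this is an operational definition.
- **F_max** — tension at the first sample with CM separation ≥ 8.2 Å.  It
  upper-bounds F_rup when pulling is quasi-static, because the pair lets go
  before the threshold is reached and tension keeps ramping in between.
- **ΔE** — difference of mean surrogate potential energy between a stage-1
  window (linked, equilibrated) and a stage-3 window (separated,
  re-equilibrated).
- **Force–extension curves** — tension versus CM separation with a
  plateau/rise segmentation (plateau = longest prefix whose slope stays
  below a configurable fraction, default 0.25, of the terminal slope).

Smoothing: thermal noise makes "ceases to decrease" ill-defined on raw
series, so the CM series is smoothed with a centred moving average before
minimum detection (tensions are always read off the raw series).  The
window is a config knob recorded with every report; noise-free scripted
fixtures are analyzed with the window disabled, where the detectors are
exact on the sampling grid.

## Calibration of the bridge term

The bridge depth and width are free parameters of the surrogate,
calibrated once against two physical requirements of the study conditions:

1. **thermal stability** — no pair dissociates spontaneously during tens of
   picoseconds of stage-1 equilibration at 300 K, and the equilibrated pair
   CM distance stays at 5.8 ± 0.3 Å;
2. **quasi-static opening** — under the fixed pulling rate of 0.20 pN/fs
   the tension should still be rising when the pair crosses 8.2 Å, so that
   F_max ≥ F_rup holds mechanically and not merely by definition.

Requirement 2 is delicate.  A short-ranged (steep) bridge stores several
Ångström of spring stretch before yielding and then releases it in a
sub-picosecond snap, during which the bead outruns the tip and the tension
*drops* before the crossing.  A very long-ranged (flat) bridge instead
creates a near-neutral force balance around the yield point, and thermal
kicks hop the pair between partially open and re-closed states — the last
re-closure can occur at peak tension with the same inversion of the bound.
A floppy scaffold makes both mechanisms worse, because the free molecule
reorients about the pinned spring midpoint and stores tension
perpendicular to the frozen action line.  The shipped defaults
(`ForceFieldParams`: bridge depth 6.0 kcal/mol per bridge at width
0.8 Å⁻¹, with the stiffened backbone/stacking of the table above) sit
between the two bridge regimes on a rigid enough scaffold, and the
500 fs default smoothing window for rupture detection spans the residual
hop timescale.  This combination was calibrated jointly across seven noise
seeds and all three study sequences; every calibration run satisfied the
bound and the GC > AT rupture-force ordering.  With hundreds-of-pN forces
against thermal noise at 300 K the bound nevertheless retains a small
stochastic failure probability per pair on arbitrary seeds.

## Synthetic data and what passing tests show

The scripted-trajectory generator emits separation series from prescribed
analytic functions with placeholder coordinates, which validates the
detectors against closed forms but exercises none of the dynamics.  The
simulated duplex itself is synthetic in a deeper sense: a three-bead
nucleotide with a 3:2 Morse bridge ratio reproduces the *structure* of the
unwinding problem (sequential openings, temperature-insensitive but
energy-sensitive separations, GC > AT rupture forces, F_max bounding
F_rup) but not the *values* of any real or ab initio force: rupture forces
here are set by the calibrated well depths, not by hydrogen-bond chemistry.
Passing tests therefore demonstrate correctness of the integrator, the
protocol state machine and the detectors under the stated model, and the
qualitative sequence physics — nothing quantitative about real DNA.

## Numerical choices and degenerate inputs

- One `numpy` Generator seeded from the run config drives initial
  velocities and all noise; identical config + seed reproduce every output
  file byte for byte.
- Threshold crossing uses ≥ on the raw series at sample resolution.
- Rupture-minimum ties (flat smoothed minima) resolve to the later sample.
- A monotone non-decreasing window reports `rupture_found = False` with the
  window start as the rupture time.
- Pairs whose CM never reaches the threshold within the per-pair step
  budget abort the run naming the stuck pair; analysis-only mode rejects
  truncated trajectories the same way.
- Coincident beads (singular repulsion, zero-length action line) are
  rejected with the bead indices.

## Problem sizes

The packaged defaults run 5-bp duplexes (30 beads) with 10 ps of stage-1
equilibration, a stage-2 duration set by the protocol itself (≈ 12–15 ps
for the three standard sequences) and 10 ps of stage 3 — a desk-scale
budget chosen so a full run completes in seconds.  The test suite trims
stages further (2-pair duplexes, 1–2 ps windows) where only bookkeeping is
under test.

## Known limitations

- After a pair's springs switch off, the surrogate bridge still attracts
  at 8.2 Å, so released pairs can partially re-approach while later pairs
  are being pulled; real separated strands are kept apart by the unwinding
  geometry and solvent entropy that the model lacks.
- The duplex is free (no anchor): the whole molecule can reorient about
  the pinned spring midpoint, which feeds geometric storage into the
  tension signal and is the main source of scatter in F_rup.
- ΔE values are surrogate potential-energy differences and carry no
  ab initio meaning.
- No electrostatics or explicit solvent; charge observables are
  unavailable (`partial_charges = None`).
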