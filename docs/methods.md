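# Methods

## Overview

`sumdkit` implements supervised molecular dynamics (SuMD), a sampling
scheme that accelerates ligand-binding events without applying any
energetic bias, together with the two trajectory analyses that are
typically run on the resulting binding trajectories: per-residue
interaction-energy decomposition and voxel-based water-occupancy mapping.
The supervision algorithm is engine-agnostic — any backend implementing
the small propagator protocol (`propagate`, `resample_velocities`,
`current_frame`, `get_state`/`set_state`) plugs in — and the package
bundles a toy Langevin engine so every part of the workflow runs and is
testable on a single CPU in seconds to minutes.

Units everywhere: Å, ps, amu, kcal/mol, elementary charges, kelvin.

## The supervision loop

Dynamics are run in windows of `step_duration_ps` (default 600 ps). Within
each window the ligand–site center-of-mass (COM) distance is recorded at
`n_checkpoints` (default 5) evenly spaced times — offsets k·(T/n) for
k = 1..n, so the last checkpoint is the window end and the window start is
*not* a checkpoint (5 samples over 5 equal intervals). An
ordinary-least-squares line is fitted through the (time, distance) pairs
in closed form.

The tabù-like acceptance rule:

* slope < 0 (strictly): the window is **productive** — its frames join the
  retained trajectory and its final state seeds the next window;
* slope ≥ 0: the window is **discarded** — the engine state is restored to
  the window start and the velocities are redrawn from the
  Maxwell–Boltzmann distribution before the retry. Restoring positions is
  what makes the retry a retry rather than a continuation; a slope of
  exactly zero is rejected because a non-approaching window should not be
  kept (the acceptance rule is stated only for strictly negative and
  strictly positive slopes; zero is a measure-zero event in practice).

Supervision is permanently switched off the first time a *retained*
window's end-of-window distance (its last checkpoint — no intra-window
minimum is consulted) drops below `switchoff_distance` (default 5 Å).
Exactly `post_switchoff_steps` (default 30) further windows then run as
plain MD and are retained regardless of slope.

Two safeguards, absent from the original description, bound adversarial
landscapes: `max_consecutive_failures` (default 40) rejections in a row or
`max_total_steps` (default 1000) propagated windows terminate the run with
an explicit reason. No memory of previously rejected states beyond the
simple retry is kept; "tabù-like" here means discard-and-retry only.

Every propagated window — rejected ones included — produces a
`StepRecord` (checkpoint times/distances, slope, verdict, supervised
flag); the retained trajectory carries a per-frame provenance list naming
the retained step each frame came from. A run manifest (seed, config,
input digests) makes every run replayable bit-for-bit.

## The toy Langevin engine

The bundled backend propagates a rigid pseudo-ligand — by default three
beads of 100 amu carried rigidly around their center of mass — as a single
Langevin particle in a *binding funnel*:

    U(r) = −W·exp(−|r−c|² / 2σ²) + ½·k·max(0, |r−c| − R)²

a Gaussian attraction basin of depth W at the binding-site COM c plus a
harmonic wall confining the particle to a sphere of radius R (the stand-in
for the solvent box). All other atoms are static.

Integrator: BAOAB Langevin splitting. It is stable at the default
2 fs / 310 K settings and samples the Maxwell–Boltzmann velocity marginal
exactly, which matters because velocity *reassignment* on rejected windows
draws from that same distribution. One seeded `numpy` generator per engine
drives both the thermostat noise and the reassignments, so
(config, seed) fully determine a run. The inner loop is JIT-compiled
(numba); a 600 ps window (300 000 steps) takes ~60 ms.

Thermostat defaults (2 fs timestep, 310 K, friction 0.1 ps⁻¹) mirror
standard explicit-solvent practice for this class of simulation. Constants
we document but deliberately do not implement: bond constraints (M-SHAKE),
PME electrostatics, barostats and staged equilibration — the toy system
has no bonds, no solvent and no box to equilibrate.

### Toy funnel study conditions

The funnel fixture (`make_toy_funnel`) builds an eight-bead pseudo-receptor
ring (site COM exactly at the funnel minimum) and places the ligand COM at
exactly 30 Å — the "ligand in the bulk" starting condition. Defaults, with
rationale:

| parameter | value | why |
|---|---|---|
| ligand mass | 3 × 100 amu | drug-like ~300 Da |
| well depth W | 8 kcal/mol (~13 kT) | binding is effectively irreversible over the post-switch-off tail |
| well width σ | 4 Å | thermal spread in the bound state √(3kT·σ²/W) ≈ 2 Å, comfortably below the 5 Å threshold |
| confinement R | 50 Å | roughly half the edge of a typical solvated receptor box |
| friction γ | 100 ps⁻¹ | see below |

The fixture's friction is *not* the 0.1 ps⁻¹ thermostat default. In
explicit solvent, the thermostat friction is a weak coupling and the real
drag comes from water and from transient nonspecific contacts with the
membrane and protein surface; in the toy there is no solvent, so the
Langevin friction must carry all of it. Bulk Stokes drag for a ~300 Da
ligand is ≈15 ps⁻¹; at that value the toy ligand crosses the whole arena
in one or two 600 ps windows and the binding event has no multi-window
structure left to supervise. The fixture therefore uses an effective
100 ps⁻¹ (D = kT/mγ ≈ 0.009 Å²/ps, a few Å of net COM motion per window),
reproducing the regime in which the approach genuinely takes tens of
windows. With these conditions, supervised runs reach the 5 Å switch-off
in fewer propagated windows than plain MD first reaches the same distance
in 17 of 20 paired seeds (one-sided sign test p ≈ 10⁻³); the test suite
recomputes this experiment, capping unsupervised reference runs at 200
windows (a right-censored observation can only favor the null).

What the toy does *not* emulate: conformational gating, competing
metastable (meta-binding) sites, explicit water, membrane anisotropy.
Passing tests show the supervision logic and analyses are correct and that
supervision accelerates diffusive funnel binding; they say nothing about
force-field accuracy on real receptors.

## Per-residue interaction analysis

Contacts: for every frame, the number of (ligand atom, residue atom)
pairs within 4.5 Å, boundary inclusive (the cutoff is stated without
strictness; we include the boundary and expose it to tests). All atoms
count by default; a heavy-atom-only mode exists. Residues are keyed
(chain, residue number, residue name) because residue numbers repeat
across chains. A ligand selection that covers part of a residue is an
error — contact counting against a residue that contains ligand atoms is
ambiguous.

Ranking: residues sorted by total contacts over the trajectory,
descending, ties broken by (chain, residue index) ascending; the energy
analysis takes the top 25 by default.

Energies: CHARMM-convention pairwise Coulomb + Lennard-Jones,
C = 332.0636 kcal·Å/(mol·e²), dielectric 1, εᵢⱼ = √(εᵢεⱼ),
Rmin,ij = Rmin,i/2 + Rmin,j/2, hard truncation at 9.0 Å (no switching
function — pairs beyond the cutoff contribute exactly zero). Parameters
come from a sidecar file since PDB carries none; an atom without sidecar
parameters is a hard error naming the atom. Energies are computed on every
frame by default (stride configurable).

Heatmap: residues × frames energy matrix; the first and third quartiles
of the flattened distribution (linear-interpolation convention) clip the
red–blue color scale. We read the quartile "mask" as color-scale clipping
bounds; the raw energies are always exported unclipped, so the alternative
reading (hiding cells outside [q1, q3]) can be applied downstream.

The contact-surface export writes each residue's total into the PDB
B-factor column of the first frame for surface coloring.

Periodicity: toy systems are non-periodic; when a frame carries box
lengths, the minimum-image convention is applied to all distances.

## Water-occupancy mapping

The analysis region is discretized into cubic voxels (default 1.0 Å — a
common hydration-site granularity; the method's native voxel size is not
specified here, so the default is declared, not inferred). Each cell's
occupancy is (#frames in which ≥1 probe atom lies in the cell)/(#frames):
two waters in one cell in the same frame count that frame once, and the
probe is the water oxygen by default. Membership is half-open
([low, high) per axis), so every point belongs to exactly one cell and
occupancy·n_frames is always an integer count.

Grid bounds default to the probe bounding box padded by one spacing;
explicit bounds are accepted (for apo-vs-holo comparisons on a shared
lattice), with out-of-bounds probes either expanding the grid along the
original lattice or raising, per flag. Note that auto-bounds derive the
origin from the data, so occupancies are exact *on that lattice*; to
recover fractions defined on a particular lattice (as the residency
fixture does), pass explicit bounds.

Sites with occupancy strictly greater than the display threshold
(default 25%) export as PDB pseudoatoms with the occupancy in the
B-factor column; the full grid exports as an ASCII OpenDX scalar field
(z-fastest order), written by a small built-in writer with a matching
reader for round-trip checks.

## Numerical choices and degenerate inputs

* Slope fit: closed-form OLS; all-equal checkpoint times are an error, a
  NaN slope is an error.
* Zero-length propagation returns the state unchanged and no frames; a
  duration that is not a positive multiple of the timestep is rejected.
* Non-finite coordinates abort integration with the offending axis named.
* Overlapping atoms (r = 0) in an energy call are an error rather than ±∞.
* COM of a zero-total-mass or empty selection is an error; ligand/site
  selections must be disjoint for the supervision distance to be defined.
* PDB coordinates round-trip at the format's 10⁻³ Å precision; fixtures
  use exact-decimal coordinates so constructed COM distances (e.g. the
  30 Å start) survive the round trip to better than 10⁻⁶ Å.
* Quantile convention: linear interpolation, configurable.
* The scripted-distance test engine consumes one script entry per
  propagated window and never rewinds on rejection, so adversarial
  scripts can drive the failure-limit path.

## Problem sizes used by the test suite

Thermostat and diffusion checks integrate 10⁷–2.5×10⁷ steps (20–50 ns of
a single particle); the acceleration experiment runs 20 paired
supervised/unsupervised toy-funnel runs; analysis oracles use
10-ligand-atom × 30-protein-atom random systems over 5 frames and
100-frame scripted water trajectories. These sizes give sub-percent
statistical resolution on the thermostat average and exact (integer)
ground truth for contacts and occupancies.

## Known limitations

* The toy engine propagates one rigid body; there is no multi-particle
  integrator, no bonded force field and no explicit solvent.
* Supervision checks the switch-off condition only at window ends, not
  mid-window, and the end-of-window distance of *rejected* windows is
  never consulted.
* DCD trajectories are read-only; mmCIF and engine-native topologies are
  out of scope.
* The water map scores occupancy only — no orientation analysis, site
  clustering or thermodynamic decomposition.
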