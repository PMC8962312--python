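"""Synthetic systems and trajectories with analytically known answers.

Every generator here writes real files (PDB structure, parameter sidecar,
XYZ-like trajectory) and reads them back through the public readers, so
the I/O layer is exercised by every test that uses a fixture. All
generators are fully reproducible from their arguments plus a seed.

Fixture kinds:

* ``toy_funnel_system`` — a pseudo-receptor ring with a rigid three-bead
  pseudo-ligand placed at an exact requested COM distance, plus the funnel
  potential and a solvent-drag propagator configuration; the desk-scale
  stand-in for a prepared receptor–ligand system with the ligand moved
  into the bulk.
* ``scripted_distance_engine`` — a propagator whose end-of-window COM
  distances follow a script exactly (linear interpolation at
  checkpoints); the oracle for the supervisor's accept/reject logic.
* ``contact_lattice`` — random small ligand/receptor point sets for
  contact-counting and energy tests against brute-force oracles.
* ``water_residency`` — water trajectories engineered so each chosen
  voxel's true occupancy equals a requested fraction exactly.
"""

from __future__ import annotations

import enum
import math
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .engine import FunnelPotential, PropagatorConfig, PropagatorState
from .io import (
    read_structure,
    read_trajectory,
    write_params,
    write_structure,
    write_trajectory,
)
from .system_model import (
    AtomRecord,
    Frame,
    Selection,
    Topology,
    Trajectory,
    center_of_mass,
    select,
)

__all__ = [
    "FixtureKind",
    "FixtureSpec",
    "ToyFunnelSystem",
    "ScriptedDistanceEngine",
    "make_toy_funnel",
    "toy_funnel_propagator_config",
    "make_scripted_engine",
    "make_contact_lattice",
    "make_water_residency",
]


class FixtureKind(str, enum.Enum):
    TOY_FUNNEL_SYSTEM = "toy_funnel_system"
    SCRIPTED_DISTANCE_ENGINE = "scripted_distance_engine"
    CONTACT_LATTICE = "contact_lattice"
    WATER_RESIDENCY = "water_residency"


@dataclass(frozen=True)
class FixtureSpec:
    """A reproducible fixture request: (kind, parameters, seed)."""

    kind: FixtureKind
    parameters: dict = field(default_factory=dict)
    seed: int = 0

    def build(self, out_dir: str | Path | None = None):
        kind = FixtureKind(self.kind)
        if kind is FixtureKind.TOY_FUNNEL_SYSTEM:
            return make_toy_funnel(seed=self.seed, out_dir=out_dir, **self.parameters)
        if kind is FixtureKind.SCRIPTED_DISTANCE_ENGINE:
            return make_scripted_engine(**self.parameters)
        if kind is FixtureKind.CONTACT_LATTICE:
            return make_contact_lattice(seed=self.seed, out_dir=out_dir, **self.parameters)
        if kind is FixtureKind.WATER_RESIDENCY:
            return make_water_residency(seed=self.seed, out_dir=out_dir, **self.parameters)
        raise ValueError(f"unknown fixture kind {self.kind!r}")


def _workdir(out_dir: str | Path | None) -> Path:
    if out_dir is None:
        return Path(tempfile.mkdtemp(prefix="sumdkit-fixture-"))
    p = Path(out_dir)
    p.mkdir(parents=True, exist_ok=True)
    return p


# ---------------------------------------------------------------------------
# Toy funnel system
# ---------------------------------------------------------------------------

@dataclass
class ToyFunnelSystem:
    """A built toy binding system plus everything a SuMD run needs."""

    topology: Topology
    frame: Frame
    potential: FunnelPotential
    ligand: Selection
    site: Selection
    structure_path: Path
    params_path: Path

    def propagator_config(self, seed: int) -> PropagatorConfig:
        return toy_funnel_propagator_config(seed)


def toy_funnel_propagator_config(seed: int, frame_interval_ps: float | None = None) -> PropagatorConfig:
    """Default propagator settings for the toy funnel.

    Temperature and timestep follow the standard thermostat settings
    (310 K, 2 fs). Friction is 100 ps⁻¹: the toy has no explicit solvent
    or membrane, so the Langevin friction must stand in for *all* drag on
    ligand translation — bulk hydrodynamics (Stokes drag of a ~300 Da
    ligand is ≈15 ps⁻¹) plus the transient nonspecific surface
    interactions that slow a ligand's center of mass to a few Å of net
    motion per 600 ps window in solvated receptor systems. The resulting
    effective diffusion constant is D = kT/(mγ) ≈ 0.009 Å²/ps, making the
    approach a genuinely multi-window event.
    """
    return PropagatorConfig(
        timestep_fs=2.0,
        temperature=310.0,
        friction=100.0,
        seed=seed,
        frame_interval_ps=frame_interval_ps,
    )


def make_toy_funnel(
    seed: int,
    ligand_start_distance: float = 30.0,
    out_dir: str | Path | None = None,
) -> ToyFunnelSystem:
    """Build the toy receptor/ligand system with the ligand in the bulk.

    The pseudo-receptor is an eight-bead ring (one residue per bead)
    whose center of mass sits exactly at the funnel minimum; the
    pseudo-ligand is a rigid three-bead triangle (total mass 300 amu)
    whose center of mass is placed exactly ``ligand_start_distance`` Å
    away, in a seed-chosen direction. Files are written to ``out_dir``
    and read back through the public readers.
    """
    rng = np.random.default_rng(seed)
    directions = [(10, 20, 20), (18, 24, 0), (4, 10, 28), (20, 10, 20), (24, 0, 18), (28, 4, 10)]
    base = np.array(directions[rng.integers(len(directions))], dtype=float)
    perm = rng.permutation(3)
    signs = rng.choice([-1.0, 1.0], size=3)
    unit = (base[perm] * signs) / 30.0
    lig_com = unit * ligand_start_distance

    site_positions = np.array(
        [(4, 0, 0), (0, 4, 0), (-4, 0, 0), (0, -4, 0), (3, 3, 0), (-3, 3, 0), (-3, -3, 0), (3, -3, 0)],
        dtype=float,
    )
    # equal-mass triangle with exact-decimal offsets summing to zero
    lig_offsets = np.array([(1.0, 0.0, 0.0), (-0.5, 0.8, 0.0), (-0.5, -0.8, 0.0)])
    coords = np.vstack([site_positions, lig_com + lig_offsets])

    atoms = []
    for i in range(len(site_positions)):
        atoms.append(
            AtomRecord(
                atom_index=i, atom_name="C1", residue_name="RES",
                residue_index=i + 1, chain_id="A", element="C", mass=12.011,
            )
        )
    for j, name in enumerate(["C1", "C2", "C3"]):
        atoms.append(
            AtomRecord(
                atom_index=len(site_positions) + j, atom_name=name,
                residue_name="LIG", residue_index=1, chain_id="L",
                element="C", mass=100.0,
            )
        )
    topology = Topology(atoms)
    frame = Frame(time=0.0, coordinates=coords)

    work = _workdir(out_dir)
    structure_path = work / "system.pdb"
    params_path = work / "params.tsv"
    write_structure(structure_path, topology, frame)
    write_params(
        params_path,
        {
            ("RES", "C1"): {"mass": 12.011, "charge": -0.05, "lj_epsilon": 0.12, "lj_rmin_half": 2.0},
            ("LIG", "C1"): {"mass": 100.0, "charge": 0.10, "lj_epsilon": 0.15, "lj_rmin_half": 2.0},
            ("LIG", "C2"): {"mass": 100.0, "charge": -0.05, "lj_epsilon": 0.15, "lj_rmin_half": 2.0},
            ("LIG", "C3"): {"mass": 100.0, "charge": -0.05, "lj_epsilon": 0.15, "lj_rmin_half": 2.0},
        },
    )
    topology, frame = read_structure(structure_path, params=params_path)

    ligand = select(topology, "resname LIG", label="ligand")
    site = select(topology, "not resname LIG", label="site")
    site_com = center_of_mass(frame, site, topology)
    potential = FunnelPotential(
        well_depth=8.0,
        well_width_sigma=4.0,
        site_center=tuple(site_com),
        confinement_radius=50.0,
        confinement_k=1.0,
    )
    return ToyFunnelSystem(
        topology=topology, frame=frame, potential=potential,
        ligand=ligand, site=site,
        structure_path=structure_path, params_path=params_path,
    )


# ---------------------------------------------------------------------------
# Scripted-distance engine
# ---------------------------------------------------------------------------

class ScriptedDistanceEngine:
    """A propagator whose end-of-window COM distances follow a script.

    Window *k* (counting every propagated attempt, retries included) ends
    at ``script[k]`` Å from the site; within a window the distance
    interpolates linearly from the window-start distance. Velocity
    reassignment is a counted no-op. Restoring a saved state rewinds the
    geometry but — like the tabù retry it models — not the script
    pointer, so a rejected window's retry consumes the next entry.
    """

    def __init__(
        self,
        topology: Topology,
        frame: Frame,
        ligand: Selection,
        site: Selection,
        script: list[float],
        window_duration: float = 600.0,
        cycle: bool = True,
    ):
        if not script:
            raise ValueError("distance script must be non-empty")
        self.topology = topology
        self.ligand = ligand
        self.site = site
        self.script = [float(d) for d in script]
        self.cycle = cycle
        self.window_duration = float(window_duration)
        self._static = frame.coordinates.copy()
        self._lig_idx = ligand.sorted_indices
        site_com = center_of_mass(frame, site, topology)
        lig_com = center_of_mass(frame, ligand, topology)
        delta = lig_com - site_com
        norm = np.linalg.norm(delta)
        self._site_com = site_com
        self._unit = delta / norm if norm > 0 else np.array([1.0, 0.0, 0.0])
        self._offsets = frame.coordinates[self._lig_idx] - lig_com
        self._distance = float(norm)
        self._time = frame.time
        self._window_elapsed = 0.0
        self._window_start_distance = self._distance
        self._script_pos = 0
        self.n_velocity_resamples = 0

    def _target(self) -> float:
        if self._script_pos >= len(self.script):
            if not self.cycle:
                raise IndexError("distance script exhausted")
            return self.script[self._script_pos % len(self.script)]
        return self.script[self._script_pos]

    def current_frame(self) -> Frame:
        coords = self._static.copy()
        lig_com = self._site_com + self._unit * self._distance
        coords[self._lig_idx] = lig_com + self._offsets
        return Frame(time=self._time, coordinates=coords)

    def get_state(self) -> PropagatorState:
        return PropagatorState(
            positions=self._site_com + self._unit * self._distance,
            velocities=np.zeros(3),
            time=self._time,
        )

    def set_state(self, state: PropagatorState) -> None:
        self._distance = float(np.linalg.norm(state.positions - self._site_com))
        self._time = state.time
        self._window_elapsed = 0.0
        self._window_start_distance = self._distance

    def resample_velocities(self) -> None:
        self.n_velocity_resamples += 1

    def propagate(self, duration: float) -> tuple[PropagatorState, list[Frame]]:
        if duration == 0:
            return self.get_state(), []
        if duration < 0:
            raise ValueError("duration must be non-negative")
        target = self._target()
        elapsed = self._window_elapsed + duration
        frac = min(elapsed / self.window_duration, 1.0)
        self._distance = self._window_start_distance + (target - self._window_start_distance) * frac
        self._time += duration
        if elapsed >= self.window_duration - 1e-9:
            self._script_pos += 1
            self._window_elapsed = 0.0
            self._window_start_distance = self._distance
        else:
            self._window_elapsed = elapsed
        return self.get_state(), [self.current_frame()]


def make_scripted_engine(
    distance_script: list[float],
    start_distance: float | None = None,
    window_duration: float = 600.0,
    cycle: bool = True,
) -> tuple[ScriptedDistanceEngine, Topology, Selection, Selection]:
    """Build a minimal two-atom system driven by a distance script.

    Returns ``(engine, topology, ligand, site)``. The starting distance
    defaults to one above the first scripted value so a decreasing script
    is productive from the first window.
    """
    if not distance_script:
        raise ValueError("distance script must be non-empty")
    if start_distance is None:
        start_distance = distance_script[0] + 1.0
    atoms = [
        AtomRecord(0, "C1", "SIT", 1, "A", "C", mass=12.011),
        AtomRecord(1, "C1", "LIG", 1, "L", "C", mass=12.011),
    ]
    topology = Topology(atoms)
    frame = Frame(
        time=0.0,
        coordinates=np.array([[0.0, 0.0, 0.0], [start_distance, 0.0, 0.0]]),
    )
    ligand = select(topology, "resname LIG", label="ligand")
    site = select(topology, "resname SIT", label="site")
    engine = ScriptedDistanceEngine(
        topology, frame, ligand, site, distance_script,
        window_duration=window_duration, cycle=cycle,
    )
    return engine, topology, ligand, site


# ---------------------------------------------------------------------------
# Contact lattice
# ---------------------------------------------------------------------------

def make_contact_lattice(
    seed: int,
    n_ligand_atoms: int = 10,
    n_protein_atoms: int = 30,
    n_frames: int = 5,
    extent: float = 12.0,
    out_dir: str | Path | None = None,
) -> tuple[Trajectory, Selection]:
    """Random ligand/receptor point clouds for contact & energy oracles.

    Protein atoms are spread over residues of three atoms each; positions
    are uniform in a cube of the given extent, re-drawn per frame, so
    ligand–residue distances straddle the 4.5 Å contact cutoff. Ground
    truth is whatever a brute-force double loop computes.
    """
    rng = np.random.default_rng(seed)
    atoms = []
    for i in range(n_protein_atoms):
        atoms.append(
            AtomRecord(
                atom_index=i, atom_name=f"C{i % 3 + 1}", residue_name="RES",
                residue_index=i // 3 + 1, chain_id="A", element="C", mass=12.011,
            )
        )
    for j in range(n_ligand_atoms):
        atoms.append(
            AtomRecord(
                atom_index=n_protein_atoms + j, atom_name=f"C{j + 1}",
                residue_name="LIG", residue_index=1, chain_id="L",
                element="C", mass=12.011,
            )
        )
    topology = Topology(atoms)
    n_atoms = len(atoms)
    frames = [
        Frame(time=float(t), coordinates=rng.uniform(0.0, extent, size=(n_atoms, 3)))
        for t in range(n_frames)
    ]

    work = _workdir(out_dir)
    params = {}
    for a in atoms:
        params[(a.residue_name, a.atom_name)] = {
            "mass": 12.011,
            "charge": float(np.round(rng.uniform(-0.3, 0.3), 4)),
            "lj_epsilon": float(np.round(rng.uniform(0.05, 0.2), 4)),
            "lj_rmin_half": float(np.round(rng.uniform(1.5, 2.2), 4)),
        }
    write_params(work / "params.tsv", params)
    write_structure(work / "system.pdb", topology, frames[0])
    write_trajectory(work / "traj.trj", Trajectory(topology, frames))
    topology, _ = read_structure(work / "system.pdb", params=work / "params.tsv")
    traj = read_trajectory(work / "traj.trj", topology)
    ligand = select(topology, "resname LIG", label="ligand")
    return traj, ligand


# ---------------------------------------------------------------------------
# Water residency
# ---------------------------------------------------------------------------

def make_water_residency(
    cells: list[tuple[tuple[int, int, int], float]],
    n_frames: int,
    spacing: float = 1.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> tuple[Trajectory, Selection, np.ndarray]:
    """Water trajectory whose voxel occupancies are known exactly.

    One water (oxygen probe) is assigned to each requested cell and placed
    inside it for exactly ``fraction·n_frames`` frames (must be integral);
    off-frames park the water in dedicated parking cells, rotated so no
    parking cell ever exceeds 20% occupancy. Returns ``(trajectory,
    water_selection, origin)`` with the grid origin at the coordinate
    origin. Files are routed through the public writers/readers.
    """
    rng = np.random.default_rng(seed)
    occupied_frames: list[np.ndarray] = []
    for (cell, fraction) in cells:
        target = fraction * n_frames
        if abs(target - round(target)) > 1e-9:
            raise ValueError(
                f"fraction {fraction} × {n_frames} frames is not an integer frame count"
            )
    if not 0 <= min([f for _, f in cells], default=0.0) <= 1 or (
        cells and max(f for _, f in cells) > 1
    ):
        raise ValueError("fractions must lie in [0, 1]")

    n_waters = len(cells)
    max_k = max((c[2] for c, _ in cells), default=0)
    park_k = max_k + 5
    max_park_frames = max(1, int(math.floor(0.2 * n_frames)))

    def cell_point(cell_idx) -> np.ndarray:
        lo = np.array(cell_idx, dtype=float) * spacing
        return lo + spacing * rng.uniform(0.1, 0.9, size=3)

    coords_per_frame = np.zeros((n_frames, max(n_waters, 1), 3))
    for w, (cell, fraction) in enumerate(cells):
        n_in = int(round(fraction * n_frames))
        in_frames = set(rng.choice(n_frames, size=n_in, replace=False).tolist())
        n_park_cells = max(1, math.ceil((n_frames - n_in) / max_park_frames))
        park = 0
        for f in range(n_frames):
            if f in in_frames:
                coords_per_frame[f, w] = cell_point(cell)
            else:
                park_cell = (2 * w, 2 * (park % n_park_cells), park_k)
                coords_per_frame[f, w] = cell_point(park_cell)
                park += 1
    if n_waters == 0:
        # a single always-parked water so the trajectory is non-empty
        for f in range(n_frames):
            coords_per_frame[f, 0] = cell_point((0, 0, park_k))

    atoms = [
        AtomRecord(
            atom_index=w, atom_name="O", residue_name="HOH",
            residue_index=w + 1, chain_id="W", element="O", mass=15.999,
        )
        for w in range(max(n_waters, 1))
    ]
    topology = Topology(atoms)
    frames = [
        Frame(time=float(f), coordinates=coords_per_frame[f]) for f in range(n_frames)
    ]

    work = _workdir(out_dir)
    write_structure(work / "waters.pdb", topology, frames[0])
    write_params(
        work / "params.tsv",
        {("HOH", "O"): {"mass": 15.999, "charge": -0.834, "lj_epsilon": 0.152, "lj_rmin_half": 1.7682}},
    )
    write_trajectory(work / "traj.trj", Trajectory(topology, frames))
    topology, _ = read_structure(work / "waters.pdb", params=work / "params.tsv")
    traj = read_trajectory(work / "traj.trj", topology)
    water = select(topology, "resname HOH and element O", label="water")
    return traj, water, np.zeros(3)
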