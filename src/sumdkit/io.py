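"""Readers and writers shared across the package.

Formats:

* **PDB** — structures and pseudoatom outputs. Reading goes through
  MDAnalysis (multi-MODEL files become trajectories); writing is a
  fixed-width wwPDB formatter so the occupancy and B-factor columns used by
  the contact-surface and hydration-site exports are under our control.
* **Parameter sidecar** — a flat TSV mapping ``(residue_name, atom_name)``
  to mass, charge and Lennard-Jones parameters, since PDB carries none of
  these. Columns: ``resname  name  mass  charge  epsilon  rmin_half``; a
  mass of ``-`` defers to the element-default table. Lines starting with
  ``#`` are comments.
* **XYZ-like trajectory** — plain-text multi-frame format for fixtures and
  retained SuMD trajectories: atom count line, a comment line
  ``t= <ps> [box= lx ly lz]``, then ``element x y z`` lines per atom.
* **DCD** — read-only, via MDAnalysis.
* **Config** — YAML with per-command sections and a strict schema.
"""

from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
import warnings
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from .system_model import (
    ELEMENT_MASSES,
    AtomRecord,
    Frame,
    Topology,
    Trajectory,
)

__all__ = [
    "read_structure",
    "write_structure",
    "read_trajectory",
    "write_trajectory",
    "read_params",
    "apply_params",
    "load_config",
    "RunManifest",
    "ParameterError",
]


class ParameterError(ValueError):
    """An atom required by an energy computation has no sidecar parameters."""


def _guess_element(atom_name: str) -> str:
    stripped = atom_name.strip().lstrip("0123456789")
    if not stripped:
        return "X"
    if len(stripped) >= 2 and stripped[:2].upper() in ELEMENT_MASSES and stripped[:2].isalpha():
        # two-letter elements (CL, BR, NA ...) only when the name says so
        if stripped[:2].upper() not in {"CA", "CD", "CE", "CZ", "CB", "CG", "NA", "ND", "NE", "NZ", "NH"}:
            return stripped[:2].upper()
    return stripped[0].upper()


def _default_mass(element: str) -> float:
    return ELEMENT_MASSES.get(element.upper(), 12.011)


# ---------------------------------------------------------------------------
# PDB
# ---------------------------------------------------------------------------

def _universe(path: str | Path):
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return mda.Universe(str(path))


def _topology_from_universe(u) -> Topology:
    atoms = []
    try:
        elements = [str(e) for e in u.atoms.elements]
    except Exception:
        elements = [_guess_element(str(n)) for n in u.atoms.names]
    try:
        chains = [str(c) for c in u.atoms.chainIDs]
    except Exception:
        chains = [str(s) if str(s) != "SYSTEM" else "A" for s in u.atoms.segids]
    for i, a in enumerate(u.atoms):
        el = elements[i].strip() or _guess_element(str(a.name))
        atoms.append(
            AtomRecord(
                atom_index=i,
                atom_name=str(a.name),
                residue_name=str(a.resname),
                residue_index=int(a.resid),
                chain_id=chains[i].strip() or "A",
                element=el.upper(),
                mass=_default_mass(el),
            )
        )
    top = Topology(atoms)
    top.has_nonbonded = np.zeros(len(atoms), dtype=bool)  # set by apply_params
    return top


def _box_from_dimensions(dims) -> np.ndarray | None:
    if dims is None:
        return None
    box = np.asarray(dims[:3], dtype=float)
    if np.all(box > 0):
        return box
    return None


def read_structure(
    path: str | Path, params: dict | str | Path | None = None
) -> tuple[Topology, Frame]:
    """Read a PDB structure; returns the topology and its first frame.

    ``params`` may be a sidecar path or a mapping from :func:`read_params`;
    when given, masses/charges/LJ parameters are attached via
    :func:`apply_params`.
    """
    u = _universe(path)
    top = _topology_from_universe(u)
    frame = Frame(
        time=0.0,
        coordinates=np.array(u.atoms.positions, dtype=float),
        box_lengths=_box_from_dimensions(u.dimensions),
    )
    if params is not None:
        if not isinstance(params, dict):
            params = read_params(params)
        top = apply_params(top, params)
    return top, frame


def _format_pdb_atom_line(serial: int, atom: AtomRecord, xyz, occupancy: float, bfactor: float) -> str:
    name = atom.atom_name
    if len(name) < 4:
        name = f" {name:<3}"
    chain = (atom.chain_id or "A")[0]
    return (
        f"ATOM  {serial:>5} {name:<4} {atom.residue_name:>3} {chain}"
        f"{atom.residue_index:>4}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
        f"{occupancy:6.2f}{bfactor:6.2f}          {atom.element:>2}"
    )


def write_structure(
    path: str | Path,
    topology: Topology,
    frames: Frame | list[Frame],
    bfactors: np.ndarray | None = None,
    occupancies: np.ndarray | None = None,
) -> None:
    """Write a PDB file; a list of frames becomes a multi-MODEL trajectory.

    ``bfactors``/``occupancies`` are per-atom columns (default 0.00/1.00);
    the analysis modules use the B-factor column to carry contact totals and
    voxel occupancies.
    """
    if isinstance(frames, Frame):
        frames = [frames]
    if bfactors is None:
        bfactors = np.zeros(topology.n_atoms)
    if occupancies is None:
        occupancies = np.ones(topology.n_atoms)
    multi = len(frames) > 1
    lines: list[str] = []
    box = frames[0].box_lengths
    if box is not None:
        lines.append(
            f"CRYST1{box[0]:9.3f}{box[1]:9.3f}{box[2]:9.3f}"
            f"{90.0:7.2f}{90.0:7.2f}{90.0:7.2f} P 1           1"
        )
    for imodel, frame in enumerate(frames, start=1):
        if multi:
            lines.append(f"MODEL     {imodel:>4}")
        for atom in topology.atoms:
            serial = min(atom.atom_index + 1, 99999)
            lines.append(
                _format_pdb_atom_line(
                    serial,
                    atom,
                    frame.coordinates[atom.atom_index],
                    float(occupancies[atom.atom_index]),
                    float(bfactors[atom.atom_index]),
                )
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb_bfactors(path: str | Path) -> np.ndarray:
    """Per-atom B-factor column of the first model of a PDB file."""
    values = []
    for line in Path(path).read_text().splitlines():
        if line.startswith("ENDMDL"):
            break
        if line.startswith(("ATOM", "HETATM")):
            values.append(float(line[60:66]))
    return np.array(values)


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def write_trajectory(path: str | Path, traj: Trajectory) -> None:
    """Write a trajectory; ``.pdb`` → multi-MODEL PDB, else XYZ-like text."""
    path = Path(path)
    if path.suffix.lower() == ".pdb":
        write_structure(path, traj.topology, traj.frames)
        return
    lines: list[str] = []
    elements = [a.element for a in traj.topology.atoms]
    for frame in traj.frames:
        lines.append(str(frame.n_atoms))
        comment = f"t= {frame.time:.6f}"
        if frame.box_lengths is not None:
            b = frame.box_lengths
            comment += f" box= {b[0]:.6f} {b[1]:.6f} {b[2]:.6f}"
        lines.append(comment)
        for el, xyz in zip(elements, frame.coordinates):
            lines.append(f"{el} {xyz[0]:.6f} {xyz[1]:.6f} {xyz[2]:.6f}")
    path.write_text("\n".join(lines) + "\n")


def _read_xyz_frames(path: Path) -> list[Frame]:
    lines = path.read_text().splitlines()
    frames: list[Frame] = []
    i = 0
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise ValueError(f"{path}:{i + 1}: expected an atom count, got {lines[i]!r}")
        comment = lines[i + 1].split()
        time = 0.0
        box = None
        for j, tok in enumerate(comment):
            if tok == "t=":
                time = float(comment[j + 1])
            elif tok == "box=":
                box = np.array([float(v) for v in comment[j + 1 : j + 4]])
        coords = np.empty((n, 3))
        for k in range(n):
            parts = lines[i + 2 + k].split()
            coords[k] = [float(v) for v in parts[1:4]]
        frames.append(Frame(time=time, coordinates=coords, box_lengths=box))
        i += 2 + n
    return frames


def read_trajectory(path: str | Path, topology: Topology | None = None, dt: float = 1.0) -> Trajectory:
    """Read a multi-frame trajectory (.pdb multi-MODEL, XYZ-like text, or .dcd).

    PDB and DCD carry no reliable time stamps here, so frames are stamped
    ``0, dt, 2·dt, …`` ps. A topology is required for XYZ-like and DCD
    input; for PDB it is parsed from the file when not supplied.
    """
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix == ".pdb":
        u = _universe(path)
        top = topology if topology is not None else _topology_from_universe(u)
        frames = []
        for i, ts in enumerate(u.trajectory):
            frames.append(
                Frame(
                    time=i * dt,
                    coordinates=np.array(u.atoms.positions, dtype=float),
                    box_lengths=_box_from_dimensions(u.dimensions),
                )
            )
        return Trajectory(top, frames)
    if suffix == ".dcd":
        if topology is None:
            raise ValueError("reading a DCD trajectory requires a topology")
        import MDAnalysis as mda

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            reader = mda.coordinates.DCD.DCDReader(str(path))
            frames = [
                Frame(time=i * dt, coordinates=np.array(ts.positions, dtype=float))
                for i, ts in enumerate(reader)
            ]
        return Trajectory(topology, frames)
    if topology is None:
        raise ValueError("reading an XYZ-like trajectory requires a topology")
    return Trajectory(topology, _read_xyz_frames(path))


# ---------------------------------------------------------------------------
# Parameter sidecar
# ---------------------------------------------------------------------------

ParamTable = dict[tuple[str, str], dict[str, float | None]]


def read_params(path: str | Path) -> ParamTable:
    """Parse a parameter sidecar TSV into a ``(resname, name) → fields`` map."""
    table: ParamTable = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 6:
            raise ValueError(
                f"{path}:{lineno}: expected 6 columns "
                "(resname name mass charge epsilon rmin_half), got "
                f"{len(parts)}"
            )
        resname, name, mass_s, charge_s, eps_s, rmin_s = parts
        mass = None if mass_s == "-" else float(mass_s)
        table[(resname, name)] = {
            "mass": mass,
            "charge": float(charge_s),
            "lj_epsilon": float(eps_s),
            "lj_rmin_half": float(rmin_s),
        }
    return table


def write_params(path: str | Path, table: ParamTable) -> None:
    lines = ["# resname name mass charge epsilon rmin_half"]
    for (resname, name), f in table.items():
        mass = "-" if f["mass"] is None else f"{f['mass']:.4f}"
        lines.append(
            f"{resname}\t{name}\t{mass}\t{f['charge']:.6f}\t"
            f"{f['lj_epsilon']:.6f}\t{f['lj_rmin_half']:.6f}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def apply_params(topology: Topology, table: ParamTable) -> Topology:
    """Return a topology with sidecar masses/charges/LJ parameters attached.

    Atoms with no sidecar entry keep element-default masses and are flagged
    so the energy routines can refuse them with a precise error.
    """
    atoms = []
    has = np.zeros(topology.n_atoms, dtype=bool)
    for a in topology.atoms:
        entry = table.get((a.residue_name, a.atom_name))
        if entry is None:
            atoms.append(a)
            continue
        mass = entry["mass"] if entry["mass"] is not None else _default_mass(a.element)
        atoms.append(
            dataclasses.replace(
                a,
                mass=mass,
                charge=entry["charge"],
                lj_epsilon=entry["lj_epsilon"],
                lj_rmin_half=entry["lj_rmin_half"],
            )
        )
        has[a.atom_index] = True
    out = Topology(atoms)
    out.has_nonbonded = has
    return out


def require_params(topology: Topology, atom_indices) -> None:
    """Raise :class:`ParameterError` naming atoms lacking nonbonded parameters."""
    has = getattr(topology, "has_nonbonded", None)
    if has is None:
        return  # topology built programmatically with explicit parameters
    missing = [i for i in atom_indices if not has[i]]
    if missing:
        labels = [
            f"{topology.atoms[i].residue_name}{topology.atoms[i].residue_index}:"
            f"{topology.atoms[i].atom_name}"
            for i in missing[:10]
        ]
        raise ParameterError(
            f"{len(missing)} atom(s) lack sidecar parameters: {', '.join(labels)}"
        )


# ---------------------------------------------------------------------------
# Config
# ---------------------------------------------------------------------------

_CONFIG_SCHEMA: dict[str, set[str]] = {
    "propagator": {"timestep_fs", "temperature", "friction", "frame_interval_ps", "ligand_mass"},
    "supervision": {
        "step_duration_ps",
        "n_checkpoints",
        "switchoff_distance",
        "post_switchoff_steps",
        "max_consecutive_failures",
        "max_total_steps",
    },
    "funnel": {"well_depth", "well_width_sigma", "confinement_radius", "confinement_k"},
    "analysis": {
        "contact_cutoff",
        "energy_cutoff",
        "top_n",
        "spacing",
        "threshold",
        "heavy_atoms_only",
    },
}


def load_config(path: str | Path) -> dict[str, dict[str, Any]]:
    """Load and validate a YAML run configuration.

    Sections and keys outside the documented schema raise an error naming
    the offending key, so typos never silently fall back to defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: config must be a mapping of sections")
    for section, keys in raw.items():
        if section not in _CONFIG_SCHEMA:
            raise ValueError(f"{path}: unknown config section {section!r}")
        if keys is None:
            continue
        for key in keys:
            if key not in _CONFIG_SCHEMA[section]:
                raise ValueError(f"{path}: unknown key {section}.{key!r}")
    return {s: dict(v or {}) for s, v in raw.items()}


# ---------------------------------------------------------------------------
# Run manifest
# ---------------------------------------------------------------------------

def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


@dataclasses.dataclass
class RunManifest:
    """Everything needed to replay a run bit-for-bit: command, seed, config,
    input digests and produced outputs."""

    command: str
    seed: int
    config: dict
    inputs: dict[str, str] = dataclasses.field(default_factory=dict)
    outputs: list[str] = dataclasses.field(default_factory=list)
    tool_version: str = ""
    created: str = ""

    def __post_init__(self) -> None:
        if not self.tool_version:
            from . import __version__

            self.tool_version = __version__
        if not self.created:
            self.created = datetime.datetime.now(datetime.timezone.utc).isoformat()

    def add_input(self, path: str | Path) -> None:
        self.inputs[str(path)] = _sha256(path)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)

    def verify_inputs(self) -> None:
        for p, digest in self.inputs.items():
            actual = _sha256(p)
            if actual != digest:
                raise ValueError(f"input {p} changed since the manifest was written")
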