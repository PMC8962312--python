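"""Voxel-based water-occupancy mapping of MD trajectories.

The simulation box is discretized into a regular grid of cubic voxels
(1 Å spacing by default) and each cell is scored by its *occupancy*: the
fraction of trajectory frames in which at least one water probe atom lies
inside the cell. High-occupancy cells mark stable hydration sites. The
probe is the water oxygen by default — a water molecule "occupies" a cell
through its oxygen position — and a cell visited by two waters in the
same frame still counts that frame once.

Cell membership is half-open, ``[low, high)`` on each axis, so every
point belongs to exactly one cell. Sites above a display threshold
(strictly greater than 25% by default) export as pseudoatoms carrying the
occupancy in the B-factor column; the full grid exports as an OpenDX
scalar field.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .io import write_structure
from .system_model import AtomRecord, Frame, Selection, Topology, Trajectory

__all__ = [
    "VoxelGrid",
    "compute_occupancy",
    "export_sites",
    "write_dx",
    "read_dx",
]


@dataclass
class VoxelGrid:
    """A regular voxel grid with per-cell occupancies in [0, 1].

    ``occupancy[i, j, k]`` is the fraction of the ``n_frames`` analyzed
    frames in which a probe atom occupied cell (i, j, k); each value times
    ``n_frames`` is an integer frame count by construction.
    """

    origin: np.ndarray    # Å, low corner of cell (0, 0, 0)
    spacing: float        # Å
    dims: tuple[int, int, int]
    occupancy: np.ndarray  # (nx, ny, nz)
    n_frames: int

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        if self.spacing <= 0:
            raise ValueError("voxel spacing must be positive")
        if self.occupancy.shape != tuple(self.dims):
            raise ValueError("occupancy array shape must equal dims")
        if np.any(self.occupancy < 0) or np.any(self.occupancy > 1):
            raise ValueError("occupancies must lie in [0, 1]")

    def cell_center(self, idx) -> np.ndarray:
        return self.origin + (np.asarray(idx, dtype=float) + 0.5) * self.spacing

    def cell_of(self, point) -> tuple[int, int, int]:
        """Half-open cell membership: the unique cell containing a point."""
        rel = np.floor((np.asarray(point, dtype=float) - self.origin) / self.spacing)
        return tuple(int(v) for v in rel)


def _auto_bounds(traj: Trajectory, probe_idx: np.ndarray, spacing: float):
    pts = np.vstack([f.coordinates[probe_idx] for f in traj.frames])
    lo = pts.min(axis=0) - spacing
    hi = pts.max(axis=0) + spacing
    return lo, hi


def compute_occupancy(
    traj: Trajectory,
    water: Selection,
    spacing: float = 1.0,
    bounds: tuple | None = None,
    out_of_bounds: str = "expand",
) -> VoxelGrid:
    """Score each voxel by the fraction of frames a water occupies it.

    ``bounds`` is ``(low_corner, high_corner)`` in Å; ``None`` uses the
    bounding box of the probe atoms over all frames, padded by one
    spacing. With explicit bounds, probe atoms falling outside are either
    counted against an expanded grid (``out_of_bounds="expand"``, the
    default, keeping the original cell lattice alignment) or rejected
    (``out_of_bounds="error"``).
    """
    if spacing <= 0:
        raise ValueError("voxel spacing must be positive")
    if out_of_bounds not in {"expand", "error"}:
        raise ValueError("out_of_bounds must be 'expand' or 'error'")
    water.validate(traj.topology)
    probe_idx = water.sorted_indices
    if bounds is None:
        lo, hi = _auto_bounds(traj, probe_idx, spacing)
    else:
        lo = np.asarray(bounds[0], dtype=float)
        hi = np.asarray(bounds[1], dtype=float)
        if np.any(hi <= lo):
            raise ValueError("bounds high corner must exceed the low corner")
        pts = np.vstack([f.coordinates[probe_idx] for f in traj.frames])
        outside = np.any((pts < lo) | (pts >= hi), axis=1)
        if np.any(outside):
            if out_of_bounds == "error":
                bad = pts[outside][0]
                raise ValueError(
                    f"probe atom at ({bad[0]:.3f}, {bad[1]:.3f}, {bad[2]:.3f}) "
                    "lies outside the declared grid bounds"
                )
            # expand along the original lattice so existing cells keep
            # their identity
            grow_lo = np.ceil(np.maximum(lo - pts.min(axis=0), 0.0) / spacing)
            grow_hi = np.ceil(np.maximum(pts.max(axis=0) + spacing - hi, 0.0) / spacing)
            lo = lo - grow_lo * spacing
            hi = hi + grow_hi * spacing
    dims = tuple(int(v) for v in np.maximum(np.ceil((hi - lo) / spacing - 1e-12), 1))
    counts = np.zeros(dims, dtype=int)
    for frame in traj.frames:
        rel = np.floor((frame.coordinates[probe_idx] - lo) / spacing).astype(int)
        rel = np.clip(rel, 0, np.array(dims) - 1)  # guards float edge cases only
        occupied = np.unique(rel, axis=0)
        counts[occupied[:, 0], occupied[:, 1], occupied[:, 2]] += 1
    return VoxelGrid(
        origin=lo,
        spacing=spacing,
        dims=dims,
        occupancy=counts / traj.n_frames,
        n_frames=traj.n_frames,
    )


def export_sites(
    grid: VoxelGrid,
    threshold: float = 0.25,
    pdb_path: str | Path | None = None,
    dx_path: str | Path | None = None,
) -> list[tuple[tuple[int, int, int], np.ndarray, float]]:
    """Export hydration sites with occupancy strictly above the threshold.

    Returns ``(cell index, cell center, occupancy)`` records, one
    pseudoatom per qualifying cell. A cell at exactly the threshold is
    excluded (the rule is "higher than"). When paths are given, the sites
    are written as PDB pseudoatoms (occupancy in the B-factor column) and
    the full grid as an OpenDX scalar field.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError("threshold must lie in [0, 1]")
    sites = []
    for idx in np.argwhere(grid.occupancy > threshold):
        cell = tuple(int(v) for v in idx)
        sites.append((cell, grid.cell_center(cell), float(grid.occupancy[cell])))
    sites.sort(key=lambda s: -s[2])
    if pdb_path is not None:
        atoms = [
            AtomRecord(
                atom_index=i, atom_name="O", residue_name="WAT",
                residue_index=i + 1, chain_id="W", element="O", mass=15.999,
            )
            for i in range(len(sites))
        ]
        if atoms:
            top = Topology(atoms)
            coords = np.array([center for (_c, center, _o) in sites])
            bf = np.array([occ for (_c, _ctr, occ) in sites])
            write_structure(pdb_path, top, Frame(time=0.0, coordinates=coords), bfactors=bf)
        else:
            Path(pdb_path).write_text("END\n")
    if dx_path is not None:
        write_dx(dx_path, grid)
    return sites


def write_dx(path: str | Path, grid: VoxelGrid) -> None:
    """Write the grid as an OpenDX scalar field (z-fastest order)."""
    nx, ny, nz = grid.dims
    o = grid.origin
    s = grid.spacing
    lines = [
        f"object 1 class gridpositions counts {nx} {ny} {nz}",
        f"origin {o[0]:.6f} {o[1]:.6f} {o[2]:.6f}",
        f"delta {s:.6f} 0.000000 0.000000",
        f"delta 0.000000 {s:.6f} 0.000000",
        f"delta 0.000000 0.000000 {s:.6f}",
        f"object 2 class gridconnections counts {nx} {ny} {nz}",
        f"object 3 class array type double rank 0 items {nx * ny * nz} data follows",
    ]
    flat = grid.occupancy.ravel(order="C")  # x slowest, z fastest
    for start in range(0, flat.size, 3):
        chunk = flat[start : start + 3]
        lines.append(" ".join(f"{v:.6f}" for v in chunk))
    lines += [
        'attribute "dep" string "positions"',
        'object "occupancy" class field',
        'component "positions" value 1',
        'component "connections" value 2',
        'component "data" value 3',
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_dx(path: str | Path) -> VoxelGrid:
    """Read back an OpenDX scalar field written by :func:`write_dx`."""
    dims = None
    origin = None
    spacing = None
    values: list[float] = []
    reading = False
    for line in Path(path).read_text().splitlines():
        parts = line.split()
        if not parts:
            continue
        if parts[:4] == ["object", "1", "class", "gridpositions"]:
            dims = tuple(int(v) for v in parts[-3:])
        elif parts[0] == "origin":
            origin = np.array([float(v) for v in parts[1:4]])
        elif parts[0] == "delta" and spacing is None:
            spacing = float(parts[1])
        elif parts[0] == "object" and "follows" in parts:
            reading = True
        elif parts[0] in {"attribute", "component", "object"}:
            reading = False
        elif reading:
            values.extend(float(v) for v in parts)
    if dims is None or origin is None or spacing is None:
        raise ValueError(f"{path}: not a grid written by write_dx")
    occ = np.array(values).reshape(dims, order="C")
    # n_frames is not stored in DX; callers needing it keep the VoxelGrid
    return VoxelGrid(origin=origin, spacing=spacing, dims=dims, occupancy=occ, n_frames=1)
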