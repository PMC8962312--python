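"""Per-residue trajectory analysis: contacts and interaction energies.

The recognition pathway of a ligand is summarized by (i) how often each
receptor residue is in contact with the ligand (atom–atom distance within
4.5 Å by default) and (ii) the nonbonded interaction energy — Coulomb plus
Lennard-Jones — between the ligand and each of the most-contacted
residues, frame by frame, rendered as a time/residue heatmap whose color
scale is clipped to the first and third quartile of the energy
distribution.

Energy model (CHARMM conventions): for an atom pair at distance r within
the cutoff,

    E(r) = C·qᵢqⱼ/r + εᵢⱼ[(Rmin,ij/r)¹² − 2(Rmin,ij/r)⁶]

with C = 332.0636 kcal·Å/(mol·e²), εᵢⱼ = √(εᵢεⱼ) and
Rmin,ij = Rmin,i/2 + Rmin,j/2. The energy is hard-truncated at the cutoff
(9.0 Å default): pairs beyond it contribute exactly 0. The minimum-image
convention is applied when a frame carries box lengths.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import require_params, write_structure
from .system_model import Frame, Selection, Topology, Trajectory

__all__ = [
    "COULOMB_CONSTANT",
    "ContactTable",
    "NonbondedParams",
    "EnergyMatrix",
    "EmptyAnalysisError",
    "count_contacts",
    "top_contacted",
    "interaction_energy",
    "energy_heatmap",
    "contact_surface",
]

#: Coulomb constant in kcal·Å/(mol·e²) at dielectric 1.
COULOMB_CONSTANT = 332.0636

ResidueKey = tuple[str, int, str]


class EmptyAnalysisError(ValueError):
    """The analysis found nothing to report (e.g. no contacted residue)."""


def _minimum_image(diff: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is not None:
        diff = diff - box * np.round(diff / box)
    return diff


def _environment_residues(
    topology: Topology, ligand: Selection
) -> tuple[list[ResidueKey], np.ndarray, np.ndarray]:
    """Non-ligand residues; errors if the ligand straddles one of them."""
    lig = ligand.atom_indices
    residues: list[ResidueKey] = []
    env_atoms: list[int] = []
    env_res_id: list[int] = []
    for key, idx in topology.residue_groups.items():
        inside = [i for i in idx if i in lig]
        if inside and len(inside) != len(idx):
            raise ValueError(
                f"ligand selection overlaps residue {key}: it covers "
                f"{len(inside)}/{len(idx)} of its atoms"
            )
        if inside:
            continue
        rid = len(residues)
        residues.append(key)
        env_atoms.extend(idx)
        env_res_id.extend([rid] * len(idx))
    return residues, np.array(env_atoms, dtype=int), np.array(env_res_id, dtype=int)


@dataclass
class ContactTable:
    """Residues × frames matrix of ligand–residue atom-pair contact counts."""

    residues: list[ResidueKey]
    counts: np.ndarray  # (n_residues, n_frames) non-negative ints
    cutoff: float
    times: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def count_contacts(
    traj: Trajectory,
    ligand: Selection,
    cutoff: float = 4.5,
    heavy_atoms_only: bool = False,
) -> ContactTable:
    """Count ligand–residue atom pairs within ``cutoff`` Å, per residue and frame.

    The boundary is inclusive: a pair at exactly the cutoff counts.
    ``heavy_atoms_only`` drops hydrogens from both sides; by default all
    atoms are counted.
    """
    if cutoff <= 0:
        raise ValueError("contact cutoff must be positive")
    top = traj.topology
    ligand.validate(top)
    residues, env_atoms, env_res_id = _environment_residues(top, ligand)
    lig_atoms = ligand.sorted_indices
    if heavy_atoms_only:
        heavy = np.array([top.atoms[i].element.upper() != "H" for i in range(top.n_atoms)])
        lig_atoms = lig_atoms[heavy[lig_atoms]]
        keep = heavy[env_atoms]
        env_atoms, env_res_id = env_atoms[keep], env_res_id[keep]
    counts = np.zeros((len(residues), traj.n_frames), dtype=int)
    cut2 = cutoff * cutoff
    for f, frame in enumerate(traj.frames):
        diff = frame.coordinates[lig_atoms][:, None, :] - frame.coordinates[env_atoms][None, :, :]
        diff = _minimum_image(diff, frame.box_lengths)
        within = (diff * diff).sum(axis=2) <= cut2
        per_env_atom = within.sum(axis=0)
        counts[:, f] = np.bincount(env_res_id, weights=per_env_atom, minlength=len(residues))
    return ContactTable(residues=residues, counts=counts, cutoff=cutoff, times=traj.times)


def top_contacted(table: ContactTable, n: int = 25) -> list[ResidueKey]:
    """The ``n`` most-contacted residues, by total contacts over all frames.

    Descending totals; ties broken by (chain, residue_index) ascending.
    Residues with zero total are excluded; fewer than ``n`` contacted
    residues returns all of them.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    totals = table.totals
    order = sorted(
        (i for i in range(len(table.residues)) if totals[i] > 0),
        key=lambda i: (-int(totals[i]), table.residues[i][0], table.residues[i][1]),
    )
    return [table.residues[i] for i in order[:n]]


@dataclass
class NonbondedParams:
    """Per-atom nonbonded parameters plus the energy constants."""

    charges: np.ndarray       # e
    lj_epsilon: np.ndarray    # kcal/mol
    lj_rmin_half: np.ndarray  # Å
    coulomb_constant: float = COULOMB_CONSTANT
    energy_cutoff: float = 9.0

    @classmethod
    def from_topology(cls, topology: Topology, energy_cutoff: float = 9.0) -> "NonbondedParams":
        return cls(
            charges=np.array([a.charge for a in topology.atoms]),
            lj_epsilon=np.array([a.lj_epsilon for a in topology.atoms]),
            lj_rmin_half=np.array([a.lj_rmin_half for a in topology.atoms]),
            energy_cutoff=energy_cutoff,
        )


def interaction_energy(
    frame: Frame,
    ligand: Selection,
    residue_atoms: Selection,
    params: NonbondedParams,
    topology: Topology | None = None,
) -> float:
    """Coulomb + Lennard-Jones energy (kcal/mol) between two atom groups.

    Pairs beyond ``params.energy_cutoff`` contribute exactly 0; a pair at
    zero distance (overlapping atoms) is an error. When a topology is
    supplied, atoms lacking sidecar parameters raise a
    :class:`~sumdkit.io.ParameterError` naming them.
    """
    i = ligand.sorted_indices
    j = residue_atoms.sorted_indices
    if topology is not None:
        require_params(topology, np.concatenate([i, j]))
    diff = frame.coordinates[i][:, None, :] - frame.coordinates[j][None, :, :]
    diff = _minimum_image(diff, frame.box_lengths)
    r = np.sqrt((diff * diff).sum(axis=2))
    if np.any(r == 0.0):
        ii, jj = np.unravel_index(int(np.argmin(r)), r.shape)
        raise ValueError(f"overlapping atoms {i[ii]} and {j[jj]} (r = 0)")
    within = r <= params.energy_cutoff
    if not np.any(within):
        return 0.0
    qq = np.outer(params.charges[i], params.charges[j])
    eps = np.sqrt(np.outer(params.lj_epsilon[i], params.lj_epsilon[j]))
    rmin = params.lj_rmin_half[i][:, None] + params.lj_rmin_half[j][None, :]
    rw = r[within]
    elec = params.coulomb_constant * qq[within] / rw
    sr6 = (rmin[within] / rw) ** 6
    vdw = eps[within] * (sr6 * sr6 - 2.0 * sr6)
    return float(elec.sum() + vdw.sum())


@dataclass
class EnergyMatrix:
    """Interaction energies for the top contacted residues across frames.

    ``q1``/``q3`` are the stated quantiles of the flattened energy
    distribution; the rendering helper clips the color scale to [q1, q3]
    while the exported table always carries the raw energies.
    """

    residues: list[ResidueKey]
    times: np.ndarray       # ps
    energies: np.ndarray    # (n_residues, n_frames), kcal/mol
    q1: float
    q3: float

    def labels(self) -> list[str]:
        return [f"{name}{idx}" for (_chain, idx, name) in self.residues]

    def to_tsv(self, path: str | Path) -> None:
        header = "residue\t" + "\t".join(f"{t:.3f}" for t in self.times)
        lines = [header]
        for label, row in zip(self.labels(), self.energies):
            lines.append(label + "\t" + "\t".join(f"{e:.6f}" for e in row))
        Path(path).write_text("\n".join(lines) + "\n")

    def plot(self, path: str | Path) -> None:
        """Render the quartile-clipped red–blue heatmap to an image file."""
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        import seaborn as sns

        fig, ax = plt.subplots(
            figsize=(max(6, 0.12 * len(self.times)), max(4, 0.25 * len(self.residues)))
        )
        sns.heatmap(
            self.energies,
            vmin=self.q1,
            vmax=self.q3,
            cmap="RdBu",
            yticklabels=self.labels(),
            xticklabels=False,
            cbar_kws={"label": "interaction energy (kcal/mol)"},
            ax=ax,
        )
        ax.set_xlabel("time (ns)")
        fig.tight_layout()
        fig.savefig(path, dpi=150)
        plt.close(fig)


def energy_heatmap(
    traj: Trajectory,
    ligand: Selection,
    params: NonbondedParams,
    n: int = 25,
    contact_cutoff: float = 4.5,
    frame_stride: int = 1,
    quantile_method: str = "linear",
) -> EnergyMatrix:
    """Per-residue interaction energies for the top-``n`` contacted residues.

    Contacts are counted first (at ``contact_cutoff``); energies are then
    computed for every analyzed frame against each of the top residues.
    q1/q3 use the linear-interpolation quantile convention by default.
    """
    if frame_stride > 1:
        frames = traj.frames[::frame_stride]
        traj = Trajectory(traj.topology, frames)
    table = count_contacts(traj, ligand, cutoff=contact_cutoff)
    top = top_contacted(table, n=n)
    if not top:
        raise EmptyAnalysisError("no residue is in contact with the ligand")
    topol = traj.topology
    energies = np.zeros((len(top), traj.n_frames))
    selections = [
        Selection(label=f"{key[2]}{key[1]}", atom_indices=frozenset(topol.residue_groups[key]))
        for key in top
    ]
    for f, frame in enumerate(traj.frames):
        for r, sel in enumerate(selections):
            energies[r, f] = interaction_energy(frame, ligand, sel, params, topology=topol)
    q1, q3 = np.percentile(energies.ravel(), [25, 75], method=quantile_method)
    return EnergyMatrix(residues=top, times=traj.times, energies=energies, q1=float(q1), q3=float(q3))


def contact_surface(
    traj: Trajectory,
    ligand: Selection,
    out_pdb: str | Path | None = None,
    cutoff: float = 4.5,
) -> dict[ResidueKey, int]:
    """Whole-trajectory contact totals per residue, for surface coloring.

    Totals are the row sums of the contact table. When ``out_pdb`` is
    given, the first frame is written with each atom's B-factor set to its
    residue's total, ready for surface coloring; ligand atoms get their
    own total against the rest of the system (0 here by symmetry of use).
    """
    table = count_contacts(traj, ligand, cutoff=cutoff)
    totals = {key: int(t) for key, t in zip(table.residues, table.totals)}
    if out_pdb is not None:
        top = traj.topology
        bf = np.zeros(top.n_atoms)
        for key, total in totals.items():
            bf[top.residue_groups[key]] = total
        write_structure(out_pdb, top, traj.frames[0], bfactors=bf)
    return totals
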