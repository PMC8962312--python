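"""Contacts, rankings and nonbonded interaction energies."""

import numpy as np
import pytest

from sumdkit import (
    AtomRecord,
    ContactTable,
    EmptyAnalysisError,
    Frame,
    NonbondedParams,
    Selection,
    Topology,
    Trajectory,
    contact_surface,
    count_contacts,
    energy_heatmap,
    interaction_energy,
    top_contacted,
)
from sumdkit.analysis import COULOMB_CONSTANT

from conftest import brute_force_contacts


def _pair_system(r, q1=0.0, q2=0.0, eps=0.2, rmin_half=1.0):
    """One site atom at the origin and one ligand atom at distance r on x."""
    atoms = [
        AtomRecord(0, "C1", "RES", 1, "A", "C", mass=12.0, charge=q1,
                   lj_epsilon=eps, lj_rmin_half=rmin_half),
        AtomRecord(1, "C1", "LIG", 1, "L", "C", mass=12.0, charge=q2,
                   lj_epsilon=eps, lj_rmin_half=rmin_half),
    ]
    top = Topology(atoms)
    frame = Frame(0.0, np.array([[0.0, 0, 0], [r, 0.0, 0.0]]))
    lig = Selection("lig", frozenset({1}))
    res = Selection("res", frozenset({0}))
    return top, frame, lig, res


class TestCountContacts:
    @pytest.mark.parametrize("r, expected", [(4.4, 1), (4.5, 1), (4.6, 0)])
    def test_single_pair_boundary_inclusive(self, r, expected):
        top, frame, lig, _ = _pair_system(r)
        table = count_contacts(Trajectory(top, [frame]), lig, cutoff=4.5)
        assert int(table.counts.sum()) == expected

    def test_boundary_epsilon_excluded(self):
        top, frame, lig, _ = _pair_system(4.5 + 1e-9)
        table = count_contacts(Trajectory(top, [frame]), lig, cutoff=4.5)
        assert int(table.counts.sum()) == 0

    def test_matches_brute_force_double_loop(self, contact_system):
        traj, ligand = contact_system
        table = count_contacts(traj, ligand, cutoff=4.5)
        residues, expected = brute_force_contacts(traj, ligand, 4.5)
        order = {key: i for i, key in enumerate(residues)}
        for i, key in enumerate(table.residues):
            assert np.array_equal(table.counts[i], expected[order[key]]), key

    def test_cutoff_monotonicity(self, contact_system):
        traj, ligand = contact_system
        small = count_contacts(traj, ligand, cutoff=3.0)
        large = count_contacts(traj, ligand, cutoff=6.0)
        assert np.all(large.counts >= small.counts)

    def test_ligand_overlapping_residue_is_an_error(self, contact_system):
        traj, _ = contact_system
        # a selection straddling a protein residue is ambiguous
        bad = Selection("bad", frozenset({0, 30}))
        with pytest.raises(ValueError, match="overlaps"):
            count_contacts(traj, bad, cutoff=4.5)


class TestTopContacted:
    def _table(self, totals_by_key):
        keys = list(totals_by_key)
        counts = np.array([[v] for v in totals_by_key.values()])
        return ContactTable(residues=keys, counts=counts, cutoff=4.5)

    def test_returns_all_when_fewer_than_n(self):
        t = self._table({("A", 1, "RES"): 3, ("A", 2, "RES"): 1, ("A", 3, "RES"): 2})
        assert len(top_contacted(t, n=25)) == 3

    def test_tie_broken_by_chain_then_index(self):
        t = self._table({
            ("A", 12, "RES"): 50, ("A", 7, "RES"): 50,
            ("A", 1, "RES"): 100, ("A", 20, "RES"): 10,
        })
        assert top_contacted(t, n=4) == [
            ("A", 1, "RES"), ("A", 7, "RES"), ("A", 12, "RES"), ("A", 20, "RES"),
        ]

    def test_matches_full_sort_oracle(self):
        rng = np.random.default_rng(5)
        keys = [("A", int(i), "RES") for i in rng.permutation(40)]
        counts = rng.integers(0, 30, size=(40, 6))
        t = ContactTable(residues=keys, counts=counts, cutoff=4.5)
        oracle = sorted(
            (k for k, c in zip(keys, counts) if c.sum() > 0),
            key=lambda k: (-counts[keys.index(k)].sum(), k[0], k[1]),
        )[:25]
        assert top_contacted(t, n=25) == oracle


class TestInteractionEnergy:
    def test_lj_minimum_equals_minus_epsilon(self):
        top, frame, lig, res = _pair_system(2.0, eps=0.2, rmin_half=1.0)
        nb = NonbondedParams.from_topology(top)
        assert interaction_energy(frame, lig, res, nb) == pytest.approx(-0.2, abs=1e-10)

    def test_coulomb_constant_definition(self):
        top, frame, lig, res = _pair_system(1.0, q1=1.0, q2=-1.0, eps=0.0)
        nb = NonbondedParams.from_topology(top)
        assert interaction_energy(frame, lig, res, nb) == pytest.approx(-COULOMB_CONSTANT, abs=1e-10)

    def test_beyond_cutoff_is_exactly_zero(self):
        top, frame, lig, res = _pair_system(9.5, q1=1.0, q2=-1.0, eps=0.3)
        nb = NonbondedParams.from_topology(top)
        assert interaction_energy(frame, lig, res, nb) == 0.0

    def test_symmetry(self, contact_system):
        traj, ligand = contact_system
        nb = NonbondedParams.from_topology(traj.topology)
        res_sel = Selection("r", frozenset(traj.topology.residue_groups[("A", 1, "RES")]))
        frame = traj.frames[0]
        assert interaction_energy(frame, ligand, res_sel, nb) == pytest.approx(
            interaction_energy(frame, res_sel, ligand, nb), abs=1e-10
        )

    def test_overlapping_atoms_error(self):
        top, frame, lig, res = _pair_system(0.0)
        nb = NonbondedParams.from_topology(top)
        with pytest.raises(ValueError, match="overlap"):
            interaction_energy(frame, lig, res, nb)

    def test_pairwise_formula_against_independent_sum(self, contact_system):
        """Matrix route equals a per-pair python loop over the CHARMM formula."""
        traj, ligand = contact_system
        top = traj.topology
        nb = NonbondedParams.from_topology(top)
        key = ("A", 2, "RES")
        res_sel = Selection("r", frozenset(top.residue_groups[key]))
        frame = traj.frames[1]
        expected = 0.0
        for i in sorted(ligand.atom_indices):
            for j in sorted(res_sel.atom_indices):
                r = float(np.linalg.norm(frame.coordinates[i] - frame.coordinates[j]))
                if r > nb.energy_cutoff:
                    continue
                ai, aj = top.atoms[i], top.atoms[j]
                eps = np.sqrt(ai.lj_epsilon * aj.lj_epsilon)
                rmin = ai.lj_rmin_half + aj.lj_rmin_half
                expected += COULOMB_CONSTANT * ai.charge * aj.charge / r
                expected += eps * ((rmin / r) ** 12 - 2 * (rmin / r) ** 6)
        assert interaction_energy(frame, ligand, res_sel, nb) == pytest.approx(expected, abs=1e-10)


class TestEnergyHeatmap:
    def test_quartiles_of_flat_distribution(self):
        from sumdkit.analysis import EnergyMatrix

        m = np.array([[1.0, 2.0], [3.0, 4.0]])
        q1, q3 = np.percentile(m.ravel(), [25, 75], method="linear")
        assert (q1, q3) == (1.75, 3.25)  # the documented convention

    def test_all_zero_matrix_quartiles(self, contact_system):
        traj, ligand = contact_system
        nb = NonbondedParams.from_topology(traj.topology)
        nb.charges[:] = 0.0
        nb.lj_epsilon[:] = 0.0
        matrix = energy_heatmap(traj, ligand, nb, n=5)
        assert matrix.q1 == 0.0 and matrix.q3 == 0.0

    def test_cells_match_isolated_recomputation(self, contact_system):
        traj, ligand = contact_system
        top = traj.topology
        nb = NonbondedParams.from_topology(top)
        matrix = energy_heatmap(traj, ligand, nb, n=25)
        assert matrix.q1 <= matrix.q3
        for r, key in enumerate(matrix.residues[:3]):
            sel = Selection("r", frozenset(top.residue_groups[key]))
            for f in range(traj.n_frames):
                single = interaction_energy(traj.frames[f], ligand, sel, nb)
                assert matrix.energies[r, f] == pytest.approx(single, abs=1e-12)

    def test_no_contacts_raises_empty_analysis(self, contact_system):
        traj, ligand = contact_system
        far = [Frame(f.time, f.coordinates.copy()) for f in traj.frames]
        for f in far:
            f.coordinates[sorted(ligand.atom_indices)] += 500.0
        nb = NonbondedParams.from_topology(traj.topology)
        with pytest.raises(EmptyAnalysisError):
            energy_heatmap(Trajectory(traj.topology, far), ligand, nb)

    def test_tsv_export(self, contact_system, tmp_path):
        traj, ligand = contact_system
        nb = NonbondedParams.from_topology(traj.topology)
        matrix = energy_heatmap(traj, ligand, nb, n=10)
        out = tmp_path / "heat.tsv"
        matrix.to_tsv(out)
        lines = out.read_text().splitlines()
        assert len(lines) == len(matrix.residues) + 1
        assert lines[0].startswith("residue\t")


class TestContactSurface:
    def test_totals_are_column_sums(self, contact_system):
        traj, ligand = contact_system
        table = count_contacts(traj, ligand, cutoff=4.5)
        totals = contact_surface(traj, ligand)
        for key, row in zip(table.residues, table.counts):
            assert totals[key] == row.sum()

    def test_uncontacted_residue_total_zero(self):
        top, frame, lig, _ = _pair_system(20.0)
        totals = contact_surface(Trajectory(top, [frame]), lig)
        assert totals[("A", 1, "RES")] == 0

    def test_pdb_round_trip_recovers_totals(self, contact_system, tmp_path):
        from sumdkit.io import read_pdb_bfactors

        traj, ligand = contact_system
        out = tmp_path / "contacts.pdb"
        totals = contact_surface(traj, ligand, out_pdb=out)
        bf = read_pdb_bfactors(out)
        top = traj.topology
        for key, total in totals.items():
            for i in top.residue_groups[key]:
                assert bf[i] == pytest.approx(total, abs=5e-3)
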