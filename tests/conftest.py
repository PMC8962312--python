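import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from sumdkit.fixtures import make_contact_lattice, make_toy_funnel

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def funnel_system(tmp_path_factory):
    """One toy funnel system, written to disk and read back once per session."""
    return make_toy_funnel(seed=7, out_dir=tmp_path_factory.mktemp("funnel"))


@pytest.fixture(scope="session")
def contact_system(tmp_path_factory):
    """Random ligand/receptor point clouds for contact & energy oracles."""
    return make_contact_lattice(seed=11, out_dir=tmp_path_factory.mktemp("lattice"))


def brute_force_contacts(traj, ligand, cutoff):
    """O(N·M) double-loop contact counts: the oracle for count_contacts."""
    top = traj.topology
    lig = sorted(ligand.atom_indices)
    residues = [key for key, idx in top.residue_groups.items()
                if not set(idx) & ligand.atom_indices]
    counts = np.zeros((len(residues), traj.n_frames), dtype=int)
    for r, key in enumerate(residues):
        for f, frame in enumerate(traj.frames):
            n = 0
            for i in lig:
                for j in top.residue_groups[key]:
                    d = np.linalg.norm(frame.coordinates[i] - frame.coordinates[j])
                    if d <= cutoff:
                        n += 1
            counts[r, f] = n
    return residues, counts
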