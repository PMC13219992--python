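import numpy as np
import pytest

import posestab as ps


@pytest.fixture(scope="session")
def toy_config():
    return ps.GeneratorConfig(seed=3)


@pytest.fixture(scope="session")
def toy_complex(toy_config):
    return ps.make_toy_complex(toy_config)


@pytest.fixture(scope="session")
def toy_selections(toy_complex):
    topo = toy_complex.topology
    return (
        ps.select_atoms(topo, "protein and heavy"),
        ps.select_atoms(topo, "ligand and heavy"),
    )


@pytest.fixture(scope="session")
def toy_contacts(toy_complex, toy_selections):
    psel, lsel = toy_selections
    return ps.identify_native_contacts(toy_complex, psel, lsel)


def make_pair_topology(n_protein=1, n_ligand=1):
    """Minimal topology: n_protein CA atoms (chain A) + n_ligand LIG atoms."""
    n = n_protein + n_ligand
    return ps.Topology(
        names=np.array(
            [f"CA" for _ in range(n_protein)] + [f"C{j+1}" for j in range(n_ligand)],
            dtype="U6",
        ),
        elements=np.full(n, "C", dtype="U2"),
        res_names=np.array(["ALA"] * n_protein + ["LIG"] * n_ligand, dtype="U5"),
        res_seqs=np.array(list(range(1, n_protein + 1)) + [1] * n_ligand, dtype=np.intp),
        ins_codes=np.full(n, "", dtype="U1"),
        chain_ids=np.array(["A"] * n_protein + ["L"] * n_ligand, dtype="U4"),
        is_ligand=np.array([False] * n_protein + [True] * n_ligand, dtype=bool),
        is_hydrogen=np.zeros(n, dtype=bool),
    )


def random_system(rng, max_atoms=30, max_frames=20):
    """A random protein/ligand point cloud + trajectory for oracle tests."""
    n_protein = int(rng.integers(3, max_atoms * 2 // 3))
    n_ligand = int(rng.integers(2, max(3, max_atoms - n_protein)))
    topo = make_pair_topology(n_protein, n_ligand)
    n = n_protein + n_ligand
    ref = ps.Structure(topo, rng.uniform(0.0, 6.0, (n, 3)))
    n_frames = int(rng.integers(2, max_frames + 1))
    coords = ref.coords[None, :, :] + rng.normal(0.0, 1.0, (n_frames, n, 3))
    traj = ps.Trajectory(
        topo,
        coords,
        replica_ids=np.zeros(n_frames, dtype=int),
        times=np.arange(n_frames, dtype=float),
    )
    return topo, ref, traj
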