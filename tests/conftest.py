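import numpy as np
import pytest

from glycontact.io import Topology, Trajectory


def random_topology(rng, n_atoms, with_params=False):
    """A flat topology of ``n_atoms`` single-atom residues, half peptide / half glycan."""
    elements = rng.choice(["C", "N", "O", "H"], size=n_atoms,
                          p=[0.5, 0.2, 0.2, 0.1])
    roles = ["peptide" if i < n_atoms // 2 else "glycan"
             for i in range(n_atoms)]
    chains = ["A" if r == "peptide" else "B" for r in roles]
    top = Topology(
        atom_names=[f"X{i}" for i in range(n_atoms)],
        elements=list(elements),
        atom_residue=list(range(n_atoms)),
        res_names=["RES"] * n_atoms,
        res_numbers=list(range(1, n_atoms + 1)),
        res_chains=chains,
        res_roles=roles,
    )
    if with_params:
        top.charges = rng.uniform(-0.5, 0.5, n_atoms)
        top.lj_epsilon = rng.uniform(0.01, 0.3, n_atoms)
        top.lj_rmin_half = rng.uniform(1.2, 2.2, n_atoms)
    return top


def random_trajectory(rng, n_atoms=20, n_frames=3, scale=10.0,
                      with_params=False):
    top = random_topology(rng, n_atoms, with_params=with_params)
    coords = rng.uniform(-scale, scale, size=(n_frames, n_atoms, 3))
    return Trajectory(top, coords)


@pytest.fixture(scope="session")
def coupled_run():
    """Small synthetic run with binding-helix coupling, shared across tests."""
    from glycontact.synthetic import SyntheticSpec, generate

    spec = SyntheticSpec(n_frames=120, n_glycans=6, seed=42,
                         p_on=0.2, p_off=0.2)
    traj, truth = generate(spec)
    return spec, traj, truth


def mdtraj_dssp(traj, tmp_path):
    """Reference DSSP labels from mdtraj on the same structure (oracle)."""
    import mdtraj as md

    from glycontact.io import write_pdb_models

    path = tmp_path / "ref.pdb"
    write_pdb_models(traj, path)
    codes = md.compute_dssp(md.load(str(path)), simplified=False)
    return np.char.replace(codes.astype("U1"), " ", "C")
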