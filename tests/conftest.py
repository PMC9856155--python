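import numpy as np
import pandas as pd
import pytest

from codyn import synthetic as syn
from codyn.trajectory import Trajectory


@pytest.fixture(scope="session")
def toy_dimer():
    """Small two-chain C-alpha scaffold (20 residues per chain)."""
    return syn.make_toy_structure(20, 2, seed=7)


@pytest.fixture(scope="session")
def toy_monomer():
    return syn.make_toy_structure(20, 1, seed=7)


@pytest.fixture()
def mixed_atom_traj():
    """3 frames over a 4-residue chain with N, CA and CB atoms per residue."""
    records = []
    for resid in range(1, 5):
        for name, element in [("N", "N"), ("CA", "C"), ("CB", "C")]:
            records.append(("A", resid, name, element))
    atoms = pd.DataFrame(records, columns=["chain_id", "resid", "name", "element"])
    rng = np.random.default_rng(0)
    coords = rng.uniform(0, 30, size=(3, len(atoms), 3))
    return Trajectory(atoms=atoms, coords=coords, system=np.array(["x"] * 3, dtype=object))


@pytest.fixture(scope="session")
def noiseless_titration():
    truth = syn.make_titration_truth(
        n_residues=5, kd=0.6, seed=11, protein=0.5, n_silent=5, noise_sd=0.0
    )
    return truth, syn.simulate_titration_set(truth, seed=12)
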