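import numpy as np
import pytest

from pmhcdyn import (
    Ensemble,
    SyntheticSpec,
    generate_ensemble,
    toy_complex_topology,
)

# Minimal single-model PDB: one aspartate (charged sidechain) for catalog tests.
ASP_PDB = """\
ATOM      1  N   ASP A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ASP A   1      12.560   6.234  -6.504  1.00  0.00           C
ATOM      3  C   ASP A   1      13.104   7.634  -6.504  1.00  0.00           C
ATOM      4  O   ASP A   1      12.504   8.634  -6.904  1.00  0.00           O
ATOM      5  CB  ASP A   1      13.104   5.434  -5.304  1.00  0.00           C
ATOM      6  CG  ASP A   1      14.604   5.334  -5.304  1.00  0.00           C
ATOM      7  OD1 ASP A   1      15.204   4.234  -5.304  1.00  0.00           O
ATOM      8  OD2 ASP A   1      15.304   6.434  -5.304  1.00  0.00           O
END
"""

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.500   0.000   0.000  1.00  0.00           C
ATOM      3  CB  ALA A   1       2.000   1.400   0.000  1.00  0.00           C
END
"""


@pytest.fixture
def asp_pdb(tmp_path):
    path = tmp_path / "asp.pdb"
    path.write_text(ASP_PDB)
    return path


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture(scope="session")
def toy_system():
    """Small fully-charged three-chain complex shared across tests."""
    topology, mean = toy_complex_topology(
        n_residues_presenter=8,
        n_residues_peptide=3,
        n_residues_receptor=6,
        charged_fraction=0.8,
        seed=11,
    )
    return topology, mean


@pytest.fixture(scope="session")
def harmonic_ensemble(toy_system):
    """200-frame harmonic ensemble, uniform per-coordinate sigma 0.2 Å."""
    topology, mean = toy_system
    spec = SyntheticSpec(
        topology=topology,
        mean_coordinates=mean,
        n_frames=200,
        noise_sigma=0.2,
        seed=17,
    )
    return generate_ensemble(spec)


def random_ensemble(n_atoms: int, n_frames: int, seed: int) -> Ensemble:
    """Unstructured random ensemble of carbon-like atoms for geometry oracles."""
    from pmhcdyn.io_model import AtomRecord, Topology

    rng = np.random.default_rng(seed)
    atoms = [
        AtomRecord(
            serial=i + 1,
            atom_name=f"C{i}",
            residue_name="ALA",
            residue_id=i + 1,
            chain_id="A",
            element="C",
            mass=float(rng.uniform(1.0, 20.0)),
        )
        for i in range(n_atoms)
    ]
    coords = rng.normal(scale=4.0, size=(n_frames, n_atoms, 3))
    return Ensemble(topology=Topology(atoms), coordinates=coords)
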