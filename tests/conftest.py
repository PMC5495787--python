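import warnings

import numpy as np
import pytest

from hrpfsasa.simulate import SimulationConfig, simulate_experiment
from hrpfsasa.structure import AtomRecord, StructureModel


def make_atom(serial=1, name="CB", element="C", resname="ALA", chain="A",
              resseq=1, coords=(0.0, 0.0, 0.0), radius=1.87):
    return AtomRecord(serial, name, element, resname, chain, resseq,
                      np.asarray(coords, dtype=float), radius)


@pytest.fixture
def atom_factory():
    return make_atom


@pytest.fixture(scope="session")
def zero_noise_experiment():
    """Seeded experiment with no replicate noise and dispersed context
    factors: the exact-cancellation regime."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_experiment(
            SimulationConfig(seed=42, n_residues=50, noise_sd=0.0)
        )


@pytest.fixture(scope="session")
def default_experiment():
    """Seeded experiment at the default study conditions (five doses,
    triplicate, replicate noise)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return simulate_experiment(SimulationConfig(seed=3, n_residues=50))


@pytest.fixture
def simple_model():
    """Three spread-out alanine-like residues (no mutual occlusion)."""
    atoms = []
    serial = 1
    for i, x in enumerate((0.0, 20.0, 40.0), start=1):
        for name, dx in (("N", -1.2), ("CA", 0.0), ("C", 1.2), ("O", 2.0), ("CB", 0.6)):
            atoms.append(
                make_atom(serial, name, name[0], "ALA", "A", i, (x + dx, 0.0, 1.5 if name == "CB" else 0.0))
            )
            serial += 1
    return StructureModel("simple", atoms)
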