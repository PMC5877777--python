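import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for `oracles`

from allonet.structure_io import Residue, Structure
from allonet.synthetic import PlantedCorrelationSpec, make_helical_bundle


@pytest.fixture(scope="session")
def bundle30() -> Structure:
    """3-helix bundle, 30 residues, the standard structural fixture."""
    return make_helical_bundle(3, 10, seed=0)


@pytest.fixture(scope="session")
def single_helix10() -> Structure:
    return make_helical_bundle(1, 10, seed=1)


@pytest.fixture()
def tiny_structure() -> Structure:
    """Hand-built 3-residue structure incl. a glycine without Cβ."""
    residues = [
        Residue("A", 1, "ALA"),
        Residue("A", 2, "GLY"),
        Residue("A", 3, "LEU"),
    ]
    atoms = [
        {"CA": np.array([0.0, 0.0, 0.0]), "CB": np.array([1.0, 0.5, 0.0])},
        {"CA": np.array([3.8, 0.0, 0.0])},
        {"CA": np.array([7.6, 0.0, 0.0]), "CB": np.array([8.3, 1.2, 0.1])},
    ]
    return Structure(residues, atoms)


@pytest.fixture(scope="session")
def planted_spec10() -> PlantedCorrelationSpec:
    """Block A={1..5}, B={6..10}, rho=0.8 over 10 residues."""
    return PlantedCorrelationSpec(
        10, blocks=[(frozenset(range(1, 6)), frozenset(range(6, 11)), 0.8)]
    )
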