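import numpy as np
import pytest

from coevomech import (
    CaStructure,
    InteractionSpec,
    ToySpec,
    build_contacts,
    make_structure,
)


@pytest.fixture(scope="session")
def spec():
    """Default interaction spec (alpha=82, cuts=169, MJ intra / KE inter)."""
    return InteractionSpec()


@pytest.fixture(scope="session")
def helix10(spec):
    s, _ = make_structure(ToySpec(topology="helix", n_residues=10, seed=0))
    return s, build_contacts(s, spec.cutoff_sq)


@pytest.fixture(scope="session")
def globule20(spec):
    s, _ = make_structure(
        ToySpec(topology="globule", n_residues=20, seed=5, sequence_model="random"))
    return s, build_contacts(s, spec.cutoff_sq)


@pytest.fixture
def two_bead():
    return CaStructure(
        coords=np.array([[0.0, 0.0, 0.0], [3.8, 0.0, 0.0]]),
        chain_ids=("A", "A"),
        residue_names=("A", "A"),
        residue_numbers=(1, 2),
    )
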