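import numpy as np
import pytest

from knobsocket.pipeline import PipelineParams, analyze_structure
from knobsocket.structure_io import AtomRecord, Residue, Structure
from knobsocket.synthetic_data import (
    HelixSpec,
    groove_spec,
    make_ideal_helix,
    make_packing_fixture,
    two_helix_spec,
)


def make_residue(chain_id, seq_num, name3, ordinal, atom_coords):
    """Fabricate a residue from {atom_name: coord} for unit tests."""
    res = Residue(chain_id=chain_id, seq_num=seq_num, icode="", name3=name3,
                  ordinal=ordinal)
    for name, coord in atom_coords.items():
        res.atoms[name] = AtomRecord(
            name=name, element=name[0], coord=np.asarray(coord, dtype=float),
            residue=res,
        )
    return res


def structure_from_points(points, source_id="cloud"):
    """One single-atom (CA) glycine residue per point; for contact oracles."""
    residues = [
        make_residue("A", i + 1, "GLY", i, {"CA": p}) for i, p in enumerate(points)
    ]
    return Structure(source_id=source_id, model_index=1, chains={"A": residues})


@pytest.fixture(scope="session")
def params():
    return PipelineParams()


@pytest.fixture(scope="session")
def helix12():
    return make_ideal_helix(HelixSpec(sequence="A" * 12))


@pytest.fixture(scope="session")
def extended_chain():
    # beta-strand-like rise/twist: no i -> i+4 hydrogen bonds
    return make_ideal_helix(HelixSpec(sequence="A" * 12, rise=3.4, twist=170.0))


@pytest.fixture(scope="session")
def two_helix():
    return make_packing_fixture(two_helix_spec())


@pytest.fixture(scope="session")
def groove():
    return make_packing_fixture(groove_spec())


@pytest.fixture(scope="session")
def two_helix_analysis(two_helix):
    return analyze_structure(two_helix[0])


@pytest.fixture(scope="session")
def groove_analysis(groove):
    return analyze_structure(groove[0])


def random_rigid_transform(rng):
    # QR of a random matrix -> uniform-ish rotation; fix det = +1
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    translation = rng.uniform(-30, 30, size=3)
    return q, translation
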