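import numpy as np
import pytest

from disteval.geometry import DistanceMap, ProteinRecord, true_distance_map
from disteval.synthetic import SyntheticSpec, make_structure


@pytest.fixture(scope="session")
def chain60():
    """A 60-residue synthetic chain plus its PDB text (session-cached)."""
    rec, pdb_text = make_structure(SyntheticSpec(n_residues=60, seed=7))
    return rec, pdb_text


@pytest.fixture(scope="session")
def true60(chain60):
    rec, _ = chain60
    return true_distance_map(rec)


@pytest.fixture
def square_record():
    """Four residues on a unit-ish square: hand-checkable distances."""
    coords = np.array(
        [[0.0, 0.0, 0.0], [3.0, 4.0, 0.0], [6.0, 0.0, 0.0], [3.0, -4.0, 0.0]]
    )
    return ProteinRecord("ACDE", coords, np.ones(4, dtype=bool))


def make_map(values, mask=None):
    return DistanceMap(np.asarray(values, dtype=float), mask)
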