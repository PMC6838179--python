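import numpy as np
import pytest

from vsp.data import VariantDataset, VariantObservation, from_arrays
from vsp.simulate import make_variant_fixture
from vsp.variogram import VariogramModel


def make_dataset(points, protein_length=10):
    """Observations from (position, y, z) triples; x = position / length."""
    obs = [
        VariantObservation(f"P{p}", p, p / protein_length, float(y), float(z))
        for p, y, z in points
    ]
    return VariantDataset(obs, protein_length)


@pytest.fixture
def four_point_line():
    """Four collinear points, alternating response: the hand-enumerable case."""
    return make_dataset([(1, 0.0, 0.0), (2, 0.0, 1.0), (3, 0.0, 0.0), (4, 0.0, 1.0)])


@pytest.fixture
def spherical_model():
    return VariogramModel("spherical", 0.01, 0.04, 0.19)


@pytest.fixture
def fixture_pair():
    return make_variant_fixture(seed=0)


@pytest.fixture
def random_dataset():
    rng = np.random.default_rng(42)
    n = 30
    x = rng.uniform(0.05, 1.0, n)
    y = rng.uniform(0.0, 1.0, n)
    z = rng.normal(0.5, 0.2, n)
    return from_arrays(x, y, z)


def make_pdb(residue_b: dict[int, float], atoms_per_residue: int = 1) -> str:
    """Minimal but column-correct PDB text with given per-residue B-factors."""
    lines = []
    serial = 1
    for res, b in residue_b.items():
        for a in range(atoms_per_residue):
            name = " CA " if a == 0 else " CB "
            lines.append(
                f"ATOM  {serial:5d} {name} ALA A{res:4d}    "
                f"{1.0 * res:8.3f}{2.0:8.3f}{3.0:8.3f}{1.00:6.2f}{b:6.2f}"
                f"           C"
            )
            serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"
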