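import numpy as np
import pytest

from af2conf.model import AF2Model
from af2conf.synth import ModelSpec, synth_model

MINIMAL_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 90.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 90.00           C
ATOM      3  C   ALA A   1       2.000   1.400   0.000  1.00 90.00           C
ATOM      4  N   GLY A   2       3.300   1.500   0.000  1.00 45.20           N
ATOM      5  CA  GLY A   2       4.200   2.600   0.000  1.00 45.20           C
ATOM      6  C   GLY A   2       5.600   2.100   0.300  1.00 45.20           C
ATOM      7  N   SER A   3       6.500   3.000   0.600  1.00 70.00           N
ATOM      8  CA  SER A   3       7.900   2.700   0.900  1.00 70.00           C
ATOM      9  C   SER A   3       8.800   3.900   1.100  1.00 70.00           C
END
"""


@pytest.fixture
def minimal_pdb(tmp_path):
    """Three-residue PDB text with Cα B-factors 90.0 / 45.2 / 70.0."""
    path = tmp_path / "minimal.pdb"
    path.write_text(MINIMAL_PDB)
    return path


@pytest.fixture
def helix_model():
    """30-residue ideal helix, confident (pLDDT ~ 95), ordered."""
    model, _ = synth_model(ModelSpec.from_tuples([("helix", 30, 95, 2, False)], seed=1))
    return model


@pytest.fixture
def mixed_model():
    """Confident helix + disordered coil with ground-truth labels."""
    spec = ModelSpec.from_tuples(
        [("helix", 50, 92, 3, False), ("coil", 40, 40, 8, True)], seed=7)
    return synth_model(spec)


def constant_model(n: int, plddt: float, chain: str = "A") -> AF2Model:
    """Straight-line Cα trace with constant pLDDT (geometry irrelevant)."""
    return AF2Model(
        chain_ids=[chain] * n,
        numbers=np.arange(1, n + 1),
        aa=["A"] * n,
        ca=np.column_stack([3.8 * np.arange(n), np.zeros(n), np.zeros(n)]),
        plddt=np.full(n, float(plddt)),
    )


def model_with_plddt(plddt) -> AF2Model:
    plddt = np.asarray(plddt, dtype=float)
    m = constant_model(len(plddt), 50.0)
    return m.with_plddt(plddt)


def random_rigid_motion(rng):
    """Uniform random rotation (QR with sign fix) plus a random translation."""
    q, r = np.linalg.qr(rng.normal(size=(3, 3)))
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.normal(scale=20.0, size=3)
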