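import numpy as np
import pytest

from saxsensemble.model_io import ProteinModel, solvent_displaced_electrons
from saxsensemble.synthetic import make_flexible_model

TINY_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 91.50           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 91.50           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 91.50           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 91.50           O
ATOM      5  CB  ALA A   1       1.988  -0.773  -1.199  1.00 91.50           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 55.25           N
ATOM      7  CA  GLY A   2       3.988   2.831   0.000  1.00 55.25           C
ATOM      8  C   GLY A   2       5.504   2.705   0.000  1.00 55.25           C
ATOM      9  O   GLY A   2       6.030   1.593   0.000  1.00 55.25           O
ATOM     10  N   SER A   3       6.235   3.812   0.000  1.00 33.00           N
ATOM     11  CA  SER A   3       7.689   3.801   0.000  1.00 33.00           C
ATOM     12  C   SER A   3       8.236   5.222   0.000  1.00 33.00           C
ATOM     13  O   SER A   3       7.479   6.193   0.000  1.00 33.00           O
ATOM     14  CB  SER A   3       8.232   3.037  -1.207  1.00 33.00           C
ATOM     15  OG  SER A   3       7.827   1.680  -1.152  1.00 33.00           O
TER
END
"""


@pytest.fixture
def tiny_pdb(tmp_path):
    path = tmp_path / "tiny.pdb"
    path.write_text(TINY_PDB)
    return path


def build_point_model(coords, b=None, radius=1.9, confidence=None):
    """Bare pseudo-atomic model from coordinates, factors pre-assigned."""
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    n = len(coords)
    m = ProteinModel(
        coords=coords,
        elements=np.array(["C"] * n, dtype=object),
        atom_names=np.array(["CA"] * n, dtype=object),
        residue_index=np.arange(1, n + 1),
        residue_names=np.array(["GLY"] * n, dtype=object),
        confidence=None if confidence is None else np.asarray(confidence, float),
    )
    m.b = np.full(n, 30.0) if b is None else np.asarray(b, dtype=float)
    m.radius = np.full(n, radius)
    m.b0 = solvent_displaced_electrons(m.radius)
    return m


def random_cloud(rng, n=50, box=30.0, b_range=(10.0, 60.0)):
    coords = rng.uniform(0, box, (n, 3))
    b = rng.uniform(*b_range, n)
    return build_point_model(coords, b=b)


@pytest.fixture
def two_domain_model():
    return make_flexible_model(n_domains=2, domain_radius=12.0,
                               linker_length=12, seed=42)


@pytest.fixture
def sphere_profile():
    """Noise-free intensity of a uniform sphere, D = 100 A, 0.2% nominal sigma."""
    R = 50.0
    q = np.linspace(0.005, 0.25, 300)
    x = q * R
    form = 3 * (np.sin(x) - x * np.cos(x)) / x**3
    intensity = 1.0e6 * form**2
    sigma = 0.002 * intensity + 2e-5 * intensity[0]
    from saxsensemble.scattering import IntensityProfile
    return IntensityProfile(q_grid=q, intensity=intensity, sigma=sigma,
                            label="sphere D=100")


def sphere_pr_shape(r, diameter):
    """Closed-form P(r) shape of a uniform sphere (unnormalized)."""
    x = np.clip(r / diameter, 0, 1)
    p = r**2 * (1 - 1.5 * x + 0.5 * x**3)
    p[r > diameter] = 0.0
    return p
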