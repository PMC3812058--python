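"""Shared fixtures and independent oracles for the test suite."""

from itertools import permutations

import numpy as np
import pytest

from pocketspace import synthetic_data as sd
from pocketspace.pocket_align import align_pockets


def random_rotation(rng: np.random.Generator) -> np.ndarray:
    """Uniform random proper rotation from a unit quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def quaternion_rmsd(A: np.ndarray, B: np.ndarray) -> float:
    """Optimal superposition RMSD by Horn's quaternion eigenvalue method.

    Independent of the SVD-based implementation under test.
    """
    A0 = A - A.mean(axis=0)
    B0 = B - B.mean(axis=0)
    S = B0.T @ A0
    Sxx, Sxy, Sxz = S[0]
    Syx, Syy, Syz = S[1]
    Szx, Szy, Szz = S[2]
    K = np.array(
        [
            [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
            [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
            [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
            [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz],
        ]
    )
    lam = float(np.linalg.eigvalsh(K)[-1])
    e = (A0 * A0).sum() + (B0 * B0).sum() - 2.0 * lam
    return float(np.sqrt(max(e, 0.0) / len(A)))


def brute_force_assignment(cost: np.ndarray) -> float:
    """Exhaustive minimum assignment cost for small square matrices."""
    n = cost.shape[0]
    perms = np.array(list(permutations(range(n))))
    return float(cost[np.arange(n), perms].sum(axis=1).min())


@pytest.fixture(scope="session")
def warm_aligner():
    """Compile the numba kernels once so timing assertions are fair."""
    p = sd.make_pocket(L=12, seed=0)
    align_pockets(p, p)
    return True


@pytest.fixture(scope="session")
def null_model_40():
    """Small Gumbel null model for pockets of length ~40 (shared across tests)."""
    from pocketspace.pipeline import calibrate_null_model

    model, samples = calibrate_null_model(n_pairs=250, lengths=(35, 45), seed=9)
    return model, samples


# --- hand-written PDB fixtures -------------------------------------------

PDB_MINIMAL = """\
HEADER    TRANSFERASE                             22-MAY-12   1ABC
REMARK   2 RESOLUTION.    1.80 ANGSTROMS.
ATOM      1  N   ALA A   1       0.000   1.400   0.000  1.00  0.00           N
ATOM      2  CA  ALA A   1       1.458   1.400   0.000  1.00  0.00           C
ATOM      3  C   ALA A   1       2.000   1.400   1.420  1.00  0.00           C
ATOM      4  O   ALA A   1       1.300   1.400   2.430  1.00  0.00           O
ATOM      5  CB  ALA A   1       2.000   0.200  -0.800  1.00  0.00           C
ATOM      6  N   ALA A   2       3.300   1.500   1.540  1.00  0.00           N
ATOM      7  CA  ALA A   2       3.980   1.600   2.830  1.00  0.00           C
ATOM      8  C   ALA A   2       5.470   1.700   2.610  1.00  0.00           C
ATOM      9  O   ALA A   2       5.950   1.800   1.480  1.00  0.00           O
ATOM     10  CB  ALA A   2       3.600   2.800   3.700  1.00  0.00           C
ATOM     11  N   ALA A   3       6.230   1.660   3.690  1.00  0.00           N
ATOM     12  CA  ALA A   3       7.680   1.740   3.610  1.00  0.00           C
ATOM     13  C   ALA A   3       8.300   1.800   5.000  1.00  0.00           C
ATOM     14  O   ALA A   3       7.680   1.700   6.050  1.00  0.00           O
ATOM     15  CB  ALA A   3       8.200   0.520   2.850  1.00  0.00           C
HETATM   16  C1  XYZ A 101       4.000   4.500   2.000  1.00  0.00           C
HETATM   17  C2  XYZ A 101       4.700   5.100   3.100  1.00  0.00           C
HETATM   18  C3  XYZ A 101       5.400   5.700   4.200  1.00  0.00           C
HETATM   19  C4  XYZ A 101       6.100   6.300   5.300  1.00  0.00           C
HETATM   20  O1  XYZ A 101       3.300   5.200   1.200  1.00  0.00           O
HETATM   21  O2  XYZ A 101       4.100   6.000   0.500  1.00  0.00           O
HETATM   22  N1  XYZ A 101       5.000   6.700   1.000  1.00  0.00           N
HETATM   23  C5  XYZ A 101       5.900   7.300   1.900  1.00  0.00           C
HETATM   24  C6  XYZ A 101       6.800   7.900   2.800  1.00  0.00           C
HETATM   25  C7  XYZ A 101       7.700   8.500   3.700  1.00  0.00           C
HETATM   26  O3  XYZ A 101       8.600   9.100   4.600  1.00  0.00           O
HETATM   27  C8  XYZ A 101       9.500   9.700   5.500  1.00  0.00           C
HETATM   28  O   HOH A 201      20.000  20.000  20.000  1.00  0.00           O
END
"""

PDB_WITH_HYDROGENS = PDB_MINIMAL.replace(
    "END\n",
    "ATOM     29  H   ALA A   1       0.500   2.000   0.500  1.00  0.00           H\n"
    "HETATM   30  H1  XYZ A 101       4.200   4.100   2.400  1.00  0.00           H\n"
    "END\n",
)

PDB_ALTLOC = """\
HEADER    HYDROLASE                               10-JAN-05   2DEF
ATOM      1  CA AALA A   1       0.000   0.000   0.000  0.60  0.00           C
ATOM      2  CA BALA A   1       0.500   0.000   0.000  0.40  0.00           C
ATOM      3  CA  GLY A   2       3.800   0.000   0.000  1.00  0.00           C
ATOM      4  CA  VAL A   3       7.600   0.000   0.000  1.00  0.00           C
END
"""
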