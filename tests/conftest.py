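"""Shared fixtures: hand-written format snippets and small synthetic data."""

import numpy as np
import pytest

from tmstruct.synthfix import make_learnable_dataset

# Hand-placed per the fixed-column PDB standard: three residues on chain A
# with CA z-coordinates -20, 0, +20 and B-factors 10.0 / 12.5 / 15.0.
PDB_THREE_RESIDUES = """\
REMARK   2 RESOLUTION.    2.00 ANGSTROMS.
ATOM      1  N   MET A   1       0.000   0.000 -21.000  1.00 10.00           N
ATOM      2  CA  MET A   1       1.500   0.000 -20.000  1.00 10.00           C
ATOM      3  C   MET A   1       3.000   0.500 -19.500  1.00 10.00           C
ATOM      4  N   ALA A   2       3.500   1.000  -1.000  1.00 12.50           N
ATOM      5  CA  ALA A   2       5.000   1.500   0.000  1.00 12.50           C
ATOM      6  C   ALA A   2       6.500   1.000   0.500  1.00 12.50           C
ATOM      7  N   GLY A   3       7.000   0.500  19.000  1.00 15.00           N
ATOM      8  CA  GLY A   3       8.500   0.000  20.000  1.00 15.00           C
ATOM      9  C   GLY A   3      10.000   0.500  20.500  1.00 15.00           C
END
"""


def dssp_row(num, chain, aa, ss, acc):
    """Build one classic-DSSP data row by explicit column placement."""
    line = [" "] * 46
    line[0:5] = f"{num:>5}"
    line[5:10] = f"{num:>5}"
    line[11] = chain
    line[13] = aa
    line[16] = ss
    line[34:38] = f"{acc:>4}"
    return "".join(line)


def dssp_text(rows):
    header = "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
    return "\n".join(["== DSSP ==", header] + rows) + "\n"


def dihedral_oracle(p0, p1, p2, p3):
    """Independent dihedral: angle between plane normals, sign from the
    triple product with the central bond."""
    p0, p1, p2, p3 = (np.asarray(p, float) for p in (p0, p1, p2, p3))
    n1 = np.cross(p1 - p0, p2 - p1)
    n2 = np.cross(p2 - p1, p3 - p2)
    cosang = np.dot(n1, n2) / (np.linalg.norm(n1) * np.linalg.norm(n2))
    ang = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    if np.dot(np.cross(n1, n2), p2 - p1) < 0:
        ang = -ang
    return 180.0 if ang == -180.0 else ang


@pytest.fixture(scope="session")
def small_dataset():
    """12 synthetic chains passing all quality filters."""
    return make_learnable_dataset(12, seed=42)
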