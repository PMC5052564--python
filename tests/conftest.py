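"""Shared fixtures: hand-written format fixtures and small synthetic models."""

from __future__ import annotations

import numpy as np
import pytest

from glycostruct import build_ideal_structure, synth_pssm

TWO_RESIDUE_PDB = """\
ATOM      1  N   ALA A   1       0.000   0.000   0.000  1.00 10.00           N
ATOM      2  CA  ALA A   1       1.458   0.000   0.000  1.00 12.00           C
ATOM      3  C   ALA A   1       2.009   1.420   0.000  1.00 11.00           C
ATOM      4  O   ALA A   1       1.251   2.390   0.000  1.00 10.00           O
ATOM      5  CB  ALA A   1       2.000  -0.800  -1.200  1.00 14.00           C
ATOM      6  N   GLY A   2       3.332   1.536   0.000  1.00 10.00           N
ATOM      7  CA AGLY A   2       3.970   2.840   0.000  0.60 16.00           C
ATOM      8  CA BGLY A   2       3.980   2.850   0.000  0.40 18.00           C
ATOM      9  C   GLY A   2       5.480   2.750   0.000  1.00 10.00           C
ATOM     10  O   GLY A   2       6.090   1.680   0.000  1.00 10.00           O
TER
END
"""


@pytest.fixture
def two_residue_pdb(tmp_path):
    p = tmp_path / "tiny.pdb"
    p.write_text(TWO_RESIDUE_PDB)
    return p


def make_dssp_line(idx: int, resseq: int, chain: str, aa: str,
                   acc: int, phi: float, psi: float) -> str:
    """Compose a fixed-column DSSP data line (enough fields for parsers)."""
    line = [" "] * 120
    line[0:5] = f"{idx:5d}"
    line[5:10] = f"{resseq:5d}"
    line[11] = chain
    line[13] = aa
    line[16] = "H"
    line[34:38] = f"{acc:4d}"
    # four H-bond (relidx, energy) pairs
    line[38:45] = f"{0:7d}"
    line[46:50] = f"{0.0:4.1f}"
    line[50:56] = f"{0:6d}"
    line[57:61] = f"{0.0:4.1f}"
    line[61:67] = f"{0:6d}"
    line[68:72] = f"{0.0:4.1f}"
    line[72:78] = f"{0:6d}"
    line[79:83] = f"{0.0:4.1f}"
    line[103:109] = f"{phi:6.1f}"
    line[109:115] = f"{psi:6.1f}"
    return "".join(line)


@pytest.fixture
def dssp_file(tmp_path):
    text = "\n".join([
        "==== Secondary Structure Definition by the program DSSP ====",
        "  #  RESIDUE AA STRUCTURE BP1 BP2  ACC     N-H-->O    O-->H-N"
        "    N-H-->O    O-->H-N    TCO  KAPPA ALPHA  PHI   PSI    X-CA   Y-CA   Z-CA",
        make_dssp_line(1, 1, "A", "A", 105, 360.0, -47.0),
        make_dssp_line(2, 2, "A", "G", 37, -57.0, -47.0),
    ]) + "\n"
    p = tmp_path / "tiny.dssp"
    p.write_text(text)
    return p


RSA_TEXT = """\
REM  Absolute sums over single chains surface
RES ALA A   1   109.22  82.5  62.10  73.1  47.12  60.2  30.00  40.0  79.22  95.0
RES GLY A   2    80.10  95.9   0.00   0.0  80.10  95.9   0.00   0.0  80.10  95.9
END
"""


@pytest.fixture
def rsa_file(tmp_path):
    p = tmp_path / "tiny.rsa"
    p.write_text(RSA_TEXT)
    return p


@pytest.fixture(scope="session")
def helix20():
    return build_ideal_structure("A" * 20, "helix", seed=11)


@pytest.fixture(scope="session")
def globule60():
    return build_ideal_structure(
        "ANSTGLKVEDYFWHRMCPQI" * 3, "globule", seed=5, structure_id="GLOB")


@pytest.fixture(scope="session")
def pssm20():
    return synth_pssm("ANSTGLKVEDYFWHRMCPQI", concentration=10.0, seed=3)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
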