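"""Shared fixtures: a hand-written two-tripeptide complex, hand-built atoms,
and the session-wide synthetic planted-signal study."""

from __future__ import annotations

import numpy as np
import pytest

from hotcontact.bfactor_norm import BfactorStats
from hotcontact.config import RunConfig
from hotcontact.rf_model import loco_cv
from hotcontact.structure_model import Atom, parse_pdb_string, vdw_radius
from hotcontact.synthetic_fixtures import FixtureSpec, make_study, make_toy_complex

# Two tripeptides (A: Gly-Ser-Leu, B: Ala-Cys-Asp) facing each other, with
# one altloc pair on Ser OG (B conformer has higher occupancy), a hydrogen
# (to be discarded), a non-standard ligand (to be skipped) and two waters.
# Hand count: chain A 18 heavy atoms, chain B 19, waters 2.
HAND_PDB = """\
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00 21.00           N
ATOM      2  CA  GLY A   1       1.460   0.000   0.000  1.00 22.00           C
ATOM      3  C   GLY A   1       2.200   1.200   0.000  1.00 23.00           C
ATOM      4  O   GLY A   1       2.200   2.430   0.000  1.00 24.00           O
ATOM      5  N   SER A   2       3.600   0.000   0.000  1.00 25.00           N
ATOM      6  CA  SER A   2       5.060   0.000   0.000  1.00 26.00           C
ATOM      7  C   SER A   2       5.800   1.200   0.000  1.00 27.00           C
ATOM      8  O   SER A   2       5.800   2.430   0.000  1.00 28.00           O
ATOM      9  CB  SER A   2       5.060  -0.900   1.200  1.00 29.00           C
ATOM     10  OG ASER A   2       5.060  -0.900   2.600  0.40 30.00           O
ATOM     11  OG BSER A   2       5.100  -0.900   2.600  0.60 31.00           O
ATOM     12  N   LEU A   3       7.200   0.000   0.000  1.00 31.00           N
ATOM     13  CA  LEU A   3       8.660   0.000   0.000  1.00 32.00           C
ATOM     14  C   LEU A   3       9.400   1.200   0.000  1.00 33.00           C
ATOM     15  O   LEU A   3       9.400   2.430   0.000  1.00 34.00           O
ATOM     16  CB  LEU A   3       8.660  -0.900   1.200  1.00 35.00           C
ATOM     17  CG  LEU A   3       8.660  -0.900   2.700  1.00 36.00           C
ATOM     18  CD1 LEU A   3       8.660   0.320   3.570  1.00 37.00           C
ATOM     19  CD2 LEU A   3       8.660  -2.120   3.570  1.00 38.00           C
ATOM     20  HB2 LEU A   3       9.200  -1.500   1.100  1.00 10.00           H
ATOM     21  N   ALA B   1       0.000   0.000  10.740  1.00 39.00           N
ATOM     22  CA  ALA B   1       1.460   0.000  10.740  1.00 40.00           C
ATOM     23  C   ALA B   1       2.200   1.200  10.740  1.00 41.00           C
ATOM     24  O   ALA B   1       2.200   2.430  10.740  1.00 42.00           O
ATOM     25  CB  ALA B   1       1.460  -0.900   9.540  1.00 43.00           C
ATOM     26  N   CYS B   2       3.600   0.000  10.740  1.00 44.00           N
ATOM     27  CA  CYS B   2       5.060   0.000  10.740  1.00 45.00           C
ATOM     28  C   CYS B   2       5.800   1.200  10.740  1.00 46.00           C
ATOM     29  O   CYS B   2       5.800   2.430  10.740  1.00 47.00           O
ATOM     30  CB  CYS B   2       5.060  -0.900   9.540  1.00 48.00           C
ATOM     31  SG  CYS B   2       5.060  -0.900   7.740  1.00 49.00           S
ATOM     32  N   ASP B   3       7.200   0.000  10.740  1.00 50.00           N
ATOM     33  CA  ASP B   3       8.660   0.000  10.740  1.00 51.00           C
ATOM     34  C   ASP B   3       9.400   1.200  10.740  1.00 52.00           C
ATOM     35  O   ASP B   3       9.400   2.430  10.740  1.00 53.00           O
ATOM     36  CB  ASP B   3       8.660  -0.900   9.540  1.00 54.00           C
ATOM     37  CG  ASP B   3       8.660  -0.900   8.040  1.00 55.00           C
ATOM     38  OD1 ASP B   3       8.660   0.117   7.315  1.00 56.00           O
ATOM     39  OD2 ASP B   3       8.660  -1.917   7.315  1.00 57.00           O
HETATM   40  C1  LIG A 900      20.000  20.000  20.000  1.00 15.00           C
HETATM   41  O   HOH W 501       5.000   5.000   5.000  1.00 44.00           O
HETATM   42  O   HOH W 502      25.000  25.000  25.000  1.00 46.00           O
END
"""

HAND_PROTEIN_ATOMS = 37  # 18 + 19, after altloc resolution and H removal
HAND_WATERS = 2


def make_atom(
    atom_id: int,
    coords,
    element: str = "C",
    name: str | None = None,
    chain: str = "A",
    seq: int = 1,
    res_name: str = "UNK",
    b: float = 30.0,
    **kwargs,
) -> Atom:
    """Bare atom for geometric unit tests."""
    return Atom(
        atom_id=atom_id,
        name=name or f"X{atom_id}",
        element=element,
        coords=np.asarray(coords, dtype=float),
        b_factor=b,
        vdw_radius=vdw_radius(element),
        chain_id=chain,
        res_key=(chain, seq, " "),
        res_name=res_name,
        **kwargs,
    )


@pytest.fixture
def hand_structure():
    with pytest.warns(UserWarning):
        return parse_pdb_string(HAND_PDB, {"A"}, {"B"}, structure_id="HAND")


# A motif-rich fixture exercising every planted contact class.
RICH_SPEC = FixtureSpec(
    n_residues_per_chain=11,
    planted_contacts=((0, "cc"), (2, "hbond"), (4, "polar"), (6, "pi"), (9, "sulfur")),
    seed=7,
    structure_id="RICH",
)


@pytest.fixture(scope="session")
def rich_fixture():
    return make_toy_complex(RICH_SPEC)


@pytest.fixture(scope="session")
def study():
    """The 20-complex planted-signal cohort (seed-fixed study conditions)."""
    return make_study(n_complexes=20, seed=11)


@pytest.fixture(scope="session")
def study_cv(study):
    return loco_cv(study, seed=5)


@pytest.fixture
def flat_stats():
    """Stats making a raw B of 30 map exactly to B'' = -1."""
    return BfactorStats(mean=30.0, std=10.0, n_used=100)
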