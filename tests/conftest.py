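"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from gtase.pose import DockedPose
from gtase.structure import Atom, ReferenceLigand

# --- hand-written PDB fixtures -------------------------------------------

THREE_ATOM_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.560   6.351  -6.500  1.00  0.00           C
ATOM      3  C   ALA A   1      13.243   5.361  -5.559  1.00  0.00           C
END
"""

# tryptophan (14 heavy atoms), a glycine, and a terminal alanine
TRIPEPTIDE_PDB = """\
ATOM      1  N   TRP A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  TRP A   1       1.458   0.000   0.000  1.00  0.00           C
ATOM      3  C   TRP A   1       2.009   1.420   0.000  1.00  0.00           C
ATOM      4  O   TRP A   1       1.251   2.390   0.000  1.00  0.00           O
ATOM      5  CB  TRP A   1       2.000  -0.750  -1.220  1.00  0.00           C
ATOM      6  CG  TRP A   1       3.480  -0.900  -1.280  1.00  0.00           C
ATOM      7  CD1 TRP A   1       4.200  -1.980  -0.870  1.00  0.00           C
ATOM      8  CD2 TRP A   1       4.420   0.050  -1.820  1.00  0.00           C
ATOM      9  NE1 TRP A   1       5.540  -1.760  -1.080  1.00  0.00           N
ATOM     10  CE2 TRP A   1       5.700  -0.530  -1.680  1.00  0.00           C
ATOM     11  CE3 TRP A   1       4.280   1.320  -2.400  1.00  0.00           C
ATOM     12  CZ2 TRP A   1       6.830   0.150  -2.110  1.00  0.00           C
ATOM     13  CZ3 TRP A   1       5.410   1.990  -2.830  1.00  0.00           C
ATOM     14  CH2 TRP A   1       6.670   1.410  -2.690  1.00  0.00           C
ATOM     15  N   GLY A   2       3.330   1.540   0.010  1.00  0.00           N
ATOM     16  CA  GLY A   2       3.970   2.850   0.010  1.00  0.00           C
ATOM     17  C   GLY A   2       5.480   2.720   0.020  1.00  0.00           C
ATOM     18  O   GLY A   2       6.030   1.620   0.030  1.00  0.00           O
ATOM     19  N   ALA A   3       6.190   3.850   0.020  1.00  0.00           N
ATOM     20  CA  ALA A   3       7.650   3.870   0.030  1.00  0.00           C
ATOM     21  C   ALA A   3       8.210   5.280   0.030  1.00  0.00           C
ATOM     22  O   ALA A   3       7.460   6.260   0.020  1.00  0.00           O
ATOM     23  CB  ALA A   3       8.180   3.120  -1.190  1.00  0.00           C
ATOM     24  OXT ALA A   3       9.450   5.420   0.040  1.00  0.00           O
END
"""

MALFORMED_PDB = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      12.5x0   6.351  -6.500  1.00  0.00           C
END
"""

# 8-heavy-atom toy ligand with 3 hydrogens and anchors A1/A2/A3
TOY_LIGAND_PDB = """\
HETATM    1  A1  LIG X   1       0.000   0.000   0.000  1.00  0.00           C
HETATM    2  A2  LIG X   1       4.000   0.000   0.000  1.00  0.00           C
HETATM    3  A3  LIG X   1       2.000   1.000   0.000  1.00  0.00           N
HETATM    4  B1  LIG X   1       0.500   0.500   0.500  1.00  0.00           C
HETATM    5  B2  LIG X   1       4.500   0.500   0.500  1.00  0.00           C
HETATM    6  B3  LIG X   1       8.000   0.000   0.000  1.00  0.00           C
HETATM    7  B4  LIG X   1       8.500   0.500   0.500  1.00  0.00           C
HETATM    8  B5  LIG X   1      12.000   0.000   0.000  1.00  0.00           O
HETATM    9  H1  LIG X   1       0.100   0.100   0.900  1.00  0.00           H
HETATM   10  H2  LIG X   1       4.100   0.100   0.900  1.00  0.00           H
HETATM   11  H3  LIG X   1       8.100   0.100   0.900  1.00  0.00           H
END
"""

TOY_LIGAND_MOIETIES = {
    "A1": -1, "B1": -1, "A3": -1,
    "A2": 1, "B2": 1,
    "B3": 2, "B4": 2,
    "B5": 3,
}


@pytest.fixture
def three_atom_pdb(tmp_path):
    path = tmp_path / "three.pdb"
    path.write_text(THREE_ATOM_PDB)
    return path


@pytest.fixture
def tripeptide_pdb(tmp_path):
    path = tmp_path / "tripeptide.pdb"
    path.write_text(TRIPEPTIDE_PDB)
    return path


@pytest.fixture
def toy_ligand_pdb(tmp_path):
    path = tmp_path / "ligand.pdb"
    path.write_text(TOY_LIGAND_PDB)
    return path


# --- array -> domain-object helpers --------------------------------------


def xyz_to_pose(xyz, name="pose") -> DockedPose:
    atoms = [
        Atom(
            serial=i + 1,
            name=f"P{i}",
            element="C",
            residue_name="LIG",
            residue_number=1,
            chain_id="X",
            position=np.asarray(p, dtype=float),
            is_hetero=True,
        )
        for i, p in enumerate(np.atleast_2d(xyz))
    ]
    return DockedPose(ligand_name=name, model_rank=1, docking_score=0.0, atoms=atoms)


def xyz_to_reference(xyz) -> ReferenceLigand:
    xyz = np.atleast_2d(xyz)
    atoms = [
        Atom(
            serial=i + 1,
            name=f"R{i}",
            element="C",
            residue_name="REF",
            residue_number=1,
            chain_id="X",
            position=np.asarray(p, dtype=float),
            is_hetero=True,
        )
        for i, p in enumerate(xyz)
    ]
    n = len(atoms)
    anchors = [atoms[0].name, atoms[min(1, n - 1)].name, atoms[min(2, n - 1)].name]
    if len(set(anchors)) < 3:  # tiny sets: pad with dummy off-ligand anchors
        raise ValueError("need >= 3 atoms for a reference")
    return ReferenceLigand(
        atoms=atoms,
        axis_start_name=atoms[0].name,
        axis_end_name=atoms[1].name,
        origin_name=atoms[2].name,
        moiety_map={a.name: -1 for a in atoms},
    )


# --- independent oracles ---------------------------------------------------


def greedy_match_oracle(pose_xyz, ref_xyz, threshold=1.0):
    """Brute-force replay of the sorted-pair removal rule.

    Materializes the full pair list sorted by (distance, pose index,
    reference index) and accepts each sub-threshold pair whose atoms are
    both still available. Independent of the implementation's incremental
    argmin loop.
    """
    pose_xyz = np.atleast_2d(pose_xyz)
    ref_xyz = np.atleast_2d(ref_xyz)
    pairs = sorted(
        (float(np.linalg.norm(p - r)), i, j)
        for i, p in enumerate(pose_xyz)
        for j, r in enumerate(ref_xyz)
    )
    used_pose, used_ref = set(), set()
    matches = []
    for d, i, j in pairs:
        if d >= threshold:
            break
        if i in used_pose or j in used_ref:
            continue
        matches.append((i, j))
        used_pose.add(i)
        used_ref.add(j)
    return matches


def optimal_match_count(pose_xyz, ref_xyz, threshold=1.0):
    """Exhaustive maximum-cardinality matching under the distance cap."""
    pose_xyz = np.atleast_2d(pose_xyz)
    ref_xyz = np.atleast_2d(ref_xyz)
    edges = [
        [j for j, r in enumerate(ref_xyz) if np.linalg.norm(p - r) < threshold]
        for p in pose_xyz
    ]

    def best(i, used):
        if i == len(edges):
            return 0
        score = best(i + 1, used)  # leave pose atom i unmatched
        for j in edges[i]:
            if not used & (1 << j):
                score = max(score, 1 + best(i + 1, used | (1 << j)))
        return score

    return best(0, 0)
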