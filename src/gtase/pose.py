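"""Geometric analysis of docked ligand poses against a reference inhibitor.

The substrate-binding groove of the enzyme is reduced to a one-dimensional
axis anchored on the reference inhibitor: the axis direction runs between two
inhibitor atoms lying along the groove, and its origin is the projection of
the glycosidic-linker atom (between the -1 and +1 moieties) onto that line.
A docked pose is then characterised by

* its *positional coordinate*: the signed projection of its heavy-atom
  centroid onto the axis (angstroms; negative = donor side),
* its *sub-angstrom match percentage*: a greedy shortest-pair correspondence
  between pose and reference heavy atoms, counting pairs closer than 1 A,
* the subsite its coordinate falls nearest to, calibrated from the reference
  ligand's own moiety centroids.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .structure import Atom, ReferenceLigand, StructureModel

__all__ = [
    "BindingAxis",
    "DockedPose",
    "PoseMetrics",
    "ResidueContact",
    "DegenerateAxisError",
    "OrientationError",
    "build_binding_axis",
    "positional_coordinate",
    "greedy_match_percent",
    "calibrate_subsites",
    "assign_subsite",
    "min_residue_ligand_distance",
    "format_subsite",
]


class DegenerateAxisError(ValueError):
    """Axis anchors coincide; no direction can be defined."""


class OrientationError(ValueError):
    """Subsite centroids are not monotone along the axis (anchors swapped?)."""


@dataclass
class BindingAxis:
    origin: np.ndarray
    direction: np.ndarray

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = np.linalg.norm(self.direction)
        if abs(norm - 1.0) > 1e-9:
            raise ValueError("direction must be a unit vector")
        if not np.all(np.isfinite(self.origin)):
            raise ValueError("origin must be finite")


@dataclass
class DockedPose:
    """One docked conformation: heavy atoms plus score and rank."""

    ligand_name: str
    model_rank: int
    docking_score: float
    atoms: list[Atom]
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.atoms:
            raise ValueError("pose must have at least one atom")
        if any(not a.is_heavy for a in self.atoms):
            raise ValueError("pose atoms must all be heavy")
        if self.model_rank < 1:
            raise ValueError("model_rank must be >= 1")

    def coordinates(self) -> np.ndarray:
        return np.vstack([a.position for a in self.atoms])

    def centroid(self) -> np.ndarray:
        return self.coordinates().mean(axis=0)


@dataclass
class PoseMetrics:
    positional_coordinate: float
    match_percent: float
    matched_pairs: list[tuple[int, int]]
    assigned_subsite: str = "unassigned"


@dataclass
class ResidueContact:
    """Minimum residue-ligand heavy-atom distance, with CA-fallback flag."""

    distance: float
    used_ca_fallback: bool = False


def build_binding_axis(reference: ReferenceLigand) -> BindingAxis:
    """Binding axis from the reference ligand's three anchor atoms.

    Direction is the unit vector from the axis-start to the axis-end atom;
    the origin is the orthogonal projection of the origin anchor onto the
    infinite line through the axis-start along that direction.
    """
    start = reference.atom(reference.axis_start_name).position
    end = reference.atom(reference.axis_end_name).position
    origin_atom = reference.atom(reference.origin_name).position
    vec = end - start
    norm = np.linalg.norm(vec)
    if norm < 1e-12:
        raise DegenerateAxisError("axis anchor atoms coincide")
    direction = vec / norm
    origin = start + np.dot(origin_atom - start, direction) * direction
    return BindingAxis(origin=origin, direction=direction)


def positional_coordinate(pose: DockedPose, axis: BindingAxis) -> float:
    """Signed projection of the pose's heavy-atom centroid onto the axis."""
    return float(np.dot(pose.centroid() - axis.origin, axis.direction))


def greedy_match_percent(
    pose: DockedPose, reference: ReferenceLigand, threshold: float = 1.0
) -> PoseMetrics:
    """Greedy shortest-pair atomic correspondence match.

    All pairwise pose-reference heavy-atom distances are computed; the
    globally shortest remaining pair is inspected, and if its distance is
    strictly below ``threshold`` the pair is recorded as a match and both
    atoms are removed from further consideration. The loop stops when no pose
    atom remains or the shortest remaining distance reaches the threshold
    (no later pair can be shorter). The match percentage is over the pose's
    heavy-atom count. Ties on distance break lexicographically on
    (pose-atom index, reference-atom index).
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    pose_xyz = pose.coordinates()
    ref_xyz = reference.coordinates()
    dist = cdist(pose_xyz, ref_xyz)
    n_pose, n_ref = dist.shape
    matched: list[tuple[int, int]] = []
    active = dist.copy()
    for _ in range(min(n_pose, n_ref)):
        flat = np.argmin(active)  # row-major argmin = lexicographic tie-break
        i, j = divmod(int(flat), n_ref)
        if not active[i, j] < threshold:
            break
        matched.append((i, j))
        active[i, :] = np.inf
        active[:, j] = np.inf
    percent = 100.0 * len(matched) / n_pose
    return PoseMetrics(
        positional_coordinate=float("nan"),
        match_percent=percent,
        matched_pairs=matched,
    )


def calibrate_subsites(
    reference: ReferenceLigand, axis: BindingAxis
) -> dict[int, float]:
    """Positional coordinate of each subsite's moiety heavy-atom centroid.

    Subsites ordered ..., -1, +1, +2, +3 must be monotone increasing along
    the axis; a violation indicates swapped axis anchors.
    """
    groups: dict[int, list[np.ndarray]] = {}
    for atom in reference.atoms:
        groups.setdefault(reference.moiety_map[atom.name], []).append(atom.position)
    calibration: dict[int, float] = {}
    for subsite, positions in groups.items():
        centroid = np.vstack(positions).mean(axis=0)
        calibration[subsite] = float(np.dot(centroid - axis.origin, axis.direction))
    ordered = sorted(calibration)
    values = [calibration[s] for s in ordered]
    if any(b <= a for a, b in zip(values, values[1:])):
        raise OrientationError(
            "subsite centroids are not increasing along the axis; "
            "axis anchors may be swapped"
        )
    return calibration


def assign_subsite(
    coordinate: float,
    calibration: dict[int, float],
    max_distance: float = 2.0,
) -> str:
    """Nearest calibrated subsite, or 'unassigned' beyond ``max_distance``.

    Ties between equidistant centroids go to the more negative (donor-side)
    subsite.
    """
    if not calibration:
        raise ValueError("calibration must be non-empty")
    if max_distance <= 0:
        raise ValueError("max_distance must be positive")
    # sort by subsite so the more negative subsite wins distance ties
    best_subsite, best_dist = None, np.inf
    for subsite in sorted(calibration):
        d = abs(coordinate - calibration[subsite])
        if d < best_dist:
            best_subsite, best_dist = subsite, d
    if best_dist > max_distance:
        return "unassigned"
    return format_subsite(best_subsite)


def format_subsite(subsite: int) -> str:
    return f"+{subsite}" if subsite > 0 else str(subsite)


_BACKBONE = {"N", "CA", "C", "O", "OXT"}


def min_residue_ligand_distance(
    structure: StructureModel,
    chain_id: str,
    residue_number: int,
    ligand_atoms: list[Atom],
) -> ResidueContact:
    """Minimum side-chain-to-ligand heavy-atom distance, in angstroms.

    Side-chain heavy atoms only (contact residues in the acceptor subsites
    interact through their aromatic side chains); for glycine, which has no
    side-chain heavy atom, the CA is used and the result flagged.
    """
    if not ligand_atoms:
        raise ValueError("ligand_atoms must be non-empty")
    residue = structure.get_residue(chain_id, residue_number)
    side = [a for a in residue if a.is_heavy and a.name not in _BACKBONE]
    used_ca = False
    if not side:
        side = [a for a in residue if a.name == "CA"]
        used_ca = True
        if not side:
            raise ValueError(
                f"residue {chain_id}/{residue_number} has no side-chain or CA atom"
            )
    ligand_heavy = [a for a in ligand_atoms if a.is_heavy]
    if not ligand_heavy:
        raise ValueError("ligand has no heavy atoms")
    d = cdist(
        np.vstack([a.position for a in side]),
        np.vstack([a.position for a in ligand_heavy]),
    )
    return ResidueContact(distance=float(d.min()), used_ca_fallback=used_ca)
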