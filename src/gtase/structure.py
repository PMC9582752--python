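"""Molecular coordinate I/O and docking-input preparation.

Reads and writes fixed-column PDB (single- and multi-model) plus a minimal
PDBQT dialect (AutoDock charge/type columns ignored), annotates a reference
ligand with its glucose-moiety subsite map, builds alanine-truncation mutant
structures, and emits Vina-style docking-box configuration.

The reference-ligand machinery is built around an acarbose-like
pseudo-substrate: a pseudo-tetrasaccharide inhibitor whose four moieties mark
the -1, +1, +2 and +3 sugar-binding subsites of a glucanotransferase groove.
Three anchor atoms define the binding-axis geometry used downstream: two atoms
lying along the groove (axis start/end, conventionally C4A and C1) and the
glycosidic-linker atom between the -1 and +1 moieties (origin, conventionally
N4A).
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "Atom",
    "StructureModel",
    "ReferenceLigand",
    "DockingBoxConfig",
    "StructureFormatError",
    "EmptyStructureError",
    "AnchorNotFoundError",
    "AnnotationError",
    "ResidueNotFoundError",
    "UnsupportedMutationError",
    "read_structure",
    "write_structure",
    "extract_reference_ligand",
    "make_alanine_mutant",
    "emit_docking_config",
    "serialize_docking_config",
]


class StructureFormatError(ValueError):
    """A coordinate line could not be parsed; the message names the line."""


class EmptyStructureError(ValueError):
    """A model contained no atoms."""


class AnchorNotFoundError(KeyError):
    """A requested anchor atom is absent from the ligand."""


class AnnotationError(ValueError):
    """The moiety map does not cover every retained ligand atom."""


class ResidueNotFoundError(KeyError):
    """The addressed residue does not exist in the structure."""


class UnsupportedMutationError(ValueError):
    """Alanine truncation requested on a residue without a beta-carbon."""


# Two-letter element symbols that occur in protein/ligand PDB files; used
# when the element column is blank and must be inferred from the atom name.
_TWO_LETTER_ELEMENTS = {
    "BR", "CL", "FE", "MG", "MN", "ZN", "CA", "NA", "CU", "NI", "CO", "SE",
}
# Atom names whose leading letters collide with two-letter metals but are
# organic: CA/CB/... are carbons, all standard amino-acid names.
_NAME_IS_ORGANIC_PREFIX = {"C", "N", "O", "S", "P", "H"}


@dataclass
class Atom:
    """One atom record; coordinates in angstroms."""

    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    chain_id: str
    position: np.ndarray
    is_hetero: bool = False
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        if self.position.shape != (3,) or not np.all(np.isfinite(self.position)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.element:
            raise ValueError(f"atom {self.name}: element must be non-empty")

    @property
    def is_heavy(self) -> bool:
        return self.element.upper() != "H"

    @property
    def residue_key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.residue_number, self.residue_name)


@dataclass
class StructureModel:
    """An ordered atom collection with residue grouping."""

    atoms: list[Atom] = field(default_factory=list)

    def residues(self) -> dict[tuple[str, int, str], list[Atom]]:
        """Group atoms by (chain_id, residue_number, residue_name), in file order."""
        groups: dict[tuple[str, int, str], list[Atom]] = {}
        for atom in self.atoms:
            groups.setdefault(atom.residue_key, []).append(atom)
        return groups

    def get_residue(self, chain_id: str, residue_number: int) -> list[Atom]:
        found = [
            a for a in self.atoms
            if a.chain_id == chain_id and a.residue_number == residue_number
        ]
        if not found:
            raise ResidueNotFoundError(
                f"residue {chain_id}/{residue_number} not found"
            )
        return found

    def heavy_atoms(self) -> list[Atom]:
        return [a for a in self.atoms if a.is_heavy]

    def coordinates(self) -> np.ndarray:
        if not self.atoms:
            return np.empty((0, 3))
        return np.vstack([a.position for a in self.atoms])


@dataclass
class ReferenceLigand:
    """Heavy-atom reference inhibitor with axis anchors and subsite moiety map.

    ``moiety_map`` maps each atom name to an integer subsite label (negative =
    donor side of the scissile bond, positive = acceptor side; -1 and +1 are
    adjacent, there is no subsite 0).
    """

    atoms: list[Atom]
    axis_start_name: str = "C4A"
    axis_end_name: str = "C1"
    origin_name: str = "N4A"
    moiety_map: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = [a.name for a in self.atoms]
        for anchor in (self.axis_start_name, self.axis_end_name, self.origin_name):
            if anchor not in names:
                raise AnchorNotFoundError(f"anchor atom {anchor!r} not in ligand")
        if len({self.axis_start_name, self.axis_end_name, self.origin_name}) != 3:
            raise ValueError("axis/origin anchor names must be distinct")
        for atom in self.atoms:
            if not atom.is_heavy:
                raise ValueError(f"reference ligand atom {atom.name} is not heavy")
            if atom.name not in self.moiety_map:
                raise AnnotationError(
                    f"atom {atom.name} has no subsite in the moiety map"
                )

    def atom(self, name: str) -> Atom:
        for a in self.atoms:
            if a.name == name:
                return a
        raise AnchorNotFoundError(f"atom {name!r} not in ligand")

    def coordinates(self) -> np.ndarray:
        return np.vstack([a.position for a in self.atoms])

    def subsites(self) -> list[int]:
        return sorted(set(self.moiety_map.values()))


@dataclass
class DockingBoxConfig:
    """Cubic search box for a docking run, Vina conventions."""

    center: np.ndarray
    edge_length: float = 30.0
    exhaustiveness: int = 100
    num_modes: int = 20

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.edge_length <= 0:
            raise ValueError("edge_length must be positive")
        if self.exhaustiveness < 1 or self.num_modes < 1:
            raise ValueError("exhaustiveness and num_modes must be >= 1")


def _infer_element(raw_name: str) -> str:
    """Infer the element from an atom name when the element column is blank."""
    stripped = raw_name.strip()
    letters = "".join(c for c in stripped if c.isalpha())
    if not letters:
        return ""
    two = letters[:2].upper()
    if two in _TWO_LETTER_ELEMENTS and letters[0].upper() not in _NAME_IS_ORGANIC_PREFIX:
        return two.capitalize()
    # Names beginning with a digit (1HB etc.) are hydrogens by PDB convention.
    if stripped[0].isdigit():
        return "H"
    return letters[0].upper()


def _parse_atom_line(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16:17].strip()
        residue_name = line[17:20].strip()
        chain_id = line[21:22].strip() or " "
        residue_number = int(line[22:26])
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 78 else ""
    except (ValueError, IndexError) as exc:
        raise StructureFormatError(
            f"unparseable coordinate record at line {lineno}: {line.rstrip()!r}"
        ) from exc
    # PDBQT stuffs an AutoDock atom type where PDB puts the element; types such
    # as 'OA'/'NA'/'HD' are not elements, so fall back to name inference for
    # anything not matching a plain element symbol.
    if element and element.upper() not in _TWO_LETTER_ELEMENTS and len(element) > 1:
        element = ""
    if not element:
        element = _infer_element(name)
    if not element:
        raise StructureFormatError(f"cannot infer element at line {lineno}")
    return Atom(
        serial=serial,
        name=name,
        element=element,
        residue_name=residue_name,
        residue_number=residue_number,
        chain_id=chain_id,
        position=np.array([x, y, z]),
        is_hetero=line.startswith("HETATM"),
        altloc=altloc,
        occupancy=occupancy,
    )


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one altloc per atom site: highest occupancy, ties prefer 'A'."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.chain_id, atom.residue_number, atom.residue_name, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            held = best[key]
            if atom.occupancy > held.occupancy or (
                atom.occupancy == held.occupancy
                and (atom.altloc or "~") < (held.altloc or "~")
            ):
                best[key] = atom
    return [best[k] for k in order]


def read_structure(
    path: str | Path,
    dialect: str = "pdb",
    chain_id: str | None = None,
) -> StructureModel | list[StructureModel]:
    """Read a coordinate file.

    Parameters
    ----------
    path:
        File in PDB fixed-column layout (``dialect='pdb'`` or
        ``'multi_model_pdb'``) or minimal PDBQT (``'pdbqt_minimal'``; charge
        and AutoDock type columns are ignored).
    chain_id:
        Optional chain filter applied after parsing.

    Returns a single :class:`StructureModel` for ``'pdb'`` and a list of
    models (one per MODEL record) for the multi-model dialects.
    """
    if dialect not in {"pdb", "multi_model_pdb", "pdbqt_minimal"}:
        raise ValueError(f"unknown dialect {dialect!r}")
    text = Path(path).read_text()
    models: list[list[Atom]] = []
    current: list[Atom] = []
    saw_model_record = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        record = line[:6].strip()
        if record == "MODEL":
            saw_model_record = True
            if current:
                models.append(current)
            current = []
        elif record == "ENDMDL":
            models.append(current)
            current = []
        elif record in ("ATOM", "HETATM"):
            current.append(_parse_atom_line(line, lineno))
    if current or not models:
        models.append(current)

    structures: list[StructureModel] = []
    for atoms in models:
        atoms = _resolve_altlocs(atoms)
        if chain_id is not None:
            atoms = [a for a in atoms if a.chain_id == chain_id]
        if not atoms:
            raise EmptyStructureError(f"{path}: model contains no atoms")
        structures.append(StructureModel(atoms=atoms))

    if dialect == "pdb" and not saw_model_record:
        return structures[0]
    if dialect == "pdb":
        return structures[0]
    return structures


def write_structure(
    model: StructureModel | Sequence[StructureModel], path: str | Path
) -> None:
    """Write one model (or MODEL/ENDMDL-wrapped models) in fixed-column PDB."""
    models = [model] if isinstance(model, StructureModel) else list(model)
    lines: list[str] = []
    multi = len(models) > 1
    for i, m in enumerate(models, start=1):
        if multi:
            lines.append(f"MODEL     {i:4d}")
        for a in m.atoms:
            record = "HETATM" if a.is_hetero else "ATOM  "
            name = a.name if len(a.name) >= 4 else f" {a.name:<3s}"
            lines.append(
                f"{record}{a.serial:5d} {name:<4.4s}{a.altloc:1.1s}"
                f"{a.residue_name:>3.3s} {a.chain_id:1.1s}{a.residue_number:4d}    "
                f"{a.position[0]:8.3f}{a.position[1]:8.3f}{a.position[2]:8.3f}"
                f"{a.occupancy:6.2f}{0.0:6.2f}          {a.element:>2.2s}"
            )
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def extract_reference_ligand(
    structure: StructureModel,
    residue_name: str,
    anchors: tuple[str, str, str] = ("C4A", "C1", "N4A"),
    moiety_map: Mapping[str, int] | None = None,
    chain_id: str | None = None,
    residue_number: int | None = None,
) -> ReferenceLigand:
    """Pull a hetero ligand residue out of a structure as a reference ligand.

    Hydrogens are dropped. ``anchors`` is (axis_start, axis_end, origin).
    When several copies of the ligand exist, an explicit ``chain_id`` /
    ``residue_number`` selector is required (no silent first-instance guess).
    """
    candidates = [
        a for a in structure.atoms
        if a.residue_name == residue_name
        and (chain_id is None or a.chain_id == chain_id)
        and (residue_number is None or a.residue_number == residue_number)
    ]
    if not candidates:
        raise ResidueNotFoundError(f"no residue named {residue_name!r}")
    instances = {a.residue_key for a in candidates}
    if len(instances) > 1:
        raise ValueError(
            f"{len(instances)} copies of {residue_name!r}; select one with "
            "chain_id/residue_number"
        )
    heavy = [copy.deepcopy(a) for a in candidates if a.is_heavy]
    if moiety_map is None:
        raise AnnotationError("a moiety_map covering every heavy atom is required")
    return ReferenceLigand(
        atoms=heavy,
        axis_start_name=anchors[0],
        axis_end_name=anchors[1],
        origin_name=anchors[2],
        moiety_map=dict(moiety_map),
    )


_ALA_KEEP = {"N", "CA", "C", "O", "CB", "OXT"}


def make_alanine_mutant(
    structure: StructureModel, chain_id: str, residue_number: int
) -> StructureModel:
    """Truncate one residue's side chain to alanine.

    Keeps only the main-chain atoms and the beta-carbon (N, CA, C, O, CB,
    plus OXT at a terminus), renames the residue ALA, and leaves everything
    else untouched. The input structure is not modified.
    """
    target = structure.get_residue(chain_id, residue_number)
    residue_name = target[0].residue_name
    if residue_name == "GLY" or not any(a.name == "CB" for a in target):
        raise UnsupportedMutationError(
            f"residue {chain_id}/{residue_number} ({residue_name}) has no "
            "beta-carbon; alanine truncation unsupported"
        )
    out_atoms: list[Atom] = []
    for atom in structure.atoms:
        if atom.chain_id == chain_id and atom.residue_number == residue_number:
            if atom.name not in _ALA_KEEP or not atom.is_heavy:
                continue
            atom = copy.deepcopy(atom)
            atom.residue_name = "ALA"
        else:
            atom = copy.deepcopy(atom)
        out_atoms.append(atom)
    return StructureModel(atoms=out_atoms)


def emit_docking_config(
    reference: ReferenceLigand,
    edge_length: float = 30.0,
    exhaustiveness: int = 100,
    num_modes: int = 20,
) -> DockingBoxConfig:
    """Docking box centred on the reference ligand's origin anchor atom."""
    origin = reference.atom(reference.origin_name)
    return DockingBoxConfig(
        center=origin.position.copy(),
        edge_length=edge_length,
        exhaustiveness=exhaustiveness,
        num_modes=num_modes,
    )


def serialize_docking_config(config: DockingBoxConfig) -> str:
    """Vina-style key = value configuration text."""
    cx, cy, cz = config.center
    e = config.edge_length
    return "\n".join(
        [
            f"center_x = {cx:.3f}",
            f"center_y = {cy:.3f}",
            f"center_z = {cz:.3f}",
            f"size_x = {e:g}",
            f"size_y = {e:g}",
            f"size_z = {e:g}",
            f"exhaustiveness = {config.exhaustiveness}",
            f"num_modes = {config.num_modes}",
        ]
    ) + "\n"
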