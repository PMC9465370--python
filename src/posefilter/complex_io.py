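"""Read, write and prepare protein-ligand complexes in PDB format.

The rest of the package operates on :class:`ComplexStructure` objects:
heavy-atom protein and ligand coordinate sets with perceived covalent
bonds.  This module handles the fixed-width PDB records (ATOM / HETATM /
CONECT), partitions protein from ligand, resolves alternate locations,
strips hydrogens, and derives docking-box specifications from crystal
ligand coordinates.

Conventions
-----------
* Waters (HOH/WAT/DOD) are never selectable as the ligand; common
  monoatomic ions and buffer components are excluded by default but the
  exclusion set is configurable.
* When a structure contains alternate locations, the highest-occupancy
  conformer is kept per atom; occupancy ties break alphabetically on the
  altloc character.
* Only the first MODEL of a multi-model file is read.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable, Sequence, TextIO

import numpy as np

__all__ = [
    "Atom",
    "BoxSpec",
    "ComplexStructure",
    "LigandNotFoundError",
    "PDBParseError",
    "Residue",
    "WATER_RESNAMES",
    "DEFAULT_ION_RESNAMES",
    "compute_pocket_box",
    "parse_pdb_complex",
    "strip_hydrogens",
    "write_pdb",
]

WATER_RESNAMES = frozenset({"HOH", "WAT", "DOD"})

#: Monoatomic ions and frequent crystallization additives excluded from
#: ligand selection unless the caller overrides ``exclude_resnames``.
DEFAULT_ION_RESNAMES = frozenset(
    {
        "NA", "K", "CL", "MG", "CA", "ZN", "MN", "FE", "FE2", "CU", "NI",
        "CO", "CD", "HG", "BR", "IOD", "CS", "LI", "SR", "BA", "SO4",
        "PO4", "NO3", "ACT", "GOL", "EDO", "PEG", "DMS", "FMT",
    }
)


class PDBParseError(ValueError):
    """A fixed-width record could not be interpreted; carries the line number."""


class LigandNotFoundError(ValueError):
    """No HETATM residue matched the ligand selector."""


@dataclass(frozen=True)
class Residue:
    chain: str
    number: int
    icode: str
    name: str


@dataclass
class Atom:
    """One heavy (or hydrogen) atom from a PDB record."""

    serial: int
    name: str
    element: str
    coords: np.ndarray
    residue: Residue
    is_hetero: bool
    altloc: str = ""
    occupancy: float = 1.0

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,):
            raise ValueError(f"coords must be a 3-vector, got {self.coords.shape}")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("atom coordinates must be finite")
        if not self.element:
            raise ValueError("element symbol must be non-empty")

    @property
    def is_hydrogen(self) -> bool:
        return self.element.upper() in ("H", "D")


@dataclass
class ComplexStructure:
    """Heavy-atom protein + ligand coordinate model with covalent bonds."""

    protein_atoms: list[Atom]
    ligand_atoms: list[Atom]
    ligand_bonds: list[tuple[int, int]] = field(default_factory=list)
    protein_bonds: list[tuple[int, int]] = field(default_factory=list)
    source_id: str = ""

    def __post_init__(self) -> None:
        for i, j in self.ligand_bonds:
            if not (0 <= i < len(self.ligand_atoms) and 0 <= j < len(self.ligand_atoms)):
                raise ValueError(f"ligand bond ({i},{j}) out of range")
        for i, j in self.protein_bonds:
            if not (0 <= i < len(self.protein_atoms) and 0 <= j < len(self.protein_atoms)):
                raise ValueError(f"protein bond ({i},{j}) out of range")

    def protein_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.protein_atoms]).reshape(-1, 3)

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.ligand_atoms]).reshape(-1, 3)


@dataclass(frozen=True)
class BoxSpec:
    """Axis-aligned docking box: center and edge lengths in Angstrom."""

    center: tuple[float, float, float]
    edges: tuple[float, float, float]

    def contains(self, point: Sequence[float]) -> bool:
        c = np.asarray(self.center)
        e = np.asarray(self.edges)
        p = np.asarray(point, dtype=float)
        return bool(np.all(np.abs(p - c) <= e / 2.0 + 1e-9))


def _parse_record(line: str, lineno: int) -> Atom:
    try:
        serial = int(line[6:11])
        name = line[12:16].strip()
        altloc = line[16].strip()
        resname = line[17:20].strip()
        chain = line[21].strip()
        resnum = int(line[22:26])
        icode = line[26].strip()
        x = float(line[30:38])
        y = float(line[38:46])
        z = float(line[46:54])
        occ_field = line[54:60].strip()
        occupancy = float(occ_field) if occ_field else 1.0
        element = line[76:78].strip() if len(line) >= 77 else ""
    except (ValueError, IndexError) as exc:
        raise PDBParseError(f"line {lineno}: malformed ATOM/HETATM record: {exc}") from exc
    if not element:
        element = _element_from_name(name)
    return Atom(
        serial=serial,
        name=name,
        element=element.capitalize(),
        coords=np.array([x, y, z]),
        residue=Residue(chain=chain, number=resnum, icode=icode, name=resname),
        is_hetero=line.startswith("HETATM"),
        altloc=altloc,
        occupancy=occupancy,
    )


def _element_from_name(name: str) -> str:
    stripped = name.strip().lstrip("0123456789")
    if not stripped:
        raise ValueError(f"cannot infer element from atom name {name!r}")
    two = stripped[:2].capitalize()
    if two in ("Cl", "Br", "Fe", "Zn", "Mg", "Mn", "Na", "Ca", "Cu", "Ni", "Se"):
        return two
    return stripped[0].upper()


def _resolve_altlocs(atoms: list[Atom]) -> list[Atom]:
    """Keep one conformer per atom: highest occupancy, altloc-alphabetical ties."""
    best: dict[tuple, Atom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = (atom.residue, atom.name)
        if key not in best:
            best[key] = atom
            order.append(key)
        else:
            cur = best[key]
            if (atom.occupancy, _altloc_rank(atom.altloc)) > (
                cur.occupancy,
                _altloc_rank(cur.altloc),
            ):
                best[key] = atom
    return [best[k] for k in order]


def _altloc_rank(altloc: str) -> int:
    # Higher rank wins; alphabetically-earlier altloc must win ties.
    return -ord(altloc) if altloc else 0


def _make_selector(ligand_selector) -> Callable[[Atom], bool]:
    if callable(ligand_selector):
        return ligand_selector
    sel = str(ligand_selector)
    if sel in ("any", "*"):
        return lambda atom: True
    if sel.startswith("chain:"):
        chain = sel.split(":", 1)[1]
        return lambda atom: atom.residue.chain == chain
    return lambda atom: atom.residue.name == sel


def parse_pdb_complex(
    text: str | TextIO,
    ligand_selector="any",
    *,
    source_id: str = "",
    exclude_resnames: Iterable[str] | None = None,
) -> ComplexStructure:
    """Parse a PDB document into protein and ligand atom lists.

    Parameters
    ----------
    text:
        PDB-format character stream or string.
    ligand_selector:
        Residue-name string (e.g. ``"LIG"``), ``"chain:X"``, ``"any"`` for
        every non-water/non-ion HETATM residue, or a predicate on
        :class:`Atom`.
    exclude_resnames:
        HETATM residue names never treated as ligand. Defaults to
        :data:`DEFAULT_ION_RESNAMES`; waters are excluded unconditionally.
    """
    if hasattr(text, "read"):
        text = text.read()
    excluded = WATER_RESNAMES | frozenset(
        DEFAULT_ION_RESNAMES if exclude_resnames is None else exclude_resnames
    )
    selector = _make_selector(ligand_selector)

    protein: list[Atom] = []
    hetero: list[Atom] = []
    conect: list[tuple[int, int]] = []
    n_records = 0
    for lineno, line in enumerate(text.splitlines(), start=1):
        rec = line[:6]
        if rec == "ENDMDL":  # only the first model is read
            break
        if rec in ("ATOM  ", "HETATM"):
            atom = _parse_record(line, lineno)
            n_records += 1
            (hetero if atom.is_hetero else protein).append(atom)
        elif rec == "CONECT":
            fields = line.split()[1:]
            try:
                serials = [int(f) for f in fields]
            except ValueError as exc:
                raise PDBParseError(f"line {lineno}: malformed CONECT record") from exc
            for other in serials[1:]:
                conect.append((serials[0], other))
    if n_records == 0:
        raise PDBParseError("no ATOM or HETATM records found")

    protein = _resolve_altlocs(protein)
    hetero = _resolve_altlocs(hetero)
    ligand = [
        a for a in hetero if a.residue.name not in WATER_RESNAMES
        and a.residue.name not in excluded and selector(a)
    ]
    if not ligand:
        raise LigandNotFoundError(
            f"ligand not found: no HETATM residue matched selector {ligand_selector!r}"
        )

    lig_index = {a.serial: i for i, a in enumerate(ligand)}
    prot_index = {a.serial: i for i, a in enumerate(protein)}
    ligand_bonds: set[tuple[int, int]] = set()
    protein_bonds: set[tuple[int, int]] = set()
    for s1, s2 in conect:
        if s1 in lig_index and s2 in lig_index:
            i, j = sorted((lig_index[s1], lig_index[s2]))
            ligand_bonds.add((i, j))
        elif s1 in prot_index and s2 in prot_index:
            i, j = sorted((prot_index[s1], prot_index[s2]))
            protein_bonds.add((i, j))

    return ComplexStructure(
        protein_atoms=protein,
        ligand_atoms=ligand,
        ligand_bonds=sorted(ligand_bonds),
        protein_bonds=sorted(protein_bonds),
        source_id=source_id,
    )


def strip_hydrogens(structure: ComplexStructure) -> ComplexStructure:
    """Return a copy without H/D atoms; incident bonds dropped, order kept.

    Idempotent: stripping an already-heavy structure returns an equal copy.
    """

    def _strip(atoms: list[Atom], bonds: list[tuple[int, int]]):
        keep = [i for i, a in enumerate(atoms) if not a.is_hydrogen]
        remap = {old: new for new, old in enumerate(keep)}
        new_atoms = [atoms[i] for i in keep]
        new_bonds = [
            (remap[i], remap[j]) for i, j in bonds if i in remap and j in remap
        ]
        return new_atoms, new_bonds

    prot, prot_bonds = _strip(structure.protein_atoms, structure.protein_bonds)
    lig, lig_bonds = _strip(structure.ligand_atoms, structure.ligand_bonds)
    return ComplexStructure(
        protein_atoms=prot,
        ligand_atoms=lig,
        ligand_bonds=lig_bonds,
        protein_bonds=prot_bonds,
        source_id=structure.source_id,
    )


def compute_pocket_box(
    ligand_atoms: Sequence[Atom],
    margin: float = 4.0,
    min_edge: float = 10.0,
) -> BoxSpec:
    """Docking box from crystal-ligand heavy-atom coordinates.

    The center is the per-axis midpoint of the ligand extent; each edge is
    the extent plus ``2 * margin``, floored at ``min_edge``.  The returned
    box always contains every input heavy atom.
    """
    heavy = [a for a in ligand_atoms if not a.is_hydrogen]
    if not heavy:
        raise ValueError("cannot compute a pocket box from an empty atom list")
    if margin < 0:
        raise ValueError("margin must be >= 0")
    coords = np.array([a.coords for a in heavy])
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    center = (lo + hi) / 2.0
    edges = np.maximum(hi - lo + 2.0 * margin, min_edge)
    return BoxSpec(center=tuple(center.tolist()), edges=tuple(edges.tolist()))


_PDB_COORD_MAX = 9999.999
_PDB_COORD_MIN = -999.999


def _format_atom_name(name: str, element: str) -> str:
    # Columns 13-16: names shorter than 4 characters start at column 14
    # when the element symbol is a single character.
    if len(name) >= 4:
        return name[:4]
    if len(element) >= 2:
        return f"{name:<4}"[:4]
    return f" {name:<3}"


def write_pdb(structure: ComplexStructure, stream: TextIO) -> None:
    """Emit fixed-width PDB records: protein as ATOM, ligand as HETATM.

    Ligand connectivity is written as CONECT records so a round trip
    through :func:`parse_pdb_complex` preserves the ligand bond graph.
    """

    def _record(kind: str, serial: int, atom: Atom) -> str:
        x, y, z = atom.coords
        for v in (x, y, z):
            if not (_PDB_COORD_MIN <= v <= _PDB_COORD_MAX):
                raise ValueError(
                    f"coordinate {v:.3f} exceeds the PDB %8.3f field width"
                )
        return (
            f"{kind:<6}{serial:>5} {_format_atom_name(atom.name, atom.element)}"
            f"{atom.altloc or ' '}{atom.residue.name:>3} {atom.residue.chain or 'A'}"
            f"{atom.residue.number:>4}{atom.residue.icode or ' '}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{atom.occupancy:6.2f}{0.0:6.2f}"
            f"          {atom.element.upper():>2}"
        )

    serial = 0
    lig_serials: list[int] = []
    for atom in structure.protein_atoms:
        serial += 1
        stream.write(_record("ATOM", serial, atom) + "\n")
    if structure.protein_atoms:
        stream.write("TER\n")
    for atom in structure.ligand_atoms:
        serial += 1
        lig_serials.append(serial)
        stream.write(_record("HETATM", serial, atom) + "\n")
    neighbors: dict[int, list[int]] = {}
    for i, j in structure.ligand_bonds:
        neighbors.setdefault(i, []).append(j)
        neighbors.setdefault(j, []).append(i)
    for i in sorted(neighbors):
        partners = "".join(f"{lig_serials[j]:>5}" for j in sorted(neighbors[i]))
        stream.write(f"CONECT{lig_serials[i]:>5}{partners}\n")
    stream.write("END\n")
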