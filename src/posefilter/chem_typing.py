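"""Covalent-bond perception, SYBYL atom typing and protein-fragment enumeration.

Ligand atoms are labelled with SYBYL mol2 atom types (C.3, C.ar, O.2, ...)
through a self-contained, versioned rule table so that typing is
deterministic and testable without an external chemistry toolkit.  Protein
fragments are all triples of covalently linked heavy atoms; the first atom
of each fragment is the distance anchor used by contact extraction.

Because the package operates on heavy atoms only (hydrogens stripped), bond
orders are not available from valence bookkeeping; the rule table infers
double/triple-bond character from interatomic distances, which is reliable
at crystallographic geometry.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .complex_io import Atom

logger = logging.getLogger(__name__)

__all__ = [
    "ProteinFragment",
    "SYBYL_TABLE_VERSION",
    "FRAGMENT_ORIENTATION_CONVENTION",
    "assign_sybyl_types",
    "enumerate_fragments",
    "perceive_bonds",
]

#: Version tag of the shipped SYBYL rule table; recorded in every pattern
#: library so mixed-convention scoring can be refused.
SYBYL_TABLE_VERSION = "posefilter-sybyl-1.0"

#: Canonical fragment orientation: each undirected 3-atom path is emitted
#: once, oriented so the (residue name, atom name) endpoint-first triple is
#: lexicographically smallest (atom-index tie-break).
FRAGMENT_ORIENTATION_CONVENTION = "lex-smallest-endpoint-v1"

# Covalent radii (Angstrom); pairs bond when closer than r_i + r_j + tolerance.
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57,
    "P": 1.07, "S": 1.05, "Cl": 1.02, "Br": 1.20, "I": 1.39, "B": 0.84,
    "Se": 1.20, "Si": 1.11,
}
_DEFAULT_RADIUS = 0.77
BOND_TOLERANCE = 0.45

# Heavy-atom connectivity of the 20 standard residues (backbone implied).
_BACKBONE = [("N", "CA"), ("CA", "C"), ("C", "O"), ("C", "OXT")]
AMINO_ACID_BONDS: dict[str, list[tuple[str, str]]] = {
    "ALA": [("CA", "CB")],
    "ARG": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "NE"),
            ("NE", "CZ"), ("CZ", "NH1"), ("CZ", "NH2")],
    "ASN": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "ND2")],
    "ASP": [("CA", "CB"), ("CB", "CG"), ("CG", "OD1"), ("CG", "OD2")],
    "CYS": [("CA", "CB"), ("CB", "SG")],
    "GLN": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "NE2")],
    "GLU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "OE1"),
            ("CD", "OE2")],
    "GLY": [],
    "HIS": [("CA", "CB"), ("CB", "CG"), ("CG", "ND1"), ("CG", "CD2"),
            ("ND1", "CE1"), ("CD2", "NE2"), ("CE1", "NE2")],
    "ILE": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2"), ("CG1", "CD1")],
    "LEU": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2")],
    "LYS": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "CE"),
            ("CE", "NZ")],
    "MET": [("CA", "CB"), ("CB", "CG"), ("CG", "SD"), ("SD", "CE")],
    "PHE": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ")],
    "PRO": [("CA", "CB"), ("CB", "CG"), ("CG", "CD"), ("CD", "N")],
    "SER": [("CA", "CB"), ("CB", "OG")],
    "THR": [("CA", "CB"), ("CB", "OG1"), ("CB", "CG2")],
    "TRP": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "NE1"), ("NE1", "CE2"), ("CD2", "CE2"), ("CD2", "CE3"),
            ("CE2", "CZ2"), ("CE3", "CZ3"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    "TYR": [("CA", "CB"), ("CB", "CG"), ("CG", "CD1"), ("CG", "CD2"),
            ("CD1", "CE1"), ("CD2", "CE2"), ("CE1", "CZ"), ("CE2", "CZ"),
            ("CZ", "OH")],
    "VAL": [("CA", "CB"), ("CB", "CG1"), ("CB", "CG2")],
}

_PEPTIDE_BOND_MAX = 2.0  # sanity bound on the C(i)-N(i+1) distance


def _radius(element: str) -> float:
    return COVALENT_RADII.get(element.capitalize(), _DEFAULT_RADIUS)


def _distance_bonds(atoms: Sequence[Atom], indices: Sequence[int]) -> set[tuple[int, int]]:
    if len(indices) < 2:
        return set()
    coords = np.array([atoms[i].coords for i in indices])
    radii = np.array([_radius(atoms[i].element) for i in indices])
    tree = cKDTree(coords)
    max_r = 2.0 * radii.max() + BOND_TOLERANCE
    bonds: set[tuple[int, int]] = set()
    for a, b in tree.query_pairs(max_r):
        d = float(np.linalg.norm(coords[a] - coords[b]))
        if d <= radii[a] + radii[b] + BOND_TOLERANCE:
            bonds.add(tuple(sorted((indices[a], indices[b]))))
    return bonds


def perceive_bonds(atoms: Sequence[Atom], mode: str = "distance") -> list[tuple[int, int]]:
    """Perceive covalent bonds among heavy atoms.

    ``distance`` mode bonds pairs with separation at most the sum of
    covalent radii plus 0.45 A.  ``template`` mode looks residues up in the
    shipped amino-acid connectivity table (including the peptide C-N link
    between sequence-adjacent residues); residues absent from the table
    fall back to distance perception with a logged warning.
    """
    if any(a.is_hydrogen for a in atoms):
        raise ValueError("perceive_bonds expects hydrogen-stripped atoms")
    if mode == "distance":
        return sorted(_distance_bonds(atoms, range(len(atoms))))
    if mode != "template":
        raise ValueError(f"unknown bond-perception mode {mode!r}")

    bonds: set[tuple[int, int]] = set()
    by_residue: dict = {}
    for idx, atom in enumerate(atoms):
        by_residue.setdefault(atom.residue, {})[atom.name] = idx
    residues = list(by_residue)
    for res, name_map in by_residue.items():
        template = AMINO_ACID_BONDS.get(res.name)
        if template is None:
            logger.warning(
                "residue %s not in template table; falling back to distance mode",
                res.name,
            )
            bonds |= _distance_bonds(atoms, sorted(name_map.values()))
            continue
        for n1, n2 in itertools.chain(_BACKBONE, template):
            if n1 in name_map and n2 in name_map:
                bonds.add(tuple(sorted((name_map[n1], name_map[n2]))))
    # Peptide links between sequence-adjacent residues in the same chain.
    for r1, r2 in itertools.combinations(residues, 2):
        if r1.chain != r2.chain or abs(r1.number - r2.number) != 1:
            continue
        prev, nxt = (r1, r2) if r1.number < r2.number else (r2, r1)
        c = by_residue[prev].get("C")
        n = by_residue[nxt].get("N")
        if c is not None and n is not None:
            d = np.linalg.norm(atoms[c].coords - atoms[n].coords)
            if d <= _PEPTIDE_BOND_MAX:
                bonds.add(tuple(sorted((c, n))))
    return sorted(bonds)


# --- SYBYL typing ---------------------------------------------------------

# Distance thresholds (A) below which a bond is treated as double/triple.
_DOUBLE_BOND_MAX = {
    frozenset(["C", "C"]): 1.43,
    frozenset(["C", "N"]): 1.36,
    frozenset(["C", "O"]): 1.30,
    frozenset(["C", "S"]): 1.71,
    frozenset(["N", "N"]): 1.32,
    frozenset(["N", "O"]): 1.28,
    frozenset(["S", "O"]): 1.50,
}
_TRIPLE_BOND_MAX = {
    frozenset(["C", "C"]): 1.25,
    frozenset(["C", "N"]): 1.20,
    frozenset(["N", "N"]): 1.15,
}

_HALOGENS = {"F": "F", "Cl": "Cl", "Br": "Br", "I": "I"}
_PLAIN_ELEMENTS = {"Na", "K", "Ca", "Li", "Al", "Si", "Zn", "Mg", "Fe", "Mn",
                   "Cu", "Se", "B"}

_PLANARITY_RMS_TOL = 0.1  # A, RMS deviation from the best-fit ring plane


def _ring_is_aromatic(ring: Sequence[int], coords: np.ndarray,
                      elements: Sequence[str], degree: Sequence[int]) -> bool:
    if not (5 <= len(ring) <= 7):
        return False
    for i in ring:
        if elements[i] not in ("C", "N", "O", "S"):
            return False
        if degree[i] > 3:  # sp3-like center cannot be aromatic
            return False
    pts = coords[list(ring)]
    centered = pts - pts.mean(axis=0)
    # RMS distance from the best-fit plane = smallest singular value / sqrt(n)
    s = np.linalg.svd(centered, compute_uv=False)
    rms = s[-1] / np.sqrt(len(ring))
    return bool(rms <= _PLANARITY_RMS_TOL)


def _find_aromatic_atoms(atoms: Sequence[Atom], bonds: Iterable[tuple[int, int]],
                         degree: Sequence[int]) -> set[int]:
    import networkx as nx

    g = nx.Graph()
    g.add_nodes_from(range(len(atoms)))
    g.add_edges_from(bonds)
    coords = np.array([a.coords for a in atoms]).reshape(-1, 3)
    elements = [a.element for a in atoms]
    aromatic: set[int] = set()
    for ring in nx.cycle_basis(g):
        if _ring_is_aromatic(ring, coords, elements, degree):
            aromatic.update(ring)
    return aromatic


def _bond_class(a: Atom, b: Atom) -> str:
    pair = frozenset([a.element, b.element])
    d = float(np.linalg.norm(a.coords - b.coords))
    if d <= _TRIPLE_BOND_MAX.get(pair, 0.0):
        return "triple"
    if d <= _DOUBLE_BOND_MAX.get(pair, 0.0):
        return "double"
    return "single"


def assign_sybyl_types(
    ligand_atoms: Sequence[Atom],
    ligand_bonds: Iterable[tuple[int, int]],
    aromatic_atoms: set[int] | None = None,
) -> list[str]:
    """Assign one SYBYL type code per heavy atom via the shipped rule table.

    Rules are keyed on element, aromatic-ring membership (SSSR rings of
    size 5-7, planar to 0.1 A RMS, degree-consistent), connectivity degree
    and distance-inferred bond order.  Atoms no rule matches are typed
    ``Du``.  Pass ``aromatic_atoms`` to override ring perception.
    """
    bonds = [tuple(b) for b in ligand_bonds]
    n = len(ligand_atoms)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in bonds:
        adj[i].append(j)
        adj[j].append(i)
    degree = [len(a) for a in adj]
    if aromatic_atoms is None:
        aromatic_atoms = _find_aromatic_atoms(ligand_atoms, bonds, degree)

    def bond_classes(i: int) -> list[tuple[int, str]]:
        return [(j, _bond_class(ligand_atoms[i], ligand_atoms[j])) for j in adj[i]]

    types: list[str] = []
    for i, atom in enumerate(ligand_atoms):
        el = atom.element.capitalize()
        classes = bond_classes(i)
        has_triple = any(c == "triple" for _, c in classes)
        has_double = any(c == "double" for _, c in classes)
        if el in _HALOGENS:
            types.append(_HALOGENS[el])
        elif el == "C":
            if i in aromatic_atoms:
                types.append("C.ar")
            elif has_triple:
                types.append("C.1")
            elif has_double:
                types.append("C.2")
            else:
                types.append("C.3")
        elif el == "N":
            if i in aromatic_atoms:
                types.append("N.ar")
            elif has_triple:
                types.append("N.1")
            elif _is_amide_nitrogen(i, adj, ligand_atoms):
                types.append("N.am")
            elif has_double:
                types.append("N.2")
            elif degree[i] >= 4:
                types.append("N.4")
            else:
                types.append("N.3")
        elif el == "O":
            if _is_carboxylate_oxygen(i, adj, degree, ligand_atoms):
                types.append("O.co2")
            elif has_double:
                types.append("O.2")
            else:
                types.append("O.3")
        elif el == "S":
            short_o = sum(
                1 for j, c in classes
                if ligand_atoms[j].element == "O" and c == "double"
            )
            if short_o >= 2:
                types.append("S.o2")
            elif short_o == 1:
                types.append("S.o")
            elif has_double:
                types.append("S.2")
            else:
                types.append("S.3")
        elif el == "P":
            types.append("P.3")
        elif el in _PLAIN_ELEMENTS:
            types.append(el)
        else:
            types.append("Du")
    return types


def _is_amide_nitrogen(i: int, adj, atoms) -> bool:
    for j in adj[i]:
        if atoms[j].element != "C":
            continue
        for k in adj[j]:
            if k == i:
                continue
            if atoms[k].element in ("O", "S") and \
                    _bond_class(atoms[j], atoms[k]) == "double":
                return True
    return False


def _is_carboxylate_oxygen(i: int, adj, degree, atoms) -> bool:
    if degree[i] != 1:
        return False
    (j,) = adj[i]
    if atoms[j].element != "C":
        return False
    terminal_o = [k for k in adj[j] if atoms[k].element == "O" and degree[k] == 1]
    return len(terminal_o) >= 2


# --- protein fragments ----------------------------------------------------


@dataclass(frozen=True)
class ProteinFragment:
    """Three covalently linked protein heavy atoms; atoms[0] is the anchor."""

    indices: tuple[int, int, int]
    type_key: tuple[str, str, str, str]

    def atoms(self, protein_atoms: Sequence[Atom]) -> tuple[Atom, Atom, Atom]:
        i, j, k = self.indices
        return protein_atoms[i], protein_atoms[j], protein_atoms[k]

    def coords(self, protein_atoms: Sequence[Atom]) -> np.ndarray:
        return np.array([protein_atoms[i].coords for i in self.indices])


def enumerate_fragments(
    protein_atoms: Sequence[Atom],
    protein_bonds: Iterable[tuple[int, int]],
) -> list[ProteinFragment]:
    """All simple 3-atom paths of the protein bond graph, each emitted once.

    Orientation follows :data:`FRAGMENT_ORIENTATION_CONVENTION`: the
    (residue name, atom name) triple read anchor-first is lexicographically
    minimal over the two directions, with the atom-index triple as the
    deterministic tie-break.  ``type_key`` is (anchor residue name, name of
    atom 1, name of atom 2, name of atom 3).
    """
    n = len(protein_atoms)
    adj: list[list[int]] = [[] for _ in range(n)]
    for i, j in protein_bonds:
        adj[i].append(j)
        adj[j].append(i)

    def label(i: int) -> tuple[str, str]:
        a = protein_atoms[i]
        return (a.residue.name, a.name)

    fragments: list[ProteinFragment] = []
    for mid in range(n):
        for a, c in itertools.combinations(sorted(adj[mid]), 2):
            fwd = (a, mid, c)
            rev = (c, mid, a)
            key_f = tuple(label(i) for i in fwd)
            key_r = tuple(label(i) for i in rev)
            path = fwd if (key_f, fwd) <= (key_r, rev) else rev
            anchor = protein_atoms[path[0]]
            type_key = (
                anchor.residue.name,
                protein_atoms[path[0]].name,
                protein_atoms[path[1]].name,
                protein_atoms[path[2]].name,
            )
            fragments.append(ProteinFragment(indices=path, type_key=type_key))
    fragments.sort(key=lambda f: f.indices)
    return fragments
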