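"""Deterministic synthetic complexes, corpora, pose sets and feature tables.

Every other module is testable without downloads: this module builds small
protein-ligand complexes out of pseudo-residue fragment templates placed on
a wide grid, plants Gaussian contact patterns with known ground truth,
perturbs ligands to exact RMSD targets, and draws separable / null /
monotone two-feature classification tables.

The geometry is deliberately minimal, not physical: fragments are bonded
heavy-atom triples ~20 A apart, so every ligand atom contacts exactly the
fragment it was planted on and bond perception cannot create spurious
links.  Generators are pure functions of (spec, seed); identical calls are
byte-identical.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from io import StringIO
from typing import Sequence

import numpy as np
import pandas as pd

from .complex_io import Atom, ComplexStructure, Residue, write_pdb

__all__ = [
    "FixtureSpec",
    "PlantedPattern",
    "make_feature_table",
    "make_planted_pattern_corpus",
    "make_pose_set",
    "make_toy_complex",
    "toy_complex_pdb",
]

#: Fragment template: three bonded heavy atoms (1.5 A bonds, bent), with the
#: anchor at the local origin.  F1-F3 are 2.6 A apart, so distance-mode bond
#: perception recovers exactly the chain F1-F2-F3.
_FRAGMENT_TEMPLATE = np.array(
    [[0.0, 0.0, 0.0], [1.5, 0.0, 0.0], [2.25, 1.3, 0.0]]
)
_FRAGMENT_ATOM_NAMES = ("F1", "F2", "F3")
_GRID_SPACING = 20.0  # A; >> cutoff + max ligand offset
_MIN_ATOM_SEPARATION = 0.5  # A


@dataclass(frozen=True)
class PlantedPattern:
    """One Gaussian contact pattern to plant in a corpus.

    ``resname`` selects the fragment type (hence the group key together
    with the ligand element); points are drawn from N(mean, stdev^2 I) in
    the fragment frame and re-drawn until they fall inside the contact
    cutoff sphere.
    """

    resname: str
    mean: tuple[float, float, float]
    stdev: float
    n_points: int
    element: str = "C"

    def __post_init__(self) -> None:
        if self.stdev <= 0:
            raise ValueError("stdev must be positive")
        if self.n_points < 0:
            raise ValueError("n_points must be non-negative")


@dataclass
class FixtureSpec:
    seed: int = 0
    n_fragments: int = 1
    n_ligand_atoms: int = 0
    planted_patterns: list[PlantedPattern] = field(default_factory=list)
    decoy_fraction: float = 0.0
    noise_stdev: float = 0.0
    # Placement control used by the toy-complex generator: each entry is
    # (fragment index, anchor distance in A) or (fragment index, 3-vector
    # offset in the global frame).
    ligand_placements: list[tuple] | None = None
    fragment_resnames: list[str] | None = None

    def __post_init__(self) -> None:
        if self.n_fragments < 0 or self.n_ligand_atoms < 0:
            raise ValueError("counts must be non-negative")
        if not 0.0 <= self.decoy_fraction <= 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1]")
        if self.noise_stdev < 0:
            raise ValueError("noise_stdev must be non-negative")


def _grid_positions(n: int) -> np.ndarray:
    """First n sites of a cubic lattice with _GRID_SPACING pitch."""
    side = max(1, int(np.ceil(n ** (1.0 / 3.0))))
    sites = list(itertools.islice(itertools.product(range(side + 1), repeat=3), n))
    return np.array(sites, dtype=float)[:n] * _GRID_SPACING


def _build_fragments(resnames: Sequence[str]) -> tuple[list[Atom], list[tuple[int, int]]]:
    offsets = _grid_positions(len(resnames))
    atoms: list[Atom] = []
    bonds: list[tuple[int, int]] = []
    serial = 0
    for fi, resname in enumerate(resnames):
        base = len(atoms)
        for local, name in zip(_FRAGMENT_TEMPLATE, _FRAGMENT_ATOM_NAMES):
            serial += 1
            atoms.append(
                Atom(
                    serial=serial,
                    name=name,
                    element="C",
                    coords=offsets[fi] + local,
                    residue=Residue(chain="A", number=fi + 1, icode="", name=resname),
                    is_hetero=False,
                )
            )
        bonds.extend([(base, base + 1), (base + 1, base + 2)])
    return atoms, bonds


def _ligand_atom(serial: int, coords: np.ndarray, element: str = "C") -> Atom:
    return Atom(
        serial=serial,
        name=f"{element.upper()}{serial}"[:4],
        element=element,
        coords=coords,
        residue=Residue(chain="L", number=1, icode="", name="LIG"),
        is_hetero=True,
    )


def _check_separation(coords: np.ndarray) -> None:
    if len(coords) < 2:
        return
    from scipy.spatial.distance import pdist

    if pdist(coords).min() < _MIN_ATOM_SEPARATION:
        raise ValueError(
            f"infeasible geometry: atoms closer than {_MIN_ATOM_SEPARATION} A"
        )


def make_toy_complex(spec: FixtureSpec) -> ComplexStructure:
    """A minimal parseable complex with controlled ligand placements.

    Fragments sit on a 20 A grid; each ``ligand_placements`` entry puts one
    ligand atom at an exact anchor distance (random direction from the
    seeded RNG) or at an explicit offset from the anchor.  Remaining
    ligand atoms (up to ``n_ligand_atoms``) are placed at random distances
    in [2, 4.5] A from cyclically chosen anchors.
    """
    rng = np.random.default_rng(spec.seed)
    resnames = spec.fragment_resnames or ["FRA"] * spec.n_fragments
    if len(resnames) != spec.n_fragments:
        raise ValueError("fragment_resnames length must equal n_fragments")
    protein, protein_bonds = _build_fragments(resnames)
    anchors = np.array(
        [protein[3 * i].coords for i in range(spec.n_fragments)]
    ).reshape(-1, 3)

    placements = list(spec.ligand_placements or [])
    n_extra = max(0, spec.n_ligand_atoms - len(placements))
    for k in range(n_extra):
        placements.append((k % max(1, spec.n_fragments), float(rng.uniform(2.0, 4.5))))

    ligand: list[Atom] = []
    serial = len(protein)
    for frag_idx, placement in placements:
        if not 0 <= frag_idx < spec.n_fragments:
            raise ValueError(f"fragment index {frag_idx} out of range")
        if np.isscalar(placement):
            direction = rng.normal(size=3)
            direction /= np.linalg.norm(direction)
            offset = float(placement) * direction
        else:
            offset = np.asarray(placement, dtype=float).reshape(3)
        serial += 1
        pos = anchors[frag_idx] + offset
        if spec.noise_stdev > 0:
            pos = pos + rng.normal(scale=spec.noise_stdev, size=3)
        ligand.append(_ligand_atom(serial, pos))

    # Overlap check within each molecule: cross protein-ligand proximity is
    # harmless (bonds are perceived per molecule; contacts use only the
    # anchor distance), but coincident atoms within a molecule would
    # corrupt bond perception.
    _check_separation(np.array([a.coords for a in ligand]).reshape(-1, 3))
    _check_separation(np.array([a.coords for a in protein]).reshape(-1, 3))
    return ComplexStructure(
        protein_atoms=protein,
        ligand_atoms=ligand,
        ligand_bonds=[],
        protein_bonds=protein_bonds,
        source_id=f"toy-{spec.seed}",
    )


def toy_complex_pdb(spec: FixtureSpec) -> str:
    """PDB text of :func:`make_toy_complex`; byte-identical for equal specs."""
    buf = StringIO()
    write_pdb(make_toy_complex(spec), buf)
    return buf.getvalue()


def _sample_in_ball(rng: np.random.Generator, mean: np.ndarray, stdev: float,
                    radius: float = 4.9) -> np.ndarray:
    for _ in range(1000):
        x = rng.normal(loc=mean, scale=stdev, size=3)
        if np.linalg.norm(x) <= radius and np.linalg.norm(x) >= 1.0:
            return x
    raise ValueError("planted pattern mean too far outside the contact sphere")


def make_planted_pattern_corpus(
    spec: FixtureSpec,
    n_complexes: int = 3,
) -> tuple[list[ComplexStructure], pd.DataFrame]:
    """Training corpus whose pooled contact groups are planted Gaussians.

    Each planted point becomes its own fragment copy (axis-aligned, so the
    fragment frame is the global frame) plus one ligand atom at
    anchor + point.  Decoy contacts (``decoy_fraction`` of the planted
    total) are uniform directions at 2.5-4.9 A around fragments of the
    reserved decoy residue type ``DEC``.  Returns the complexes and a
    ground-truth table (complex, fragment residue, planted offset, source
    pattern label).
    """
    if not spec.planted_patterns:
        raise ValueError("at least one planted pattern is required")
    rng = np.random.default_rng(spec.seed)
    entries: list[tuple[str, np.ndarray, str]] = []  # (resname, offset, label)
    for p, pattern in enumerate(spec.planted_patterns):
        mean = np.asarray(pattern.mean, dtype=float)
        for _ in range(pattern.n_points):
            offset = _sample_in_ball(rng, mean, pattern.stdev)
            entries.append((pattern.resname, offset, f"pattern-{p}"))
    n_decoys = int(round(spec.decoy_fraction * len(entries)))
    for _ in range(n_decoys):
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        offset = direction * rng.uniform(2.5, 4.9)
        entries.append(("DEC", offset, "decoy"))
    rng.shuffle(entries)

    chunks = np.array_split(np.arange(len(entries)), max(1, n_complexes))
    complexes: list[ComplexStructure] = []
    truth_rows = []
    for ci, chunk in enumerate(chunks):
        if len(chunk) == 0:
            continue
        resnames = [entries[i][0] for i in chunk]
        placements = [(k, entries[i][1]) for k, i in enumerate(chunk)]
        sub = FixtureSpec(
            seed=spec.seed + ci + 1,
            n_fragments=len(chunk),
            n_ligand_atoms=len(chunk),
            ligand_placements=placements,
            fragment_resnames=resnames,
        )
        cplx = make_toy_complex(sub)
        cplx.source_id = f"corpus-{spec.seed}-{ci}"
        complexes.append(cplx)
        for k, i in enumerate(chunk):
            truth_rows.append(
                {
                    "complex": cplx.source_id,
                    "fragment_resname": entries[i][0],
                    "label": entries[i][2],
                    "lx": entries[i][1][0],
                    "ly": entries[i][1][1],
                    "lz": entries[i][1][2],
                }
            )
    return complexes, pd.DataFrame(truth_rows)


def make_pose_set(
    reference: ComplexStructure,
    rmsd_targets: Sequence[float],
    seed: int = 0,
) -> list[tuple[ComplexStructure, float]]:
    """Perturbed copies of a complex hitting exact ligand-RMSD targets.

    Each pose displaces every ligand atom by ``target`` times a unit
    direction drawn per atom, so the in-place RMSD equals the target
    exactly (to floating point).  The receptor is untouched.
    """
    poses = []
    rng = np.random.default_rng(seed)
    ref_coords = reference.ligand_coords()
    n = len(reference.ligand_atoms)
    if n == 0:
        raise ValueError("reference complex has no ligand atoms")
    for t, target in enumerate(rmsd_targets):
        if target < 0:
            raise ValueError("RMSD targets must be non-negative")
        directions = rng.normal(size=(n, 3))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        new_coords = ref_coords + target * directions
        ligand = [
            Atom(
                serial=a.serial,
                name=a.name,
                element=a.element,
                coords=new_coords[i],
                residue=a.residue,
                is_hetero=True,
            )
            for i, a in enumerate(reference.ligand_atoms)
        ]
        pose = ComplexStructure(
            protein_atoms=list(reference.protein_atoms),
            ligand_atoms=ligand,
            ligand_bonds=list(reference.ligand_bonds),
            protein_bonds=list(reference.protein_bonds),
            source_id=f"{reference.source_id}-pose{t}",
        )
        achieved = float(
            np.sqrt(np.mean(np.sum((new_coords - ref_coords) ** 2, axis=1)))
        )
        poses.append((pose, achieved))
    return poses


def make_feature_table(
    kind: str,
    n: int,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Two-feature (pattern_num, pattern_ratio) tables with known structure.

    ``separable``: disjoint positive/negative clouds (high count + high
    ratio vs low/low).  ``null``: features and labels independent.
    ``monotone``: label true iff ratio > 0.5, count uninformative.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    rng = np.random.default_rng(seed)
    if kind == "separable":
        n_pos = n // 2
        pos = np.column_stack(
            [rng.integers(600, 900, n_pos), rng.uniform(0.8, 1.0, n_pos)]
        )
        neg = np.column_stack(
            [rng.integers(0, 200, n - n_pos), rng.uniform(0.0, 0.3, n - n_pos)]
        )
        X = np.vstack([pos, neg]).astype(float)
        y = np.concatenate([np.ones(n_pos, bool), np.zeros(n - n_pos, bool)])
    elif kind == "null":
        X = np.column_stack([rng.integers(0, 1000, n), rng.uniform(0, 1, n)]).astype(float)
        y = rng.integers(0, 2, n).astype(bool)
        while len(np.unique(y)) < 2:  # tiny-n guard; deterministic continuation
            y = rng.integers(0, 2, n).astype(bool)
    elif kind == "monotone":
        ratio = rng.uniform(0, 1, n)
        X = np.column_stack([rng.integers(0, 1000, n), ratio]).astype(float)
        y = ratio > 0.5
    else:
        raise ValueError(f"unknown feature-table kind {kind!r}")
    order = rng.permutation(n)
    return X[order], y[order]
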