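"""Interaction-pair extraction and grouping.

An interaction pair is one ligand heavy atom together with one protein
fragment (three covalently linked heavy atoms) whose anchor — the first
fragment atom — lies within the distance cutoff (default 5.0 A, inclusive)
of the ligand atom.  Each pair carries the ligand atom's position expressed
in the fragment's local orthonormal frame, a rotation/translation-invariant
3-vector that downstream mixture modelling clusters.

Pairs are grouped by (SYBYL atom type of the ligand atom, fragment type
key); each group is one statistical population of contact geometries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import cKDTree

from .chem_typing import ProteinFragment
from .complex_io import ComplexStructure

__all__ = [
    "FRAME_CONVENTION",
    "GroupKey",
    "InteractionPair",
    "extract_interaction_pairs",
    "fragment_local_frame",
    "group_pairs",
]

#: Local-frame convention identifier, recorded in pattern-library metadata.
#: origin = anchor; x along anchor->atom2; y in the fragment plane with a
#: positive component toward atom3; z = x cross y.
FRAME_CONVENTION = "anchor-x2-plane3-v1"

_COLLINEAR_TOL = 1e-6

GroupKey = tuple[str, tuple[str, str, str, str]]


@dataclass(frozen=True)
class InteractionPair:
    """One ligand atom paired with one protein fragment within the cutoff."""

    ligand_atom_index: int
    fragment: ProteinFragment
    distance: float
    local_coords: tuple[float, float, float]
    group_key: GroupKey


def fragment_local_frame(
    fragment_coords: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, bool]:
    """Orthonormal frame of a 3-atom fragment.

    Parameters
    ----------
    fragment_coords:
        (3, 3) array of anchor, atom2, atom3 positions.

    Returns
    -------
    origin : (3,) anchor position.
    axes : (3, 3) array with rows x, y, z of a right-handed frame.
    collinear : True when the deterministic fallback y axis was used
        because the three atoms are (near-)collinear.
    """
    p = np.asarray(fragment_coords, dtype=float)
    origin = p[0]
    x = p[1] - origin
    nx = np.linalg.norm(x)
    if nx < _COLLINEAR_TOL:
        raise ValueError("fragment anchor and second atom coincide")
    x = x / nx
    v = p[2] - origin
    y = v - np.dot(v, x) * x
    ny = np.linalg.norm(y)
    collinear = bool(ny < _COLLINEAR_TOL)
    if collinear:
        # Deterministic fallback: smallest-index global axis not parallel to x.
        for axis in np.eye(3):
            cand = axis - np.dot(axis, x) * x
            nc = np.linalg.norm(cand)
            if nc > 0.5:  # |sin| of the angle to x; excludes near-parallel axes
                y = cand / nc
                break
    else:
        y = y / ny
    z = np.cross(x, y)
    return origin, np.vstack([x, y, z]), collinear


def extract_interaction_pairs(
    structure: ComplexStructure,
    sybyl_types: Sequence[str],
    fragments: Sequence[ProteinFragment],
    cutoff: float = 5.0,
) -> list[InteractionPair]:
    """Every (ligand atom, fragment) pair with anchor distance <= cutoff.

    The cutoff comparison is inclusive.  Pairs are returned in deterministic
    order: ligand atom index first, then fragment enumeration order.  A
    k-d tree over fragment anchors accelerates the scan; the final distance
    test is the same exact comparison a brute-force scan would apply.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if len(sybyl_types) != len(structure.ligand_atoms):
        raise ValueError("one SYBYL type per ligand atom is required")
    if not structure.ligand_atoms or not fragments:
        return []

    anchors = np.array(
        [structure.protein_atoms[f.indices[0]].coords for f in fragments]
    )
    lig = structure.ligand_coords()
    tree = cKDTree(anchors)
    # Query slightly beyond the cutoff, then apply the exact inclusive test.
    candidates = tree.query_ball_point(lig, r=cutoff * (1.0 + 1e-9) + 1e-9)

    frames = [fragment_local_frame(f.coords(structure.protein_atoms)) for f in fragments]
    pairs: list[InteractionPair] = []
    for li, frag_ids in enumerate(candidates):
        for fi in sorted(frag_ids):
            d = float(np.linalg.norm(lig[li] - anchors[fi]))
            if d <= cutoff:
                origin, axes, _ = frames[fi]
                local = axes @ (lig[li] - origin)
                pairs.append(
                    InteractionPair(
                        ligand_atom_index=li,
                        fragment=fragments[fi],
                        distance=d,
                        local_coords=tuple(local.tolist()),
                        group_key=(sybyl_types[li], fragments[fi].type_key),
                    )
                )
    return pairs


def group_pairs(
    pairs: Sequence[InteractionPair],
) -> dict[GroupKey, list[InteractionPair]]:
    """Partition pairs by (SYBYL type, fragment type key).

    Every pair lands in exactly one group; group sizes sum to the input
    length.  Keys are returned in sorted order for reproducibility.
    """
    groups: dict[GroupKey, list[InteractionPair]] = {}
    for pair in pairs:
        groups.setdefault(pair.group_key, []).append(pair)
    return dict(sorted(groups.items()))
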