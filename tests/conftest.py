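"""Shared builders for the test suite.

All fixtures are generated programmatically; nothing is read from disk.
"""

from __future__ import annotations

import numpy as np
import pytest

from posefilter.complex_io import Atom, ComplexStructure, Residue


def make_atom(
    serial: int,
    coords,
    element: str = "C",
    name: str | None = None,
    resname: str = "LIG",
    resnum: int = 1,
    chain: str = "A",
    hetero: bool = False,
    altloc: str = "",
    occupancy: float = 1.0,
) -> Atom:
    return Atom(
        serial=serial,
        name=name or f"{element.upper()}{serial}",
        element=element,
        coords=np.asarray(coords, dtype=float),
        residue=Residue(chain=chain, number=resnum, icode="", name=resname),
        is_hetero=hetero,
        altloc=altloc,
        occupancy=occupancy,
    )


def random_protein_atoms(rng: np.random.Generator, n: int, spread: float = 30.0):
    """n protein atoms at random positions, one per residue."""
    coords = rng.uniform(-spread, spread, size=(n, 3))
    return [
        make_atom(i + 1, coords[i], element="C", name="CX", resname="RND", resnum=i + 1)
        for i in range(n)
    ]


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260927)
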