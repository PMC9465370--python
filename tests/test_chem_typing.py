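"""Bond perception, SYBYL typing and fragment enumeration."""

import itertools

import numpy as np
import pytest

from posefilter.chem_typing import (
    BOND_TOLERANCE,
    COVALENT_RADII,
    assign_sybyl_types,
    enumerate_fragments,
    perceive_bonds,
)

from conftest import make_atom


def brute_force_distance_bonds(atoms):
    bonds = set()
    for i, j in itertools.combinations(range(len(atoms)), 2):
        d = np.linalg.norm(atoms[i].coords - atoms[j].coords)
        r = (
            COVALENT_RADII.get(atoms[i].element, 0.77)
            + COVALENT_RADII.get(atoms[j].element, 0.77)
            + BOND_TOLERANCE
        )
        if d <= r:
            bonds.add((i, j))
    return bonds


class TestPerceiveBonds:
    def test_glycine_template_connectivity(self):
        coords = {
            "N": (0.0, 0.0, 0.0),
            "CA": (1.46, 0.0, 0.0),
            "C": (2.0, 1.42, 0.0),
            "O": (1.3, 2.4, 0.0),
        }
        atoms = [
            make_atom(i + 1, xyz, name=name, element=name[0], resname="GLY")
            for i, (name, xyz) in enumerate(coords.items())
        ]
        bonds = perceive_bonds(atoms, mode="template")
        names = {frozenset((atoms[i].name, atoms[j].name)) for i, j in bonds}
        assert names == {
            frozenset(("N", "CA")),
            frozenset(("CA", "C")),
            frozenset(("C", "O")),
        }

    def test_peptide_link_between_adjacent_residues(self):
        atoms = [
            make_atom(1, (0, 0, 0), name="CA", resname="GLY", resnum=1),
            make_atom(2, (1.5, 0, 0), name="C", resname="GLY", resnum=1),
            make_atom(3, (2.8, 0.2, 0), name="N", element="N", resname="GLY", resnum=2),
            make_atom(4, (4.0, 1.0, 0), name="CA", resname="GLY", resnum=2),
        ]
        bonds = perceive_bonds(atoms, mode="template")
        assert (1, 2) in bonds  # the C(i)-N(i+1) backbone link

    def test_distant_atoms_not_bonded(self):
        atoms = [make_atom(1, (0, 0, 0)), make_atom(2, (10, 0, 0))]
        assert perceive_bonds(atoms, mode="distance") == []

    def test_unknown_residue_falls_back_to_distance(self, caplog):
        atoms = [
            make_atom(1, (0, 0, 0), name="Q1", resname="XXX"),
            make_atom(2, (1.5, 0, 0), name="Q2", resname="XXX"),
        ]
        with caplog.at_level("WARNING"):
            bonds = perceive_bonds(atoms, mode="template")
        assert bonds == [(0, 1)]
        assert any("XXX" in rec.message for rec in caplog.records)

    def test_rejects_hydrogens(self):
        with pytest.raises(ValueError, match="hydrogen"):
            perceive_bonds([make_atom(1, (0, 0, 0), "H")], mode="distance")

    @pytest.mark.parametrize("seed", range(5))
    def test_distance_mode_equals_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        elements = rng.choice(["C", "N", "O", "S"], size=n)
        coords = rng.uniform(0, 12, size=(n, 3))
        atoms = [make_atom(i + 1, coords[i], elements[i]) for i in range(n)]
        assert set(perceive_bonds(atoms, "distance")) == brute_force_distance_bonds(atoms)


def hexagon(radius=1.39, z=0.0):
    return [
        (radius * np.cos(a), radius * np.sin(a), z)
        for a in np.linspace(0, 2 * np.pi, 7)[:-1]
    ]


class TestSybylTyping:
    def test_aromatic_ring_carbons(self):
        atoms = [make_atom(i + 1, xyz, "C") for i, xyz in enumerate(hexagon())]
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        assert assign_sybyl_types(atoms, bonds) == ["C.ar"] * 6

    def test_puckered_ring_is_not_aromatic(self):
        coords = hexagon()
        coords = [(x, y, 0.4 * (-1) ** i) for i, (x, y, _) in enumerate(coords)]
        atoms = [make_atom(i + 1, xyz, "C") for i, xyz in enumerate(coords)]
        bonds = [(i, (i + 1) % 6) for i in range(6)]
        assert "C.ar" not in assign_sybyl_types(atoms, bonds)

    def test_hydroxyl_vs_carbonyl_oxygen(self):
        # C-OH at 1.43 A (single) and C=O at 1.22 A (double).
        atoms = [
            make_atom(1, (0, 0, 0), "C"),
            make_atom(2, (1.43, 0, 0), "O"),
            make_atom(3, (4, 0, 0), "C"),
            make_atom(4, (4, 1.22, 0), "O"),
        ]
        types = assign_sybyl_types(atoms, [(0, 1), (2, 3)])
        assert types[1] == "O.3"
        assert types[3] == "O.2"
        assert types[2] == "C.2"  # carbonyl carbon

    def test_carboxylate_oxygens(self):
        atoms = [
            make_atom(1, (0, 0, 0), "C"),
            make_atom(2, (1.26, 0, 0), "O"),
            make_atom(3, (-0.63, 1.09, 0), "O"),
        ]
        types = assign_sybyl_types(atoms, [(0, 1), (0, 2)])
        assert types[1] == types[2] == "O.co2"

    def test_amide_nitrogen(self):
        # N-C(=O)-C: the nitrogen bonded to a carbonyl carbon is N.am.
        atoms = [
            make_atom(1, (0, 0, 0), "N"),
            make_atom(2, (1.33, 0, 0), "C"),
            make_atom(3, (1.95, 1.05, 0), "O"),
            make_atom(4, (2.0, -1.3, 0), "C"),
        ]
        types = assign_sybyl_types(atoms, [(0, 1), (1, 2), (1, 3)])
        assert types[0] == "N.am"

    def test_halogens_and_fallback(self):
        atoms = [
            make_atom(1, (0, 0, 0), "Cl"),
            make_atom(2, (5, 0, 0), "Br"),
            make_atom(3, (10, 0, 0), "Xe"),
        ]
        assert assign_sybyl_types(atoms, []) == ["Cl", "Br", "Du"]

    def test_rule_table_applied_atom_by_atom(self):
        """Typing of a multi-group ligand equals manual rule application."""
        atoms = [
            make_atom(1, (0, 0, 0), "C"),       # sp3 carbon
            make_atom(2, (1.54, 0, 0), "C"),    # bonded sp3 carbon
            make_atom(3, (2.1, 1.43, 0), "O"),  # ether/hydroxyl oxygen
            make_atom(4, (-1.28, 1.28, 0), "S"),  # thioether sulfur (C-S 1.81)
            make_atom(5, (-3.0, 2.0, 0), "P"),  # phosphorus
            make_atom(6, (0.3, -1.47, 0), "N"),  # amine nitrogen (C-N 1.50)
        ]
        bonds = [(0, 1), (1, 2), (0, 3), (3, 4), (0, 5)]
        assert assign_sybyl_types(atoms, bonds) == [
            "C.3", "C.3", "O.3", "S.3", "P.3", "N.3",
        ]

    def test_permutation_equivariance(self, rng):
        atoms = [
            make_atom(1, (0, 0, 0), "C"),
            make_atom(2, (1.43, 0, 0), "O"),
            make_atom(3, (-1.54, 0, 0), "C"),
            make_atom(4, (-2.1, 1.22, 0.2), "O"),
        ]
        bonds = [(0, 1), (0, 2), (2, 3)]
        base = assign_sybyl_types(atoms, bonds)
        perm = rng.permutation(len(atoms))
        inverse = np.argsort(perm)
        shuffled = [atoms[i] for i in perm]
        remapped = [(inverse[i], inverse[j]) for i, j in bonds]
        permuted = assign_sybyl_types(shuffled, remapped)
        assert [permuted[inverse[i]] for i in range(len(atoms))] == base


def brute_force_three_paths(n, bonds):
    """All undirected simple 3-atom paths of a bond graph."""
    adj = {i: set() for i in range(n)}
    for i, j in bonds:
        adj[i].add(j)
        adj[j].add(i)
    paths = set()
    for mid in range(n):
        for a in adj[mid]:
            for c in adj[mid]:
                if a != c:
                    paths.add(frozenset([(a, mid, c), (c, mid, a)]))
    return paths


class TestEnumerateFragments:
    def _atoms(self, n):
        return [
            make_atom(i + 1, (2.0 * i, 0, 0), name=f"A{i}", resname="RES", resnum=1)
            for i in range(n)
        ]

    def test_linear_chain_has_two_fragments(self):
        frags = enumerate_fragments(self._atoms(4), [(0, 1), (1, 2), (2, 3)])
        assert len(frags) == 2
        assert {f.indices for f in frags} == {(0, 1, 2), (1, 2, 3)}

    def test_star_has_three_fragments(self):
        frags = enumerate_fragments(self._atoms(4), [(0, 1), (1, 2), (1, 3)])
        assert len(frags) == 3
        assert {frozenset((f.indices[0], f.indices[2])) for f in frags} == {
            frozenset((0, 2)), frozenset((0, 3)), frozenset((2, 3)),
        }

    def test_isolated_atoms_yield_nothing(self):
        assert enumerate_fragments(self._atoms(2), []) == []

    def test_canonical_orientation_is_lexicographically_minimal(self):
        atoms = [
            make_atom(1, (0, 0, 0), name="ZZ", resname="RES"),
            make_atom(2, (2, 0, 0), name="MM", resname="RES"),
            make_atom(3, (4, 0, 0), name="AA", resname="RES"),
        ]
        (frag,) = enumerate_fragments(atoms, [(0, 1), (1, 2)])
        assert frag.indices == (2, 1, 0)  # AA end first
        assert frag.type_key == ("RES", "AA", "MM", "ZZ")

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_path_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 40))
        possible = list(itertools.combinations(range(n), 2))
        k = int(rng.integers(0, min(len(possible), 3 * n)))
        chosen = [possible[i] for i in rng.choice(len(possible), size=k, replace=False)]
        frags = enumerate_fragments(self._atoms(n), chosen)
        expected = brute_force_three_paths(n, chosen)
        got = {frozenset([f.indices, f.indices[::-1]]) for f in frags}
        assert got == expected
        assert len(frags) == len(expected)  # each path emitted exactly once
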