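"""Extract and group interaction pairs from a complex.

Every ligand heavy atom within 5 A of a protein-fragment anchor (the first
atom of a covalently linked heavy-atom triple) forms one interaction pair,
carrying its position in the fragment's local frame.  Pairs sharing a
(SYBYL type, fragment type) key form one statistical group.
"""

from posefilter import group_pairs
from posefilter.pattern_library import extract_complex_pairs
from posefilter.synthetic_fixtures import FixtureSpec, make_toy_complex

complex_ = make_toy_complex(
    FixtureSpec(
        seed=7,
        n_fragments=3,
        ligand_placements=[(0, 3.0), (0, 4.5), (1, 5.0), (2, 6.5)],
    )
)
pairs = extract_complex_pairs(complex_)

print(f"{len(pairs)} interaction pairs (the 6.5 A placement is beyond the cutoff):")
for p in pairs:
    print(
        f"  ligand atom {p.ligand_atom_index} <-> fragment {p.fragment.type_key[0]}"
        f" at {p.distance:.2f} A, local frame coords "
        f"({p.local_coords[0]:+.2f}, {p.local_coords[1]:+.2f}, {p.local_coords[2]:+.2f})"
    )

groups = group_pairs(pairs)
print(f"{len(groups)} contact group(s); sizes:", [len(v) for v in groups.values()])
print("Each group is one population whose geometry the mixture model clusters.")
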