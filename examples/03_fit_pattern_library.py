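"""Fit a significant-interaction-pattern library on planted contacts.

A corpus is generated with two Gaussian contact patterns planted in
distinct groups (60 points each) plus 20% uniform decoy contacts.  The
variational Bayesian mixture should flag exactly two components as
significant (>= 20 member ligand atoms each).
"""

from posefilter import LibraryParams, build_pattern_library
from posefilter.synthetic_fixtures import (
    FixtureSpec,
    PlantedPattern,
    make_planted_pattern_corpus,
)

patterns = [
    PlantedPattern("P00", (2.0, 0.5, 0.5), stdev=0.3, n_points=60),
    PlantedPattern("P01", (-2.0, 1.0, -1.0), stdev=0.3, n_points=60),
]
corpus, truth = make_planted_pattern_corpus(
    FixtureSpec(seed=3, planted_patterns=patterns, decoy_fraction=0.2)
)
library = build_pattern_library(corpus, LibraryParams(seed=17))

print(f"training pairs: {library.metadata['training_set']['n_pairs']}")
print(f"contact groups: {len(library.components)}")
for comp in library.significant_components():
    mean = ", ".join(f"{v:+.2f}" for v in comp.mean)
    print(
        f"  significant pattern in group {comp.group_key[1][0]}: "
        f"{comp.member_count} members, mean ({mean}) A"
    )
print(
    "Member counts near 60 at the planted means show the mixture recovered "
    "the planted patterns; the uniform decoys formed no 20-member component."
)
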