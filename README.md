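# posefilter

Molecular docking is cheap and fast — and notoriously prone to
false-positive poses. `posefilter` screens docked protein–ligand poses
with *significant interaction patterns*: recurring contact geometries
learned from crystal structures of ligand-bound proteins. It is aimed at
computational chemists and structural bioinformaticians doing pose
rescoring or reverse docking (target fishing), where each candidate
receptor's best pose must be judged plausible or not.

## The method

An **interaction pair** is one ligand heavy atom together with one
**protein fragment** — three covalently linked protein heavy atoms —
whose first atom (the *anchor*) lies within 5 Å of the ligand atom.
Unlike typed interaction fingerprints (H-bonds, salt bridges,
π-stacking), generic atomic contacts subsume all of these at once.

Training pools pairs from many complexes and groups them by
(SYBYL atom type of the ligand atom, fragment type). Within each group
the ligand-atom positions, expressed in the fragment's local orthonormal
frame, are clustered with a variational Bayesian Gaussian mixture
(Dirichlet-process weight prior, full covariances):

    x | z=k  ~  N(mu_k, Sigma_k),      w ~ DP-stick-breaking prior

A component with **≥ 20 member ligand atoms** (hard argmax-responsibility
assignment) is a *significant interaction pattern*. A docked pose is then
summarized by two statistics:

- `pattern_num` — its interaction pairs assigned to significant patterns;
- `pattern_ratio` — their fraction of all its pairs.

Screening rules at full training scale: a candidate target requires
`pattern_num ≥ 600` **and** `pattern_ratio ≥ 0.8`; the Youden-optimal
single-feature cutoffs are 285 pairs and 0.679 ratio. A two-feature
classifier (gradient-boosted trees by default; LR/KNN/DT/RF also
available) fuses both statistics into the probability that the pose is
near-native (ligand RMSD ≤ 2.5 Å to the crystal pose).

The `evaluation` module reproduces the validation machinery: in-place
ligand RMSD, per-complex extreme-pose selection, empirical ROC with
Youden-index cutoffs, confusion metrics (accuracy, sensitivity,
specificity, PPV, NPV), seeded 70/30 train/test splitting, and the
five-family model comparison.

## Worked example

Fit a library on a synthetic corpus with two planted contact patterns
(60 points each, 20 % uniform decoy contacts), then score poses
(`examples/03_fit_pattern_library.py` and `examples/04_score_poses.py`):

```
training pairs: 144
contact groups: 3
  significant pattern in group P00: 60 members, mean (+2.01, +0.52, +0.50) A
  significant pattern in group P01: 50 members, mean (-1.99, +1.08, -0.93) A
```

Both planted Gaussians are recovered as significant patterns at their
planted means; the decoy contacts never accumulate 20 members. Scoring a
pattern-consistent pose and a decoy pose:

```
corpus-5-0: pattern_num=20 total=20 ratio=1.00 target_rule=False youden_num=False youden_ratio=True
decoy:      pattern_num=0  total=4  ratio=0.00 target_rule=False youden_num=False youden_ratio=False
```

The consistent pose keeps ratio 1.0 (every contact sits on a learned
pattern) while the decoy scores zero because its fragment chemistry was
never seen in training. Neither reaches the 600-pair count — that rule is
calibrated for libraries trained on hundreds of thousands of structures,
not a toy corpus.

A thin CLI wraps the same functions for shell use:

```sh
posefilter simulate --kind corpus --out corpus/ --seed 3
posefilter fit --complexes corpus/ --out library.json --seed 17
posefilter score --pose corpus/corpus-3-0.pdb --library library.json
posefilter box --in corpus/corpus-3-0.pdb --ligand LIG
```

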