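# Methods

This note documents the model, the conventions that make results
reproducible, the synthetic data the tests run on, and the design
choices made where the method left room.

## Contact model

A complex is reduced to heavy atoms (hydrogens and deuteriums stripped;
they are never re-added, since fragments and contacts are defined on
heavy atoms only). Protein covalent bonds come either from a shipped
amino-acid connectivity template (including peptide C–N links between
sequence-adjacent residues, sanity-bounded at 2.0 Å) or from distance
perception: two atoms bond when their separation is at most the sum of
covalent radii plus 0.45 Å. Ligand bonds always use distance perception
unless CONECT records are present.

A *protein fragment* is any simple path of three bonded heavy atoms.
Each undirected path is emitted exactly once, oriented so the
(residue name, atom name) triple read anchor-first is lexicographically
smallest (atom-index tie-break). The convention is versioned
(`lex-smallest-endpoint-v1`) and recorded in every library; scoring
refuses to mix conventions.

An *interaction pair* joins a ligand heavy atom to a fragment whose
anchor lies within the cutoff (default 5.0 Å, inclusive). The geometric
feature carried to clustering is the ligand atom's position in the
fragment's local frame: origin at the anchor, x toward the second atom,
y in the fragment plane with positive component toward the third atom,
z completing a right-handed basis. This 3-vector is rotation- and
translation-invariant and preserves the anchor distance (|local| =
distance), making pooled contacts from differently oriented complexes
directly comparable. Near-collinear fragments (cross-product norm
< 1e-6) fall back to the smallest-index global axis not parallel to x,
deterministically. The frame definition is itself a documented
reconstruction: which geometric feature the original mixture model
clustered is not restated in the source method, so this
distance-preserving 3-D choice is the module's key gap-filling decision
and is fingerprinted in library metadata (`anchor-x2-plane3-v1`).

SYBYL atom types are assigned by a self-contained, versioned rule table
(`posefilter-sybyl-1.0`) keyed on element, aromatic-ring membership
(rings of size 5–7, members of degree ≤ 3, planar to 0.1 Å RMS from the
best-fit plane), connectivity degree, and bond order inferred from bond
lengths (e.g. C–O ≤ 1.30 Å reads as a double bond). Hydrogen-free
typing cannot use valence bookkeeping, which is why distances stand in
for orders; at crystallographic geometry this is reliable, and atoms no
rule matches sink to `Du`. Delegating to an external toolkit was
rejected so that typing is deterministic, versionable and testable.

## Pattern library

Pairs pooled over the training set are grouped by
(SYBYL type, fragment type key) and each group's local-frame point
cloud is fitted with `sklearn.mixture.BayesianGaussianMixture`:
Dirichlet-process weight prior, full covariances, at most 10 components
per group (never more than half the group size), covariance
regularization 1e-4 Å², tolerance 1e-3, 500 iterations, 10 restarts.
The weight prior's mean-precision hyperparameter is set to 1e-2 rather
than the library default of 1: the default shrinks component means
toward the group centroid strongly enough to merge clusters separated
by many standard deviations, and the relaxed prior together with the
extra restarts makes recovery of well-separated planted mixtures
(≥ 8σ apart, ≥ 50 points) reliable at the ≥ 95 % level the test suite
demands. Groups that defeat the fit numerically (collapsed or singleton
samples) retry with stiffer regularization and finally fall back to a
single moment-matched Gaussian, flagged as unconverged in metadata.

Member counts use hard assignment: each training point belongs to the
component maximizing weight × Gaussian density, computed from the
stored (weight, mean, covariance) triples — not from the variational
predictive — so a serialized library reproduces the fit-time assignment
rule exactly. A component with ≥ 20 members is significant; groups
smaller than 20 points therefore can never contain one, but are still
fitted for a uniform code path. Determinism: groups are fitted in
sorted key order with per-group seeds derived as
CRC-32(canonical key) XOR master-seed mod 2³¹.

`assign_pair` marks a docked pair significant iff its group exists in
the library and its argmax-responsibility component is significant. An
optional Mahalanobis gate (χ², 3 dof, 0.99 quantile) is exposed for
stringency experiments but off by default — without it any point in a
group whose nearest component is significant counts, which matches the
count-then-ratio semantics of the screening statistics.

## Scoring and thresholds

`pattern_num` and `pattern_ratio = pattern_num / total_pairs` (defined
0 for contact-free poses, which are flagged) feed three rules: the
conjunctive target rule (≥ 600 and ≥ 0.8), and the two independent
Youden-optimal cutoffs (285 pairs; 0.679 ratio). Those constants are
calibrated at full training scale (hundreds of thousands of PDB
complexes) and are configuration here, not quantities a toy corpus can
reproduce. The probability model trains on exactly the two features;
logistic regression and k-NN see standardized features (the count is
O(100), the ratio O(1)), the tree ensembles take them raw. Defaults:
sklearn's, except 200 trees for the forests and gradient boosting with
depth 4 and learning rate 0.1 — stated hyperparameters exist nowhere
upstream, so these are package configuration.

## Evaluation conventions

- Ligand RMSD is in-place (no superposition, no graph-symmetry
  correction), correspondence by atom order — the docking convention,
  since poses already live in the receptor frame.
- Near-native means RMSD ≤ 2.5 Å, inclusive.
- ROC: positives are called at score ≥ threshold, thresholds are the
  unique scores, AUC is the trapezoid over the empirical curve (equal to
  the normalized Mann–Whitney U with half credit for ties — asserted in
  tests), and Youden ties break toward the smallest threshold.
- Confusion metrics with vanishing denominators return NaN markers,
  never raise.
- `split_train_test` shuffles with a seeded generator and cuts at
  round(n·fraction); the shipped default fraction 0.7 maps 1,252 items
  to 876/376. An optional grouping key keeps the two poses drawn from
  one docking run on the same side (off by default, matching the
  ungrouped random split of the validation design); sensitivity and
  specificity treat near-native as the positive class.
- Model comparison evaluates the test half at probability cutoff 0.5
  plus AUC from the predicted probabilities.

## Synthetic data

Fixtures place three-atom fragment templates (1.5 Å bonds, bent so
distance perception recovers the chain exactly) on a 20 Å cubic grid —
far enough apart that every planted ligand atom contacts exactly its
own fragment and bond perception cannot bridge sites. Planted corpora
realize each contact as its own axis-aligned fragment copy, so the
fragment frame is the global frame and the planted offset *is* the
local-frame feature; Gaussian draws are re-sampled into the 1.0–4.9 Å
shell. Pose sets hit exact RMSD targets by displacing every ligand atom
along its own unit direction scaled by the target. Feature tables come
in three kinds: separable clouds, label-independent null, and a
monotone ratio rule.

What this does *not* emulate: real ligand chemistry (fixture ligand
atoms are isolated carbons typed C.3), correlated contacts from a
connected ligand, fragment-frame noise from protein flexibility, and
class imbalance. Passing tests therefore demonstrate the correctness of
the machinery and its statistical identities, not screening performance
on real docked poses — the published full-scale operating points cannot
be recomputed without the original corpus and docking runs.

The end-to-end benchmark (`workflows.pose_discrimination_experiment`)
trains on two planted patterns and scores 300 + 300 poses by default:
pattern-consistent poses put ~85 % of 12–30 contacts at the trained
means (noise 0.2 Å), decoys put ~90 % on unseen fragment chemistry.
The 600-pose size keeps the permutation-null AUC band [0.35, 0.65]
several standard errors wide on the 30 % test half, so the null check
reflects correctness rather than sampling noise.

## Known limitations

- SYBYL typing covers the common organic vocabulary; exotic charge
  states (N.4 without formal charges, C.cat) are approximated or sink
  to `Du`.
- Fragment enumeration is exhaustive; for very large receptors the
  pair stage, not the mixture stage, dominates runtime.
- RMSD ignores molecular-graph automorphisms; symmetric ligands can
  score pessimistically high.
- The library's significance floor (20) and the screening thresholds
  are scale-coupled: retraining on a corpus of different size warrants
  re-deriving the Youden cutoffs with the shipped ROC machinery.
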