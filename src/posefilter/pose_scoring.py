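"""Score docked poses against a significant-interaction-pattern library.

Two statistics summarise a pose: ``pattern_num``, the number of its
interaction pairs assigned to significant patterns, and ``pattern_ratio``,
their fraction of all pairs.  Candidate targets satisfy the screening rule
pattern_num >= 600 AND pattern_ratio >= 0.8 (a strict conjunction); the
two Youden-optimal single-feature cutoffs (285 pairs, 0.679 ratio) are
reported as independent flags.  A two-feature probability classifier
(gradient-boosted trees by default, mirroring the deployed screen) fuses
the statistics into the probability that the pose is near-native.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.tree import DecisionTreeClassifier
from sklearn.ensemble import RandomForestClassifier
from xgboost import XGBClassifier

from .chem_typing import FRAGMENT_ORIENTATION_CONVENTION, SYBYL_TABLE_VERSION
from .complex_io import ComplexStructure
from .contacts import FRAME_CONVENTION
from .pattern_library import PatternLibrary, assign_pair, extract_complex_pairs

__all__ = [
    "ALGORITHMS",
    "ConventionMismatchError",
    "PoseClassifier",
    "PoseScore",
    "ScoringThresholds",
    "evaluate_rules",
    "predict_probability",
    "score_pose",
    "train_pose_classifier",
]


class ConventionMismatchError(ValueError):
    """Library was built under different typing/frame conventions."""


@dataclass(frozen=True)
class ScoringThresholds:
    """Screening cutoffs on the two pose statistics.

    ``target_min_num``/``target_min_ratio`` form the conjunctive target
    rule; ``youden_num``/``youden_ratio`` are the single-feature
    Youden-index optimal cutoffs reported independently.
    """

    target_min_num: int = 600
    target_min_ratio: float = 0.8
    youden_num: int = 285
    youden_ratio: float = 0.679

    def __post_init__(self) -> None:
        if self.target_min_num < 0 or self.youden_num < 0:
            raise ValueError("count thresholds must be non-negative")
        for r in (self.target_min_ratio, self.youden_ratio):
            if not 0.0 <= r <= 1.0:
                raise ValueError("ratio thresholds must lie in [0, 1]")


@dataclass
class PoseScore:
    pose_id: str
    pattern_num: int
    total_pairs: int
    pattern_ratio: float
    target_rule_pass: bool
    youden_num_pass: bool
    youden_ratio_pass: bool
    probability: float | None = None
    no_contacts: bool = False


def evaluate_rules(
    pattern_num: int,
    total_pairs: int,
    thresholds: ScoringThresholds | None = None,
) -> tuple[float, bool, bool, bool]:
    """Pattern ratio and the three screening flags for one pose.

    Returns (pattern_ratio, target_rule_pass, youden_num_pass,
    youden_ratio_pass).  The target rule is a strict conjunction: the pose
    must reach the pair count AND the ratio; the two Youden cutoffs are
    evaluated independently.  A pose with no pairs has ratio 0 and fails
    every rule (counts cannot be negative, nor exceed the total).
    """
    thresholds = thresholds or ScoringThresholds()
    if pattern_num < 0 or total_pairs < 0:
        raise ValueError("pair counts must be non-negative")
    if pattern_num > total_pairs:
        raise ValueError("pattern_num cannot exceed total_pairs")
    ratio = pattern_num / total_pairs if total_pairs else 0.0
    return (
        ratio,
        pattern_num >= thresholds.target_min_num and ratio >= thresholds.target_min_ratio,
        pattern_num >= thresholds.youden_num,
        ratio >= thresholds.youden_ratio,
    )


def _check_conventions(library: PatternLibrary) -> None:
    meta = library.metadata
    expected = {
        "frame_convention": FRAME_CONVENTION,
        "fragment_orientation_convention": FRAGMENT_ORIENTATION_CONVENTION,
        "sybyl_table_version": SYBYL_TABLE_VERSION,
    }
    for field_name, value in expected.items():
        found = meta.get(field_name)
        if found != value:
            raise ConventionMismatchError(
                f"library {field_name} is {found!r} but this build uses {value!r}; "
                "refusing to mix conventions"
            )


def score_pose(
    pose: ComplexStructure,
    library: PatternLibrary,
    thresholds: ScoringThresholds | None = None,
    classifier: "PoseClassifier | None" = None,
) -> PoseScore:
    """Compute pattern statistics, rule flags and (optionally) a probability.

    Pairs are extracted with the library's own cutoff and bond mode; the
    library's typing/frame convention fingerprints must match this build.
    A pose with no contacts scores (0, 0, ratio 0) with every flag false
    and ``no_contacts`` set.
    """
    thresholds = thresholds or ScoringThresholds()
    _check_conventions(library)
    pairs = extract_complex_pairs(
        pose,
        cutoff=float(library.metadata.get("cutoff", 5.0)),
        bond_mode=str(library.metadata.get("bond_mode", "distance")),
    )
    total = len(pairs)
    pattern_num = sum(assign_pair(p, library) for p in pairs)
    ratio, target_pass, num_pass, ratio_pass = evaluate_rules(
        pattern_num, total, thresholds
    )
    score = PoseScore(
        pose_id=pose.source_id,
        pattern_num=pattern_num,
        total_pairs=total,
        pattern_ratio=ratio,
        target_rule_pass=target_pass,
        youden_num_pass=num_pass,
        youden_ratio_pass=ratio_pass,
        no_contacts=(total == 0),
    )
    if classifier is not None:
        score.probability = predict_probability(classifier, pattern_num, ratio)
    return score


# --- two-feature probability classifier -----------------------------------

#: The five model families compared on the validation set.  LR and KNN are
#: scale-sensitive, so they see standardized features; the tree ensembles
#: are scale-free and take the raw (pattern_num, pattern_ratio) pairs.
ALGORITHMS = ("LR", "KNN", "DT", "RF", "GBT")


def _make_estimator(algorithm: str, seed: int):
    if algorithm == "LR":
        return make_pipeline(
            StandardScaler(), LogisticRegression(max_iter=1000, random_state=seed)
        )
    if algorithm == "KNN":
        return make_pipeline(StandardScaler(), KNeighborsClassifier(n_neighbors=5))
    if algorithm == "DT":
        return DecisionTreeClassifier(random_state=seed)
    if algorithm == "RF":
        return RandomForestClassifier(n_estimators=200, random_state=seed)
    if algorithm in ("GBT", "XGB"):
        return XGBClassifier(
            n_estimators=200,
            max_depth=4,
            learning_rate=0.1,
            eval_metric="logloss",
            random_state=seed,
        )
    raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")


@dataclass
class PoseClassifier:
    """A fitted two-feature (pattern_num, pattern_ratio) probability model."""

    algorithm: str
    model: object
    seed: int

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return self.model.predict_proba(features)[:, 1]


def train_pose_classifier(
    features: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    algorithm: str = "GBT",
    seed: int = 0,
) -> PoseClassifier:
    """Fit one of the five families on exactly the two pose features.

    ``labels`` flag near-native poses (ligand RMSD below the 2.5 A
    threshold).  Training is deterministic given the seed.
    """
    X = np.asarray(features, dtype=float).reshape(-1, 2)
    y = np.asarray(labels, dtype=int).reshape(-1)
    if len(X) != len(y):
        raise ValueError("features and labels must have equal length")
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    if len(np.unique(y)) < 2:
        raise ValueError("training labels contain a single class")
    est = _make_estimator(algorithm, seed)
    est.fit(X, y)
    return PoseClassifier(algorithm=algorithm, model=est, seed=seed)


def predict_probability(
    classifier: PoseClassifier, pattern_num: float, pattern_ratio: float
) -> float:
    """Probability that a pose with the given statistics is near-native."""
    if pattern_num < 0:
        raise ValueError("pattern_num must be non-negative")
    if not 0.0 <= pattern_ratio <= 1.0:
        raise ValueError("pattern_ratio must lie in [0, 1]")
    prob = classifier.predict_proba(np.array([[pattern_num, pattern_ratio]]))
    return float(prob[0])
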