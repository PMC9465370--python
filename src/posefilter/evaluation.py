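"""Validation harness: RMSD labelling, ROC/Youden analysis, model comparison.

Implements the statistics used to validate pattern-based pose screening:
in-place ligand RMSD against the crystal pose, two-group labelling at the
2.5 A near-native threshold, per-complex extreme-pose selection, empirical
ROC curves with Youden-index optimal cutoffs, contingency-table metrics,
seeded train/test splitting, and a five-family classifier comparison on
the two pose features.

Conventions (fixed so results are reproducible):

* decision rule "score >= threshold => positive" for higher-is-positive
  features; thresholds are the unique observed scores;
* AUC by trapezoid over the empirical ROC (equals the normalized
  Mann-Whitney U statistic with half credit for ties);
* Youden ties break toward the smallest threshold;
* test-set metrics are computed at probability cutoff 0.5.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .pose_scoring import ALGORITHMS, train_pose_classifier

__all__ = [
    "ConfusionMetrics",
    "ExtremePoses",
    "PoseLabel",
    "ROCResult",
    "compare_models",
    "confusion_metrics",
    "label_poses",
    "ligand_rmsd",
    "roc_with_youden",
    "select_extreme_poses",
    "split_train_test",
]

NEAR_NATIVE_RMSD = 2.5  # A


@dataclass(frozen=True)
class PoseLabel:
    pose_id: str
    rmsd: float
    near_native: bool


def ligand_rmsd(
    pose_coords: Sequence[Sequence[float]] | np.ndarray,
    reference_coords: Sequence[Sequence[float]] | np.ndarray,
) -> float:
    """In-place ligand RMSD (no superposition), atom correspondence by index.

    The docking convention: poses live in the receptor frame, so deviation
    from the crystal ligand is measured without refitting.
    """
    a = np.asarray(pose_coords, dtype=float).reshape(-1, 3)
    b = np.asarray(reference_coords, dtype=float).reshape(-1, 3)
    if len(a) != len(b):
        raise ValueError(f"coordinate lists differ in length: {len(a)} vs {len(b)}")
    if len(a) == 0:
        raise ValueError("at least one atom is required")
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def label_poses(
    poses_with_rmsd: Sequence[tuple[str, float]],
    threshold: float = NEAR_NATIVE_RMSD,
) -> list[PoseLabel]:
    """Two-group labelling: near-native iff RMSD <= threshold (default 2.5 A)."""
    return [
        PoseLabel(pose_id=pid, rmsd=r, near_native=r <= threshold)
        for pid, r in poses_with_rmsd
    ]


@dataclass(frozen=True)
class ExtremePoses:
    lowest: str
    highest: str
    degenerate: bool  # single input pose: both ids coincide


def select_extreme_poses(
    poses_with_rmsd: Sequence[tuple[str, float]],
) -> ExtremePoses:
    """The lowest- and highest-RMSD poses of one docking run.

    Validation keeps exactly these two poses per complex.  RMSD ties break
    toward the lexicographically smallest pose id.
    """
    if not poses_with_rmsd:
        raise ValueError("at least one pose is required")
    lowest = min(poses_with_rmsd, key=lambda pr: (pr[1], pr[0]))
    highest = max(poses_with_rmsd, key=lambda pr: (pr[1], _neg_str(pr[0])))
    return ExtremePoses(
        lowest=lowest[0],
        highest=highest[0],
        degenerate=len(poses_with_rmsd) == 1,
    )


class _neg_str(str):
    # Inverts lexicographic comparison so max() prefers the smaller id on ties.
    def __lt__(self, other):  # pragma: no cover - trivial
        return str.__gt__(self, other)

    def __gt__(self, other):  # pragma: no cover - trivial
        return str.__lt__(self, other)


@dataclass
class ROCResult:
    thresholds: np.ndarray  # ascending unique score values
    sensitivity: np.ndarray  # parallel to thresholds
    specificity: np.ndarray
    auc: float
    youden_cutoff: float
    youden_j: float
    youden_sens: float
    youden_spec: float


def roc_with_youden(
    scores: Sequence[float],
    labels: Sequence[bool],
    direction: str = "higher",
) -> ROCResult:
    """Empirical ROC with the Youden-index optimal cutoff.

    Thresholds are the unique score values; a case is called positive when
    its score passes the threshold in the stated ``direction`` ("higher":
    score >= t).  AUC is the trapezoid over the empirical ROC.  The Youden
    index J = sensitivity + specificity - 1 is maximized over thresholds,
    ties broken toward the smallest threshold.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if direction not in ("higher", "lower"):
        raise ValueError("direction must be 'higher' or 'lower'")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for ROC analysis")

    work = s if direction == "higher" else -s
    thresholds_w = np.unique(work)  # ascending
    # Predicted positive iff work >= t.
    sens = np.empty(len(thresholds_w))
    spec = np.empty(len(thresholds_w))
    for i, t in enumerate(thresholds_w):
        pred = work >= t
        sens[i] = np.sum(pred & y) / n_pos
        spec[i] = np.sum(~pred & ~y) / n_neg

    # ROC points: (FPR, TPR) from the threshold sweep plus the two corners.
    fpr = np.concatenate([[0.0], (1.0 - spec)[::-1], [1.0]])
    tpr = np.concatenate([[0.0], sens[::-1], [1.0]])
    auc = float(np.trapezoid(tpr, fpr))

    j = sens + spec - 1.0
    best = int(np.argmax(j))  # first occurrence = smallest threshold
    cutoff = thresholds_w[best] if direction == "higher" else -thresholds_w[best]
    out_thresholds = thresholds_w if direction == "higher" else np.sort(-thresholds_w)
    out_sens = sens if direction == "higher" else sens[::-1]
    out_spec = spec if direction == "higher" else spec[::-1]
    return ROCResult(
        thresholds=out_thresholds,
        sensitivity=out_sens,
        specificity=out_spec,
        auc=auc,
        youden_cutoff=float(cutoff),
        youden_j=float(j[best]),
        youden_sens=float(sens[best]),
        youden_spec=float(spec[best]),
    )


@dataclass(frozen=True)
class ConfusionMetrics:
    accuracy: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    auc: float | None = None

    def as_row(self) -> dict[str, float | None]:
        return {
            "AUC": self.auc,
            "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "PPV": self.ppv,
            "NPV": self.npv,
        }


def _ratio(num: int, den: int) -> float:
    # Degenerate denominators yield NaN, the "undefined" marker, never an error.
    return num / den if den > 0 else math.nan


def confusion_metrics(tp: int, fp: int, tn: int, fn: int,
                      auc: float | None = None) -> ConfusionMetrics:
    """Contingency-table metrics; zero denominators produce NaN markers."""
    for name, v in (("tp", tp), ("fp", fp), ("tn", tn), ("fn", fn)):
        if v < 0:
            raise ValueError(f"{name} must be non-negative, got {v}")
    total = tp + fp + tn + fn
    if total == 0:
        raise ValueError("contingency table is empty")
    return ConfusionMetrics(
        accuracy=(tp + tn) / total,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        auc=auc,
    )


def split_train_test(
    items: Sequence,
    train_fraction: float = 0.7,
    seed: int = 0,
    group_key: Callable | None = None,
) -> tuple[list, list]:
    """Seeded shuffle-and-split; disjoint and exhaustive.

    The train side receives ``round(n * train_fraction)`` items (at the
    shipped default 0.7, 1,252 poses split 876/376).  With ``group_key``
    (e.g. the source complex of a pose), whole groups are kept on one side
    so the two poses drawn from one docking run cannot straddle the split.
    """
    n = len(items)
    if n < 2:
        raise ValueError("need at least two items to split")
    if not 0.0 < train_fraction < 1.0:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    n_train = int(round(n * train_fraction))
    if group_key is None:
        order = rng.permutation(n)
        train_idx = set(order[:n_train].tolist())
        train = [items[i] for i in range(n) if i in train_idx]
        test = [items[i] for i in range(n) if i not in train_idx]
        return train, test
    groups: dict = {}
    for i, item in enumerate(items):
        groups.setdefault(group_key(item), []).append(i)
    keys = list(groups)
    rng.shuffle(keys)
    train_ids: set[int] = set()
    for key in keys:
        if len(train_ids) >= n_train:
            break
        train_ids.update(groups[key])
    train = [items[i] for i in range(n) if i in train_ids]
    test = [items[i] for i in range(n) if i not in train_ids]
    if not test:  # a single giant group swallowed everything
        raise ValueError("grouped split produced an empty test set")
    return train, test


def compare_models(
    features: Sequence[Sequence[float]] | np.ndarray,
    labels: Sequence[bool] | np.ndarray,
    algorithms: Sequence[str] = ALGORITHMS,
    seed: int = 0,
    train_fraction: float = 0.7,
    probability_cutoff: float = 0.5,
) -> pd.DataFrame:
    """Train/test comparison of the classifier families on the two features.

    Each family is fitted on the train split and evaluated on the test
    split: AUC from the predicted probabilities plus the five
    contingency metrics at the probability cutoff.  Returns a DataFrame
    with one row per family and columns AUC, Accuracy, Sensitivity,
    Specificity, PPV, NPV.
    """
    X = np.asarray(features, dtype=float).reshape(-1, 2)
    y = np.asarray(labels, dtype=bool).reshape(-1)
    idx_train, idx_test = split_train_test(list(range(len(y))), train_fraction, seed)
    for half, name in ((idx_train, "train"), (idx_test, "test")):
        if len(np.unique(y[half])) < 2:
            raise ValueError(f"{name} split contains a single class")
    rows = {}
    for algo in algorithms:
        clf = train_pose_classifier(X[idx_train], y[idx_train], algo, seed=seed)
        prob = clf.predict_proba(X[idx_test])
        roc = roc_with_youden(prob, y[idx_test])
        pred = prob >= probability_cutoff
        truth = y[idx_test]
        metrics = confusion_metrics(
            tp=int(np.sum(pred & truth)),
            fp=int(np.sum(pred & ~truth)),
            tn=int(np.sum(~pred & ~truth)),
            fn=int(np.sum(~pred & truth)),
            auc=roc.auc,
        )
        rows[algo] = metrics.as_row()
    return pd.DataFrame.from_dict(rows, orient="index")[
        ["AUC", "Accuracy", "Sensitivity", "Specificity", "PPV", "NPV"]
    ]
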