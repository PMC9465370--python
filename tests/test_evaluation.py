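"""RMSD, pose labelling, ROC/Youden, confusion metrics, splitting,
model comparison."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import mannwhitneyu

from posefilter.evaluation import (
    compare_models,
    confusion_metrics,
    label_poses,
    ligand_rmsd,
    roc_with_youden,
    select_extreme_poses,
    split_train_test,
)
from posefilter.synthetic_fixtures import make_feature_table


class TestLigandRMSD:
    def test_identical_coordinates_give_zero(self, rng):
        coords = rng.uniform(-5, 5, (10, 3))
        assert ligand_rmsd(coords, coords) == 0.0

    def test_uniform_shift(self, rng):
        coords = rng.uniform(-5, 5, (7, 3))
        shifted = coords + [3.0, 0.0, 0.0]
        assert ligand_rmsd(shifted, coords) == pytest.approx(3.0)

    def test_two_atom_closed_form(self):
        a = [[1.0, 0, 0], [0, 0, 0]]
        b = [[0.0, 0, 0], [0, 0, 0]]
        assert ligand_rmsd(a, b) == pytest.approx(math.sqrt(0.5))

    def test_symmetry_and_scaling(self, rng):
        a = rng.uniform(-5, 5, (6, 3))
        b = rng.uniform(-5, 5, (6, 3))
        assert ligand_rmsd(a, b) == pytest.approx(ligand_rmsd(b, a))
        mid = (a + b) / 2  # halving every displacement halves the RMSD
        assert ligand_rmsd(mid, b) == pytest.approx(0.5 * ligand_rmsd(a, b))

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            ligand_rmsd([[0, 0, 0]], [[0, 0, 0], [1, 1, 1]])


class TestLabelling:
    def test_threshold_is_inclusive_at_2_5(self):
        labels = label_poses([("a", 2.5), ("b", 2.500001), ("c", 0.1)])
        assert [l.near_native for l in labels] == [True, False, True]


class TestExtremePoses:
    def test_min_and_max_selected(self):
        result = select_extreme_poses([("p1", 1.2), ("p2", 3.4), ("p3", 0.8)])
        assert (result.lowest, result.highest) == ("p3", "p2")
        assert not result.degenerate

    def test_single_pose_is_degenerate(self):
        result = select_extreme_poses([("only", 2.0)])
        assert result.lowest == result.highest == "only"
        assert result.degenerate

    def test_ties_break_to_smallest_id(self):
        result = select_extreme_poses([("b", 1.0), ("a", 1.0), ("d", 9.0), ("c", 9.0)])
        assert result.lowest == "a"
        assert result.highest == "c"

    def test_matches_exhaustive_scan(self, rng):
        poses = [(f"p{i:03d}", float(r)) for i, r in enumerate(rng.uniform(0, 10, 30))]
        result = select_extreme_poses(poses)
        rmsds = dict(poses)
        assert rmsds[result.lowest] == min(r for _, r in poses)
        assert rmsds[result.highest] == max(r for _, r in poses)

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            select_extreme_poses([])


def exhaustive_confusion(scores, labels, threshold):
    pred = scores >= threshold
    tp = np.sum(pred & labels)
    fn = np.sum(~pred & labels)
    tn = np.sum(~pred & ~labels)
    fp = np.sum(pred & ~labels)
    return tp / (tp + fn), tn / (tn + fp)


class TestROC:
    def test_perfect_separation(self):
        scores = [0.9, 0.8, 0.2, 0.1]
        labels = [True, True, False, False]
        roc = roc_with_youden(scores, labels)
        assert roc.auc == pytest.approx(1.0)
        assert roc.youden_j == pytest.approx(1.0)
        # Any cutoff in (0.2, 0.8] is optimal; smallest-threshold tie-break.
        assert roc.youden_cutoff == pytest.approx(0.8)

    def test_identical_scores_give_chance_auc(self):
        roc = roc_with_youden([1.0] * 10, [True] * 5 + [False] * 5)
        assert roc.auc == pytest.approx(0.5)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            roc_with_youden([0.1, 0.2], [True, True])

    @pytest.mark.parametrize("seed", range(6))
    def test_sens_spec_match_exhaustive_scan(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.choice(np.linspace(0, 1, 20), size=50)  # force ties
        labels = rng.uniform(size=50) < 0.4
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_with_youden(scores, labels)
        for t, sens, spec in zip(roc.thresholds, roc.sensitivity, roc.specificity):
            e_sens, e_spec = exhaustive_confusion(scores, labels, t)
            assert sens == pytest.approx(e_sens)
            assert spec == pytest.approx(e_spec)
        # Youden cutoff equals the exhaustive argmax with smallest-t tie-break.
        j = roc.sensitivity + roc.specificity - 1.0
        assert roc.youden_j == pytest.approx(j.max())
        assert roc.youden_cutoff == roc.thresholds[np.argmax(j)]

    @pytest.mark.parametrize("seed", range(6))
    def test_auc_equals_normalized_mann_whitney(self, seed):
        rng = np.random.default_rng(100 + seed)
        scores = np.round(rng.uniform(size=60), 2)
        labels = rng.uniform(size=60) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_with_youden(scores, labels)
        u = mannwhitneyu(scores[labels], scores[~labels]).statistic
        assert roc.auc == pytest.approx(u / (labels.sum() * (~labels).sum()))

    def test_lower_is_positive_direction(self):
        scores = [0.1, 0.2, 0.8, 0.9]
        labels = [True, True, False, False]
        roc = roc_with_youden(scores, labels, direction="lower")
        assert roc.auc == pytest.approx(1.0)


class TestConfusionMetrics:
    def test_closed_form_example(self):
        m = confusion_metrics(tp=3, fp=2, tn=4, fn=1)
        assert m.sensitivity == pytest.approx(0.75)
        assert m.specificity == pytest.approx(2 / 3)
        assert m.accuracy == pytest.approx(0.70)
        assert m.ppv == pytest.approx(0.60)
        assert m.npv == pytest.approx(0.80)

    def test_perfect_classifier(self):
        assert confusion_metrics(tp=5, fp=0, tn=5, fn=0).accuracy == 1.0

    def test_degenerate_denominator_yields_nan_marker(self):
        m = confusion_metrics(tp=0, fp=0, tn=4, fn=2)
        assert math.isnan(m.ppv)
        assert not math.isnan(m.npv)

    def test_negative_counts_raise(self):
        with pytest.raises(ValueError):
            confusion_metrics(tp=-1, fp=0, tn=1, fn=0)

    def test_label_flip_swaps_metric_pairs(self):
        for tp, fp, tn, fn in itertools.product(range(1, 4), repeat=4):
            m = confusion_metrics(tp, fp, tn, fn)
            flipped = confusion_metrics(tp=tn, fp=fn, tn=tp, fn=fp)
            assert m.sensitivity == pytest.approx(flipped.specificity)
            assert m.ppv == pytest.approx(flipped.npv)


class TestSplit:
    def test_reproduces_876_376_split(self):
        train, test = split_train_test(list(range(1252)), seed=0)
        assert (len(train), len(test)) == (876, 376)
        # The published fraction stated to four decimals gives the same sizes.
        train, test = split_train_test(list(range(1252)), train_fraction=0.6997, seed=0)
        assert (len(train), len(test)) == (876, 376)

    def test_same_seed_same_split(self):
        items = list(range(100))
        assert split_train_test(items, seed=5) == split_train_test(items, seed=5)

    @pytest.mark.parametrize("seed", range(4))
    def test_disjoint_and_exhaustive(self, seed):
        items = [f"pose-{i}" for i in range(137)]
        train, test = split_train_test(items, seed=seed)
        assert set(train) | set(test) == set(items)
        assert not set(train) & set(test)

    def test_grouping_keeps_complexes_together(self):
        # Two poses per source complex must land on the same side.
        items = [(f"c{i:02d}", j) for i in range(40) for j in range(2)]
        train, test = split_train_test(items, seed=3, group_key=lambda it: it[0])
        train_groups = {c for c, _ in train}
        test_groups = {c for c, _ in test}
        assert not train_groups & test_groups

    def test_too_few_items_raise(self):
        with pytest.raises(ValueError):
            split_train_test([1], seed=0)

    def test_bad_fraction_raises(self):
        with pytest.raises(ValueError):
            split_train_test(list(range(10)), train_fraction=1.0)


class TestCompareModels:
    def test_table_shape_and_columns(self):
        X, y = make_feature_table("separable", 200, seed=1)
        table = compare_models(X, y, seed=0)
        assert table.shape == (5, 6)
        assert list(table.columns) == [
            "AUC", "Accuracy", "Sensitivity", "Specificity", "PPV", "NPV",
        ]
        assert list(table.index) == ["LR", "KNN", "DT", "RF", "GBT"]

    def test_every_family_solves_separable_data(self):
        X, y = make_feature_table("separable", 400, seed=2)
        table = compare_models(X, y, seed=1)
        assert (table["AUC"] >= 0.95).all()

    def test_single_class_half_raises(self):
        X = np.column_stack([np.arange(10.0), np.linspace(0, 1, 10)])
        y = np.zeros(10, dtype=bool)
        with pytest.raises(ValueError):
            compare_models(X, y, seed=0)
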