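"""Run the validation harness on an end-to-end synthetic experiment.

Trains a pattern library on planted contacts, scores 120 poses (60
pattern-consistent, 60 decoys), then reproduces the evaluation pipeline:
per-feature ROC with Youden-optimal cutoffs and the five-model
(LR/KNN/DT/RF/GBT) comparison table on a 70/30 train/test split.
"""

from posefilter import compare_models, roc_with_youden
from posefilter.workflows import pose_discrimination_experiment

result = pose_discrimination_experiment(seed=2, n_near=60, n_decoy=60)

for name, column in (("pattern_num", 0), ("pattern_ratio", 1)):
    roc = roc_with_youden(result.features[:, column], result.labels)
    print(
        f"{name}: AUC={roc.auc:.3f}, Youden cutoff={roc.youden_cutoff:.3f} "
        f"(sens={roc.youden_sens:.3f}, spec={roc.youden_spec:.3f})"
    )

table = compare_models(result.features, result.labels, seed=2)
print()
print(table.round(3))
print(
    "\nBoth features separate the pose populations almost perfectly here "
    "because the synthetic decoys share no trained contact chemistry; on "
    "real docked poses the same harness quantifies a much noisier margin."
)
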