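"""Train the full hybrid network with 5-fold cross-validation on a planted,
perfectly separable dataset.

Active pairs carry at most one mismatch; inactive pairs carry three or more
(sometimes plus a bulge), so a perfect classifier exists and the run shows
the whole pipeline — encoding, stratified splitting, Adam with the plateau
learning-rate schedule, and PR/ROC evaluation — learning a signal it should
be able to learn.  Takes a few minutes on one CPU.
"""

from crisprhw import ModelSpec, TrainConfig, cross_validate, planted_signal_separable

dataset = planted_signal_separable(n_pairs=3000, imbalance_ratio=10, seed=1)
print(f"dataset: {len(dataset)} pairs, {sum(dataset.labels())} active")

config = TrainConfig(epochs=5, batch_size=512, shuffle_seed=1)
result = cross_validate(dataset, ModelSpec(), variant="full", config=config)

for i, fold in enumerate(result.fold_metrics):
    print(f"fold {i}: PR-AUC {fold.pr_auc:.3f}  ROC-AUC {fold.roc_auc:.3f}")
mean = result.mean
print(f"mean:   PR-AUC {mean.pr_auc:.3f}  ROC-AUC {mean.roc_auc:.3f}")

print(
    "\nPR-AUC near 1.0 means the network ranks essentially every active pair"
    "\nabove every inactive one despite the 10:1 class imbalance; on real"
    "\nscreens the signal is far weaker and PR-AUC is correspondingly lower."
)
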