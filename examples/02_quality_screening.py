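"""Screen corrupted pulse windows with the unsupervised VAE quality index.

Generates a 12-subject cohort where 30% of windows carry injected
corruptions (spikes, drift, noise bursts, dropouts, lost periodicity),
fits the VAE scorer on training subjects only (reduced epochs for a quick
demo), scores every window, and reports how well the fused quality score
separates clean from corrupted windows.  ROC-AUC near 1 means corrupted
windows reliably land below the retention threshold.
"""

import numpy as np

from radarbp.harness import split_by_subject
from radarbp.sqi import SQIScorer, VAEConfig, evaluate_sqi, screen_dataset
from radarbp.synth import DatasetSpec, make_dataset

dataset = make_dataset(12, 20, corrupt_fraction=0.3, rng_seed=3,
                       spec=DatasetSpec(window_len=512))
train_ds, val_ds, test_ds = split_by_subject(dataset, seed=3)

scorer = SQIScorer(VAEConfig.tiny(dataset.window_len))
scorer.fit(train_ds, rng_seed=3, stage1_epochs=10, stage2_epochs=5)

splits, reports = screen_dataset(
    {"train": train_ds, "val": val_ds, "test": test_ds}, scorer, 0.8)

rep = scorer.score(test_ds)
ev = evaluate_sqi(rep.score, 1 - test_ds.corrupt)
print(f"test windows: {len(test_ds)} ({test_ds.corrupt.sum()} corrupted)")
print(f"quality-score ROC-AUC vs ground-truth labels: {ev.roc_auc:.3f}")
print(f"average precision: {ev.average_precision:.3f}, "
      f"best F1: {ev.f1_at_best_threshold:.3f}")
kept = reports["test"].passed
print(f"retained {kept.sum()}/{len(test_ds)} test windows at the 80% "
      f"threshold; corrupted fraction among retained: "
      f"{test_ds.corrupt[kept].mean():.2f} (before screening: "
      f"{test_ds.corrupt.mean():.2f})")
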