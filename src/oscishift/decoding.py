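"""Time-resolved two-class decoding of decision labels from multichannel
features.

At each time bin independently, channels are the feature vector of a
shrinkage-regularized Linear Discriminant Analysis classifier evaluated by
stratified k-fold cross-validation (8 folds, repeated twice with reshuffled
folds); performance is the area under the ROC curve of the held-out
decision values, averaged over folds and repeats.  Group-level inference
contrasts the per-subject AUC time courses against chance (0.5) with the
cluster permutation test over time bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score

from .stats import ClusterResult, StatsParams, cluster_permutation_test

__all__ = ["DecodingResult", "time_resolved_decode", "decode_cohort", "stratified_folds"]


def stratified_folds(y: np.ndarray, n_folds: int, seed: int) -> np.ndarray:
    """Fold id per trial; stratified, seeded, and invariant to label renaming.

    One seeded permutation of all trials is drawn and fold ids are assigned
    round-robin within each class in permuted order, so swapping the two
    class names leaves the partition unchanged (which makes per-fold AUC
    map exactly to 1 − AUC under a label swap).
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(y))
    folds = np.empty(len(y), dtype=int)
    counters: dict = {}
    for idx in perm:
        c = y[idx]
        k = counters.get(c, 0)
        folds[idx] = k % n_folds
        counters[c] = k + 1
    return folds


@dataclass
class DecodingResult:
    """AUC per time bin for one subject."""

    auc: np.ndarray  # (n_times,)
    per_fold_auc: np.ndarray  # (n_repeats, n_folds, n_times)
    times: np.ndarray
    n_folds: int
    n_repeats: int
    classes: list
    subject_id: str = "s00"


def time_resolved_decode(features: np.ndarray, labels: np.ndarray,
                         times: np.ndarray | None = None, n_folds: int = 8,
                         n_repeats: int = 2, seed: int = 0,
                         subject_id: str = "s00") -> DecodingResult:
    """Cross-validated LDA AUC at every time bin.

    ``features``: (n_trials, n_channels, n_times); ``labels``: two-level
    per-trial labels.  Folds are stratified and shuffled; repeats differ
    only in the shuffle.  The LDA uses least-squares fitting with analytic
    (Ledoit-Wolf) shrinkage of the covariance toward the scaled identity.
    """
    features = np.asarray(features, dtype=np.float64)
    labels = np.asarray(labels)
    classes = sorted(set(labels.tolist()))
    if len(classes) != 2:
        raise ValueError(f"time_resolved_decode: need exactly two classes, got {classes}")
    y = (labels == classes[1]).astype(int)
    counts = np.bincount(y)
    if counts.min() < n_folds:
        raise ValueError(
            f"time_resolved_decode: smallest class has {counts.min()} trials; "
            f"needs >= n_folds={n_folds}"
        )
    n_trials, n_channels, n_times = features.shape
    times = np.arange(n_times, dtype=float) if times is None else np.asarray(times, dtype=float)
    per_fold = np.full((n_repeats, n_folds, n_times), np.nan)
    for rep in range(n_repeats):
        fold_ids = stratified_folds(y, n_folds, seed + rep)
        for fold in range(n_folds):
            te_idx = np.flatnonzero(fold_ids == fold)
            tr_idx = np.flatnonzero(fold_ids != fold)
            for ti in range(n_times):
                X_tr = features[tr_idx, :, ti]
                X_te = features[te_idx, :, ti]
                clf = LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
                clf.fit(X_tr, y[tr_idx])
                scores = clf.decision_function(X_te)
                per_fold[rep, fold, ti] = roc_auc_score(y[te_idx], scores)
    return DecodingResult(
        auc=per_fold.mean(axis=(0, 1)),
        per_fold_auc=per_fold,
        times=times,
        n_folds=n_folds,
        n_repeats=n_repeats,
        classes=classes,
        subject_id=subject_id,
    )


def decode_cohort(results: list[DecodingResult],
                  params: StatsParams | None = None) -> tuple[np.ndarray, ClusterResult]:
    """Group AUC time course and its cluster test against chance (0.5).

    Returns the subject-mean AUC per time bin and the
    :class:`~oscishift.stats.ClusterResult` of the paired contrast of the
    per-subject AUC curves vs the constant 0.5, clustered over time bins
    (one-tailed positive by default: above-chance decoding).
    """
    if len(results) < 2:
        raise ValueError("decode_cohort: need >= 2 subjects")
    times = results[0].times
    aucs = np.stack([r.auc for r in results])[:, None, :]  # (subjects, 1, times)
    chance = np.full_like(aucs, 0.5)
    if params is None:
        params = StatsParams(tail="pos")
    res = cluster_permutation_test(aucs, chance, graph=None, params=params,
                                   channel_ids=["auc"], bins=times, bin_unit="s")
    return aucs[:, 0, :].mean(axis=0), res
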