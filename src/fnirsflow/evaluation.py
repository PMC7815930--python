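"""Cross-validated accuracy estimation and pairwise classification.

The accuracy statistic is the fraction of correctly identified samples over
all classes,

    P = (N_D + N_S + N_L) / N_T * 100,

with N_D, N_S, N_L the correctly classified dislike / so-so / like samples
and N_T the total.  Folds are built at trial granularity (every augmented
window of a trial shares its fold — no leakage) and stratified by label;
z-score normalization statistics are fit on the training folds only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .decoder import (NetworkSpec, TrainConfig, TrialTensor, predict, train,
                      zscore_apply, zscore_fit)
from .hemodynamics import ConfigError, DataError
from .paradigm import PREFERENCES

__all__ = [
    "FoldAssignment",
    "AccuracyReport",
    "accuracy",
    "kfold_split",
    "cross_validate",
    "pairwise_classify",
    "PAIRS",
]

#: The three two-class restrictions, in reporting order.
PAIRS = (("like", "so-so"), ("like", "dislike"), ("so-so", "dislike"))


@dataclass(frozen=True)
class FoldAssignment:
    """fold_id (1..k) per sample; all samples of a group share a fold."""

    fold_ids: np.ndarray
    k: int
    groups: np.ndarray

    def test_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids == fold)

    def train_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.fold_ids != fold)


@dataclass
class AccuracyReport:
    per_fold: list[float]           # percent
    mean: float                     # percent
    classes: tuple[str, ...]
    correct_per_class: dict = field(default_factory=dict)  # e.g. N_D, N_S, N_L
    n_total: int = 0

    @property
    def sd(self) -> float:
        return float(np.std(self.per_fold))


def accuracy(pred: list[str], true: list[str]) -> float:
    """Percent of index-wise matches (the multi-class correct count over N_T)."""
    if len(pred) != len(true):
        raise DataError(f"{len(pred)} predictions for {len(true)} labels")
    if not true:
        raise DataError("empty label lists")
    correct = sum(p == t for p, t in zip(pred, true))
    return 100.0 * correct / len(true)


def kfold_split(tensors: list[TrialTensor], k: int = 8, seed: int = 0) -> FoldAssignment:
    """Grouped, stratified fold assignment.

    Groups (trial_index) are shuffled within each label stratum and dealt
    round-robin to folds 1..k, the deal continuing across strata so fold
    sizes differ by at most one group.
    """
    groups = np.array([t.trial_index for t in tensors])
    uniq = []
    group_label = {}
    for t in tensors:
        if t.trial_index not in group_label:
            group_label[t.trial_index] = t.label
            uniq.append(t.trial_index)
        elif group_label[t.trial_index] != t.label:
            raise DataError(f"trial {t.trial_index} carries conflicting labels")
    if len(uniq) < k:
        raise ConfigError(f"{len(uniq)} groups cannot fill {k} folds")
    rng = np.random.default_rng(seed)
    strata = sorted({group_label[g] for g in uniq},
                    key=lambda lab: (PREFERENCES.index(lab) if lab in PREFERENCES else 99, lab))
    fold_of_group = {}
    pos = 0
    for lab in strata:
        members = sorted(g for g in uniq if group_label[g] == lab)
        rng.shuffle(members)
        for g in members:
            fold_of_group[g] = pos % k + 1
            pos += 1
    fold_ids = np.array([fold_of_group[g] for g in groups])
    return FoldAssignment(fold_ids, k, groups)


def cross_validate(tensors: list[TrialTensor], spec: NetworkSpec, cfg: TrainConfig,
                   k: int = 8, classes: tuple[str, ...] = PREFERENCES,
                   normalize: bool = True,
                   folds: FoldAssignment | None = None) -> AccuracyReport:
    """k-fold cross-validation: train on k-1 folds, score the held-out fold.

    Each fold retrains from a fold-derived seed (cfg.seed + fold id).  The
    report carries per-fold accuracies, their mean, and per-class correct
    counts pooled over held-out folds.
    """
    if folds is None:
        folds = kfold_split(tensors, k=k, seed=cfg.seed)
    per_fold = []
    correct = {c: 0 for c in classes}
    n_total = 0
    for fold in range(1, folds.k + 1):
        tr_idx = folds.train_indices(fold)
        te_idx = folds.test_indices(fold)
        tr = [tensors[i] for i in tr_idx]
        te = [tensors[i] for i in te_idx]
        test_classes = {t.label for t in te}
        if test_classes != set(classes):
            warnings.warn(f"fold {fold} is missing classes "
                          f"{sorted(set(classes) - test_classes)}; scored anyway")
        if normalize:
            stats = zscore_fit(tr)
            tr = zscore_apply(tr, stats)
            te = zscore_apply(te, stats)
        fitted = train(tr, spec, replace(cfg, seed=cfg.seed + fold), classes=classes)
        preds = predict(fitted, te)
        truth = [t.label for t in te]
        per_fold.append(accuracy(preds, truth))
        for p, t in zip(preds, truth):
            if p == t:
                correct[t] += 1
        n_total += len(te)
    return AccuracyReport(per_fold, float(np.mean(per_fold)), tuple(classes),
                          correct, n_total)


def pairwise_classify(tensors: list[TrialTensor], pair: tuple[str, str],
                      spec: NetworkSpec, cfg: TrainConfig, k: int = 8) -> AccuracyReport:
    """Two-class restriction: keep only the pair's samples, rebuild the output
    layer with 2 nodes, and cross-validate."""
    pair = tuple(pair)
    subset = [t for t in tensors if t.label in pair]
    present = {t.label for t in subset}
    if present != set(pair):
        raise DataError(f"classes {sorted(set(pair) - present)} absent from the data")
    classes = tuple(sorted(pair, key=PREFERENCES.index)) \
        if all(p in PREFERENCES for p in pair) else pair
    spec2 = replace(spec, n_classes=2)
    return cross_validate(subset, spec2, cfg, k=k, classes=classes)
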