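"""Classifier evaluation: confusion metrics, ROC/PR, CV and scaffold splits.

Threshold metrics are the standard confusion-table formulas:

    sensitivity = TP / (TP + FN)            specificity = TN / (TN + FP)
    accuracy    = (TP + TN) / total         balanced accuracy = (sens + spec)/2
    MCC = (TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN))

with MCC defined as 0 when any denominator factor vanishes.  Curves and
AUCs use scikit-learn: the trapezoidal ROC-AUC equals the Mann-Whitney
probability that a random positive outscores a random negative with half
credit for ties, and the PR "AUC" is average precision (step-wise
interpolation).  Model selection protocols are seeded k-fold cross-validation
and a Bemis-Murcko framework scaffold split that keeps each scaffold group
whole on one side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.metrics import (
    auc as _sk_auc,
    average_precision_score,
    precision_recall_curve,
    roc_curve as _sk_roc_curve,
)

from .chem_io import Dataset
from .dmpnn import DMPNNConfig, TrainedEnsemble, predict, train_ensemble
from .fingerprints import fingerprint_dataset, max_similarity


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class MetricBundle:
    sensitivity: float
    specificity: float
    accuracy: float
    balanced_accuracy: float
    mcc: float
    counts: ConfusionCounts
    roc_auc: Optional[float] = None
    pr_auc: Optional[float] = None

    def as_dict(self) -> dict:
        d = {
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "accuracy": self.accuracy,
            "balanced_accuracy": self.balanced_accuracy,
            "mcc": self.mcc,
        }
        if self.roc_auc is not None:
            d["roc_auc"] = self.roc_auc
        if self.pr_auc is not None:
            d["pr_auc"] = self.pr_auc
        return d


def confusion_counts(labels: Sequence[int], calls: Sequence[int]) -> ConfusionCounts:
    labels = np.asarray(labels, dtype=int)
    calls = np.asarray(calls, dtype=int)
    return ConfusionCounts(
        TP=int(np.sum((labels == 1) & (calls == 1))),
        TN=int(np.sum((labels == 0) & (calls == 0))),
        FP=int(np.sum((labels == 0) & (calls == 1))),
        FN=int(np.sum((labels == 1) & (calls == 0))),
    )


def compute_metrics(counts: ConfusionCounts) -> MetricBundle:
    """Threshold metrics from a confusion table (exact formula evaluation)."""
    if counts.total == 0:
        raise ValueError("empty confusion table")
    tp, tn, fp, fn = counts.TP, counts.TN, counts.FP, counts.FN
    sens = tp / (tp + fn) if tp + fn else 0.0
    spec = tn / (tn + fp) if tn + fp else 0.0
    acc = (tp + tn) / counts.total
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    mcc = (tp * tn - fp * fn) / math.sqrt(denom) if denom else 0.0
    return MetricBundle(
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        balanced_accuracy=(sens + spec) / 2.0,
        mcc=mcc,
        counts=counts,
    )


def _check_both_classes(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("undefined AUC: only one class present")


def roc_curve_auc(labels: Sequence[int], scores: Sequence[float]):
    """ROC staircase and its area.

    Returns ``((fpr, tpr, thresholds), auc)``.  The trapezoidal area equals
    the tie-corrected concordant-pair probability.
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    _check_both_classes(labels)
    fpr, tpr, thresholds = _sk_roc_curve(labels, scores)
    return (fpr, tpr, thresholds), float(_sk_auc(fpr, tpr))


def pr_curve_auc(labels: Sequence[int], scores: Sequence[float]):
    """Precision-recall staircase and its average-precision area."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.sum() == 0:
        raise ValueError("undefined PR-AUC: no positive labels")
    precision, recall, thresholds = precision_recall_curve(labels, scores)
    return (precision, recall, thresholds), float(average_precision_score(labels, scores))


def evaluate_predictions(
    labels: Sequence[int], scores: Sequence[float], threshold: float = 0.5
) -> MetricBundle:
    """Full bundle: threshold metrics at ``score >= threshold`` plus AUCs."""
    labels_arr = np.asarray(labels, dtype=int)
    scores_arr = np.asarray(scores, dtype=float)
    calls = (scores_arr >= threshold).astype(int)
    bundle = compute_metrics(confusion_counts(labels_arr, calls))
    _, bundle.roc_auc = roc_curve_auc(labels_arr, scores_arr)
    _, bundle.pr_auc = pr_curve_auc(labels_arr, scores_arr)
    return bundle


# --------------------------------------------------------------------------
# Splits
# --------------------------------------------------------------------------


def kfold_splits(
    dataset: Dataset, k: int, seed: int, stratified: bool = False
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Seeded random partition into k near-equal folds.

    Returns ``[(train_idx, test_idx), ...]``; each record appears in exactly
    one test fold.  ``stratified=True`` balances class prevalence per fold
    (useful for very small or imbalanced fixtures).
    """
    n = len(dataset)
    if k < 2:
        raise ValueError("k must be at least 2")
    if n < k:
        raise ValueError(f"dataset of {n} records cannot be split into {k} folds")
    rng = np.random.default_rng(seed)
    if stratified:
        labels = np.asarray([r.label for r in dataset.records])
        fold_of = np.empty(n, dtype=int)
        for cls in np.unique(labels):
            cls_idx = rng.permutation(np.flatnonzero(labels == cls))
            fold_of[cls_idx] = np.arange(len(cls_idx)) % k
    else:
        perm = rng.permutation(n)
        fold_of = np.empty(n, dtype=int)
        # contiguous near-equal chunks of the permutation
        sizes = np.full(k, n // k)
        sizes[: n % k] += 1
        start = 0
        for f, size in enumerate(sizes):
            fold_of[perm[start : start + size]] = f
            start += size
    splits = []
    all_idx = np.arange(n)
    for f in range(k):
        test = all_idx[fold_of == f]
        train = all_idx[fold_of != f]
        splits.append((train, test))
    return splits


def scaffold_of(smiles: str) -> str:
    """Bemis-Murcko framework scaffold (ring systems plus linkers, side
    chains removed); acyclic molecules key to their own canonical SMILES."""
    scaffold = MurckoScaffold.MurckoScaffoldSmiles(smiles=smiles)
    return scaffold if scaffold else smiles


def scaffold_split(
    dataset: Dataset, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Split with whole scaffold groups, largest groups into test first.

    Scaffold groups are placed whole into the test side, largest first (size
    ties broken by a seed-shuffled order), until the test fraction is
    reached; the remainder is the training side.  No scaffold occurs on both
    sides.  Returns ``(train_idx, test_idx)``.
    """
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must lie in (0, 1)")
    groups: dict[str, list[int]] = {}
    for i, rec in enumerate(dataset.records):
        if rec.canonical_smiles is None:
            raise ValueError(f"record {rec.record_id!r} is not standardized")
        groups.setdefault(scaffold_of(rec.canonical_smiles), []).append(i)
    if len(groups) < 2:
        raise ValueError("cannot satisfy fraction without leakage: single scaffold")
    rng = np.random.default_rng(seed)
    keys = list(groups)
    shuffled = [keys[i] for i in rng.permutation(len(keys))]
    shuffled.sort(key=lambda s: -len(groups[s]))  # stable: ties stay shuffled
    target = test_fraction * len(dataset)
    test_idx: list[int] = []
    train_idx: list[int] = []
    for key in shuffled:
        if len(test_idx) < target:
            test_idx.extend(groups[key])
        else:
            train_idx.extend(groups[key])
    if not train_idx:
        raise ValueError("cannot satisfy fraction without leakage")
    return np.array(sorted(train_idx)), np.array(sorted(test_idx))


# --------------------------------------------------------------------------
# Cross-validation and the similarity-screen protocol
# --------------------------------------------------------------------------


@dataclass
class FoldResult:
    fold_index: int
    metrics: MetricBundle
    n_test: int


@dataclass
class CVSummary:
    folds: list[FoldResult] = field(default_factory=list)
    mean: dict = field(default_factory=dict)
    sd: dict = field(default_factory=dict)


def cross_validate(
    dataset: Dataset,
    config: DMPNNConfig,
    k: int,
    seed: Optional[int] = None,
    stratified: bool = False,
) -> CVSummary:
    """k-fold cross-validation of the message-passing ensemble.

    Each fold trains a fresh ensemble on the remaining k-1 groups and scores
    the left-out group; the summary reports mean and standard deviation of
    each metric across folds.  Deterministic per (dataset, config, seed).
    """
    split_seed = config.seed if seed is None else seed
    splits = kfold_splits(dataset, k, split_seed, stratified=stratified)
    summary = CVSummary()
    for fold, (train_idx, test_idx) in enumerate(splits):
        train = dataset.subset(train_idx, name=f"{dataset.name}-fold{fold}-train")
        test = dataset.subset(test_idx, name=f"{dataset.name}-fold{fold}-test")
        ensemble = train_ensemble(train, config)
        probs, _, _ = predict(ensemble, test)
        bundle = evaluate_predictions(
            [r.label for r in test.records], probs, threshold=config.call_threshold
        )
        summary.folds.append(FoldResult(fold_index=fold, metrics=bundle, n_test=len(test)))
    keys = summary.folds[0].metrics.as_dict().keys()
    for key in keys:
        vals = np.array([f.metrics.as_dict()[key] for f in summary.folds])
        summary.mean[key] = float(vals.mean())
        summary.sd[key] = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
    return summary


def evaluate_similarity_screen(
    reference: Dataset,
    external: Dataset,
    active_cutoff: float = 1e-6,
    inactive_cutoff: float = 1e-5,
    radius: int = 2,
    width: int = 2048,
):
    """ROC-AUC of the MAX-similarity screen on a potency-labeled external set.

    External records are binarized by potency (molar): at or below
    ``active_cutoff`` (1 µM) active, at or above ``inactive_cutoff`` (10 µM)
    inactive, strictly between the cutoffs dropped.  External records whose
    canonical SMILES occurs in the reference set are excluded, every survivor
    is scored by its maximum Tanimoto similarity to the reference set, and
    the ranking ROC-AUC is returned as ``(curve, auc, scores_df_rows)``.
    """
    ref_smiles = {r.canonical_smiles for r in reference.records}
    ref_fps = fingerprint_dataset(reference, radius=radius, width=width)
    ref_ids = [r.record_id for r in reference.records]
    labels, scores, rows = [], [], []
    for rec in external.records:
        if rec.potency is None:
            raise ValueError(f"external record {rec.record_id!r} lacks a potency value")
        if rec.canonical_smiles in ref_smiles:
            continue
        if rec.potency <= active_cutoff:
            label = 1
        elif rec.potency >= inactive_cutoff:
            label = 0
        else:
            continue
        from .fingerprints import fingerprint as _fp

        res = max_similarity(
            _fp(rec, radius=radius, width=width), ref_fps, ref_ids, query_id=rec.record_id
        )
        labels.append(label)
        scores.append(res.max_score)
        rows.append(
            {
                "query_id": rec.record_id,
                "label": label,
                "max_score": res.max_score,
                "argmax_reference_id": res.argmax_reference_id,
            }
        )
    labels_arr = np.asarray(labels)
    if len(labels_arr) == 0 or labels_arr.min() == labels_arr.max():
        raise ValueError("similarity screen needs both classes after filtering")
    curve, auc_value = roc_curve_auc(labels_arr, scores)
    return curve, auc_value, rows
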