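"""Metrics, curve areas, split protocols and the similarity-screen evaluation."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from sklearn.metrics import balanced_accuracy_score, matthews_corrcoef

from transportscreen import (
    ConfusionCounts,
    Dataset,
    compute_metrics,
    confusion_counts,
    evaluate_similarity_screen,
    from_smiles,
    kfold_splits,
    pr_curve_auc,
    roc_curve_auc,
    scaffold_split,
)
from transportscreen.evaluation import scaffold_of


def pair_auc_oracle(labels, scores):
    """Exhaustive concordant-pair count with half credit for ties."""
    pos = [s for l, s in zip(labels, scores) if l == 1]
    neg = [s for l, s in zip(labels, scores) if l == 0]
    total = sum(1.0 if p > n else 0.5 if p == n else 0.0 for p in pos for n in neg)
    return total / (len(pos) * len(neg))


def average_precision_oracle(labels, scores):
    """Step-wise PR area by exhaustive threshold enumeration."""
    thresholds = sorted(set(scores), reverse=True)
    n_pos = sum(labels)
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        calls = [s >= t for s in scores]
        tp = sum(1 for l, c in zip(labels, calls) if l == 1 and c)
        fp = sum(1 for l, c in zip(labels, calls) if l == 0 and c)
        if tp + fp == 0:
            continue
        precision = tp / (tp + fp)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestConfusionMetrics:
    def test_worked_case(self):
        m = compute_metrics(ConfusionCounts(TP=40, FN=10, TN=30, FP=20))
        assert m.sensitivity == pytest.approx(0.8)
        assert m.specificity == pytest.approx(0.6)
        assert m.accuracy == pytest.approx(0.7)
        assert m.balanced_accuracy == pytest.approx(0.7)
        assert m.mcc == pytest.approx(1000.0 / math.sqrt(6_000_000), abs=1e-12)

    def test_perfect_and_inverted(self):
        perfect = compute_metrics(ConfusionCounts(TP=50, TN=50, FP=0, FN=0))
        assert perfect.sensitivity == perfect.specificity == perfect.accuracy == 1.0
        assert perfect.mcc == 1.0
        inverted = compute_metrics(ConfusionCounts(TP=0, TN=0, FP=50, FN=50))
        assert inverted.mcc == -1.0

    def test_all_zero_counts_error(self):
        with pytest.raises(ValueError):
            compute_metrics(ConfusionCounts(0, 0, 0, 0))

    def test_zero_denominator_mcc_convention(self):
        m = compute_metrics(ConfusionCounts(TP=5, FN=0, TN=0, FP=5))
        assert m.mcc == 0.0

    @pytest.mark.filterwarnings("ignore:A single label was found:UserWarning")
    @settings(deadline=None, derandomize=True, max_examples=300)
    @given(st.tuples(*[st.integers(0, 50)] * 4).filter(lambda t: sum(t) > 0))
    def test_matches_sklearn_on_reconstructed_predictions(self, t):
        tp, tn, fp, fn = t
        m = compute_metrics(ConfusionCounts(TP=tp, TN=tn, FP=fp, FN=fn))
        y_true = [1] * tp + [0] * tn + [0] * fp + [1] * fn
        y_pred = [1] * tp + [0] * tn + [1] * fp + [0] * fn
        if tp + fn and tn + fp:
            assert m.balanced_accuracy == pytest.approx(
                balanced_accuracy_score(y_true, y_pred), abs=1e-12
            )
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred), abs=1e-9)
        assert m.balanced_accuracy == pytest.approx(
            (m.sensitivity + m.specificity) / 2, abs=1e-15
        )


class TestCurves:
    def test_roc_hand_case(self):
        _, auc = roc_curve_auc([1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1])
        assert auc == pytest.approx(0.75)

    def test_perfect_separation(self):
        _, auc = roc_curve_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0
        _, ap = pr_curve_auc([0, 0, 1, 1], [0.1, 0.2, 0.8, 0.9])
        assert ap == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_curve_auc([1, 0, 1, 0], [0.5, 0.5, 0.5, 0.5])
        assert auc == pytest.approx(0.5)

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="undefined AUC"):
            roc_curve_auc([1, 1, 1], [0.1, 0.2, 0.3])
        with pytest.raises(ValueError, match="no positive"):
            pr_curve_auc([0, 0], [0.1, 0.2])

    def test_all_positive_pr_is_one(self):
        _, ap = pr_curve_auc([1, 1, 1], [0.2, 0.9, 0.4])
        assert ap == 1.0

    def test_pr_hand_case_vs_threshold_enumeration(self):
        labels, scores = [1, 0, 1, 0], [0.9, 0.8, 0.7, 0.1]
        _, ap = pr_curve_auc(labels, scores)
        assert ap == pytest.approx(average_precision_oracle(labels, scores), abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=200)
    @given(
        st.lists(
            st.tuples(st.integers(0, 1), st.sampled_from([0.1, 0.4, 0.7])),
            min_size=2,
            max_size=8,
        ).filter(lambda lst: len({l for l, _ in lst}) == 2)
    )
    def test_roc_matches_pair_oracle(self, pairs):
        labels = [l for l, _ in pairs]
        scores = [s for _, s in pairs]
        _, auc = roc_curve_auc(labels, scores)
        assert auc == pytest.approx(pair_auc_oracle(labels, scores), abs=1e-12)


class TestKFold:
    def test_partition_covers_everything_once(self, small_motif_dataset):
        splits = kfold_splits(small_motif_dataset, 5, seed=3)
        tests = [set(te) for _, te in splits]
        assert sum(len(t) for t in tests) == len(small_motif_dataset)
        assert set().union(*tests) == set(range(len(small_motif_dataset)))
        for a, b in itertools.combinations(tests, 2):
            assert not (a & b)
        for tr, te in splits:
            assert not (set(tr) & set(te))
            assert len(tr) + len(te) == len(small_motif_dataset)

    def test_near_equal_sizes(self, small_motif_dataset):
        splits = kfold_splits(small_motif_dataset, 3, seed=0)
        sizes = [len(te) for _, te in splits]
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_per_seed(self, small_motif_dataset):
        a = kfold_splits(small_motif_dataset, 5, seed=7)
        b = kfold_splits(small_motif_dataset, 5, seed=7)
        for (tra, tea), (trb, teb) in zip(a, b):
            assert np.array_equal(tea, teb) and np.array_equal(tra, trb)

    def test_leave_one_out_boundary(self):
        ds, _ = from_smiles(["CCO", "CCN", "CCC", "CCCC"], [1, 0, 1, 0])
        splits = kfold_splits(ds, 4, seed=0)
        assert all(len(te) == 1 for _, te in splits)

    def test_k_too_small(self, small_motif_dataset):
        with pytest.raises(ValueError):
            kfold_splits(small_motif_dataset, 1, seed=0)

    def test_stratified_keeps_class_balance(self, small_motif_dataset):
        labels = np.array(small_motif_dataset.labels)
        for _, te in kfold_splits(small_motif_dataset, 4, seed=1, stratified=True):
            frac = labels[te].mean()
            assert abs(frac - labels.mean()) < 0.15


class TestScaffoldSplit:
    def test_disjoint_scaffolds(self, small_motif_dataset):
        for seed in range(5):
            tr, te = scaffold_split(small_motif_dataset, 0.3, seed)
            tr_sc = {scaffold_of(small_motif_dataset.records[i].canonical_smiles) for i in tr}
            te_sc = {scaffold_of(small_motif_dataset.records[i].canonical_smiles) for i in te}
            assert not (tr_sc & te_sc)
            assert len(tr) + len(te) == len(small_motif_dataset)

    def test_single_scaffold_errors(self):
        ds, _ = from_smiles(
            ["Cc1ccccc1", "CCc1ccccc1", "CCCc1ccccc1"], [1, 0, 1]
        )
        with pytest.raises(ValueError, match="leakage"):
            scaffold_split(ds, 0.3, seed=0)

    def test_two_scaffold_groups_split_whole(self):
        smiles = [f"{'C' * i}c1ccccc1" for i in range(1, 7)] + [
            f"{'C' * i}C1CCCCC1" for i in range(1, 5)
        ]
        ds, _ = from_smiles(smiles, [1, 0] * 5)
        tr, te = scaffold_split(ds, 0.4, seed=0)
        te_sc = {scaffold_of(ds.records[i].canonical_smiles) for i in te}
        tr_sc = {scaffold_of(ds.records[i].canonical_smiles) for i in tr}
        assert len(te_sc) == 1 and len(tr_sc) == 1

    def test_bad_fraction(self, small_motif_dataset):
        with pytest.raises(ValueError):
            scaffold_split(small_motif_dataset, 0.0, seed=0)

    def test_acyclic_molecules_form_singletons(self):
        assert scaffold_of("CCO") == "CCO"
        assert scaffold_of("Cc1ccccc1") == "c1ccccc1"


class TestSimilarityScreenEvaluation:
    def _record(self, smiles, rid, potency):
        from transportscreen import standardize_record

        rep = standardize_record(smiles, rid, potency=potency)
        return rep.record

    def test_overlap_and_gray_zone_rules(self):
        reference = Dataset(records=[self._record("c1ccccc1CC", "ref0", None)])
        external = Dataset(
            records=[
                self._record("c1ccccc1CC", "dup", 1e-7),     # in reference: excluded
                self._record("c1ccccc1CCC", "act", 1e-7),    # active
                self._record("c1ccccc1CCO", "gray", 5e-6),   # between cutoffs: dropped
                self._record("CCCCCCCC", "inact", 1e-4),     # inactive
            ]
        )
        _, auc, rows = evaluate_similarity_screen(reference, external)
        scored = {r["query_id"] for r in rows}
        assert scored == {"act", "inact"}
        assert auc == 1.0  # near-duplicate active outranks the alkane

    def test_one_class_after_filtering_errors(self):
        reference = Dataset(records=[self._record("c1ccccc1", "r", None)])
        external = Dataset(records=[self._record("c1ccccc1C", "a", 1e-7)])
        with pytest.raises(ValueError, match="both classes"):
            evaluate_similarity_screen(reference, external)

    def test_missing_potency_errors(self):
        reference = Dataset(records=[self._record("c1ccccc1", "r", None)])
        external = Dataset(records=[self._record("c1ccccc1C", "a", None)])
        with pytest.raises(ValueError, match="potency"):
            evaluate_similarity_screen(reference, external)
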