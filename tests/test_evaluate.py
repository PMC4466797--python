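"""Confusion-matrix metrics, ROC/AUC, cross-validation, consensus."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from steptriage.classify import CostMatrix
from steptriage.errors import ValidationError
from steptriage.evaluate import (
    ConfusionMatrix,
    consensus,
    cross_validate,
    metrics,
    roc_auc,
    stratified_folds,
)
from tests.conftest import make_numeric_table, overlapping_classes

# 5-fold CV confusion matrices of the reference screen (177 actives and 71,669
# inactives per fold), with the published metric values.
REFERENCE_ROWS = [
    # tp, tn, fp, fn, sens%, spec%, acc%, g-mean
    (92, 57215, 14454, 85, 52.0, 79.8, 79.7, 0.64),
    (115, 56697, 14972, 62, 64.9, 79.1, 79.0, 0.71),
    (123, 56903, 14766, 54, 69.4, 79.3, 79.3, 0.74),
    (58, 57588, 14081, 119, 32.8, 80.3, 80.2, 0.51),
    (102, 58049, 13620, 75, 57.6, 80.9, 80.9, 0.68),
    (65, 57796, 13873, 112, 36.7, 80.6, 80.5, 0.54),
]


class TestMetrics:
    @pytest.mark.parametrize("tp,tn,fp,fn,sens,spec,acc,gmean", REFERENCE_ROWS)
    def test_reference_screen_rows(self, tp, tn, fp, fn, sens, spec, acc, gmean):
        """Published per-fold results are reproduced within the precision the
        source table prints (it mixes round-half and truncation, hence 0.1)."""
        rep = metrics(ConfusionMatrix(tp=tp, tn=tn, fp=fp, fn=fn))
        assert 100 * rep.sensitivity == pytest.approx(sens, abs=0.1)
        assert 100 * rep.specificity == pytest.approx(spec, abs=0.1)
        assert 100 * rep.accuracy == pytest.approx(acc, abs=0.1)
        assert rep.g_mean == pytest.approx(gmean, abs=0.01)

    def test_fold_total_matches_reference_screen(self):
        for tp, tn, fp, fn, *_ in REFERENCE_ROWS:
            assert tp + tn + fp + fn == 71846

    def test_perfect_classifier(self):
        rep = metrics(ConfusionMatrix(tp=7, tn=7, fp=0, fn=0))
        assert rep.sensitivity == rep.specificity == rep.accuracy == rep.g_mean == 1.0

    def test_gmean_is_geometric_mean(self):
        rep = metrics(ConfusionMatrix(tp=50, tn=60, fp=40, fn=50))
        assert rep.g_mean == pytest.approx(math.sqrt(rep.sensitivity * rep.specificity))

    def test_empty_margin_is_undefined_not_zero(self):
        rep = metrics(ConfusionMatrix(tp=0, tn=5, fp=5, fn=0))
        assert rep.sensitivity is None and rep.g_mean is None
        assert rep.specificity == 0.5

    def test_negative_cells_rejected(self):
        with pytest.raises(ValidationError):
            ConfusionMatrix(tp=-1, tn=0, fp=0, fn=0)


def _pairwise_auc(labels, scores):
    """Exhaustive concordance oracle: ties count half."""
    pos = [s for s, y in zip(scores, labels) if y == 1]
    neg = [s for s, y in zip(scores, labels) if y == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


class TestRocAuc:
    def test_perfect_ranking(self):
        labels = [0, 0, 1, 1]
        _, auc = roc_auc(labels, [0.1, 0.2, 0.8, 0.9])
        assert auc == 1.0

    def test_all_tied_scores(self):
        _, auc = roc_auc([0, 1, 0, 1], [0.5] * 4)
        assert auc == 0.5

    def test_six_point_hand_case(self):
        # actives 0.9, 0.6; inactives 0.8, 0.4, 0.3, 0.2 -> 7 of 8 pairs concordant
        labels = [1, 1, 0, 0, 0, 0]
        scores = [0.9, 0.6, 0.8, 0.4, 0.3, 0.2]
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(7 / 8)
        assert auc == pytest.approx(_pairwise_auc(labels, scores))

    def test_one_class_rejected(self):
        with pytest.raises(ValidationError):
            roc_auc([1, 1, 1], [0.1, 0.2, 0.3])

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_pairwise_oracle_on_random_inputs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(10, 200))
        labels = rng.integers(0, 2, size=n)
        if labels.min() == labels.max():
            labels[0] = 1 - labels[0]
        scores = np.round(rng.random(n), 2)  # coarse grid to exercise ties
        _, auc = roc_auc(labels, scores)
        assert auc == pytest.approx(_pairwise_auc(labels, scores), abs=1e-12)


class TestCrossValidation:
    def test_pooled_matrix_conserves_rows(self):
        table, y = overlapping_classes(n=300, seed=1)
        pooled, fold_reports, auc = cross_validate(
            "naive_bayes", table, y, cost=CostMatrix(), folds=5, seed=0
        )
        assert pooled.total == 300
        assert len(fold_reports) == 5
        assert 0.5 < auc <= 1.0

    def test_fold_sizes_balanced(self):
        y = np.array([1] * 10 + [0] * 90)
        folds = stratified_folds(y, folds=5, seed=0)
        for _, test_idx in folds:
            assert len(test_idx) == 20
            assert y[test_idx].sum() == 2  # stratification keeps actives in every fold

    def test_same_seed_same_folds(self):
        y = np.array([1] * 10 + [0] * 90)
        a = stratified_folds(y, folds=5, seed=3)
        b = stratified_folds(y, folds=5, seed=3)
        for (_, ta), (_, tb) in zip(a, b):
            np.testing.assert_array_equal(ta, tb)

    def test_too_few_actives_advises_fewer_folds(self):
        y = np.array([1] * 3 + [0] * 97)
        with pytest.raises(ValidationError, match="fewer folds"):
            stratified_folds(y, folds=5, seed=0)


class TestConsensus:
    def test_intersection(self):
        assert consensus([{"A", "B", "C"}, {"B", "C"}, {"B", "C", "D"}]) == {"B", "C"}

    def test_empty_model_set_empties_consensus(self):
        assert consensus([{"A"}, set(), {"A"}]) == set()

    def test_single_model_identity(self):
        assert consensus([{"X", "Y"}]) == {"X", "Y"}

    def test_no_models_rejected(self):
        with pytest.raises(ValidationError):
            consensus([])

    @given(
        st.lists(
            st.sets(st.sampled_from("ABCDEFGH")), min_size=1, max_size=5
        )
    )
    @settings(max_examples=100, derandomize=True)
    def test_consensus_is_subset_of_every_model(self, sets):
        result = consensus(sets)
        for s in sets:
            assert result <= s
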