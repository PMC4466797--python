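"""Cost-sensitive learners and FN-cost tuning against the FP ceiling."""

import numpy as np
import pytest

from steptriage.classify import (
    CostMatrix,
    cv_confusion,
    predict,
    train,
    tune_fn_cost,
)
from steptriage.errors import DegenerateDataError, ValidationError
from tests.conftest import make_numeric_table, overlapping_classes

FAMILIES = ("naive_bayes", "random_forest", "svm_smo_like")


def separable_table(n=40, seed=0):
    rng = np.random.default_rng(seed)
    y = np.array([0, 1] * (n // 2))
    X = rng.normal(0, 0.2, size=(n, 2))
    X[y == 1] += 5.0
    return make_numeric_table(X), y


class TestTrainPredict:
    @pytest.mark.parametrize("family", FAMILIES)
    def test_separable_training_accuracy(self, family):
        table, y = separable_table()
        model = train(family, table, y, seed=0)
        pred, scores = predict(model, table)
        assert (pred == y).all()
        assert scores.shape == y.shape

    def test_cost_matrix_invariants(self):
        with pytest.raises(ValidationError):
            CostMatrix(c_fn=0.5)
        with pytest.raises(ValidationError):
            CostMatrix(c_fn=2.0, c_fp=2.0)

    def test_naive_bayes_hand_posterior(self):
        # 4 rows, one binary feature: actives see x={1,0}, inactives x={1,1}.
        # With Laplace alpha=1: P(x=1|act)=(1+1)/(2+2)=1/2, P(x=1|inact)=(2+1)/(2+2)=3/4,
        # priors 1/2 each -> P(act|x=1) = (1/2*1/2)/(1/2*1/2 + 1/2*3/4) = 0.4
        table = make_numeric_table(np.array([[1.0], [0.0], [1.0], [1.0]]))
        y = np.array([1, 1, 0, 0])
        model = train("naive_bayes", table, y, seed=0)
        probe = make_numeric_table(np.array([[1.0]]))
        _, score = predict(model, probe)
        assert score[0] == pytest.approx(0.4, abs=1e-12)

    def test_weighting_equals_replication_for_naive_bayes(self):
        rng = np.random.default_rng(4)
        X = np.column_stack([
            rng.integers(0, 2, size=30).astype(float),
            rng.normal(size=30),
        ])
        y = (rng.random(30) < 0.3).astype(int)
        table = make_numeric_table(X)
        k = 3
        weighted = train("naive_bayes", table, y, cost=CostMatrix(c_fn=k), seed=0)
        rep_rows = np.concatenate([X] + [X[y == 1]] * (k - 1))
        rep_y = np.concatenate([y, np.ones((k - 1) * int(y.sum()), dtype=int)])
        replicated = train(
            "naive_bayes",
            make_numeric_table(rep_rows, binary_mask=[True, False]),
            rep_y,
            seed=0,
        )
        probe = make_numeric_table(rng.normal(size=(10, 2)), binary_mask=[True, False])
        probe.values[:, 0] = rng.integers(0, 2, size=10)
        _, s1 = predict(weighted, probe)
        _, s2 = predict(replicated, probe)
        np.testing.assert_allclose(s1, s2, atol=1e-12)

    @pytest.mark.parametrize("family", FAMILIES)
    def test_raising_fn_cost_shifts_toward_sensitivity(self, family):
        table, y = overlapping_classes(n=400, shift=1.0, seed=2)
        lo = cv_confusion(family, table, y, CostMatrix(c_fn=1), folds=5, seed=0)
        hi = cv_confusion(family, table, y, CostMatrix(c_fn=16), folds=5, seed=0)
        sens = lambda cm: cm.tp / (cm.tp + cm.fn)
        spec = lambda cm: cm.tn / (cm.tn + cm.fp)
        assert sens(hi) >= sens(lo)
        assert spec(hi) <= spec(lo)

    def test_single_class_training_rejected(self):
        table, _ = separable_table()
        with pytest.raises(DegenerateDataError):
            train("naive_bayes", table, np.zeros(len(table.compound_ids), dtype=int))

    def test_predict_schema_mismatch_names_columns(self):
        table, y = separable_table()
        model = train("naive_bayes", table, y, seed=0)
        other = make_numeric_table(np.zeros((3, 2)), names=["a", "b"])
        with pytest.raises(ValidationError, match="f00"):
            predict(model, other)

    def test_predict_permutation_equivariance(self):
        table, y = separable_table()
        model = train("random_forest", table, y, seed=0)
        perm = np.random.default_rng(0).permutation(len(y))
        permuted = make_numeric_table(table.values[perm], ids=[f"p{i}" for i in perm])
        c1, s1 = predict(model, table)
        c2, s2 = predict(model, permuted)
        np.testing.assert_array_equal(c1[perm], c2)
        np.testing.assert_allclose(s1[perm], s2)

    def test_identical_rows_identical_scores(self):
        table, y = separable_table()
        model = train("svm_smo_like", table, y, seed=0)
        probe = make_numeric_table(np.tile([[1.0, 2.0]], (5, 1)))
        _, scores = predict(model, probe)
        assert np.ptp(scores) == 0.0

    def test_deterministic_per_seed(self):
        table, y = overlapping_classes(n=200, seed=5)
        m1 = train("random_forest", table, y, seed=7)
        m2 = train("random_forest", table, y, seed=7)
        _, s1 = predict(m1, table)
        _, s2 = predict(m2, table)
        np.testing.assert_array_equal(s1, s2)

    def test_model_persistence_round_trip(self, tmp_path):
        from steptriage.classify import CostModel

        table, y = separable_table()
        model = train("naive_bayes", table, y, cost=CostMatrix(c_fn=4), seed=0)
        path = tmp_path / "model.pkl"
        model.save(path)
        back = CostModel.load(path)
        assert back.cost == model.cost and back.learner_family == "naive_bayes"
        _, s1 = predict(model, table)
        _, s2 = predict(back, table)
        np.testing.assert_allclose(s1, s2)


class TestTuneFnCost:
    def test_separable_needs_no_escalation(self):
        table, y = separable_table(n=60)
        model, c_fn, cm = tune_fn_cost("naive_bayes", table, y, folds=3, seed=0)
        assert c_fn == 1.0
        assert cm.fp == 0
        assert model.warning is None

    def test_returned_cost_respects_ceiling_and_brackets(self):
        table, y = overlapping_classes(n=400, shift=1.2, seed=3)
        model, c_fn, cm = tune_fn_cost("naive_bayes", table, y, fp_ceiling=0.20, seed=0)
        assert cm.fp_rate <= 0.20
        assert model.warning is None
        nxt = cv_confusion(
            "naive_bayes", table, y, CostMatrix(c_fn=c_fn + 1), folds=5, seed=0
        )
        assert nxt.fp_rate > 0.20

    def test_linear_scan_oracle_agrees(self):
        # small enough to scan every integer cost up to the bracketing point
        table, y = overlapping_classes(n=240, shift=1.2, seed=8)
        model, c_fn, _ = tune_fn_cost("naive_bayes", table, y, fp_ceiling=0.20,
                                      folds=4, seed=0)
        rates = {}
        c = 1
        while True:
            rates[c] = cv_confusion(
                "naive_bayes", table, y, CostMatrix(c_fn=c), folds=4, seed=0
            ).fp_rate
            if rates[c] > 0.20 or c > 4 * c_fn + 8:
                break
            c += 1
        oracle = max(k for k, r in rates.items() if r <= 0.20)
        assert c_fn == oracle

    def test_ceiling_monotone_in_threshold(self):
        table, y = overlapping_classes(n=400, shift=1.2, seed=3)
        _, loose, _ = tune_fn_cost("naive_bayes", table, y, fp_ceiling=0.5, seed=0)
        _, tight, _ = tune_fn_cost("naive_bayes", table, y, fp_ceiling=0.2, seed=0)
        assert loose >= tight

    def test_unreachable_ceiling_flagged(self):
        # heavy overlap and a tiny ceiling: FP rate exceeds it already at cost 1
        table, y = overlapping_classes(n=300, active_fraction=0.5, shift=0.1, seed=0)
        model, c_fn, _ = tune_fn_cost("naive_bayes", table, y, fp_ceiling=0.01, seed=0)
        assert c_fn == 1.0
        assert model.warning is not None
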