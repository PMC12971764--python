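"""Split plans, leakage audit, metrics, grid search, paired comparisons."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neuroskill.evaluation import (compute_metrics, grid_search,
                                   holm_adjust, leakage_audit,
                                   make_split_plan, paired_tests)
from neuroskill.model import ModelConfig

from conftest import toy_batch


class TestSplitPlan:
    def test_23_participants_split_16_7_disjoint(self):
        ps = [f"P{i:02d}" for i in range(23)]
        plan = make_split_plan(ps, seed=0)
        assert len(plan.repeats) == 10
        for rep in plan.repeats:
            assert len(rep.train_participants) == 16
            assert len(rep.test_participants) == 7
            assert not set(rep.train_participants) & set(rep.test_participants)
            assert len(rep.folds) == 4

    def test_fold_validation_disjoint_from_fold_training(self):
        ps = [f"P{i:02d}" for i in range(23)]
        plan = make_split_plan(ps, seed=1)
        for rep in plan.repeats:
            for tr, va in rep.folds:
                assert not set(tr) & set(va)
                assert set(tr) | set(va) == set(rep.train_participants)

    def test_same_seed_identical_plan(self):
        ps = [f"P{i}" for i in range(23)]
        a = make_split_plan(ps, seed=5)
        b = make_split_plan(ps, seed=5)
        for ra, rb in zip(a.repeats, b.repeats):
            assert ra.train_participants == rb.train_participants
            assert ra.test_participants == rb.test_participants
            assert ra.folds == rb.folds

    def test_too_few_participants_rejected(self):
        with pytest.raises(ValueError):
            make_split_plan(["a", "b"], n_train=16, n_test=7)

    def test_leakage_audit_clean_on_generated_plans(self):
        ps = [f"P{i:02d}" for i in range(23)]
        for seed in (0, 1, 2):
            assert leakage_audit(make_split_plan(ps, seed=seed)) == []

    def test_stratified_plan_covers_all_classes_everywhere(self):
        ps = [f"P{i:02d}" for i in range(12)]
        classes = {p: (i % 3) + 1 for i, p in enumerate(ps)}
        plan = make_split_plan(ps, n_train=8, n_test=4, k=2, repeats=3,
                               seed=2, classes=classes)
        assert leakage_audit(plan) == []
        for rep in plan.repeats:
            for group in ([rep.test_participants]
                          + [tr for tr, _ in rep.folds]):
                assert {classes[p] for p in group} == {1, 2, 3}


def brute_force_metrics(t, p):
    """Independent recount: python loops over every pair and class."""
    classes = (1, 2, 3)
    cm = [[sum(1 for a, b in zip(t, p) if a == ti and b == pi)
           for pi in classes] for ti in classes]
    total = len(t)
    acc = sum(cm[i][i] for i in range(3)) / total
    f1s, supports, precs, recs = [], [], [], []
    for i in range(3):
        tp = cm[i][i]
        fp = sum(cm[r][i] for r in range(3)) - tp
        fn = sum(cm[i][c] for c in range(3)) - tp
        prec = tp / (tp + fp) if tp + fp else 0.0
        rec = tp / (tp + fn) if tp + fn else 0.0
        f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
        f1s.append(f1)
        supports.append(sum(cm[i]))
        precs.append(prec)
        recs.append(rec)
    wf1 = sum(f * s for f, s in zip(f1s, supports)) / total
    return np.array(cm), acc, wf1, precs, recs


class TestMetrics:
    def test_perfect_predictions(self):
        y = np.array([1, 2, 3, 1, 2, 3])
        rep = compute_metrics(y, y)
        assert rep.accuracy == 1.0
        assert rep.weighted_f1 == pytest.approx(1.0)

    def test_hand_computed_confusion_example(self):
        # confusion [[8,2,0],[1,7,2],[0,1,9]]
        t, p = [], []
        for i, row in enumerate([[8, 2, 0], [1, 7, 2], [0, 1, 9]]):
            for j, n in enumerate(row):
                t += [i + 1] * n
                p += [j + 1] * n
        rep = compute_metrics(np.array(t), np.array(p))
        assert rep.accuracy == pytest.approx(24 / 30)
        # hand-derived per-class F1: 0.8421, 0.7000, 0.8571
        np.testing.assert_allclose(
            rep.per_class_f1, [0.842105, 0.7, 0.857143], atol=1e-6)
        assert rep.weighted_f1 == pytest.approx(0.799749, abs=1e-6)

    def test_matches_bruteforce_recount_on_random_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(300):
            n = int(rng.integers(3, 60))
            t = rng.integers(1, 4, n)
            p = rng.integers(1, 4, n)
            rep = compute_metrics(t, p)
            cm, acc, wf1, precs, recs = brute_force_metrics(t.tolist(),
                                                            p.tolist())
            np.testing.assert_array_equal(rep.confusion, cm)
            assert rep.accuracy == pytest.approx(acc, abs=1e-12)
            assert rep.weighted_f1 == pytest.approx(wf1, abs=1e-12)
            np.testing.assert_allclose(rep.per_class_precision, precs,
                                       atol=1e-12)
            np.testing.assert_allclose(rep.per_class_recall, recs,
                                       atol=1e-12)

    def test_matches_sklearn_weighted_f1(self):
        from sklearn.metrics import f1_score

        rng = np.random.default_rng(1)
        t = rng.integers(1, 4, 200)
        p = rng.integers(1, 4, 200)
        rep = compute_metrics(t, p)
        assert rep.weighted_f1 == pytest.approx(
            f1_score(t, p, average="weighted"), abs=1e-12)

    def test_empty_prediction_class_precision_zero_with_warning(self):
        t = np.array([1, 2, 3, 3])
        p = np.array([1, 1, 1, 1])
        with pytest.warns(UserWarning, match="zero predicted"):
            rep = compute_metrics(t, p)
        assert rep.per_class_precision[1] == 0.0

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(np.array([1, 2]), np.array([1]))


class TestPairedTests:
    def test_holm_worked_example(self):
        adj = holm_adjust(np.array([0.01, 0.02, 0.04]))
        np.testing.assert_allclose(adj, [0.03, 0.04, 0.04], atol=1e-12)

    def test_identical_scores_family_p_1(self):
        s = {"a": np.ones(10) * 0.8, "b": np.ones(10) * 0.8,
             "c": np.ones(10) * 0.8}
        res = paired_tests(s)
        assert all(r.p_value == 1.0 and r.p_holm == 1.0 for r in res)

    def test_adjusted_p_at_least_raw(self):
        rng = np.random.default_rng(2)
        s = {"a": rng.normal(0.8, 0.02, 10),
             "b": rng.normal(0.7, 0.02, 10),
             "c": rng.normal(0.75, 0.02, 10),
             "d": rng.normal(0.75, 0.02, 10)}
        res = paired_tests(s)
        assert len(res) == 6         # all unordered pairs
        for r in res:
            assert r.p_holm >= r.p_value - 1e-15
            assert r.p_holm <= 1.0

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_holm_monotone_in_sorted_order(self, ps):
        adj = holm_adjust(np.array(ps))
        order = np.argsort(ps)
        assert (np.diff(adj[order]) >= -1e-12).all()

    def test_unequal_run_counts_rejected(self):
        with pytest.raises(ValueError):
            paired_tests({"a": np.ones(5), "b": np.ones(6)})

    def test_wilcoxon_companion_reported(self):
        rng = np.random.default_rng(3)
        s = {"a": rng.normal(0.8, 0.05, 12), "b": rng.normal(0.6, 0.05, 12)}
        res = paired_tests(s, wilcoxon=True)
        assert res[0].wilcoxon_p is not None
        assert 0 <= res[0].wilcoxon_p <= 1


class TestGridSearch:
    def _folds(self):
        return [(["p0", "p1"], ["p2", "p3"]), (["p2", "p3"], ["p0", "p1"])]

    def test_single_point_grid_short_circuits(self):
        cfg = ModelConfig(seed=1)
        best, info = grid_search([cfg], self._folds(), toy_batch())
        assert best is cfg

    def test_duplicated_config_deterministic_selection(self):
        batch = toy_batch(n=16, s=32, f=4, seed=4)
        a = ModelConfig(conv_filters=4, kernel_size=3, lstm_units=4,
                        dense_units=4, epochs=2, batch_size=8, seed=1)
        b = ModelConfig(conv_filters=4, kernel_size=3, lstm_units=4,
                        dense_units=4, epochs=2, batch_size=8, seed=1)
        best1, _ = grid_search([a, b], self._folds(), batch)
        best2, _ = grid_search([b, a], self._folds(), batch)
        assert best1.key() == best2.key()

    def test_superior_config_wins_on_separable_data(self):
        # class signal: large constant offset per class in every feature
        batch = toy_batch(n=24, s=32, f=4, seed=5)
        batch.labels[:] = np.repeat([1, 2, 3], 8)
        batch.participant_ids[:] = np.tile(["p0", "p1", "p2", "p3"], 6)
        offset = (batch.labels.astype(np.float32) - 2.0) * 3.0
        batch.data += offset[:, None, None, None]
        learner = ModelConfig(conv_filters=4, kernel_size=3, lstm_units=6,
                              dense_units=8, epochs=40, batch_size=8,
                              learning_rate=1e-2, dropout=0.0, l2=0.0, seed=1)
        frozen = ModelConfig(conv_filters=4, kernel_size=3, lstm_units=6,
                             dense_units=8, epochs=40, batch_size=8,
                             learning_rate=0.0, dropout=0.0, l2=0.0, seed=1)
        best, info = grid_search([frozen, learner], self._folds(), batch)
        assert best.learning_rate == 1e-2
        scores = list(info["scores"].values())
        assert max(scores) == info["scores"][repr(learner.key())]

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            grid_search([], self._folds(), toy_batch())
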