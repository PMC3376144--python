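import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from methylpred import EncoderConfig, SvmHyperparams
from methylpred.dataset import DatasetBundle
from methylpred.encoders import encode_windows
from methylpred.evaluation import (
    ConfusionCounts,
    EvaluationError,
    LeakageError,
    confusion,
    cross_validate,
    independent_test,
    kfold_split,
    metrics,
    self_consistency,
)
from methylpred.svm import predict, train

from oracles import metrics_oracle


class TestConfusion:
    def test_all_correct(self):
        y = [1] * 5 + [0] * 5
        c = confusion(y, y)
        assert (c.tp, c.fp, c.tn, c.fn) == (5, 0, 5, 0)

    def test_all_inverted(self):
        y = np.array([1] * 5 + [0] * 5)
        c = confusion(y, 1 - y)
        assert (c.tp, c.fp, c.tn, c.fn) == (0, 5, 0, 5)

    def test_mixed_hand_count(self):
        y_true = [1, 1, 1, 1, 0, 0, 0, 0, 0, 1]
        y_pred = [1, 0, 1, 1, 0, 1, 0, 0, 1, 0]
        c = confusion(y_true, y_pred)
        assert (c.tp, c.fp, c.tn, c.fn) == (3, 2, 3, 2)
        assert c.total == len(y_true)

    def test_length_mismatch(self):
        with pytest.raises(EvaluationError, match="mismatch"):
            confusion([1, 0], [1])


class TestMetrics:
    def test_perfect_classifier(self):
        m = metrics(ConfusionCounts(5, 0, 5, 0))
        assert (m.sn, m.sp, m.acc, m.mcc) == (1.0, 1.0, 1.0, 1.0)

    def test_symmetric_case(self):
        m = metrics(ConfusionCounts(1, 1, 1, 1))
        assert (m.sn, m.sp, m.acc, m.mcc) == (0.5, 0.5, 0.5, 0.0)

    def test_inverted_classifier(self):
        m = metrics(ConfusionCounts(0, 5, 0, 5))
        assert m.mcc == -1.0

    def test_worked_example(self):
        m = metrics(ConfusionCounts(tp=3, fp=2, tn=2, fn=1))
        assert m.sn == 0.75
        assert m.sp == 0.5
        assert m.acc == 0.625
        assert m.mcc == pytest.approx(4 / math.sqrt(240))

    def test_degenerate_denominators_return_zero(self):
        with pytest.warns(UserWarning, match="Sn"):
            m = metrics(ConfusionCounts(0, 1, 1, 0))  # no positives evaluated
        assert m.sn == 0.0 and m.mcc == 0.0

    def test_matches_direct_formula_on_random_tuples(self):
        rng = np.random.default_rng(5)
        for _ in range(500):
            tp, fp, tn, fn = (int(v) for v in rng.integers(0, 50, size=4))
            if tp + fp + tn + fn == 0:
                continue
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                m = metrics(ConfusionCounts(tp, fp, tn, fn))
            sn, sp, acc, mcc = metrics_oracle(tp, fp, tn, fn)
            assert (m.sn, m.sp, m.acc) == (sn, sp, acc)
            assert m.mcc == pytest.approx(mcc, abs=1e-12)

    def test_mcc_agrees_with_sklearn(self):
        from sklearn.metrics import matthews_corrcoef

        rng = np.random.default_rng(6)
        y_true = rng.integers(0, 2, size=200)
        y_pred = rng.integers(0, 2, size=200)
        m = metrics(confusion(y_true, y_pred))
        assert m.mcc == pytest.approx(matthews_corrcoef(y_true, y_pred))

    @given(st.integers(0, 100), st.integers(0, 100), st.integers(0, 100), st.integers(0, 100))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_mcc_invariant_under_class_swap(self, tp, fp, tn, fn):
        """Swapping (TP,FN) with (TN,FP) relabels the classes: MCC is
        unchanged, Sn and Sp trade places."""
        if tp + fp + tn + fn == 0:
            return
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = metrics(ConfusionCounts(tp, fp, tn, fn))
            b = metrics(ConfusionCounts(tn, fn, tp, fp))
        assert a.mcc == pytest.approx(b.mcc, abs=1e-12)
        assert a.sn == pytest.approx(b.sp) and a.sp == pytest.approx(b.sn)


class TestKfoldSplit:
    def test_exact_division(self):
        folds = kfold_split(20, 20, 10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 4 for f in folds)
        for f in folds:  # 2 positives + 2 negatives each
            assert int(np.sum(f < 20)) == 2

    def test_remainder_rule(self):
        folds = kfold_split(21, 20, 10, seed=0)
        pos_sizes = sorted(int(np.sum(f < 21)) for f in folds)
        assert pos_sizes == [2] * 9 + [3]

    def test_partition_property(self):
        folds = kfold_split(33, 47, 5, seed=3)
        combined = np.concatenate(folds)
        assert sorted(combined) == list(range(80))

    def test_determinism(self):
        a = kfold_split(30, 30, 10, seed=4)
        b = kfold_split(30, 30, 10, seed=4)
        assert all(np.array_equal(x, y) for x, y in zip(a, b))

    def test_k_too_large(self):
        with pytest.raises(EvaluationError, match="exceeds"):
            kfold_split(5, 100, 10, seed=0)

    def test_loo_mode(self):
        folds = kfold_split(3, 4, 7, seed=0)
        assert [list(f) for f in folds] == [[i] for i in range(7)]

    @given(st.integers(5, 40), st.integers(5, 40), st.integers(2, 5), st.integers(0, 10**6))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_stratification_property(self, n_pos, n_neg, k, seed):
        folds = kfold_split(n_pos, n_neg, k, seed)
        pos_counts = [int(np.sum(f < n_pos)) for f in folds]
        neg_counts = [len(f) - p for f, p in zip(folds, pos_counts)]
        assert max(pos_counts) - min(pos_counts) <= 1
        assert max(neg_counts) - min(neg_counts) <= 1
        assert sorted(np.concatenate(folds)) == list(range(n_pos + n_neg))


@pytest.fixture
def toy_bundle(small_bundle):
    """20 positives + one 20-negative set, for fast protocol tests."""
    return DatasetBundle(
        positives=small_bundle.positives[:20],
        negative_sets=[small_bundle.negative_sets[0][:20]],
        ratio=1,
        seed=0,
    )


class TestCrossValidate:
    def test_report_structure(self, small_bundle, default_config):
        report = cross_validate(
            small_bundle, default_config, SvmHyperparams(), k=5, seed=1
        )
        assert len(report.per_set) == 5
        assert report.window_size == 15
        summary = report.summary()
        assert set(summary) == {"sn", "sp", "acc", "mcc"}
        # overall mean equals the mean of per-set values
        assert summary["acc"][0] == pytest.approx(
            np.mean([m.acc for m in report.per_set])
        )

    def test_label_shuffle_destroys_signal(self, small_bundle, default_config):
        """With labels randomized, accuracy sits near chance."""
        rng = np.random.default_rng(9)
        from dataclasses import replace

        pos, neg = list(small_bundle.positives), list(small_bundle.negative_sets[0])
        windows = pos + neg
        labels = ["positive"] * len(pos) + ["negative"] * len(neg)
        rng.shuffle(labels)
        shuffled = [replace(w, label=l) for w, l in zip(windows, labels)]
        bundle = DatasetBundle(
            positives=[w for w in shuffled if w.label == "positive"],
            negative_sets=[[w for w in shuffled if w.label == "negative"]],
            ratio=1,
            seed=0,
        )
        report = cross_validate(bundle, default_config, SvmHyperparams(), k=10, seed=9)
        assert abs(report.mean("mcc")) <= 0.25
        assert 0.35 <= report.mean("acc") <= 0.65

    def test_loo_equals_explicit_loop(self, toy_bundle, default_config):
        n = len(toy_bundle.positives) + len(toy_bundle.negative_sets[0])
        report = cross_validate(
            toy_bundle, default_config, SvmHyperparams(), k=n, seed=2
        )
        y_true, y_pred = report.predictions[0]

        windows = list(toy_bundle.positives) + list(toy_bundle.negative_sets[0])
        X, y = encode_windows(windows, default_config)
        loop_pred = []
        for i in range(n):
            mask = np.ones(n, dtype=bool)
            mask[i] = False
            model = train(X[mask], y[mask], SvmHyperparams())
            labels, _ = predict(model, X[i : i + 1])
            loop_pred.append(labels[0])
        assert np.array_equal(y_true, y)
        assert np.array_equal(y_pred, np.array(loop_pred))

    def test_grid_tuning_mode_runs(self, toy_bundle, default_config):
        grid = [SvmHyperparams(C=1.0, gamma=0.01), SvmHyperparams(C=8.0, gamma=2.0**-5)]
        report = cross_validate(
            toy_bundle, default_config, k=5, seed=3, tune_grid=grid, tune_folds=4
        )
        assert report.params_per_set[0] in grid


class TestSelfConsistency:
    def test_separable_data_scores_perfectly(self, small_bundle, default_config):
        m = self_consistency(small_bundle, default_config, SvmHyperparams())
        assert m.acc >= 0.95  # training-set evaluation of a strong signal

    def test_deterministic(self, toy_bundle, default_config):
        a = self_consistency(toy_bundle, default_config, SvmHyperparams())
        b = self_consistency(toy_bundle, default_config, SvmHyperparams())
        assert a == b


class TestIndependentTest:
    def test_protein_overlap_rejected(self, small_bundle, default_config):
        with pytest.raises(LeakageError):
            independent_test(
                small_bundle, small_bundle.positives[:3], default_config
            )

    def test_empty_test_set_rejected(self, small_bundle, default_config):
        with pytest.raises(EvaluationError, match="empty"):
            independent_test(small_bundle, [], default_config)

    def test_held_out_proteins_score_near_cv(self, default_config):
        from methylpred import build_bundle, make_fixture
        from methylpred.dataset import deduplicate, enumerate_candidates

        train_ds = make_fixture("small", seed=21)
        test_ds = make_fixture("small", seed=22)
        # re-id the test proteins so the two generator runs cannot collide
        for p in test_ds.proteins:
            p.id = "held_" + p.id
        test_sites = [
            type(s)("held_" + s.protein_id, s.position, s.residue, s.label, s.source)
            for s in test_ds.sites
        ]
        bundle = build_bundle(train_ds.proteins, train_ds.sites, "R", seed=21)
        pos, neg = enumerate_candidates(test_ds.proteins, test_sites, "R", L=7)
        reduced = deduplicate(pos + neg)
        rng = np.random.default_rng(23)
        negs = [w for w in reduced if w.label == "negative"]
        keep = rng.choice(len(negs), size=len(pos), replace=False)
        test_windows = [w for w in reduced if w.label == "positive"] + [
            negs[i] for i in keep
        ]
        m = independent_test(bundle, test_windows, default_config, SvmHyperparams())
        assert m.mcc >= 0.7  # generalizes across generator runs
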