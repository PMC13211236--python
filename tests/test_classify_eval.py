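import numpy as np
import pandas as pd
import pytest

from tasd.classify_eval import (
    ClassifierSpec,
    StressClassifier,
    decide,
    evaluate,
    grouped_kfold,
    report_from_confusion,
    round_half_up,
    run_ablation,
    split_by_participant,
    train_classifier,
)
from tasd.feature_extract import FEATURE_COLUMNS
from tasd.stats_separability import mann_whitney


def _feature_table(n_participants=15, rows_each=40, separable=True, seed=0):
    rng = np.random.default_rng(seed)
    frames = []
    for i in range(n_participants):
        y = rng.integers(0, 2, rows_each)
        X = rng.normal(0, 1, (rows_each, len(FEATURE_COLUMNS)))
        if separable:
            X[:, 0] += 3.0 * y
            X[:, 1] -= 2.0 * y
        frames.append(pd.DataFrame(X, columns=FEATURE_COLUMNS).assign(
            participant=f"P{i:02d}", session="S01", binary_label=y))
    return pd.concat(frames, ignore_index=True)


class TestSplits:
    def test_equal_participants_greedy_fill(self):
        table = _feature_table(15, 40)
        plan = split_by_participant(table, 0.2, seed=1)
        assert len(plan.test_participants) == 3
        assert not (plan.train_participants & plan.test_participants)

    def test_split_determinism(self):
        table = _feature_table(10, 20)
        p1 = split_by_participant(table, 0.2, seed=5)
        p2 = split_by_participant(table, 0.2, seed=5)
        assert p1.test_participants == p2.test_participants
        assert p1.plan_hash == p2.plan_hash

    def test_single_participant_error(self):
        with pytest.raises(ValueError):
            split_by_participant(_feature_table(1, 20), 0.2, 0)

    def test_grouped_kfold_partition(self):
        table = _feature_table(15, 10)
        plan = grouped_kfold(table, k=5, seed=2)
        test_sets = [te for _, te in plan.folds]
        assert all(len(te) == 3 for te in test_sets)
        union = frozenset().union(*test_sets)
        assert union == frozenset(table["participant"].unique())
        for i in range(5):
            for j in range(i + 1, 5):
                assert not (test_sets[i] & test_sets[j])

    def test_kfold_degenerate(self):
        with pytest.raises(ValueError):
            grouped_kfold(_feature_table(3, 5), k=5, seed=0)
        with pytest.raises(ValueError):
            grouped_kfold(_feature_table(5, 5), k=1, seed=0)


class TestDecide:
    def test_boundary_inclusive(self):
        assert decide(np.array([0.5]), 0.5)[0] == 1

    def test_threshold_semantics(self):
        np.testing.assert_array_equal(decide(np.array([0.2, 0.8]), 0.5), [0, 1])
        np.testing.assert_array_equal(decide(np.array([0.1, 0.2]), 0.5), [0, 0])

    def test_invalid_theta(self):
        with pytest.raises(ValueError):
            decide(np.array([0.5]), 1.5)


class TestConfusionReport:
    def test_printed_counts_reproduce_reported_metrics(self):
        rep = report_from_confusion(tn=1431, fp=135, fn=146, tp=688)
        assert rep["accuracy"] == pytest.approx(2119 / 2400)
        expected = {
            ("nostress", "precision"): 0.907, ("nostress", "recall"): 0.914,
            ("nostress", "f1"): 0.911,
            ("stress", "precision"): 0.836, ("stress", "recall"): 0.825,
            ("stress", "f1"): 0.830,
            ("macro", "precision"): 0.872, ("macro", "recall"): 0.869,
            ("macro", "f1"): 0.871,
            ("weighted", "precision"): 0.883, ("weighted", "recall"): 0.883,
            ("weighted", "f1"): 0.883,
        }
        for (section, metric), value in expected.items():
            assert rep[section][metric] == pytest.approx(value, abs=5e-4)
        assert rep["nostress"]["support"] == 1566
        assert rep["stress"]["support"] == 834

    def test_perfect_diagonal(self):
        rep = report_from_confusion(tn=10, fp=0, fn=0, tp=5)
        assert rep["accuracy"] == 1.0
        assert rep["stress"]["precision"] == rep["stress"]["recall"] == 1.0

    def test_degenerate_single_class_predictions_flagged(self):
        rep = report_from_confusion(tn=10, fp=0, fn=5, tp=0)
        assert rep["stress"]["recall"] == 0.0
        assert rep["stress"]["flagged"]

    def test_metric_closure(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            tn, fp, fn, tp = rng.integers(0, 100, 4)
            if tn + fp + fn + tp == 0:
                continue
            rep = report_from_confusion(int(tn), int(fp), int(fn), int(tp))
            n = tn + fp + fn + tp
            assert rep["accuracy"] == pytest.approx((tn + tp) / n, abs=1e-12)
            s0, s1 = rep["nostress"]["support"], rep["stress"]["support"]
            w_f1 = (s0 * rep["nostress"]["f1"] + s1 * rep["stress"]["f1"]) / n
            assert rep["weighted"]["f1"] == pytest.approx(w_f1, abs=1e-9)

    def test_round_half_up(self):
        assert round_half_up(0.8705, 3) == 0.871
        assert round_half_up(0.8294, 3) == 0.829


class TestClassifier:
    def test_separable_features_high_training_accuracy(self):
        table = _feature_table(6, 40, separable=True, seed=1)
        clf = train_classifier(table, ClassifierSpec(n_estimators=50, seed=0))
        pred = clf.predict(table[FEATURE_COLUMNS].to_numpy(float))
        acc = np.mean(pred == table["binary_label"].to_numpy())
        assert acc >= 0.95

    def test_null_features_auc_near_chance(self):
        aucs = []
        for rep in range(20):
            table = _feature_table(6, 30, separable=False, seed=100 + rep)
            train = table[table["participant"] < "P03"]
            test = table[table["participant"] >= "P03"]
            clf = train_classifier(train, ClassifierSpec(n_estimators=30, seed=rep))
            out = evaluate(clf, test, ClassifierSpec(n_estimators=30, seed=rep))
            aucs.append(out["auc"])
        assert abs(np.mean(aucs) - 0.5) <= 0.1

    def test_importances_normalized(self):
        table = _feature_table(4, 30, seed=2)
        clf = train_classifier(table, ClassifierSpec(n_estimators=30, seed=0))
        imp = clf.feature_importances_
        assert np.all(imp >= 0) and imp.sum() == pytest.approx(1.0, abs=1e-6)

    def test_single_class_training_error(self):
        table = _feature_table(4, 30, seed=3)
        table["binary_label"] = 0
        with pytest.raises(ValueError, match="single class"):
            train_classifier(table, ClassifierSpec(n_estimators=10))


class TestEvaluate:
    def test_scores_equal_labels_auc_one(self):
        y = np.array([0, 0, 1, 1, 0, 1])

        class Fake:
            def predict_proba(self, X):
                return np.column_stack([1 - y, y]).astype(float)

        table = pd.DataFrame(np.zeros((6, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
        table["binary_label"] = y
        out = evaluate(Fake(), table.assign(participant="P"), ClassifierSpec())
        assert out["auc"] == 1.0

    def test_auc_matches_bruteforce_pair_counting_and_u(self):
        y = np.array([0, 1, 0, 1, 1, 0])
        scores = np.array([0.1, 0.9, 0.4, 0.35, 0.8, 0.2])

        class Fake:
            def predict_proba(self, X):
                return np.column_stack([1 - scores, scores])

        table = pd.DataFrame(np.zeros((6, len(FEATURE_COLUMNS))), columns=FEATURE_COLUMNS)
        table["binary_label"] = y
        out = evaluate(Fake(), table.assign(participant="P"), ClassifierSpec())
        pos, neg = scores[y == 1], scores[y == 0]
        pairs = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        auc_brute = pairs / (len(pos) * len(neg))
        assert out["auc"] == pytest.approx(auc_brute, abs=1e-12)
        u = mann_whitney(pos, neg).statistic
        assert out["auc"] == pytest.approx(u / (len(pos) * len(neg)), abs=1e-12)

    def test_single_class_test_flags_missing_auc(self):
        table = _feature_table(4, 20, seed=4)
        clf = train_classifier(table, ClassifierSpec(n_estimators=10, seed=0))
        test = table[table["binary_label"] == 1]
        out = evaluate(clf, test, ClassifierSpec())
        assert out["auc"] is None and "single-class" in out["auc_flag"]


class TestAblation:
    def test_shared_split_plan_across_configs(self):
        spec = ClassifierSpec(n_estimators=20, seed=0)
        tables = {name: _feature_table(6, 30, seed=5) for name in ("RAW", "PA", "AS", "TASD")}
        reports = run_ablation(tables, spec)
        hashes = {r["plan_hash"] for r in reports.values()}
        assert len(hashes) == 1 and set(reports) == {"RAW", "PA", "AS", "TASD"}

    def test_identity_adjustment_equals_raw(self):
        # identical tables must yield identical reports under the shared plan
        spec = ClassifierSpec(n_estimators=20, seed=0)
        table = _feature_table(6, 30, seed=6)
        reports = run_ablation({"RAW": table, "PA": table.copy()}, spec)
        assert reports["RAW"]["accuracy"] == reports["PA"]["accuracy"]
        assert reports["RAW"]["confusion"] == reports["PA"]["confusion"]
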