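"""Subject-independent classification harness.

Feature windows are mapped to a stress probability P_stress = M(F) by a
gradient-boosted tree ensemble and thresholded at theta (inclusive). All
splits — the hold-out partition and the grouped k-fold — assign every
participant's rows exclusively to one side, so evaluation always measures
generalization to unseen physiology.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score, roc_curve
from xgboost import XGBClassifier

from .feature_extract import FEATURE_COLUMNS


@dataclass
class ClassifierSpec:
    """Gradient-boosting hyperparameters and the decision threshold."""

    max_depth: int = 6
    n_estimators: int = 500
    learning_rate: float = 0.03
    subsample: float = 0.8
    theta: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.theta < 1):
            raise ValueError("theta must lie in (0, 1)")
        if min(self.max_depth, self.n_estimators) <= 0 or self.learning_rate <= 0:
            raise ValueError("hyperparameters must be positive")


@dataclass
class SplitPlan:
    """Participant-exclusive train/test assignment (and optional CV folds)."""

    train_participants: frozenset
    test_participants: frozenset
    folds: list[tuple[frozenset, frozenset]] = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.train_participants & self.test_participants:
            raise ValueError("train and test participant sets overlap")
        for tr, te in self.folds:
            if tr & te:
                raise ValueError("a fold's train and test sets overlap")

    @property
    def plan_hash(self) -> str:
        parts = [",".join(sorted(self.test_participants))]
        parts += [",".join(sorted(te)) for _, te in self.folds]
        return hashlib.sha256("|".join(parts).encode()).hexdigest()[:16]


def split_by_participant(table: pd.DataFrame, test_fraction: float = 0.2,
                         seed: int = 0, group_col: str = "participant") -> SplitPlan:
    """Greedy participant-exclusive hold-out split.

    Participants are shuffled by the seeded RNG and moved into the test set
    until the test row fraction first reaches ``test_fraction``.
    """
    participants = sorted(table[group_col].astype(str).unique())
    if len(participants) < 2:
        raise ValueError("need >= 2 participants to split")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(participants))
    counts = table[group_col].astype(str).value_counts()
    total = len(table)
    test: list[str] = []
    rows = 0
    for p in order:
        test.append(p)
        rows += int(counts[p])
        if rows / total >= test_fraction:
            break
    train = [p for p in participants if p not in test]
    return SplitPlan(frozenset(train), frozenset(test), seed=seed)


def grouped_kfold(table: pd.DataFrame, k: int = 5, seed: int = 0,
                  group_col: str = "participant") -> SplitPlan:
    """Partition participants into k near-equal groups; fold i tests group i."""
    participants = sorted(table[group_col].astype(str).unique())
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(participants) < k:
        raise ValueError(f"{len(participants)} participants < k={k}")
    rng = np.random.default_rng(seed)
    order = list(rng.permutation(participants))
    groups = [list(g) for g in np.array_split(order, k)]
    folds = []
    for i in range(k):
        te = frozenset(groups[i])
        tr = frozenset(p for j, g in enumerate(groups) if j != i for p in g)
        folds.append((tr, te))
    return SplitPlan(frozenset(participants) - frozenset(groups[0]),
                     frozenset(groups[0]), folds=folds, seed=seed)


class StressClassifier(BaseEstimator, ClassifierMixin):
    """Gradient-boosted stress classifier with an inclusive decision threshold.

    Thin sklearn-style wrapper over XGBoost with the framework's default
    configuration (depth 6, 500 trees, learning rate 0.03, 0.8 subsampling).
    ``predict_proba`` exposes P_stress; ``predict`` applies P_stress >= theta;
    ``feature_importances_`` is normalized to sum one.
    """

    def __init__(self, max_depth: int = 6, n_estimators: int = 500,
                 learning_rate: float = 0.03, subsample: float = 0.8,
                 theta: float = 0.5, seed: int = 0):
        self.max_depth = max_depth
        self.n_estimators = n_estimators
        self.learning_rate = learning_rate
        self.subsample = subsample
        self.theta = theta
        self.seed = seed

    def fit(self, X, y):
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValueError("training set contains a single class")
        self.model_ = XGBClassifier(
            max_depth=self.max_depth,
            n_estimators=self.n_estimators,
            learning_rate=self.learning_rate,
            subsample=self.subsample,
            random_state=self.seed,
            eval_metric="logloss",
            n_jobs=1,
            tree_method="hist",
        )
        self.model_.fit(np.asarray(X, float), y)
        self.classes_ = np.array([0, 1])
        return self

    def predict_proba(self, X):
        return self.model_.predict_proba(np.asarray(X, float))

    def predict(self, X):
        return decide(self.predict_proba(X)[:, 1], self.theta)

    @property
    def feature_importances_(self) -> np.ndarray:
        imp = np.asarray(self.model_.feature_importances_, dtype=float)
        total = imp.sum()
        return imp / total if total > 0 else np.full_like(imp, 1.0 / len(imp))


def train_classifier(train: pd.DataFrame, spec: ClassifierSpec | None = None,
                     feature_cols: list[str] | None = None) -> StressClassifier:
    spec = spec or ClassifierSpec()
    cols = feature_cols or FEATURE_COLUMNS
    clf = StressClassifier(spec.max_depth, spec.n_estimators, spec.learning_rate,
                          spec.subsample, spec.theta, spec.seed)
    clf.fit(train[cols].to_numpy(float), train["binary_label"].to_numpy(int))
    return clf


def decide(p_stress: np.ndarray, theta: float = 0.5) -> np.ndarray:
    """Binary decision D = 1 (Stress) iff P_stress >= theta (inclusive)."""
    if not (0 < theta < 1):
        raise ValueError("theta must lie in (0, 1)")
    p = np.asarray(p_stress, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    return (p >= theta).astype(int)


def _prf(tp: int, fp: int, fn: int) -> tuple[float, float, float, bool]:
    flagged = False
    if tp + fp == 0:
        precision, flagged = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, flagged = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, flagged = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return precision, recall, f1, flagged


def report_from_confusion(tn: int, fp: int, fn: int, tp: int) -> dict:
    """Full classification report derived from binary confusion counts.

    Returns a nested dict with per-class precision/recall/F1/support for the
    non-stress (0) and stress (1) classes, overall accuracy, and macro /
    support-weighted aggregates. Degenerate zero-denominator metrics are
    reported as 0 with ``flagged`` set.
    """
    counts = (tn, fp, fn, tp)
    if any(c < 0 for c in counts):
        raise ValueError("confusion counts must be nonnegative")
    total = sum(counts)
    if total == 0:
        raise ValueError("empty confusion matrix")
    # class 0 (non-stress): "positive" means predicted 0
    p0, r0, f0, flag0 = _prf(tp=tn, fp=fn, fn=fp)
    p1, r1, f1_, flag1 = _prf(tp=tp, fp=fp, fn=fn)
    s0, s1 = tn + fp, fn + tp
    accuracy = (tn + tp) / total
    macro = tuple((a + b) / 2 for a, b in ((p0, p1), (r0, r1), (f0, f1_)))
    weighted = tuple((s0 * a + s1 * b) / total for a, b in ((p0, p1), (r0, r1), (f0, f1_)))
    return {
        "confusion": {"tn": tn, "fp": fp, "fn": fn, "tp": tp},
        "accuracy": accuracy,
        "nostress": {"precision": p0, "recall": r0, "f1": f0, "support": s0, "flagged": flag0},
        "stress": {"precision": p1, "recall": r1, "f1": f1_, "support": s1, "flagged": flag1},
        "macro": {"precision": macro[0], "recall": macro[1], "f1": macro[2]},
        "weighted": {"precision": weighted[0], "recall": weighted[1], "f1": weighted[2]},
        "n_test": total,
    }


def round_half_up(x: float, ndigits: int = 3) -> float:
    """Round-half-up presentation rounding for reported metrics."""
    scale = 10 ** ndigits
    return float(np.floor(x * scale + 0.5) / scale)


def evaluate(clf: StressClassifier, test: pd.DataFrame,
             spec: ClassifierSpec | None = None,
             feature_cols: list[str] | None = None) -> dict:
    """Evaluate on held-out rows: confusion at theta, AUC, ROC points.

    AUC is the rank statistic (probability a random stress window outranks a
    random non-stress window), equivalent to U / (n1 * n0).
    """
    spec = spec or ClassifierSpec()
    cols = feature_cols or FEATURE_COLUMNS
    if len(test) == 0:
        raise ValueError("empty test set")
    y = test["binary_label"].to_numpy(int)
    p = clf.predict_proba(test[cols].to_numpy(float))[:, 1]
    pred = decide(p, spec.theta)
    tn = int(np.sum((y == 0) & (pred == 0)))
    fp = int(np.sum((y == 0) & (pred == 1)))
    fn = int(np.sum((y == 1) & (pred == 0)))
    tp = int(np.sum((y == 1) & (pred == 1)))
    report = report_from_confusion(tn, fp, fn, tp)
    if len(np.unique(y)) < 2:
        report["auc"] = None
        report["auc_flag"] = "single-class test set; AUC undefined"
        report["roc"] = None
    else:
        report["auc"] = float(roc_auc_score(y, p))
        fpr, tpr, thr = roc_curve(y, p)
        report["roc"] = {"fpr": fpr.tolist(), "tpr": tpr.tolist(),
                         "thresholds": thr.tolist()}
    imp = getattr(clf, "feature_importances_", None)
    if imp is not None:
        report["feature_importance"] = dict(
            sorted(zip(cols, np.asarray(imp).tolist()), key=lambda kv: -kv[1])
        )
    return report


def _subset(table: pd.DataFrame, participants: frozenset,
            group_col: str = "participant") -> pd.DataFrame:
    return table[table[group_col].astype(str).isin(participants)]


def holdout_evaluate(table: pd.DataFrame, spec: ClassifierSpec | None = None,
                     test_fraction: float = 0.2,
                     feature_cols: list[str] | None = None) -> dict:
    """80/20 participant-exclusive hold-out training and evaluation."""
    spec = spec or ClassifierSpec()
    plan = split_by_participant(table, test_fraction, spec.seed)
    train = _subset(table, plan.train_participants)
    test = _subset(table, plan.test_participants)
    clf = train_classifier(train, spec, feature_cols)
    report = evaluate(clf, test, spec, feature_cols)
    report["plan_hash"] = plan.plan_hash
    report["test_participants"] = sorted(plan.test_participants)
    return report


def cross_validate(table: pd.DataFrame, spec: ClassifierSpec | None = None,
                   k: int = 5, feature_cols: list[str] | None = None) -> dict:
    """Grouped k-fold CV; every participant appears in exactly one test fold."""
    spec = spec or ClassifierSpec()
    plan = grouped_kfold(table, k, spec.seed)
    fold_reports = []
    for i, (tr, te) in enumerate(plan.folds):
        assert not (tr & te), "fold train/test participant overlap"
        clf = train_classifier(_subset(table, tr), spec, feature_cols)
        rep = evaluate(clf, _subset(table, te), spec, feature_cols)
        rep["fold"] = i
        rep["test_participants"] = sorted(te)
        fold_reports.append(rep)
    aucs = [r["auc"] for r in fold_reports if r["auc"] is not None]
    return {
        "folds": fold_reports,
        "mean_accuracy": float(np.mean([r["accuracy"] for r in fold_reports])),
        "mean_auc": float(np.mean(aucs)) if aucs else None,
        "mean_f1_stress": float(np.mean([r["stress"]["f1"] for r in fold_reports])),
        "plan_hash": plan.plan_hash,
    }


def run_ablation(tables: dict[str, pd.DataFrame], spec: ClassifierSpec | None = None,
                 test_fraction: float = 0.2,
                 feature_cols: list[str] | None = None) -> dict[str, dict]:
    """Evaluate the RAW / PA / AS / TASD feature tables under one shared split.

    All configurations reuse the split plan derived from the first table so
    the comparison isolates the adjustment, not the partition.
    """
    spec = spec or ClassifierSpec()
    first = next(iter(tables.values()))
    plan = split_by_participant(first, test_fraction, spec.seed)
    out: dict[str, dict] = {}
    for name, table in tables.items():
        clf = train_classifier(_subset(table, plan.train_participants), spec, feature_cols)
        rep = evaluate(clf, _subset(table, plan.test_participants), spec, feature_cols)
        rep["plan_hash"] = plan.plan_hash
        out[name] = rep
    return out
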