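"""Multi-level baseline deviations and their correlation-driven fusion.

Conductance is referenced against three baselines — global (all rows),
individual (per participant), and pre-task (leading fraction of each session)
— yielding deviation streams Delta_global, Delta_indiv, Delta_pre. The three
streams are combined into a single fused deviation with nonnegative weights
proportional to each stream's absolute point-biserial correlation with the
binary training label, fit on training rows only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin


@dataclass
class BaselineSet:
    """Global / per-participant / per-session-pre-task conductance baselines (uS)."""

    baseline_global: float
    baseline_indiv: dict[str, float]
    baseline_pre: dict[tuple[str, str], float]
    alpha_pre: float = 0.20
    weights: tuple[float, float, float] | None = None

    def validate_weights(self) -> None:
        if self.weights is not None:
            w = np.asarray(self.weights)
            if np.any(w < 0) or abs(w.sum() - 1.0) > 1e-9:
                raise ValueError("fusion weights must be nonnegative and sum to 1")


def compute_baselines(table: pd.DataFrame, alpha_pre: float = 0.20) -> BaselineSet:
    """Compute the three baseline levels from a labeled table.

    The pre-task baseline of each session is the mean conductance over the
    first ceil(alpha_pre * n_session) rows in time order.
    """
    if len(table) == 0:
        raise ValueError("empty table")
    if not (0 < alpha_pre <= 1):
        raise ValueError("alpha_pre must lie in (0, 1]")
    g = float(table["GSR"].mean())
    indiv = {str(p): float(v) for p, v in table.groupby("Participant_ID")["GSR"].mean().items()}
    pre: dict[tuple[str, str], float] = {}
    for (p, s), grp in table.groupby(["Participant_ID", "Session_ID"]):
        ordered = grp.sort_values("Time")["GSR"].to_numpy()
        n_pre = int(np.ceil(alpha_pre * len(ordered)))
        if n_pre < 1:
            raise ValueError(f"session ({p}, {s}) has an empty pre-task window")
        pre[(str(p), str(s))] = float(ordered[:n_pre].mean())
    return BaselineSet(baseline_global=g, baseline_indiv=indiv, baseline_pre=pre, alpha_pre=alpha_pre)


def deviation_features(
    gsr: np.ndarray, baselines: BaselineSet, participant: str, session: str
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Pointwise deviations of conductance from the three baseline levels."""
    gsr = np.asarray(gsr, dtype=float)
    participant, session = str(participant), str(session)
    if participant not in baselines.baseline_indiv:
        raise KeyError(f"no individual baseline for participant {participant!r}")
    if (participant, session) not in baselines.baseline_pre:
        raise KeyError(f"no pre-task baseline for session ({participant!r}, {session!r})")
    d_global = gsr - baselines.baseline_global
    d_indiv = gsr - baselines.baseline_indiv[participant]
    d_pre = gsr - baselines.baseline_pre[(participant, session)]
    return d_global, d_indiv, d_pre


def _point_biserial(x: np.ndarray, y: np.ndarray) -> float:
    """|corr| between a numeric stream and a 0/1 label; 0 on zero variance."""
    if np.std(x) < 1e-12 or np.std(y) < 1e-12:
        return 0.0
    return float(abs(np.corrcoef(x, y)[0, 1]))


def fuse_deviations(
    deltas: np.ndarray,
    labels_train: np.ndarray,
    beta_reg: float = 1e-2,
) -> tuple[np.ndarray, np.ndarray]:
    """Correlation-weighted linear fusion of the three deviation streams.

    ``deltas`` is (n, 3) in the order (global, indiv, pre); ``labels_train``
    is the binary 0/1 stress label on the same rows. Weights are the absolute
    point-biserial correlations, ridge-damped by 1/(1+beta_reg) and normalized
    to sum one. When every stream is uncorrelated or constant the weights fall
    back to uniform with a warning.

    Returns (fused_series, weights).
    """
    deltas = np.asarray(deltas, dtype=float)
    labels = np.asarray(labels_train, dtype=float)
    if deltas.ndim != 2 or deltas.shape[1] != 3:
        raise ValueError("deltas must be (n, 3)")
    raw = np.array([_point_biserial(deltas[:, k], labels) for k in range(3)])
    raw = raw / (1.0 + beta_reg)
    total = raw.sum()
    if total < 1e-12:
        warnings.warn("all deviation streams uncorrelated with the label; uniform weights",
                      RuntimeWarning, stacklevel=2)
        weights = np.full(3, 1.0 / 3.0)
    else:
        weights = raw / total
    fused = deltas @ weights
    return fused, weights


def annotate_table(table: pd.DataFrame, baselines: BaselineSet) -> pd.DataFrame:
    """Fill the Baseline_* and Delta_* columns of a labeled table in place of
    whatever they currently hold."""
    out = table.copy()
    out["Baseline_global"] = baselines.baseline_global
    out["Baseline_indiv"] = out["Participant_ID"].astype(str).map(baselines.baseline_indiv)
    key = list(zip(out["Participant_ID"].astype(str), out["Session_ID"].astype(str)))
    out["Baseline_pre"] = [baselines.baseline_pre[k] for k in key]
    out["Delta_global"] = out["GSR"] - out["Baseline_global"]
    out["Delta_indiv"] = out["GSR"] - out["Baseline_indiv"]
    out["Delta_pre"] = out["GSR"] - out["Baseline_pre"]
    return out


class DeviationFuser(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer fusing the three deviation streams.

    ``fit(X, y)`` learns the correlation-driven weights on training rows only
    (``weights_`` is a probability vector); ``transform(X)`` applies the frozen
    weights, so no test-label information leaks into the fusion.
    """

    def __init__(self, beta_reg: float = 1e-2):
        self.beta_reg = beta_reg

    def fit(self, X, y):
        _, self.weights_ = fuse_deviations(np.asarray(X, float), np.asarray(y, float),
                                           self.beta_reg)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        return (X @ self.weights_)[:, None]
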