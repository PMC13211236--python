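"""Feature-separability statistics: one-way ANOVA, Kruskal-Wallis,
Mann-Whitney U, and per-class descriptives.

Raw per-feature p values are reported (no correction by default; a Bonferroni
option exists for users who want family-wise control).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as st


@dataclass
class StatResult:
    test_name: str
    statistic: float
    p_value: float
    group_sizes: tuple[int, ...]
    feature_name: str = ""

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value outside [0, 1]")


def anova_oneway(*groups, feature_name: str = "") -> StatResult:
    """Classical one-way ANOVA F = MS_between / MS_within."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 values each")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        # no variance anywhere: no between-group signal
        return StatResult("anova", 0.0, 1.0, tuple(len(g) for g in groups), feature_name)
    within_var = sum(np.var(g, ddof=1) for g in groups)
    if within_var == 0:
        warnings.warn("zero within-group variance with distinct means; F is infinite",
                      RuntimeWarning, stacklevel=2)
        return StatResult("anova", np.inf, 0.0, tuple(len(g) for g in groups), feature_name)
    f, p = st.f_oneway(*groups)
    return StatResult("anova", float(f), float(p), tuple(len(g) for g in groups), feature_name)


def kruskal_wallis(*groups, feature_name: str = "") -> StatResult:
    """Kruskal-Wallis H with tie correction; p from chi^2 with k-1 df."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if sum(len(g) for g in groups) < 3 or len(groups) < 2:
        raise ValueError("need >= 2 groups and >= 3 total values")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return StatResult("kruskal", 0.0, 1.0, tuple(len(g) for g in groups), feature_name)
    h, p = st.kruskal(*groups)
    return StatResult("kruskal", float(h), float(p), tuple(len(g) for g in groups), feature_name)


# exact U-distribution enumeration is affordable up to this product of sizes
_EXACT_LIMIT = 64


def mann_whitney(a, b, alternative: str = "two-sided", feature_name: str = "") -> StatResult:
    """Mann-Whitney U (U of the first sample).

    Exact p by full enumeration of the U null distribution when
    n_a * n_b <= 64 and there are no ties; tie-corrected normal approximation
    otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 1 or len(b) < 1:
        raise ValueError("both samples must be non-empty")
    has_ties = len(np.unique(np.concatenate([a, b]))) < len(a) + len(b)
    method = "exact" if (len(a) * len(b) <= _EXACT_LIMIT and not has_ties) else "asymptotic"
    res = st.mannwhitneyu(a, b, alternative=alternative, method=method)
    return StatResult("mannwhitney", float(res.statistic), float(res.pvalue),
                      (len(a), len(b)), feature_name)


def class_descriptives(features: pd.DataFrame, by: str = "label",
                       columns: list[str] | None = None) -> pd.DataFrame:
    """Per class x feature descriptives: mean, sample SD (n-1), n."""
    if by not in features.columns:
        raise ValueError(f"class column {by!r} not present")
    if columns is None:
        columns = [c for c in features.columns
                   if c != by and pd.api.types.is_numeric_dtype(features[c])]
    rows = []
    for cls, grp in features.groupby(by):
        if len(grp) == 0:
            warnings.warn(f"empty class {cls!r} omitted", RuntimeWarning, stacklevel=2)
            continue
        for col in columns:
            vals = grp[col].to_numpy(float)
            rows.append({
                "Feature": col,
                "Class": cls,
                "Mean": float(np.mean(vals)),
                "SD": float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0,
                "N": len(vals),
            })
    return pd.DataFrame(rows)


def separability_report(features: pd.DataFrame, columns: list[str],
                        class_col: str = "label", binary_col: str = "binary_label",
                        bonferroni: bool = False) -> pd.DataFrame:
    """Per-feature battery in the layout Feature, Class, Mean, SD, N,
    ANOVA_F, ANOVA_p, U, U_p: multi-class ANOVA plus the binary-mapping
    Mann-Whitney comparison."""
    desc = class_descriptives(features, by=class_col, columns=columns)
    m = len(columns)
    rows = []
    for col in columns:
        groups = [g[col].to_numpy(float) for _, g in features.groupby(class_col)]
        try:
            a = anova_oneway(*groups, feature_name=col)
        except ValueError:
            a = StatResult("anova", np.nan, 1.0, tuple(len(g) for g in groups), col)
        stress = features.loc[features[binary_col] == 1, col].to_numpy(float)
        nostress = features.loc[features[binary_col] == 0, col].to_numpy(float)
        u = mann_whitney(stress, nostress, feature_name=col)
        scale = m if bonferroni else 1
        rows.append({
            "Feature": col,
            "ANOVA_F": a.statistic,
            "ANOVA_p": min(1.0, a.p_value * scale),
            "U": u.statistic,
            "U_p": min(1.0, u.p_value * scale),
        })
    return desc.merge(pd.DataFrame(rows), on="Feature", how="left")
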