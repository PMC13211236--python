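"""Windowed thermal-aware feature extraction.

Sliding windows of length L (default 30 s, 5 s hop) over each corrected
recording yield one feature row per window: adjusted-conductance descriptors
(mean level, SCR count/amplitude/rise time, slope), temperature descriptors
(EMA level, gradient, acceleration, trailing drift), a conductance-temperature
coupling ratio, and window means of the baseline-deviation streams.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .baseline_norm import BaselineSet, deviation_features, fuse_deviations
from .signal_model import STRESS_CLASS
from .thermal_adjust import AdjustedRecord

FEATURE_COLUMNS = [
    "mean_eda_adj",
    "scr_count",
    "scr_amp_mean",
    "scr_rise_mean",
    "eda_slope",
    "delta_global",
    "delta_indiv",
    "delta_pre",
    "fused_deviation",
    "temp_ema",
    "temp_gradient",
    "temp_accel",
    "thermal_drift",
    "coupling_ratio",
]

META_COLUMNS = ["participant", "session", "win_start", "win_end", "label", "binary_label"]


@dataclass
class SCREvent:
    """One detected skin conductance response."""

    onset_time: float
    peak_time: float
    amplitude: float

    @property
    def rise_time(self) -> float:
        return self.peak_time - self.onset_time


@dataclass
class FeatureConfig:
    """Windowing and SCR-detection knobs.

    window_len : coupling window length L (s).
    hop : window hop (s).
    theta_scr : minimum SCR amplitude (uS).
    onset_slope_min : derivative threshold marking an SCR onset (uS/s).
    refractory : minimum onset separation (s).
    drift_window : trailing window for the thermal-drift level (s).
    eps_delta : numerical tolerance guarding the coupling-ratio denominator.
    """

    window_len: float = 30.0
    hop: float = 5.0
    theta_scr: float = 0.05
    onset_slope_min: float = 0.01
    refractory: float = 1.0
    drift_window: float = 60.0
    eps_delta: float = 1e-4

    def __post_init__(self) -> None:
        if not (self.window_len >= self.hop > 0):
            raise ValueError("require window_len >= hop > 0")
        if self.theta_scr <= 0:
            raise ValueError("theta_scr must be positive")


def detect_scrs(eda_adj: np.ndarray, fs: float, cfg: FeatureConfig | None = None) -> list[SCREvent]:
    """Derivative-threshold SCR detection.

    An onset is a sample where the first-difference slope rises above
    ``onset_slope_min`` after being below it; the event peak is the next local
    maximum; amplitude is peak minus onset conductance. Onsets closer than the
    refractory period are merged (first kept) and events below ``theta_scr``
    are discarded.
    """
    cfg = cfg or FeatureConfig()
    x = np.asarray(eda_adj, dtype=float)
    if len(x) < 3:
        return []
    slope = np.diff(x) * fs  # uS/s at each inter-sample step
    above = slope > cfg.onset_slope_min
    onset_idx = np.flatnonzero(above & ~np.concatenate(([False], above[:-1])))

    # merge onsets inside the refractory period
    merged: list[int] = []
    for i in onset_idx:
        if not merged or (i - merged[-1]) / fs >= cfg.refractory:
            merged.append(int(i))

    events: list[SCREvent] = []
    for i in merged:
        # walk forward to the next local maximum (slope turns non-positive)
        j = i
        while j < len(slope) and slope[j] > 0:
            j += 1
        peak = j  # x[j] is the turning point sample
        amp = x[peak] - x[i]
        if amp >= cfg.theta_scr:
            events.append(SCREvent(onset_time=i / fs, peak_time=peak / fs, amplitude=float(amp)))
    return events


def window_bounds(n_samples: int, fs: float, cfg: FeatureConfig) -> list[tuple[int, int]]:
    """Half-open sample windows [k*hop, k*hop + L) fully inside the record."""
    win = int(round(cfg.window_len * fs))
    hop = int(round(cfg.hop * fs))
    if n_samples < win:
        warnings.warn("record shorter than one window; no features", RuntimeWarning, stacklevel=2)
        return []
    return [(s, s + win) for s in range(0, n_samples - win + 1, hop)]


def _ls_slope(y: np.ndarray, fs: float) -> float:
    """Least-squares slope of y against time, in units of y per minute."""
    n = len(y)
    if n < 2 or np.ptp(y) == 0:
        return 0.0
    t = np.arange(n) / fs
    slope = np.polyfit(t, y, 1)[0]
    return float(slope * 60.0)


def extract_features(
    adj: AdjustedRecord,
    lo: int,
    hi: int,
    deltas: np.ndarray,
    fused: np.ndarray,
    events: list[SCREvent],
    cfg: FeatureConfig,
) -> dict:
    """Feature dictionary for one window [lo, hi) of an adjusted record."""
    rec = adj.base
    fs = rec.fs
    eda = adj.eda_adj[lo:hi]
    temp_s = rec.temp_smooth[lo:hi]
    t0, t1 = lo / fs, hi / fs

    in_win = [e for e in events if t0 <= e.onset_time < t1]
    scr_count = len(in_win)
    scr_amp = float(np.mean([e.amplitude for e in in_win])) if in_win else 0.0
    scr_rise = float(np.mean([e.rise_time for e in in_win])) if in_win else 0.0

    grad_series = np.gradient(rec.temp_smooth[lo:hi]) * fs * 60.0  # degC/min per sample
    d_eda = np.sum(np.abs(np.diff(eda)))
    d_temp = np.sum(np.abs(np.diff(temp_s)))
    degenerate = d_temp < cfg.eps_delta
    coupling = float(d_eda / (d_temp + cfg.eps_delta))

    drift_lo = max(0, hi - int(round(cfg.drift_window * fs)))
    labels = rec.label[lo:hi]
    counts = np.bincount(labels)
    label = int(np.argmax(counts))

    return {
        "participant": rec.participant_id,
        "session": rec.session_id,
        "win_start": t0,
        "win_end": t1,
        "label": label,
        "binary_label": int(label == STRESS_CLASS),
        "mean_eda_adj": float(np.mean(eda)),
        "scr_count": float(scr_count),
        "scr_amp_mean": scr_amp,
        "scr_rise_mean": scr_rise,
        "eda_slope": _ls_slope(eda, fs),
        "delta_global": float(np.mean(deltas[lo:hi, 0])),
        "delta_indiv": float(np.mean(deltas[lo:hi, 1])),
        "delta_pre": float(np.mean(deltas[lo:hi, 2])),
        "fused_deviation": float(np.mean(fused[lo:hi])),
        "temp_ema": float(np.mean(temp_s)),
        "temp_gradient": _ls_slope(temp_s, fs),
        "temp_accel": _ls_slope(grad_series, fs),
        "thermal_drift": float(np.mean(rec.temp_smooth[drift_lo:hi])),
        "coupling_ratio": coupling,
        "coupling_degenerate": bool(degenerate),
    }


def build_feature_table(
    records: list[AdjustedRecord],
    baselines: BaselineSet,
    cfg: FeatureConfig | None = None,
    fusion_weights: np.ndarray | None = None,
) -> pd.DataFrame:
    """Concatenate per-window feature rows across a cohort of adjusted records.

    Deviation streams are computed per record from ``baselines``; the fused
    stream uses ``fusion_weights`` when given (frozen training weights) and
    otherwise fits correlation-driven weights on the pooled per-sample labels
    of these records.
    """
    cfg = cfg or FeatureConfig()
    if not records:
        return pd.DataFrame(columns=META_COLUMNS + FEATURE_COLUMNS + ["coupling_degenerate"])

    per_rec_deltas = []
    for adj in records:
        rec = adj.base
        d = np.column_stack(
            deviation_features(rec.eda, baselines, rec.participant_id, rec.session_id)
        )
        per_rec_deltas.append(d)

    if fusion_weights is None:
        pooled = np.vstack(per_rec_deltas)
        pooled_labels = np.concatenate(
            [(adj.base.label == STRESS_CLASS).astype(float) for adj in records]
        )
        _, fusion_weights = fuse_deviations(pooled, pooled_labels)
    fusion_weights = np.asarray(fusion_weights, dtype=float)

    rows = []
    for adj, deltas in zip(records, per_rec_deltas):
        fused = deltas @ fusion_weights
        events = detect_scrs(adj.eda_adj, adj.base.fs, cfg)
        for lo, hi in window_bounds(adj.base.n_samples, adj.base.fs, cfg):
            rows.append(extract_features(adj, lo, hi, deltas, fused, events, cfg))
    table = pd.DataFrame(rows)
    bad = ~np.isfinite(table[FEATURE_COLUMNS].to_numpy(float)).all(axis=1)
    if bad.any():
        raise FloatingPointError(f"{int(bad.sum())} window(s) produced non-finite features")
    return table


def standardize_per_participant(
    table: pd.DataFrame, columns: list[str] | None = None
) -> pd.DataFrame:
    """Z-score each feature column within each participant.

    Removes inter-individual conductance/temperature offsets so that
    subject-independent classifiers see comparable scales. Zero-variance
    columns (and single-row participants, with a warning) map to zero.
    """
    columns = columns or FEATURE_COLUMNS
    out = table.copy()
    for pid, grp in table.groupby("participant"):
        if len(grp) < 2:
            warnings.warn(f"participant {pid!r} has a single row; set to 0",
                          RuntimeWarning, stacklevel=2)
            out.loc[grp.index, columns] = 0.0
            continue
        vals = grp[columns].to_numpy(float)
        mu = vals.mean(axis=0)
        sd = vals.std(axis=0, ddof=0)
        z = np.where(sd > 0, (vals - mu) / np.where(sd > 0, sd, 1.0), 0.0)
        out.loc[grp.index, columns] = z
    return out


class ParticipantStandardizer(BaseEstimator, TransformerMixin):
    """Stateless per-group z-scoring as an sklearn-style transformer.

    Each participant's statistics use only that participant's rows, so the
    transform is leakage-free across subject-independent splits and needs no
    fitted state.
    """

    def __init__(self, columns: list[str] | None = None):
        self.columns = columns

    def fit(self, X: pd.DataFrame, y=None):
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return standardize_per_participant(X, self.columns)
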