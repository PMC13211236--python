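"""Domain types and I/O for synchronized EDA/temperature recordings.

The tabular interchange format is a flat CSV with one row per sample and the
columns listed in :data:`LABELED_COLUMNS` (conductance in microsiemens, skin
temperature in degrees Celsius, integer affect codes). Continuous per-subject
recordings are carried as :class:`SignalRecord` objects.
"""

from __future__ import annotations

import logging
import pickle
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Exact column set of the labeled-table CSV schema, in canonical order.
LABELED_COLUMNS = [
    "Time",
    "GSR",
    "Class",
    "Participant_ID",
    "Session_ID",
    "Temperature",
    "Baseline_global",
    "Baseline_indiv",
    "Baseline_pre",
    "Delta_global",
    "Delta_indiv",
    "Delta_pre",
    "TEMP_Literature",
    "TEMP_Simulated",
]

_NUMERIC_COLUMNS = [c for c in LABELED_COLUMNS if c not in ("Participant_ID", "Session_ID")]

#: Affect codes retained for analysis: 1 neutral, 2 stress (negative), 3 positive.
VALID_CLASSES = (1, 2, 3)
STRESS_CLASS = 2

TEMP_SANITY_BOUNDS = (15.0, 45.0)


class SchemaError(ValueError):
    """Raised when a labeled table violates the CSV schema."""


class AlignmentError(ValueError):
    """Raised when two channels share no temporal overlap."""


@dataclass
class SignalRecord:
    """A synchronized per-subject EDA/temperature recording.

    Attributes
    ----------
    participant_id, session_id : str
        Opaque provenance identifiers.
    fs : float
        Sampling frequency in Hz (uniform grid).
    t : ndarray
        Time stamps in seconds from session start, strictly increasing.
    eda : ndarray
        Skin conductance in microsiemens, nonnegative.
    temp : ndarray
        Raw skin temperature in degrees Celsius.
    temp_smooth : ndarray or None
        EMA-smoothed temperature; populated by preprocessing.
    label : ndarray
        Per-sample integer affect code.
    """

    participant_id: str
    session_id: str
    fs: float
    t: np.ndarray
    eda: np.ndarray
    temp: np.ndarray
    label: np.ndarray
    temp_smooth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.eda = np.asarray(self.eda, dtype=float)
        self.temp = np.asarray(self.temp, dtype=float)
        self.label = np.asarray(self.label, dtype=int)
        if self.temp_smooth is not None:
            self.temp_smooth = np.asarray(self.temp_smooth, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.fs <= 0:
            raise ValueError("sampling frequency must be positive")
        n = len(self.t)
        arrays = {"eda": self.eda, "temp": self.temp, "label": self.label}
        if self.temp_smooth is not None:
            arrays["temp_smooth"] = self.temp_smooth
        for name, arr in arrays.items():
            if len(arr) != n:
                raise ValueError(f"channel {name!r} length {len(arr)} != time length {n}")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(np.abs(dt - 1.0 / self.fs) >= 1e-6):
                raise ValueError("time stamps are not uniform at 1/fs")
        if np.any(self.eda < 0):
            raise ValueError("conductance must be nonnegative")
        lo, hi = TEMP_SANITY_BOUNDS
        if np.any((self.temp < lo) | (self.temp > hi)):
            raise ValueError(f"temperature outside sanity bounds [{lo}, {hi}] degC")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Record duration in seconds (sample count over fs)."""
        return self.n_samples / self.fs

    def copy(self, **changes) -> "SignalRecord":
        base = dict(
            participant_id=self.participant_id,
            session_id=self.session_id,
            fs=self.fs,
            t=self.t.copy(),
            eda=self.eda.copy(),
            temp=self.temp.copy(),
            label=self.label.copy(),
            temp_smooth=None if self.temp_smooth is None else self.temp_smooth.copy(),
        )
        base.update(changes)
        return SignalRecord(**base)


@dataclass
class ExclusionReport:
    """Bookkeeping for the binary label mapping."""

    n_input: int
    n_stress: int
    n_nostress: int
    n_excluded: int
    excluded_codes: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        assert self.n_stress + self.n_nostress + self.n_excluded == self.n_input


def validate_labeled_table(table: pd.DataFrame, strict: bool = True) -> pd.DataFrame:
    """Validate (and coerce) a DataFrame against the labeled-table schema."""
    missing = [c for c in LABELED_COLUMNS if c not in table.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    unknown = [c for c in table.columns if c not in LABELED_COLUMNS]
    if unknown:
        if strict:
            raise SchemaError(f"unknown column(s) in strict mode: {', '.join(unknown)}")
        logger.warning("ignoring unknown columns: %s", ", ".join(unknown))
    out = table[LABELED_COLUMNS].copy()
    for col in _NUMERIC_COLUMNS:
        try:
            out[col] = pd.to_numeric(out[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = pd.to_numeric(out[col], errors="coerce")
            row = int(bad[bad.isna() & out[col].notna()].index[0])
            raise SchemaError(f"non-numeric value in column {col!r} at row {row}") from exc
    out["Class"] = out["Class"].astype(int)
    out["Participant_ID"] = out["Participant_ID"].astype(str)
    out["Session_ID"] = out["Session_ID"].astype(str)
    if (out["Participant_ID"].str.len() == 0).any():
        raise SchemaError("empty Participant_ID")
    return out


def read_labeled_csv(path, strict: bool = True) -> pd.DataFrame:
    """Read a labeled-table CSV and validate its schema.

    In strict mode unknown columns are rejected; otherwise they are dropped
    with a logged warning.
    """
    raw = pd.read_csv(path)
    return validate_labeled_table(raw, strict=strict)


def write_labeled_csv(table: pd.DataFrame, path) -> None:
    """Write a labeled table; ``read_labeled_csv`` round-trips it exactly."""
    validate_labeled_table(table, strict=False).to_csv(path, index=False)


def map_binary_labels(table: pd.DataFrame) -> tuple[pd.DataFrame, ExclusionReport]:
    """Map affect codes to the binary stress labels.

    Code 2 becomes Stress; codes 1 and 3 become NoStress; anything else
    (meditation, transition, unknown codes) is dropped and counted in the
    returned :class:`ExclusionReport`.
    """
    cls = table["Class"].to_numpy()
    keep = np.isin(cls, VALID_CLASSES)
    excluded = table.loc[~keep, "Class"]
    out = table.loc[keep].copy()
    out["Binary"] = np.where(out["Class"].to_numpy() == STRESS_CLASS, "Stress", "NoStress")
    report = ExclusionReport(
        n_input=len(table),
        n_stress=int((out["Binary"] == "Stress").sum()),
        n_nostress=int((out["Binary"] == "NoStress").sum()),
        n_excluded=int((~keep).sum()),
        excluded_codes={int(k): int(v) for k, v in excluded.value_counts().items()},
    )
    return out, report


def align_channels(
    eda_series: tuple[np.ndarray, np.ndarray],
    temp_series: tuple[np.ndarray, np.ndarray],
    target_fs: float,
    participant_id: str = "P00",
    session_id: str = "S00",
    label_series: tuple[np.ndarray, np.ndarray] | None = None,
) -> SignalRecord:
    """Resample two (t, values) channels onto a common uniform grid.

    Both channels are linearly interpolated onto a grid at ``target_fs``
    restricted to the overlap of their time supports. Labels, when given,
    are mapped by nearest-sample lookup (codes are categorical).
    """
    t_e, x_e = (np.asarray(a, dtype=float) for a in eda_series)
    t_t, x_t = (np.asarray(a, dtype=float) for a in temp_series)
    for t in (t_e, t_t):
        if np.any(np.diff(t) <= 0):
            raise AlignmentError("time stamps must be strictly increasing")
    t0 = max(t_e[0], t_t[0])
    t1 = min(t_e[-1], t_t[-1])
    if t1 <= t0:
        raise AlignmentError("channels have no temporal overlap")
    n = int(np.floor((t1 - t0) * target_fs)) + 1
    grid = t0 + np.arange(n) / target_fs
    eda = np.interp(grid, t_e, x_e)
    temp = np.interp(grid, t_t, x_t)
    if label_series is not None:
        t_l, lab = np.asarray(label_series[0], float), np.asarray(label_series[1])
        idx = np.clip(np.searchsorted(t_l, grid), 0, len(t_l) - 1)
        left = np.clip(idx - 1, 0, len(t_l) - 1)
        use_left = np.abs(t_l[left] - grid) <= np.abs(t_l[idx] - grid)
        labels = lab[np.where(use_left, left, idx)].astype(int)
    else:
        labels = np.zeros(n, dtype=int)
    # re-anchor time at zero so record timestamps are session-relative
    return SignalRecord(
        participant_id=participant_id,
        session_id=session_id,
        fs=target_fs,
        t=grid - grid[0],
        eda=np.clip(eda, 0.0, None),
        temp=temp,
        label=labels,
    )


def load_wesad_subject(path, channel_set: str = "wrist", target_fs: float = 4.0) -> SignalRecord:
    """Load one subject from the public WESAD archive's native serialization.

    Optional convenience for users who have downloaded the dataset; nothing in
    the core pipeline or test suite depends on it. Wrist EDA and TEMP channels
    (4 Hz) are aligned with the 700 Hz label stream via :func:`align_channels`.
    """
    if channel_set != "wrist":
        raise ValueError("only the wrist channel set is supported")
    try:
        with open(path, "rb") as fh:
            data = pickle.load(fh, encoding="latin1")
    except (OSError, pickle.UnpicklingError, EOFError) as exc:
        raise IOError(f"malformed subject archive: {path}") from exc
    try:
        wrist = data["signal"]["wrist"]
    except (TypeError, KeyError) as exc:
        raise IOError("archive lacks the expected signal/wrist structure") from exc
    for ch in ("EDA", "TEMP"):
        if ch not in wrist:
            raise KeyError(f"missing wrist channel {ch!r}")
    eda = np.asarray(wrist["EDA"], dtype=float).ravel()
    temp = np.asarray(wrist["TEMP"], dtype=float).ravel()
    labels = np.asarray(data.get("label", np.zeros(1)), dtype=int).ravel()
    fs_wrist = 4.0
    fs_label = 700.0
    rec = align_channels(
        (np.arange(len(eda)) / fs_wrist, eda),
        (np.arange(len(temp)) / fs_wrist, temp),
        target_fs,
        participant_id=str(data.get("subject", "S?")),
        session_id="wesad",
        label_series=(np.arange(len(labels)) / fs_label, labels),
    )
    return rec


def record_to_frame(rec: SignalRecord) -> pd.DataFrame:
    """Flatten a record to a tidy per-sample DataFrame (internal artifact I/O)."""
    df = pd.DataFrame(
        {
            "Time": rec.t,
            "EDA": rec.eda,
            "Temperature": rec.temp,
            "Class": rec.label,
            "Participant_ID": rec.participant_id,
            "Session_ID": rec.session_id,
        }
    )
    if rec.temp_smooth is not None:
        df["Temperature_smooth"] = rec.temp_smooth
    return df


def frame_to_record(df: pd.DataFrame, fs: float) -> SignalRecord:
    return SignalRecord(
        participant_id=str(df["Participant_ID"].iloc[0]),
        session_id=str(df["Session_ID"].iloc[0]),
        fs=fs,
        t=df["Time"].to_numpy(float),
        eda=df["EDA"].to_numpy(float),
        temp=df["Temperature"].to_numpy(float),
        label=df["Class"].to_numpy(int),
        temp_smooth=df["Temperature_smooth"].to_numpy(float)
        if "Temperature_smooth" in df.columns
        else None,
    )
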