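"""Seeded simulator of coupled EDA-temperature cohorts with ground truth.

Each synthetic subject is generated as

    eda(t) = tonic + lambda_true * T_smooth(t) + phasic(t) + noise,

where the temperature T(t) follows a slow linear drift plus a sinusoidal
component and measurement noise, T_smooth is its EMA, and the phasic stream is
a superposition of skin conductance responses (linear rise, exponential decay)
whose Poisson rate and amplitude depend on the affect condition. The thermal
coupling is class-independent by default so that classification performance
must come from the stress-driven SCR activity, not the temperature confound.

One independent RNG stream per subject is derived from the master seed, so a
cohort is bit-reproducible and individual subjects are stable under changes of
cohort size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .baseline_norm import compute_baselines, annotate_table
from .preprocessing import PreprocessConfig, ema_smooth
from .signal_model import SignalRecord

#: default per-class SCR rates (events/min): stress (2) is eventful,
#: neutral (1) and positive (3) are sparse
DEFAULT_SCR_RATES = {1: 2.0, 2: 8.0, 3: 2.0}
#: default per-class lognormal amplitude medians (uS)
DEFAULT_AMP_MEDIANS = {1: 0.15, 2: 0.20, 3: 0.15}


@dataclass
class SynthConfig:
    """Cohort-level simulation settings.

    The defaults emulate a 15-subject laboratory protocol: three affect
    conditions (neutral / stress / positive) of 300 s each at 4 Hz, skin
    temperature near 34.5 degC with a gentle drift, thermal-conductance
    coupling lambda_true = 0.5 uS/degC, and stress expressed through an
    elevated SCR rate (8/min vs 2/min) and slightly larger amplitudes.
    """

    n_subjects: int = 15
    fs: float = 4.0
    schedule: tuple[tuple[int, float], ...] = ((1, 300.0), (2, 300.0), (3, 300.0))
    scr_rates: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_SCR_RATES))
    amp_medians: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_AMP_MEDIANS))
    amp_sigma: float = 0.4
    scr_rise: float = 1.0
    scr_decay: float = 4.0
    lambda_true: float = 0.5
    tonic_range: tuple[float, float] = (1.5, 3.5)
    temp_start: float = 33.5
    temp_start_jitter: float = 0.5
    temp_drift: float = 0.05  # degC/min
    temp_sin_amp: float = 0.2
    temp_sin_period: float = 300.0
    temp_noise_sd: float = 0.02
    eda_noise_sd: float = 0.02
    class_dependent_temp: bool = False
    temp_class_offsets: dict[int, float] = field(default_factory=dict)
    tau_ema: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if any(d <= 0 for _, d in self.schedule):
            raise ValueError("condition durations must be positive")
        if any(r < 0 for r in self.scr_rates.values()):
            raise ValueError("SCR rates must be nonnegative")

    @property
    def duration(self) -> float:
        return float(sum(d for _, d in self.schedule))


@dataclass
class SubjectTruth:
    """Generator ground truth for one subject (for oracle tests)."""

    participant_id: str
    lambda_true: float
    tonic: float
    events: list[dict]
    seed_key: tuple[int, int]


def _subject_rng(cfg: SynthConfig, subject_index: int) -> np.random.Generator:
    # fixed (master seed, subject index) key -> independent, stable stream
    return np.random.default_rng([cfg.seed, subject_index])


def simulate_temperature(cfg: SynthConfig, rng: np.random.Generator,
                         duration: float | None = None,
                         start: float | None = None) -> np.ndarray:
    """Skin temperature: start + drift + sinusoid + Gaussian noise, clipped to
    physiological bounds [15, 45] degC."""
    duration = duration if duration is not None else cfg.duration
    start = start if start is not None else cfg.temp_start
    n = int(round(duration * cfg.fs))
    t = np.arange(n) / cfg.fs
    temp = (
        start
        + cfg.temp_drift * t / 60.0
        + cfg.temp_sin_amp * np.sin(2 * np.pi * t / cfg.temp_sin_period)
        + rng.normal(0.0, cfg.temp_noise_sd, n)
    )
    return np.clip(temp, 15.0, 45.0)


def simulate_scr_train(rate: float, duration: float, fs: float,
                       rise: float, decay: float,
                       amp_median: float, amp_sigma: float,
                       rng: np.random.Generator,
                       t_offset: float = 0.0) -> tuple[np.ndarray, list[dict]]:
    """Homogeneous Poisson train of canonical SCR shapes.

    Each event rises linearly over ``rise`` seconds to its drawn amplitude
    (lognormal around ``amp_median``) and decays exponentially with time
    constant ``decay``. Returns the superposed phasic series and the
    ground-truth event list (onset times shifted by ``t_offset``).
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    n = int(round(duration * fs))
    series = np.zeros(n)
    events: list[dict] = []
    if rate == 0 or n == 0:
        return series, events
    n_events = rng.poisson(rate * duration / 60.0)
    onsets = np.sort(rng.uniform(0.0, duration, n_events))
    kernel_len = int(round((rise + 8.0 * decay) * fs))
    tk = np.arange(kernel_len) / fs
    base_kernel = np.where(tk < rise, tk / rise, np.exp(-(tk - rise) / decay))
    for onset in onsets:
        amp = float(rng.lognormal(np.log(amp_median), amp_sigma))
        i0 = int(round(onset * fs))
        seg = base_kernel[: max(0, n - i0)]
        series[i0 : i0 + len(seg)] += amp * seg
        events.append({"onset": float(onset + t_offset), "amplitude": amp,
                       "peak": float(onset + t_offset + rise)})
    return series, events


def simulate_subject(cfg: SynthConfig, subject_index: int) -> tuple[SignalRecord, SubjectTruth]:
    """Generate one subject's synchronized recording plus its ground truth."""
    rng = _subject_rng(cfg, subject_index)
    pid = f"P{subject_index + 1:02d}"
    tonic = float(rng.uniform(*cfg.tonic_range))
    start = cfg.temp_start + float(rng.uniform(-1, 1)) * cfg.temp_start_jitter

    temp = simulate_temperature(cfg, rng, start=start)
    n_total = len(temp)

    if cfg.class_dependent_temp and cfg.temp_class_offsets:
        offset = np.concatenate([
            np.full(int(round(d * cfg.fs)), cfg.temp_class_offsets.get(c, 0.0))
            for c, d in cfg.schedule
        ])
        temp = np.clip(temp + offset[:n_total], 15.0, 45.0)

    temp_smooth = ema_smooth(temp, cfg.fs, PreprocessConfig(tau_ema=cfg.tau_ema))

    phasic = np.zeros(n_total)
    labels = np.zeros(n_total, dtype=int)
    events: list[dict] = []
    t_cursor = 0.0
    i_cursor = 0
    for cls, dur in cfg.schedule:
        n_seg = int(round(dur * cfg.fs))
        seg, ev = simulate_scr_train(
            cfg.scr_rates.get(cls, 0.0), dur, cfg.fs,
            cfg.scr_rise, cfg.scr_decay,
            cfg.amp_medians.get(cls, 0.15), cfg.amp_sigma,
            rng, t_offset=t_cursor,
        )
        end = min(i_cursor + n_seg, n_total)
        phasic[i_cursor:end] += seg[: end - i_cursor]
        labels[i_cursor:end] = cls
        for e in ev:
            e["class"] = cls
        events.extend(ev)
        t_cursor += dur
        i_cursor += n_seg

    noise = rng.normal(0.0, cfg.eda_noise_sd, n_total)
    eda = np.clip(tonic + cfg.lambda_true * temp_smooth + phasic + noise, 0.0, None)

    rec = SignalRecord(
        participant_id=pid,
        session_id="S01",
        fs=cfg.fs,
        t=np.arange(n_total) / cfg.fs,
        eda=eda,
        temp=temp,
        label=labels,
    )
    truth = SubjectTruth(pid, cfg.lambda_true, tonic, events, (cfg.seed, subject_index))
    return rec, truth


def simulate_cohort(cfg: SynthConfig) -> tuple[list[SignalRecord], list[SubjectTruth]]:
    """Simulate all subjects of the configured cohort."""
    records, truths = [], []
    for i in range(cfg.n_subjects):
        rec, truth = simulate_subject(cfg, i)
        records.append(rec)
        truths.append(truth)
    return records, truths


def _split_counts(total: int, parts: int) -> list[int]:
    base, extra = divmod(total, parts)
    return [base + (1 if i < extra else 0) for i in range(parts)]


def make_wesad_like_table(cfg: SynthConfig | None = None,
                          rows_per_class: int = 4000,
                          n_participants: int = 15) -> pd.DataFrame:
    """Emit a labeled table shaped like the study's tabular subset.

    Exactly ``rows_per_class`` rows for each affect code {1, 2, 3} at 1 Hz,
    spread over ``n_participants`` subjects (so the binary mapping yields the
    1:2 stress/no-stress imbalance). Baseline and delta columns are populated
    from the generated conductance; TEMP_Literature carries the smoothed
    temperature and TEMP_Simulated the raw simulated temperature.
    """
    cfg = cfg or SynthConfig()
    per_class = {c: _split_counts(rows_per_class, n_participants) for c in (1, 2, 3)}
    frames = []
    for i in range(n_participants):
        schedule = tuple((c, float(per_class[c][i])) for c in (1, 2, 3))
        sub_cfg = replace(cfg, fs=1.0, schedule=schedule, n_subjects=n_participants)
        rec, _ = simulate_subject(sub_cfg, i)
        temp_smooth = ema_smooth(rec.temp, rec.fs, PreprocessConfig(tau_ema=cfg.tau_ema))
        frames.append(pd.DataFrame({
            "Time": rec.t,
            "GSR": rec.eda,
            "Class": rec.label,
            "Participant_ID": rec.participant_id,
            "Session_ID": rec.session_id,
            "Temperature": rec.temp,
            "TEMP_Literature": temp_smooth,
            "TEMP_Simulated": rec.temp,
        }))
    table = pd.concat(frames, ignore_index=True)
    for col in ("Baseline_global", "Baseline_indiv", "Baseline_pre",
                "Delta_global", "Delta_indiv", "Delta_pre"):
        table[col] = 0.0
    baselines = compute_baselines(table, alpha_pre=0.20)
    table = annotate_table(table, baselines)
    from .signal_model import LABELED_COLUMNS

    return table[LABELED_COLUMNS]
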