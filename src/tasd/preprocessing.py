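"""Frequency-domain conditioning of EDA and temporal smoothing of temperature.

EDA is low-pass filtered (second-order Butterworth, 1 Hz cutoff by default) to
retain slow sympathetic dynamics; skin temperature is smoothed with an
exponential moving average to emphasize gradual thermal drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .signal_model import SignalRecord


class NyquistError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    """Preprocessing knobs.

    fc_eda : low-pass cutoff for EDA (Hz).
    filter_order : Butterworth order.
    zero_phase : forward-backward filtering (no phase lag) when True;
        a causal single pass otherwise.
    tau_ema : EMA time constant for temperature smoothing (s).
    """

    fc_eda: float = 1.0
    filter_order: int = 2
    zero_phase: bool = True
    tau_ema: float = 5.0

    def __post_init__(self) -> None:
        if self.fc_eda <= 0:
            raise ValueError("fc_eda must be positive")
        if self.filter_order < 1:
            raise ValueError("filter_order must be >= 1")
        if self.tau_ema <= 0:
            raise ValueError("tau_ema must be positive")


def butterworth_lowpass(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Low-pass filter a series with a Butterworth design.

    Zero-phase mode runs the filter forward and backward (squared magnitude,
    zero lag) with reflective edge padding; single-pass mode applies the
    causal filter once, matching the analytic order-n magnitude response
    |H(f)| = (1 + (f/fc)^(2n))^(-1/2) away from the Nyquist warping region.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if cfg.fc_eda >= fs / 2:
        raise NyquistError(f"cutoff {cfg.fc_eda} Hz >= Nyquist {fs / 2} Hz")
    if len(x) < 3 * cfg.filter_order:
        raise ValueError("series too short for the requested filter order")
    sos = sps.butter(cfg.filter_order, cfg.fc_eda, btype="low", fs=fs, output="sos")
    if cfg.zero_phase:
        return sps.sosfiltfilt(sos, x, padtype="even")
    # start the causal pass at step steady state so constants pass unchanged
    zi = sps.sosfilt_zi(sos) * x[0]
    y, _ = sps.sosfilt(sos, x, zi=zi)
    return y


def ema_smooth(x: np.ndarray, fs: float, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Exponential moving average with time constant ``tau_ema``.

    Recursion s[0] = x[0], s[n] = (1-beta) s[n-1] + beta x[n] with
    beta = 1 - exp(-dt/tau); the decay is expressed per unit time so the
    smoother behaves identically across sampling rates.
    """
    cfg = cfg or PreprocessConfig()
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        raise ValueError("cannot smooth an empty series")
    beta = 1.0 - np.exp(-1.0 / (fs * cfg.tau_ema))
    # IIR form of the recursion: y[n] = beta x[n] + (1-beta) y[n-1], y[-1] = x[0]
    zi = np.array([(1.0 - beta) * x[0]])
    y, _ = sps.lfilter([beta], [1.0, -(1.0 - beta)], x, zi=zi)
    return y


def preprocess_record(rec: SignalRecord, cfg: PreprocessConfig | None = None) -> SignalRecord:
    """Filter EDA and populate the smoothed-temperature channel.

    Raw temperature is retained unmodified: the adaptive-scaling denominator
    operates on raw T(t) while the proportional fit uses the smoothed series.
    """
    cfg = cfg or PreprocessConfig()
    eda = butterworth_lowpass(rec.eda, rec.fs, cfg)
    temp_smooth = ema_smooth(rec.temp, rec.fs, cfg)
    return rec.copy(eda=np.clip(eda, 0.0, None), temp_smooth=temp_smooth)
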