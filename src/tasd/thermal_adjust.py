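"""Thermal compensation of electrodermal activity.

Two complementary corrections separate stress-induced conductance from
thermoregulatory drift:

* **Proportional adjustment (PA)** removes the linear temperature-coupled
  component: ``EDA_PA(t) = EDA(t) - lambda_prop * T_smooth(t)`` where
  ``lambda_prop = Cov(EDA, T_smooth) / (Var(T_smooth) + epsilon)`` is fit per
  session from sample (n-1) moments.

* **Adaptive scaling (AS)** rescales the PA output by a temperature-deviation
  factor: ``EDA_AS(t) = EDA_PA(t) / (1 + alpha_t * (T(t) - T_base))``. In
  fixed-alpha mode the sensitivity ``alpha`` is constant; in adaptive mode it
  is updated window-by-window by a ridge-damped gradient step that reduces the
  squared windowed correlation between the scaled output and the temperature
  deviation.

PA consumes the smoothed temperature; the AS denominator consumes raw
temperature, so fast thermal deviations still enter the scaling factor.
Both corrections reduce to the identity in their natural limits
(``lambda = 0``; ``alpha = 0`` or ``T == T_base``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .signal_model import SignalRecord

MODES = ("raw", "pa", "as", "tasd")


@dataclass
class AdjustmentParams:
    """Parameters of the PA/AS models.

    Attributes
    ----------
    lambda_prop : float or None
        Proportional coefficient (uS/degC). None means "fit per session".
    epsilon : float
        Variance-denominator tolerance (degC^2) keeping the fit finite.
    alpha : float
        Adaptive sensitivity (1/degC) used in fixed-alpha mode and as the
        initial value in adaptive mode.
    t_base : float or None
        Baseline temperature (degC); None means "estimate from the record".
    t_base_strategy : {"pre_task", "session_mean", "fixed"}
    alpha_pre : float
        Pre-task fraction of the record used by the pre_task strategy.
    k_adapt : float
        Adaptive update rate for alpha.
    beta_reg : float
        Ridge weight shrinking the adaptive step toward zero.
    denom_floor : float
        Minimum allowed scaling denominator 1 + alpha (T - T_base).
    """

    lambda_prop: float | None = None
    epsilon: float = 1e-4
    alpha: float = 0.0
    t_base: float | None = None
    t_base_strategy: str = "pre_task"
    alpha_pre: float = 0.20
    k_adapt: float = 1e-3
    beta_reg: float = 1e-2
    denom_floor: float = 0.2

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be >= 0")
        if self.k_adapt <= 0:
            raise ValueError("k_adapt must be positive")
        if not (0 < self.denom_floor <= 1):
            raise ValueError("denom_floor must lie in (0, 1]")


@dataclass
class AdjustedRecord:
    """A record together with its thermally corrected conductance streams."""

    base: SignalRecord
    eda_pa: np.ndarray
    eda_as: np.ndarray
    params: AdjustmentParams
    mode: str = "tasd"
    alpha_trace: np.ndarray | None = None

    @property
    def eda_adj(self) -> np.ndarray:
        """The mode's final corrected signal (RAW passes EDA through)."""
        if self.mode == "raw":
            return self.base.eda
        if self.mode == "pa":
            return self.eda_pa
        return self.eda_as


def estimate_lambda_prop(eda: np.ndarray, temp_smooth: np.ndarray, epsilon: float = 1e-4) -> float:
    """Covariance-based proportional coefficient Cov(EDA, T)/(Var(T) + eps)."""
    eda = np.asarray(eda, dtype=float)
    temp_smooth = np.asarray(temp_smooth, dtype=float)
    if eda.shape != temp_smooth.shape:
        raise ValueError("eda and temp_smooth must have equal length")
    if len(eda) < 2:
        raise ValueError("need at least 2 samples to fit lambda_prop")
    cov = np.cov(eda, temp_smooth, ddof=1)[0, 1]
    var = np.var(temp_smooth, ddof=1)
    return float(cov / (var + epsilon))


def apply_proportional_adjustment(
    eda: np.ndarray, temp_smooth: np.ndarray, lambda_prop: float
) -> np.ndarray:
    """Pointwise PA correction eda - lambda * temp_smooth."""
    eda = np.asarray(eda, dtype=float)
    temp_smooth = np.asarray(temp_smooth, dtype=float)
    if eda.shape != temp_smooth.shape:
        raise ValueError("eda and temp_smooth must have equal length")
    return eda - lambda_prop * temp_smooth


def estimate_t_base(
    temp: np.ndarray,
    strategy: str = "pre_task",
    alpha_pre: float = 0.20,
    fixed_value: float | None = None,
) -> float:
    """Baseline temperature from the pre-task window, session mean, or a constant."""
    temp = np.asarray(temp, dtype=float)
    if len(temp) == 0:
        raise ValueError("empty temperature series")
    if strategy == "fixed":
        if fixed_value is None:
            raise ValueError("fixed strategy requires fixed_value")
        return float(fixed_value)
    if strategy == "session_mean":
        return float(np.mean(temp))
    if strategy == "pre_task":
        if not (0 < alpha_pre <= 1):
            raise ValueError("alpha_pre must lie in (0, 1]")
        n_pre = int(np.ceil(alpha_pre * len(temp)))
        if n_pre < 1:
            raise ValueError("empty pre-task window")
        return float(np.mean(temp[:n_pre]))
    raise ValueError(f"unknown t_base strategy {strategy!r}")


def _windowed_abs_corr(x: np.ndarray, d: np.ndarray) -> float:
    sx, sd = np.std(x), np.std(d)
    if sx < 1e-12 or sd < 1e-12:
        return 0.0
    return float(abs(np.corrcoef(x, d)[0, 1]))


def apply_adaptive_scaling(
    eda_pa: np.ndarray,
    temp: np.ndarray,
    params: AdjustmentParams,
    mode: str = "fixed_alpha",
    window: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Scale eda_pa by 1 / (1 + alpha (T - T_base)).

    Parameters
    ----------
    mode : {"fixed_alpha", "adaptive"}
        fixed_alpha uses ``params.alpha`` throughout. adaptive starts from
        ``params.alpha`` (default 0) and, per window of ``window`` samples,
        takes a step ``alpha += k_adapt * g`` where ``g`` is the central-
        difference descent direction of the ridge-penalized objective
        ``corr(eda_as, T - T_base)^2 + beta_reg * alpha^2``.
    window : int
        Adaptation window in samples (defaults to 128 when adaptive).

    Returns
    -------
    (eda_as, alpha_trace) : the scaled series and per-sample alpha values.
    """
    eda_pa = np.asarray(eda_pa, dtype=float)
    temp = np.asarray(temp, dtype=float)
    if eda_pa.shape != temp.shape:
        raise ValueError("eda_pa and temp must have equal length")
    t_base = params.t_base
    if t_base is None:
        t_base = estimate_t_base(temp, params.t_base_strategy, params.alpha_pre)
    dev = temp - t_base
    n = len(eda_pa)

    def scale(alpha: float, lo: int, hi: int) -> np.ndarray:
        denom = 1.0 + alpha * dev[lo:hi]
        n_clamped = int(np.sum(denom < params.denom_floor))
        if n_clamped:
            warnings.warn(
                f"adaptive-scaling denominator clamped at {params.denom_floor} "
                f"for {n_clamped} sample(s)",
                RuntimeWarning,
                stacklevel=3,
            )
            denom = np.maximum(denom, params.denom_floor)
        return eda_pa[lo:hi] / denom

    if mode == "fixed_alpha":
        alpha_trace = np.full(n, params.alpha)
        return scale(params.alpha, 0, n), alpha_trace
    if mode != "adaptive":
        raise ValueError(f"unknown adaptive-scaling mode {mode!r}")

    win = int(window) if window else 128
    alpha = params.alpha
    delta = 1e-3  # finite-difference probe for the correlation gradient
    out = np.empty(n)
    alpha_trace = np.empty(n)
    for lo in range(0, n, win):
        hi = min(lo + win, n)
        out[lo:hi] = scale(alpha, lo, hi)
        alpha_trace[lo:hi] = alpha
        d = dev[lo:hi]
        j_plus = _windowed_abs_corr(scale(alpha + delta, lo, hi), d) ** 2
        j_minus = _windowed_abs_corr(scale(alpha - delta, lo, hi), d) ** 2
        grad = (j_plus - j_minus) / (2 * delta) + 2.0 * params.beta_reg * alpha
        step = -params.k_adapt * grad
        if not np.isfinite(step):
            raise FloatingPointError("non-finite adaptive alpha update")
        alpha = alpha + step
    return out, alpha_trace


def adjust_session(
    rec: SignalRecord,
    params: AdjustmentParams | None = None,
    mode: str = "tasd",
    as_mode: str = "adaptive",
) -> AdjustedRecord:
    """Fit lambda per session and apply the requested correction chain.

    ``mode`` selects the ablation configuration: "raw" (no correction),
    "pa" (proportional only), "as" (adaptive scaling of raw EDA), or
    "tasd" (PA then AS).
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    params = params or AdjustmentParams()
    if rec.temp_smooth is None:
        raise ValueError("record must be preprocessed (temp_smooth missing)")
    lam = params.lambda_prop
    if lam is None:
        lam = estimate_lambda_prop(rec.eda, rec.temp_smooth, params.epsilon)
    fitted = AdjustmentParams(**{**params.__dict__, "lambda_prop": lam})
    eda_pa = apply_proportional_adjustment(rec.eda, rec.temp_smooth, lam)
    window = int(round(30.0 * rec.fs))  # coupling window length L at this rate
    as_input = eda_pa if mode in ("tasd", "pa") else rec.eda
    eda_as, alpha_trace = apply_adaptive_scaling(
        as_input, rec.temp, fitted, mode=as_mode, window=max(window, 2)
    )
    return AdjustedRecord(
        base=rec,
        eda_pa=eda_pa,
        eda_as=eda_as,
        params=fitted,
        mode=mode,
        alpha_trace=alpha_trace,
    )


class ProportionalAdjuster(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for the proportional (PA) correction.

    ``X`` is an (n, 2) array of columns [eda, temp_smooth]; ``transform``
    returns the corrected conductance as an (n, 1) array. The fitted
    coefficient is exposed as ``lambda_prop_``.
    """

    def __init__(self, epsilon: float = 1e-4):
        self.epsilon = epsilon

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): [eda, temp_smooth]")
        self.lambda_prop_ = estimate_lambda_prop(X[:, 0], X[:, 1], self.epsilon)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        out = apply_proportional_adjustment(X[:, 0], X[:, 1], self.lambda_prop_)
        return out[:, None]


class AdaptiveScaler(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer for the adaptive-scaling (AS) correction.

    ``X`` is an (n, 2) array of columns [eda_pa, temp_raw]. ``fit`` estimates
    the baseline temperature (``t_base_``); ``transform`` divides by
    ``1 + alpha (T - t_base_)`` with fixed or adaptively updated alpha.
    """

    def __init__(
        self,
        alpha: float = 0.0,
        adaptive: bool = True,
        t_base_strategy: str = "pre_task",
        alpha_pre: float = 0.20,
        k_adapt: float = 1e-3,
        beta_reg: float = 1e-2,
        denom_floor: float = 0.2,
        window: int = 128,
    ):
        self.alpha = alpha
        self.adaptive = adaptive
        self.t_base_strategy = t_base_strategy
        self.alpha_pre = alpha_pre
        self.k_adapt = k_adapt
        self.beta_reg = beta_reg
        self.denom_floor = denom_floor
        self.window = window

    def _params(self) -> AdjustmentParams:
        return AdjustmentParams(
            alpha=self.alpha,
            t_base=getattr(self, "t_base_", None),
            t_base_strategy=self.t_base_strategy,
            alpha_pre=self.alpha_pre,
            k_adapt=self.k_adapt,
            beta_reg=self.beta_reg,
            denom_floor=self.denom_floor,
        )

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be (n_samples, 2): [eda_pa, temp]")
        self.t_base_ = estimate_t_base(X[:, 1], self.t_base_strategy, self.alpha_pre)
        return self

    def transform(self, X):
        X = np.asarray(X, dtype=float)
        mode = "adaptive" if self.adaptive else "fixed_alpha"
        out, self.alpha_trace_ = apply_adaptive_scaling(
            X[:, 0], X[:, 1], self._params(), mode=mode, window=self.window
        )
        return out[:, None]
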