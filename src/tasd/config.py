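"""Pipeline configuration: a YAML file whose sections mirror the module
configs, using the framework's canonical parameter names as keys."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import yaml

from .feature_extract import FeatureConfig
from .preprocessing import PreprocessConfig
from .thermal_adjust import AdjustmentParams
from .classify_eval import ClassifierSpec
from .synthetic_data import SynthConfig

DEFAULTS: dict = {
    "preprocessing": {
        "fcEDA": 1.0,        # EDA low-pass cutoff (Hz)
        "filter_order": 2,
        "zero_phase": True,
        "tauEMA": 5.0,       # temperature EMA window (s)
    },
    "adjustment": {
        "lambda_prop": "session-fit",  # proportional coefficient
        "kadapt": 1e-3,                # adaptive update rate
        "epsilon_delta": 1e-4,         # numerical tolerance
        "beta_reg": 1e-2,              # ridge regularization
        "alpha": 0.0,
        "alpha_pre": 0.20,             # pre-task fraction
        "t_base_strategy": "pre_task",
        "denom_floor": 0.2,
        "as_mode": "adaptive",
    },
    "baselines": {
        "alpha_pre": 0.20,
        "beta_reg": 1e-2,
    },
    "features": {
        "L": 30.0,             # coupling window length (s)
        "hop": 5.0,
        "theta_SCR": 0.05,     # SCR amplitude threshold (uS)
        "onset_slope_min": 0.01,
        "refractory": 1.0,
        "drift_window": 60.0,
        "eps_delta": 1e-4,
    },
    "classifier": {
        "max_depth": 6,
        "n_estimators": 500,
        "learning_rate": 0.03,
        "subsample": 0.8,
        "theta": 0.5,
        "test_fraction": 0.2,
        "k_folds": 5,
    },
    "simulation": {
        "n_subjects": 15,
        "fs": 4.0,
        "segment_duration": 300.0,
        "scr_rate_stress": 8.0,
        "scr_rate_nostress": 2.0,
        "lambda_true": 0.5,
        "temp_drift": 0.05,
        "eda_noise_sd": 0.02,
    },
}


class ConfigError(ValueError):
    pass


def _merge_section(name: str, user: dict) -> dict:
    base = dict(DEFAULTS[name])
    for key, value in (user or {}).items():
        if key not in base:
            raise ConfigError(f"unknown key {key!r} in section {name!r}")
        base[key] = value
    return base


@dataclass
class PipelineConfig:
    preprocessing: dict = field(default_factory=lambda: dict(DEFAULTS["preprocessing"]))
    adjustment: dict = field(default_factory=lambda: dict(DEFAULTS["adjustment"]))
    baselines: dict = field(default_factory=lambda: dict(DEFAULTS["baselines"]))
    features: dict = field(default_factory=lambda: dict(DEFAULTS["features"]))
    classifier: dict = field(default_factory=lambda: dict(DEFAULTS["classifier"]))
    simulation: dict = field(default_factory=lambda: dict(DEFAULTS["simulation"]))

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        unknown = set(data) - set(DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown section(s): {', '.join(sorted(unknown))}")
        return cls(**{name: _merge_section(name, data.get(name, {})) for name in DEFAULTS})

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError("config file must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return {
            "preprocessing": dict(self.preprocessing),
            "adjustment": dict(self.adjustment),
            "baselines": dict(self.baselines),
            "features": dict(self.features),
            "classifier": dict(self.classifier),
            "simulation": dict(self.simulation),
        }

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    # --- typed views consumed by the modules -------------------------------

    def preprocess_config(self) -> PreprocessConfig:
        p = self.preprocessing
        return PreprocessConfig(fc_eda=p["fcEDA"], filter_order=p["filter_order"],
                                zero_phase=p["zero_phase"], tau_ema=p["tauEMA"])

    def adjustment_params(self) -> AdjustmentParams:
        a = self.adjustment
        lam = a["lambda_prop"]
        return AdjustmentParams(
            lambda_prop=None if lam == "session-fit" else float(lam),
            epsilon=a["epsilon_delta"],
            alpha=a["alpha"],
            t_base_strategy=a["t_base_strategy"],
            alpha_pre=a["alpha_pre"],
            k_adapt=a["kadapt"],
            beta_reg=a["beta_reg"],
            denom_floor=a["denom_floor"],
        )

    def feature_config(self) -> FeatureConfig:
        f = self.features
        return FeatureConfig(window_len=f["L"], hop=f["hop"], theta_scr=f["theta_SCR"],
                             onset_slope_min=f["onset_slope_min"], refractory=f["refractory"],
                             drift_window=f["drift_window"], eps_delta=f["eps_delta"])

    def classifier_spec(self, seed: int = 0) -> ClassifierSpec:
        c = self.classifier
        return ClassifierSpec(max_depth=c["max_depth"], n_estimators=c["n_estimators"],
                              learning_rate=c["learning_rate"], subsample=c["subsample"],
                              theta=c["theta"], seed=seed)

    def synth_config(self, seed: int = 0) -> SynthConfig:
        s = self.simulation
        d = float(s["segment_duration"])
        return SynthConfig(
            n_subjects=int(s["n_subjects"]),
            fs=float(s["fs"]),
            schedule=((1, d), (2, d), (3, d)),
            scr_rates={1: float(s["scr_rate_nostress"]), 2: float(s["scr_rate_stress"]),
                       3: float(s["scr_rate_nostress"])},
            lambda_true=float(s["lambda_true"]),
            temp_drift=float(s["temp_drift"]),
            eda_noise_sd=float(s["eda_noise_sd"]),
            seed=seed,
        )
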