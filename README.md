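# tasd — temperature-adjusted stress detection

`tasd` separates stress-induced electrodermal activity (EDA) from
thermoregulatory conductance drift and classifies Stress vs No-Stress windows
under a strict subject-independent protocol. It is aimed at researchers in
wearable psychophysiology who work with synchronized skin-conductance and
skin-temperature recordings (wrist-worn devices, VR/XR headset studies) and
need conductance features that are not confounded by thermally driven
sweating.

## The model

Skin conductance mixes two sources: emotional (sympathetic) sweating and
thermoregulatory sweating that tracks skin temperature. `tasd` applies two
complementary corrections before any feature is computed:

**Proportional adjustment (PA)** removes the linear temperature-coupled
component,

    EDA_PA(t) = EDA(t) − λ_prop · T̃(t),
    λ_prop   = Cov(EDA, T̃) / (Var(T̃) + ε),

where T̃ is the EMA-smoothed skin temperature and λ_prop is fit per session
(ε = 10⁻⁴ keeps the fit finite when temperature is flat). With ε = 0 the PA
residual is exactly decorrelated from T̃.

**Adaptive scaling (AS)** compensates nonlinear, subject-specific thermal
sensitivity by rescaling against the deviation of raw temperature from a
baseline level T_base (the mean of the pre-task window by default):

    EDA_AS(t) = EDA_PA(t) / (1 + α(T(t) − T_base)),

with α either fixed or updated window-by-window (rate k_adapt = 10⁻³, ridge
weight β_reg = 10⁻²) to shrink the residual correlation between the scaled
signal and the temperature deviation.

The corrected signal is normalized against three conductance baselines —
global, per-participant, and pre-task (Δ_global, Δ_indiv, Δ_pre), fused with
correlation-driven weights — and summarized over sliding 30 s windows into a
feature vector F(t): mean adjusted level, SCR count/amplitude/rise time
(θ_SCR = 0.05 µS), conductance and temperature slopes, temperature EMA and
acceleration, trailing thermal drift, and a conductance–temperature coupling
ratio. A gradient-boosted tree ensemble maps F(t) to a stress probability
P_stress(t) = M(F(t)), thresholded at θ (decision D(t) = Stress iff
P_stress ≥ θ, default θ = 0.5). All evaluation splits are
participant-exclusive.

A seeded simulator of coupled EDA–temperature cohorts (tonic level + λ_true·T̃
+ Poisson SCR trains + noise, with condition-dependent SCR rates) provides
ground truth for every stage.

## Worked example

```python
import pandas as pd
from tasd import (SynthConfig, simulate_cohort, preprocess_record,
                  adjust_session, compute_baselines, build_feature_table,
                  standardize_per_participant, cross_validate, ClassifierSpec)

records, truth = simulate_cohort(SynthConfig(seed=42))   # 15 subjects, 4 Hz
pre = [preprocess_record(r) for r in records]            # 1 Hz low-pass + EMA
adjusted = [adjust_session(r, mode="tasd") for r in pre] # PA + AS per session
print(round(adjusted[0].params.lambda_prop, 3))          # 0.48 (λ_true = 0.5)

samples = pd.concat([pd.DataFrame({"Time": r.t, "GSR": r.eda, "Class": r.label,
                                   "Participant_ID": r.participant_id,
                                   "Session_ID": r.session_id})
                     for r in pre], ignore_index=True)
features = standardize_per_participant(
    build_feature_table(adjusted, compute_baselines(samples)))
report = cross_validate(features, ClassifierSpec(seed=42), k=5)
print(round(report["mean_accuracy"], 3), round(report["mean_auc"], 3))
# 0.992 1.0
```

The fitted λ recovers the injected thermal coupling coefficient (0.5 µS/°C);
the grouped five-fold CV numbers are the mean accuracy and AUC over folds
that never share a participant between training and testing — on this clean
synthetic cohort the stress-dependent SCR rate (8/min vs 2/min) is almost
perfectly separable.

The same chain is available from the shell:

```bash
tasd report --seed 42 --out runs/demo       # full chain incl. stats + CV
tasd ablation --seed 42 --out runs/demo     # RAW / PA / AS / TASD comparison
```

Artifacts (`signals.csv`, `features.csv`, `train_report.json`,
`cv_report.json`, `stats_report.csv`, …) land in the output directory, each
logged with the config hash and seed that produced it.

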