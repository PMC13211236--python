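# Methods

This note documents the signal model, the numerical choices behind each
processing stage, what the synthetic cohort generator does and does not
emulate, and the known limitations of the package.

## Signal model and assumptions

Skin conductance EDA(t) (µS) is treated as an additive mixture of a slowly
varying tonic level, transient skin conductance responses (SCRs) driven by
sympathetic activation, a thermoregulatory component coupled to skin
temperature T(t) (°C), and measurement noise. The thermal component is
modeled as linear in the EMA-smoothed temperature T̃(t) at first order; the
residual subject- and condition-specific sensitivity is treated as a
multiplicative distortion in the temperature deviation T − T_base. The two
corrections mirror this decomposition:

* **Proportional adjustment.** λ_prop = Cov(EDA, T̃) / (Var(T̃) + ε) with the
  sample (n−1) moment convention, applied as EDA_PA = EDA − λ_prop·T̃. λ_prop
  is fit per session on the whole session (a per-segment fit is available
  through the parameter object). With ε = 0 this is the ordinary
  least-squares slope, so the residual is exactly uncorrelated with T̃;
  ε > 0 shrinks λ̂ toward zero, monotonically in ε for positive covariance,
  and keeps the estimate finite when temperature is constant.
* **Adaptive scaling.** EDA_AS = EDA_PA / (1 + α(T − T_base)). The smoothed
  series feeds the proportional fit; the raw series feeds the scaling
  denominator, so fast thermal deviations still enter the correction.

## Tunable parameters

| Parameter | Meaning | Default | Rationale |
|---|---|---|---|
| fc_EDA | EDA low-pass cutoff | 1.0 Hz | retains slow sympathetic dynamics, attenuates motion/line noise |
| filter order | Butterworth order | 2 | standard electrodermal practice |
| τ_EMA | temperature EMA time constant | 5 s | emphasizes gradual thermal drift |
| ε | variance-denominator tolerance | 10⁻⁴ °C² | single numerical-tolerance constant used throughout |
| k_adapt | adaptive α update rate | 10⁻³ | slow, stable adaptation |
| β_reg | ridge weight | 10⁻² | damps the adaptive step and the fusion weights |
| α_pre | pre-task fraction | 0.20 | defines both T_base and the pre-task conductance baseline |
| L | coupling window length | 30 s | also the feature window and the adaptation window |
| hop | window hop | 5 s | 6× overlap, smooth temporal coverage |
| θ_SCR | SCR amplitude threshold | 0.05 µS | conventional minimum response amplitude |
| θ | decision threshold | 0.5 | symmetric operating point; tunable per deployment |

Classifier defaults: XGBoost with depth 6, 500 trees, learning rate 0.03,
row subsampling 0.8, no class reweighting despite the 1:2 imbalance.

## Numerical and design choices

* **Filtering.** Zero-phase (forward–backward) filtering is the default so
  that SCR rise times are not biased by phase lag; a causal single-pass mode
  exists for real-time parity, initialized at step steady state so constant
  inputs pass unchanged. The single-pass magnitude follows the analytic
  order-2 Butterworth form |H(f)| = (1 + (f/fc)⁴)^(−1/2) up to bilinear
  frequency warping, which is negligible when fc ≪ fs/2 and material within
  a factor ~3 of Nyquist; analytic-response checks are therefore run at high
  sampling rates.
* **EMA.** The "window" is interpreted as a time constant with per-sample
  decay β = 1 − exp(−Δt/τ), which makes the smoother invariant to the
  sampling rate. The recursion starts at s[0] = x[0].
* **Adaptive α update.** The update law is this package's own construction
  (only the rate and ridge constants are externally fixed): per window of L
  seconds, α takes a step −k_adapt·∇J with J(α) = corr(EDA_AS(α), T−T_base)²
  + β_reg·α², the gradient estimated by central differences (probe 10⁻³),
  initialized at α = 0. Fixed-α mode is the reference behavior. The scaling
  denominator is clamped at 0.2 with a warning — division by a vanishing
  denominator is replaced by a bounded amplification rather than an error so
  pathological temperature excursions do not abort a run.
* **T_base.** Default strategy is the mean of the first ⌈α_pre·n⌉ samples
  (pre-task window); session-mean and fixed-value strategies are available.
* **Baselines and fusion.** The three deviation baselines are computed on
  raw conductance (the deviation definitions are written in terms of GSR);
  a config switch lets deviations operate on adjusted conductance instead.
  Fusion weights are normalized absolute point-biserial correlations between
  each deviation stream and the binary training label, computed on training
  rows only and frozen before application to test rows. The uniform ridge
  shrink 1/(1+β_reg) cancels under normalization except in the degenerate
  all-zero branch, where weights fall back to uniform (1/3 each) with a
  warning; this is implemented exactly as specified for auditability.
* **SCR detection** is a derivative-threshold scheme: onsets where the
  first-difference slope crosses 0.01 µS/s upward, peak at the next local
  maximum, amplitude = peak − onset conductance, 1 s refractory merging,
  events below θ_SCR discarded. Only the amplitude threshold is externally
  fixed; the remaining knobs are standard electrodermal practice.
* **Windowing** uses half-open windows [k·hop, k·hop + L) fully inside the
  record, labeled by per-sample majority vote. Features are finite by
  construction; the coupling ratio Σ|ΔEDA_AS| / (Σ|ΔT̃| + ε) falls back to an
  ε-guarded value with a degeneracy flag when temperature is constant.
  Slopes are least-squares fits expressed per minute; thermal drift is the
  trailing-60 s mean of smoothed temperature.
* **Per-participant standardization** z-scores each feature within each
  participant. Because each participant's statistics use only that
  participant's rows, applying it before splitting leaks nothing across
  subject-exclusive partitions.
* **Splits.** Hold-out: participants are shuffled by a seeded RNG and moved
  into the test set until the test row fraction first reaches the target
  (0.2). CV: participants are partitioned into k near-equal groups; fold i
  tests group i. Both assert train/test disjointness on every run.
* **Metrics.** AUC is the rank statistic (identical to U/(n₁n₀)); the
  classification report is computed directly from confusion counts, with
  zero-denominator cells reported as 0 and flagged. Presentation rounding is
  half-up to 3 decimals.
* **Statistics battery.** ANOVA, Kruskal–Wallis and Mann–Whitney are
  delegated to scipy (exact U enumeration for n₁·n₂ ≤ 64 without ties,
  tie-corrected normal approximation otherwise); raw per-feature p values
  are reported, with Bonferroni correction available but off by default.

## The synthetic cohort

Each subject is generated as eda = tonic + λ_true·T̃ + phasic + noise with

* temperature: start 33.5 ± 0.5 °C per subject, drift 0.05 °C/min, 0.2 °C
  sinusoid with 300 s period, 0.02 °C Gaussian noise, clipped to [15, 45] °C;
* phasic: homogeneous Poisson SCR trains, canonical shape (1 s linear rise,
  4 s exponential decay), lognormal amplitudes (median 0.15 µS; 0.20 µS
  under stress; σ = 0.4), rates 8/min in the stress condition vs 2/min
  otherwise;
* tonic: uniform 1.5–3.5 µS per subject; EDA noise SD 0.02 µS;
* schedule: neutral / stress / positive segments of 300 s each at 4 Hz for
  15 subjects (the acceptance runs use exactly these defaults).

Temperature statistics are class-independent by default so that any
classification signal must come from the stress-driven SCR activity and not
from the thermal confound; a config switch adds class-correlated temperature
offsets for confound experiments. One RNG stream per subject is derived from
the (master seed, subject index) pair, so cohorts are bit-reproducible and
single subjects are stable under cohort-size changes.

The generator emulates operating ranges and the coupling structure, not
empirical wrist-sensor distributions: it has no motion artifacts, no
electrode drift or contact loss, no tonic habituation, no inter-event
amplitude correlation, and its thermal coupling is exactly linear.
Consequently, green end-to-end tests demonstrate that the pipeline recovers
known structure under its own generative assumptions — near-perfect CV
scores on the clean cohort say nothing about accuracy on field recordings,
where the mixture is harsher and the coupling only approximately linear.

A 12,000-row tabular fixture (4,000 rows per affect class across 15
participants at 1 Hz, baseline and deviation columns populated) emulates the
shape of the study's tabular subset for schema and label-mapping tests; the
two auxiliary temperature columns carry the smoothed and raw simulated
temperature respectively and are treated as opaque predictors.

## Problem sizes

Default test and acceptance runs use the 15-subject, 900 s/subject cohort
(≈ 2,600 feature windows), 20 sessions of 10,000 samples for coefficient
recovery, and 500-tree ensembles; these sizes keep a full run in the
low tens of seconds on one CPU while leaving every statistical margin wide.

## Known limitations

* The adaptive α update law is an interpretation; only its rate constant and
  ridge weight are externally fixed. Fixed-α mode is the reference.
* λ_prop is a whole-session fit; strong stress-driven conductance trends that
  happen to correlate with temperature will leak into the thermal estimate.
* The coupling-ratio, thermal-drift and temperature-gradient descriptor
  formulas are this package's definitions; other formulations exist.
* The optional loader for the public WESAD archive is provided for users who
  have downloaded that dataset, but nothing dataset-derived ships with the
  package, and results on that dataset are not reproduced by the test suite.
* No motion-artifact correction and no tonic/phasic convex decomposition are
  implemented.
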