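# preictal

Patient-specific EEG **seizure prediction vs. seizure forecasting** pipelines
with Firing Power postprocessing and surrogate-based statistical validation.

About one third of people with epilepsy do not achieve seizure control with
medication. Warning devices try to detect the *preictal* state — the
transitional period before a seizure — from scalp EEG. Two philosophies
compete:

- **Prediction**: raise a crisp alarm announcing that a seizure will occur
  inside a *Seizure Occurrence Period* (SOP) that starts after an
  intervention horizon (SPH, 10 min here).
- **Forecasting**: continuously report a graded seizure risk (low /
  moderate / high), like a weather forecast.

This package implements both branches on top of one shared per-patient
classifier so they can be compared under identical conditions, and provides
a synthetic-data generator so the whole pipeline is exercisable without
access to licensed long-term monitoring recordings.

## Pipeline

1. **Features** (`preictal.features`): non-overlapping 5-s windows; 59
   univariate linear features per channel — relative/absolute power of 8
   bands (δ 0.5–4, θ 4–8, α 8–13, β 13–30 Hz and four γ sub-bands up to
   128 Hz, skipping the 47–53 / 97–103 Hz notch gaps), the 28 pairwise
   band-power ratios, spectral edge frequency/power at 50%, the four
   statistical moments, Hjörth activity/mobility/complexity, decorrelation
   time, and db4 wavelet detail energies D1–D5. A 19-channel recording
   yields 1121 columns per window.
2. **Dataset** (`preictal.dataset`): windows starting in
   `[onset − (SOP+SPH), onset)` are preictal; ictal windows and a 30-min
   postictal buffer are masked; first 3 seizures train, the rest test;
   z-score normalization with training statistics; class imbalance handled
   by inverse-frequency class weights `w_i = N/(2 N_i)` (logistic
   regression) or systematic random undersampling (ensembles); ANOVA-F or
   Random-Forest feature ranking.
3. **Models** (`preictal.models`): class-weighted logistic regression
   (`logreg`), a 15-member linear-SVM voting ensemble (`svm15`), or a
   15-member shallow dropout-network ensemble (`snn15`). SOP ∈ {20,…,50}
   min, k ∈ {3,…,30} and C ∈ {2⁻¹⁰,…,2⁸} are chosen by grid search with
   leave-one-seizure-out cross-validation, maximizing the geometric mean
   √(SS·SP) of pooled validation sample sensitivity/specificity.
4. **Postprocessing** (`preictal.postprocess`): the *Firing Power*
   `fp[n] = (1/τ) Σ O[k]` — a causal moving average of the binary outputs
   over the preictal duration τ. Prediction: alarm when fp > 0.7, with a
   refractory period of SOP+SPH. Forecasting: high risk if fp > 0.7,
   moderate if fp > 0.3, low otherwise.
5. **Evaluation** (`preictal.evaluation`): SS and FPR/h for prediction;
   SS, time in warning, Brier score `BS = (1/N) Σ (fᵢ−oᵢ)²` and Brier
   skill score `BSS = 1 − BS/BS_ref` for forecasting. Statistical
   validation re-places onsets in the interictal period (30 surrogates,
   one-sample t-test, α = 0.05) and compares BS to 1000 shuffled forecasts;
   the improvement-over-chance (IoC) is the fraction of validated patients.

## Worked example

```python
from preictal import RunConfig, SynthConfig, run_patient
from preictal.synth import generate_feature_dataset

# synthetic patient: 4 seizures ≥ 4.5 h apart, a 3-SD preictal signature
# on 5 of 59 features spanning 40 min (SOP 30 + SPH 10) before each onset
fm, seizures = generate_feature_dataset(SynthConfig(effect_size=3.0, seed=42))
report = run_patient(RunConfig(backend="logreg", seed=7), fm, seizures)
print(report.hyperparameters)   # {'sop_minutes': 30, 'k': 10, 'C': None}
print(report.prediction.ss,     # 1.0   – the test seizure was predicted
      report.forecasting.ss,    # 1.0   – and forecast (high risk in its SOP)
      round(report.forecasting.bs, 3),   # 0.053 – Brier score
      round(report.forecasting.bss, 2))  # 0.72  – skill over shuffled forecasts
```

The grid search recovers the generating 30-min SOP, both branches detect
the held-out seizure, and the forecast clearly beats its shuffled reference
(BSS ≫ 0). The same entry points are scriptable from the shell:

```bash
preictal simulate --out data/p1 --effect-size 3 --seed 1
preictal run-patient data/p1/features.csv data/p1/annotations.csv --out runs/p1
preictal run-cohort --n-patients 10 --effect-size 1.2 --seed 3 --out runs/cohort
```

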