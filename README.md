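# sepsishrv

Heart-rate-variability (HRV) analysis pipeline for predicting early clinical
deterioration in emergency-department (ED) sepsis patients, from continuous
single-lead ECG.

Patients presenting with suspected sepsis are monitored from ED arrival for up
to 48 h. The question the pipeline addresses: do HRV features extracted from
the first hours of continuous ECG predict **progressive organ dysfunction
(POD)** — de novo kidney, liver or respiratory failure, ICU admission or death
within 72 h — better than, or as well as, bedside scores such as qSOFA?

## What the pipeline does

1. **R-peak detection** — Pan-Tompkins (5–15 Hz band-pass, derivative,
   squaring, 150 ms moving-window integration, adaptive dual thresholds with
   200 ms refractory period and search-back) on 500 Hz ECG.
2. **Tachogram cleaning** — NN intervals from successive peaks; artifacts
   flagged by ADARRI (absolute difference of adjacent RR intervals) against a
   robust threshold and excluded, never interpolated.
3. **Feature windows** — consecutive 5-min windows, retained when they hold
   ≥ 60 clean beats (20% of the 300 expected). Per window, 17 features:
   time-domain (AVNN, SDNN, RMSSD, NN50, pNN50, CV), nonlinear (SampEn,
   Poincaré SD1/SD2), and Lomb-Scargle band powers
   (ULF < 0.003 Hz, VLF 0.0033–0.04, LF 0.04–0.15, HF 0.15–0.4 Hz,
   TotalPower = LF + HF, LFnorm, HFnorm, LF/HF).
4. **Aggregation** — per-feature mean and OLS slope in 3-hour bins aligned to
   ED admission (16 bins over 48 h); only bin 0 (the first 3 h) enters the
   prediction model.
5. **Stratification** — NOD / SOD / POD labels from daily labs, blood gases,
   SpO2/oxygen context, ventilation, ICU and death times (KDIGO-style
   creatinine criterion, bilirubin + enzyme criterion, respiratory criterion).
6. **Statistics** — Kruskal–Wallis screening of every feature × bin across the
   three groups; univariate logistic regression of POD vs pooled controls with
   a p < 0.20 candidate gate; forward-stepwise logistic regression selected by
   AIC; AUROC and DeLong tests against comparator scores.

The model layer follows the statsmodels idiom:

```python
from sepsishrv import DeteriorationModel
res = DeteriorationModel(design, labels).fit()   # design: bin-0 feature means
print(res.summary())                             # ORs, 95% CIs, AIC, deviance, pseudo-R²
res.predict(), res.auroc()
```

Because real bedside recordings are not distributable, a first-class
synthetic-cohort generator produces everything the analysis consumes: beat
series with controllable band power (IPFM-style sinusoidal modulation),
rendered 500 Hz ECG with noise and baseline wander, injected ectopic/missed
beats, clinical courses that classify deterministically to intended labels,
and attrition matching a 168 → 105 → 69 → 25 record count over 0/12/24/48 h.

## Worked example

```python
from sepsishrv import PipelineConfig, run_pipeline

cfg = PipelineConfig(seed=7, simulation={
    "record_duration": 1800.0,
    "group_sizes": {"NOD": 20, "SOD": 8, "POD": 6},
    "dropout_times": [48.0],
})
report = run_pipeline(cfg, "out/")
print(report["selected_features"], report["auroc"])
```

prints (seed 7):

```
['AVNN'] {'HRV': 0.9226, 'qSOFA': 0.7530, 'SepsisSeverity': 0.8333}
```

meaning the stepwise model selected the mean NN interval (AVNN — depressed in
deteriorating patients, i.e. relative tachycardia) and its in-sample AUROC for
POD was 0.92 on this synthetic cohort, versus 0.75 for qSOFA and 0.83 for the
external severity score; `out/` holds every stage table (features, 3-hour
summaries, labels, Kruskal–Wallis screen, univariate ORs, model summary, ROC
comparison) plus a JSON report, all tagged with the config hash and seed.

The same stages are available as a CLI:
`sepsishrv simulate|preprocess|features|aggregate|stratify|analyze|run`.

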