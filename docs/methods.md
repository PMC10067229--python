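# Methods

## The problem and the estimand

Continuous single-lead ECG is recorded from ED arrival for up to 48 h in
patients with suspected sepsis. Each patient is stratified post hoc by
outcome: **NOD** (no kidney, liver or respiratory dysfunction at any point),
**SOD** (dysfunction present at admission that neither spreads to a new organ
system nor leads to ICU admission or death within 72 h), and **POD**
(progressive: a de novo organ system fails within the horizon, or ICU
admission or death occurs within 72 h). The analysis asks whether HRV features
from the first three hours of monitoring predict POD, and how that prediction
compares with qSOFA and an externally supplied severity score.

## Signal processing

**QRS detection.** Canonical Pan-Tompkins: zero-phase 5–15 Hz second-order
Butterworth band-pass, derivative, squaring, 150 ms moving-window
integration, adaptive signal/noise thresholds (threshold = noise + 0.25 ×
(signal − noise), exponential updates 0.125/0.875), a 200 ms refractory
period, and search-back at half threshold when the gap since the last beat
exceeds 1.66 × the running mean RR. Accepted detections are refined to the
local maximum of the band-passed signal with parabolic sub-sample
interpolation. All detector constants are exposed in `PanTompkinsParams`.

**Artifact correction (ADARRI).** The artifact statistic for interval *i* is
|RR_i − RR_{i−1}|. The decision threshold is `median + k·IQR` of the record's
own ADARRI distribution (k = 4 by default), floored at 100 ms so that
physiological successive differences are never treated as artifacts. A pure
over-threshold rule would also flag the first clean interval after every
artifact (its backward difference is necessarily large), so an interval is
flagged only when it participates in an over-threshold jump **and** deviates
from the centered 11-beat running median by more than the threshold. On
synthetic records with ~5% injected ectopic pairs (shortened + compensatory
lengthened interval) and missed beats (merged, doubled intervals) this flags
every injected position and no clean ones at the default settings; the
acceptance run reports the measured rates. Flagged intervals are excluded,
not interpolated: interpolation fabricates data.

**Windowing.** Half-open 5-minute windows `[300k, 300(k+1))` seconds from ED
admission; an interval belongs to the window containing its end-time, so
every clean interval is assigned exactly once. A window is retained iff it
holds ≥ 60 unflagged intervals (20% of the 300 beats minimally expected in
5 min). The count rule is applied to cleaned (unflagged) beats.

## Features (17 per window)

Time domain: AVNN, SDNN (n−1 denominator throughout), RMSSD, NN50 (strictly
> 50 ms), pNN50 = 100·NN50/(n−1), CV = SDNN/AVNN. Nonlinear: SampEn with
m = 2, r = 0.2 × window SDNN (Richman–Moorman convention: both template
lengths use the same n−m templates, Chebyshev distance, self-matches
excluded, so a constant series gives exactly 0); Poincaré SD1 = SDSD/√2 and
SD2 = √(2·SDNN² − SD1²) floored at 0, so SD1² + SD2² = 2·SDNN² holds by
construction.

Frequency domain: the tachogram is unevenly sampled, so the default estimator
is the Lomb-Scargle periodogram evaluated on a regular grid (spacing
1/(4·span), i.e. 4× oversampled) up to 0.4 Hz. The raw periodogram of a
sinusoid of amplitude A peaks at N·A²/4 with a main lobe of equivalent width
1/span; multiplying by 2·span/N makes the density integrate to the
sinusoid's variance A²/2, so band powers come out in ms². A cubic-spline
resample at 4 Hz + Welch estimator is available for cross-checking. Band
edges follow the published convention (ULF < 0.003, VLF 0.0033–0.04,
LF 0.04–0.15, HF 0.15–0.4 Hz); the 0.003–0.0033 Hz sliver belongs to neither
band. **TotalPower is defined as LF + HF** (the study's own definition), and
the conventional full-band integral is additionally reported as
`FullBandPower` to avoid ambiguity. LFnorm/HFnorm normalize by LF + HF.
A 5-minute window cannot resolve frequencies below 1/300 Hz, so ULF and most
of VLF are below resolution; they are computed anyway (mirroring the study
design) and every row carries a `spectral_reliable` flag that is false for
the default bands in 5-minute windows.

## Aggregation and modelling

Features are summarized per 3-hour bin (bin k = [3k, 3k+3) h; 16 bins over
48 h) as the arithmetic mean over non-missing windows and the OLS slope of
feature against window midpoint time in hours (≥ 2 windows required; the
midpoint centring is a package choice — any within-bin time origin gives the
same slope). Missing feature values (e.g. undefined SampEn) are dropped from
that bin's mean/slope. Group differences are tested per feature × kind × bin
by Kruskal–Wallis with tie correction, uncorrected p < 0.05 (a
Benjamini-Hochberg option exists but is off by default, mirroring the study's
uncorrected reporting).

The prediction model uses only bin-0 feature **means** (slopes are available
via configuration but excluded by default). POD = 1 versus pooled SOD+NOD
controls. Univariate logistic fits per feature give Wald 95% CIs on the OR
scale; p < 0.20 gates candidacy; separating or non-convergent fits are
flagged and excluded. Forward-stepwise selection starts from intercept-only
and at each step adds the candidate with the largest AIC decrease, stopping
when none decreases AIC; exact ties break by candidate order
(deterministic). Patients missing any bin-0 feature are excluded listwise
with a report. Diagnostics report deviance (−2 log-likelihood), non-intercept
degrees of freedom, McFadden pseudo-R² (Nagelkerke alongside) and the
likelihood-ratio p-value. AUROC uses the Mann-Whitney formulation with ties
counting ½; correlated AUROCs are compared with DeLong's
structural-components test.

qSOFA is computed from its published definition (RR ≥ 22, SBP ≤ 100,
GCS < 15). The "sepsis severity score" has no published internal definition
and enters only as an externally supplied column.

## Stratification rules

AKI: creatinine rise ≥ 25.6 µmol/L above baseline **or** ≥ 150% of baseline
(the 25.6 value follows the study's printed criterion; the canonical KDIGO
26.5 is a configuration switch). Baseline = earliest value at/before
admission. Liver: bilirubin > 35.2 µmol/L **and** any of ALP/ASAT/ALAT >
2× the upper limit of normal. Respiratory: ventilation, PaO2 < 8.0 kPa,
PaCO2 > 6.5 kPa, SpO2 < 90% on ambient air, or SpO2 < 95% on ≥ 2 L/min
oxygen; daily worst values are used. "De novo" is evaluated organ-system-wise
against the admission-day assessment: worsening of an already-dysfunctional
organ does not make POD, a newly affected organ system does. The ICU/death
horizon is the explicit 72 h; the de novo organ horizon defaults to 72 h for
symmetry and is configurable. Flow rates between 0 and 2 L/min match neither
printed SpO2 rule and therefore trigger neither.

## Synthetic cohort: what it emulates, and what it does not

Beat times follow an IPFM-style scheme: instantaneous interval = per-patient
mean NN + sinusoidal modulations in the four bands (default amplitudes
25/30/25/20 ms at 0.002/0.02/0.1/0.3 Hz; band-limited noise modulation is an
option). This gives controllable, analytically known band powers. Ectopic
beats are a shortened interval followed by a compensatory lengthened one;
missed beats are merged doubled intervals — the two classes ADARRI targets.
ECG is rendered by Gaussian Q/R/S/P/T components (R = 1 mV, 12 ms width) at
each beat time plus Gaussian noise and sinusoidal baseline wander.

Cohort structure: group sizes default to 119 NOD / 38 SOD / 11 POD. Group
effects are multiplicative on the per-patient mean NN (drawn N(850, 70) ms)
and on modulation amplitudes: POD ×0.85 / ×0.5, SOD ×0.97 / ×0.85,
NOD ×1/×1. No numeric effect sizes are published for the source setting, so
these are package choices representing moderate relative tachycardia and
clearly reduced variability in deteriorating patients — large enough to be
recoverable at 11 events, small enough that recovery is not trivial.
Attrition is deterministic per-patient censoring drawn from the
piecewise-linear survival schedule through (0 h, 168/168), (12 h, 105/168),
(24 h, 69/168), (48 h, 25/168), reproducing the study-shaped record counts
without inventing a hazard model. Clinical courses are constructed to
classify deterministically to the intended label, POD realising exactly one
randomly chosen trigger. All randomness flows from one root seed through
per-patient spawned streams.

The generator does **not** emulate real ECG morphology variation (EASI-lead
specifics, respiration, beat-shape ectopy), circadian or treatment-driven HRV
nonstationarity, correlated missingness, or measurement error in labs.
Passing tests therefore demonstrate that the machinery is correct and
calibrated under the stated generative assumptions — not that the clinical
effect sizes or AUROCs would be attained on real patients.

## Problem sizes and numerical choices

Validation runs use scaled-down problem sizes chosen to exercise every code
path with comfortable statistical margins: detection accuracy on three 1-hour
records at 50/95/140 bpm with 0.316 mV additive noise (10 dB against the 1 mV
R wave); artifact rates on 10,000 intervals with ~5% injected artifacts;
oracle agreement on 1,000 random windows; null calibration with 1,000
replicates (KW, DeLong) and 500 (CI coverage); effect recovery on 50
replicates of the full 168-patient cohort with 15-minute records (three
5-minute windows per patient in bin 0), 10 of them scored on an independently
simulated cohort for held-out AUROC. Tolerances: 1e-9 relative for algebraic
oracles, exact equality for SampEn counting and the TotalPower identity,
1e-6 relative for scale equivariance (float cancellation in spectral sums),
calibration bands of ±0.02 around 0.05 and ±2.5% around 95%.

Known limitations: the Pan-Tompkins "modifications" of the original bedside
implementation are unpublished, so canonical 1985 parameters are used; the
ADARRI decision constant is likewise unpublished, so the robust default is
calibrated on synthetic artifacts and exposed as a tunable; ULF/VLF in 5-min
windows are below spectral resolution by construction; and the univariate OR
scale depends on raw feature units (band powers in ms² give extreme-looking
ORs per unit, as in the source setting's tables).
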