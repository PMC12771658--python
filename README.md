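# divebudget

Time-activity budgets and energy expenditure for wintering diving ducks,
estimated from implanted tri-axial accelerometer (ACC) transmitters, and
contrasted with traditional shore-based instantaneous scan sampling.

Biologists studying sea ducks such as Lesser Scaup (*Aythya affinis*) need
daily energy expenditure (DEE) to assess winter habitat quality, but
shore-based scans only see birds by day, near shore, and on the surface.
Implanted transmitters record a 5-s burst of 10 Hz x/y/z acceleration every
10 min around the clock. This package implements the full chain from raw
bursts to energy budgets:

1. **Censoring** — daily path length from hourly GPS fixes is screened with
   mean-shift change-point detection (binary segmentation, Cohen's *d* ≥ 0.5)
   to discard abnormal post-surgery movement; birds surviving ≤ 14 days or
   leaving the study box are excluded.
2. **Features** — each burst is trimmed to its middle 3 s and summarised into
   a 92-feature battery (per-axis statistics, static/dynamic decomposition,
   ODBA/VeDBA, pitch/roll/yaw, inverse coefficients of variation, axis
   correlations), then de-correlated at |r| > 0.9.
3. **Classification** — an XGBoost multiclass model is trained on
   behavior-verified bursts (≥ 3 s purity), reduced to its top-3 features by
   total gain, and applied to the unclassified field bursts
   (feeding / flying / preening / resting).
4. **Budgets** — bursts are assigned diurnal/nocturnal periods from NOAA
   solar phases ([sunrise, sunset) is diurnal); bird-days with < 95 % of the
   expected 144 bursts are dropped; behavior proportions are tabulated per
   period.
5. **Bioenergetics** — hourly energy expenditure

   HEE = RMR · Σᵢ aᵢ·tᵢ + C_T,  C_T = 0.1392 · max(0, LCT − T) · 20.1 kJ/h

   with RMR = 15.89 kJ/bird/h, activity multipliers a_feeding = 1.85,
   a_preening = 1.66, a_resting = 1.05, a_flight from the allometric flight
   power P = 52.6·M^0.74 W (9.2 at M = 0.70 kg), and LCT = 14.4 °C. DEE is
   the 24-h sum of HEE, or mean HEE × 24 for diurnal-only (scan) data.
6. **Comparison** — Wilcoxon rank-sum tests (r = |Z|/√N), binomial GLM/GLMM
   with per-bird random intercepts, and Welch t-tests contrast periods and
   methods.

A first-class synthetic-data module generates every input with known ground
truth — behavior-specific ACC signatures, post-release displacement decay,
winter temperatures straddling the LCT with colder nights, configurable
diurnal/nocturnal behavior schedules, and 200-m-truncated shore scans — so
the whole pipeline is testable at desk scale.

## Worked example

```sh
divebudget run-all --seed 7 --out out/
```

runs simulate → censor → features → train/classify → budget → energy →
compare on the default synthetic world (6 birds × 16 days) and prints the
comparison block of `out/report.json`. With seed 7 the run reports, among
others:

```
train.holdout_accuracy                 0.996
censor.bursts_in / bursts_out          13824 / 5616
energy.acc_mean_diurnal_hee_kj_h       49.07
energy.acc_mean_nocturnal_hee_kj_h     64.36
energy.acc_mean_dee_sum24_kj_day       1391.7
energy.scan_dee_diurnal_extrapolated   1168.7
compare.t_dee_acc_vs_scan              t = 16.3, p < 0.001
compare.scan_dee_lt_acc_dee            true
```

Reading it: the classifier separates the four synthetic behavior signatures
almost perfectly (0.996 held-out accuracy); censoring removed the first
post-release days (13 824 → 5 616 bursts); nights are both colder and
flight-heavier in the configured world, so mean nocturnal HEE (64.4 kJ/bird/h)
exceeds diurnal HEE (49.1), and extrapolating diurnal-only scan data to 24 h
(1 168.7 kJ/bird/day) underestimates the accelerometer-based 24-h DEE
(1 391.7) — the directional bias the round-the-clock method exists to expose.

The same stages are available individually (`divebudget simulate|censor|
features|train|classify|budget|energy|compare`) and as library functions.

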