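# pwavekit

Postoperative atrial fibrillation (POAF) is the most common complication of
cardiac surgery, and much of it is missed by routine ward/ICU monitoring
because episodes are transient. Long-term single-lead ECG patches capture
days of preoperative sinus rhythm, in which subtle P-wave abnormalities —
wider and more dispersed atrial depolarisation — precede the arrhythmia.

`pwavekit` is a toolkit for analysts working with such recordings. It covers
the full chain from raw signal to risk model:

* **Synthetic data** — a parametric single-lead ECG generator (raised-cosine
  P/QRS/T lobes, patient-specific P-duration distributions, baseline
  wander / powerline / white noise) with exact fiducial ground truth, and a
  two-group clinical cohort generator with realistic covariate structure.
* **Preprocessing** — zero-phase Butterworth band-pass (default 0.5–40 Hz)
  plus a centred moving average (default 20 ms).
* **Delineation** — Pan–Tompkins-style QRS anchoring, then P-wave onset /
  first-peak / offset measured at the intersection with the isoelectric
  line, with rule-based quality control.
* **P-wave features** — the seven per-patient parameters: with per-beat
  durations *d*ᵢ and onset-to-peak times *q*ᵢ (ms),

  | feature | definition |
  |---|---|
  | Pmax, Pmin | max dᵢ, min dᵢ |
  | Pmean, Pstd | mean dᵢ, sample SD of dᵢ |
  | PWd | Pmax − Pmin (P-wave dispersion) |
  | Pptmean, Pptstd | mean qᵢ, sample SD of qᵢ |

* **Cohort statistics** — pooled two-sample *t* / Mann–Whitney *U* /
  chi-square (Fisher for sparse 2×2) dispatch, plus a summary-statistics
  *t*-test for auditing published tables.
* **Risk models** — multivariable logistic regression (clinical model:
  sex, age, LA diameter, GFR, mechanical ventilation time; clinical+ECG
  model: + Pmax, Pstd, PWd) with Mann–Whitney AUC and DeLong 95% CI, and an
  RBF-SVM protocol with class-balanced 7:3 splits (scheme A: full leftover
  test set; scheme B: class-balanced test set), five-fold stratified
  grid search over (C, γ), and confusion-matrix accuracy / sensitivity /
  specificity.

## Worked example

Run the bundled 20-patient demonstration study (synthesise cohort + ECGs,
delineate, extract features, compare groups, fit all models):

```sh
pwavekit run --config examples/demo.yaml
```

which prints (abridged; full artifacts land in `pwavekit_out/`):

```
"n_patients": 20,
"model1_auc": 0.845,
"model2_auc": 0.940
```

and writes a group-comparison table whose P-wave rows look like

```
variable   group0 (no POAF)  group1 (POAF)   p_value
pmax_ms    157.57 ± 33.38    195.00 ± 37.58  0.040
pmean_ms   122.93 ± 27.78    150.17 ± 22.97  0.050
pwd_ms     65.29 ± 29.91     86.67 ± 51.33   0.253
```

The POAF group is generated with wider, more variable P waves, so Pmax is
already separated at n = 20; the clinical+ECG logistic model (AUC 0.94)
outperforms the clinical model (AUC 0.85) on this cohort. `models.json`
additionally holds the SVM row — tuned (C, γ), train/test accuracy,
sensitivity and specificity. Every output file embeds the configuration
hash and seed, and reruns are bit-identical.

The same stages are available as library functions (`simulate_ecg`,
`preprocess`, `detect_qrs`, `locate_p_waves`, `compute_features`,
`compare_groups`, `fit_logistic`, `run_svm_protocol`, ...) and as individual
CLI subcommands (`simulate`, `preprocess`, `delineate`, `features`,
`stats`, `train`).

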