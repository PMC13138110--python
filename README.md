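# rptdose

Dosimetry and dose–response analysis for multi-cycle [¹⁷⁷Lu]Lu-DOTATATE
therapy of somatostatin-receptor-positive neuroendocrine tumors.

In radiopharmaceutical therapy, SPECT/CT imaging at a few time points after
each administration yields sparse absorbed-dose-rate samples per tumor and
kidney. This package implements the full analysis chain from those samples
to response prediction, for physicists and analysts working with multi-cycle
Lu-177 dosimetry data:

* **Kinetic fitting** — the per-cycle dose-rate curve is modelled as a
  biexponential, D̊(t) = A·(e^(−λ₁t) − e^(−λ₂t)), with the washout
  half-time ln2/λ₁ constrained to be no slower than physical ¹⁷⁷Lu decay
  (159.5 h). The cycle absorbed dose is the closed-form integral
  AD = A·(1/λ₁ − 1/λ₂).
* **Dose metrics** — per-cycle patient-mean AD and AD/AA (absorbed dose per
  administered activity, Gy/GBq) over lesions ≥ 10 cm³, cumulative dose
  cAD = Σ_c AD_c, and the cyclic uptake-decline biomarker
  ΔAD/AA = (AD/AA₄ − AD/AA₁)/AD/AA₁ × 100%.
* **Activity adaptation** — the trial's kidney-dose-driven rule: 7.4 GBq at
  cycle 1, then the activity needed to bring the cumulative kidney dose to
  23 Gy, split over the remaining cycles and capped at 11.1 GBq.
* **Dose–response models** — patients sorted by a dose metric and binned in
  groups of 11; a sigmoid P_PR(cAD) = Pmax/(1 + e^(−(cAD−Dhalf)/k)) fitted
  to group medians and response proportions with R²/RMSE; an unpenalized 2D
  logistic model and an RBF-kernel SVM on (cAD, ΔAD/AA) with stratified
  5-fold cross-validated ROC/AUC; Wilcoxon and Spearman rank statistics.
* **Synthetic cohort generator** — produces patients whose kinetics, noise,
  activity schedules and response labels emulate the statistical structure
  of a four-cycle course with imaging at 4/24/72 h, so the whole pipeline is
  testable without patient data.
* **Phantom / partial-volume module** — synthetic 3D dose-rate maps,
  fixed-point adaptive-threshold segmentation, and recovery-coefficient
  correction RC(V) = 1 − e^(−(V/v₀)^b) calibrated from generated spheres.

## Worked example

The numbered scripts under `analysis/` run the study end to end on a
73-patient synthetic cohort (fixed seed), writing tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_fit_doserate_curves.py
python analysis/03_dose_metrics.py
python analysis/04_dose_response.py
```

which prints (abridged):

```
generated 73 patients, 132 lesions, 2460 dose-rate samples -> results/cohort.csv
fitted 820 curves (61 clamped at 159.5 h) -> results/fits.csv
cycle-1 medians: tumor AD/AA 3.45 Gy/GBq, kidney AD/AA 0.429 Gy/GBq, tumor washout 74.3 h
median tumor AD/AA change vs cycle 1: ['-6%', '-20%', '-29%']
kidney AD/AA cycle 4 vs 1: medians 0.429 -> 0.437 Gy/GBq (signed-rank p = 0.20)
adaptation example: kidney AD/AA 0.43 Gy/GBq after 7.4 GBq -> cycle-2 recommendation 11.1 GBq (cap)
sigmoid: Pmax 100%, Dhalf 141 Gy, k 52 Gy; R2 0.71, RMSE 17.3%, AUC 0.802
2D logistic: beta = (-3.04, 0.0228/Gy, 0.0059/%), CV AUC 0.753
RBF SVM: CV AUC 0.744
```

Reading: tumor uptake efficiency (AD/AA) declines cycle over cycle while the
kidneys stay flat, the cycle-2 activity recommendation hits the per-cycle
cap, and both the cumulative dose and the uptake decline carry predictive
signal for partial response (cross-validated AUC ≈ 0.75). At n = 73 the
group-level sigmoid parameters are noisy; `analysis/05_parameter_recovery.py`
repeats the fit on 5,000 simulated patients and recovers the generating
curve (Pmax 100%, Dhalf 135 Gy, k 58 Gy) closely.

The same stages are available as a CLI (`rptdose generate|fit|summarize|
doseresponse|run`) and as library functions (`rptdose.pipeline.run_pipeline`).

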