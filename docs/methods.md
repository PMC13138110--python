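# Methods

## Dose-rate model and fitting

Each structure-cycle absorbed-dose-rate curve is modelled as

    D̊(t) = A · (exp(−λ₁ t) − exp(−λ₂ t)),   t in hours,

with a single shared amplitude A (Gy/h), washout rate λ₁ and uptake rate λ₂
(1/h), λ₂ > λ₁. Because effective clearance includes physical decay, the
washout half-time ln2/λ₁ cannot exceed the ¹⁷⁷Lu half-life of 159.5 h; the
fit enforces λ₁ ≥ ln2/159.5 ≈ 0.004346 h⁻¹. The cycle absorbed dose is the
closed-form integral AD = A·(1/λ₁ − 1/λ₂), validated against adaptive
quadrature to 10⁻⁶ relative.

Fitting is least squares on the dose-rate residuals. The amplitude enters
linearly and is profiled out analytically (for fixed rates the optimal A is
the projection of the data onto the shape vector), leaving a 2-parameter
problem in (log λ₁, log(λ₂/λ₁ − 1)), which builds the rate ordering into the
parameterization. A fully unconstrained fit is run first from a small
multistart (washout initialized from the log-slope of the last two samples,
or 2× the physical decay constant when the tail is non-decreasing; uptake/
washout ratio starts at 3, 11, 40). Only if its washout rate violates the
physical bound is the fit redone with λ₁ fixed at ln2/159.5 and the result
flagged `clamped` — so the flag means exactly "the unconstrained optimum was
infeasible". With three noise-free samples the fit reproduces generating
parameters to ≤ 10⁻⁶ relative; on noisy data its SSE matches a dense
grid-search oracle.

Degenerate inputs: fewer than three distinct sample times or non-positive
dose rates are input errors; if the free fit fails numerically the
bound-constrained fit is used (flagged).

**Known estimator property.** With only three samples and ~10% multiplicative
noise, the fitted washout half-time has a small (~1–3%) downward median skew
at the default kinetics. This is a sampling property of the constrained
least-squares estimator (fits verified globally optimal against the grid
oracle), visible in cohort-scale medians.

## Synthetic cohort

The generator emulates the statistical structure of a four-cycle course with
SPECT dosimetry at 4, 24 and 72 h. Defaults (changeable in `CohortConfig`):

| parameter | default | note |
|---|---|---|
| cycles / sampling times | 4 / {4, 24, 72} h | trial schedule |
| lesions per patient | 1 + Poisson(0.9), max 6 | mean ≈ 1.9, range 1–6 |
| tumor AD/AA cycle 1 | lognormal, median 3.2 Gy/GBq, σ = 0.45 | σ chosen so cAD spans ~40–280 Gy |
| per-cycle decline | lognormal factor, median 0.90, σ = 0.10 | ≈10% decline per cycle, independent draws |
| kidney AD/AA | lognormal, median 0.43 Gy/GBq, σ = 0.15; per-cycle jitter σ = 0.05 | stable in expectation across cycles |
| washout half-times | lognormal, medians 79.5 h (tumor), 47.2 h (kidney), σ = 0.10 | constant per structure across cycles |
| uptake half-time | lognormal, median 6 h, σ = 0.15 | places the 4-h sample near the rising edge |
| lesion AD/AA perturbation | lognormal, CV 20%, mean 1 | lesions share the patient-level value |
| lesion volume | lognormal, median 28.4 cm³, σ = 1.0, truncated 10–2340 cm³ | all generated lesions eligible |
| measurement noise | multiplicative lognormal, CV 10% | median 1 (see below) |
| activity schedule | adaptive (7.4 GBq first, 23 Gy kidney target, 11.1 GBq cap) | fixed schedule available |

The noise factor is lognormal with **median** 1 rather than mean 1: the
calibration targets are cohort medians, and median-1 noise keeps fitted
medians centred on the configured values (the difference is ~0.5% at CV 10%).

Response labels are Bernoulli draws from a configurable model evaluated on
the patient's **true** (noise-free) cAD and ΔAD/AA — either the sigmoid in
cAD or, by default, a 2D logistic with β₀ = −3.3, β₁ = 0.02 Gy⁻¹,
β₂ = −0.02 %⁻¹. At the cohort's typical operating point (cAD ≈ 110 Gy,
ΔAD/AA ≈ −27%) this gives ≈38% responders, with response probability rising
with cumulative dose and with deeper uptake decline. Patients not drawn as
responders are labelled SD or PD at a fixed dose-independent 33:12 ratio; no
dose-dependent model for that split is assumed. Decline factors are drawn
independently per cycle (no plateau), consistent with successive reductions
of similar magnitude.

What the generator does **not** emulate: lesion-level response, spatial dose
heterogeneity, registration/segmentation error structure beyond i.i.d.
multiplicative noise, correlations between uptake and washout, missing
cycles, or activity reductions for adverse events. Passing calibration tests
therefore demonstrates pipeline correctness and statistical behavior under
the stated model, not clinical accuracy on real data.

## Dose metrics and activity adaptation

Lesions enter the analysis when their first-cycle volume is ≥ 10 cm³
(inclusive). Patient per-cycle means over lesions are **unweighted**
arithmetic means — the patient-level record is a single value per cycle even
for multifocal disease; volume weighting is a documented alternative not
taken. cAD sums the per-cycle means; ΔAD/AA uses cycle-1 and final-cycle
means. Cycle indices are 1-based.

The adaptation rule projects delivered kidney dose as Σ AAᵢ·(AD/AA)ᵢ,
splits the remainder to 23 Gy evenly over remaining cycles, converts to
activity with the **most recent** measured kidney AD/AA, and caps at
11.1 GBq. Kidneys are treated as one combined structure. With constant
noiseless kidney AD/AA and a non-binding cap the schedule delivers exactly
23 Gy over 4 cycles.

## Dose-response analyses

Patients are sorted ascending by the metric (stable ties) and assigned to
consecutive groups of 11, the last group holding the remainder (73 patients
→ 6×11 + 7). The sigmoid P_PR(cAD) = Pmax/(1 + e^(−(cAD−Dhalf)/k)) is fitted
by unweighted least squares to the per-group (median cAD, % responders)
points, in percent units so Pmax ∈ [0, 100]; k > 0 via log-parameterization;
small multistart over steepness. R² = 1 − SS_res/SS_tot and
RMSE = √(SS_res/n) on the percent scale; R² is flagged undefined when the
observed proportions have zero variance.

The 2D logistic model is the unpenalized Bernoulli MLE (statsmodels);
separation is flagged, not raised. The SVM uses an RBF kernel on internally
standardized features, C = 1, gamma = "scale" (hyperparameters unreported in
the source setting; AUC is invariant to monotone score transforms, so
calibration is not attempted). Cross-validation uses seeded class-stratified
5-fold splits ("balanced groups" read as stratification); out-of-fold
decision scores are pooled for the headline AUC and per-fold AUCs are also
reported. AUC is computed by the rank (Mann–Whitney) formulation with
average-rank tie handling, cross-checked in tests against brute-force pair
counting and scikit-learn. The sigmoid model's AUC scores each patient by
the fitted curve at their own cAD (a monotone transform of cAD, so this
equals the AUC of cAD itself).

## Phantom and partial-volume correction

Phantoms are background + spheres rendered on an isotropic voxel grid
(world coordinates in mm at voxel centers, volumes = voxel count × voxel
volume, no partial voxels), blurred with a normalized Gaussian PSF of given
FWHM, and degraded with multiplicative lognormal noise. Segmentation is a
fixed-point iteration inside an oversized seed box:
T ← background + f·(mean-of-mask − background), starting at the box peak,
capped at 100 iterations (flagged if hit), reduced to the component
containing the peak. The default fraction f = 0.55 places the contour near
the half-intensity surface, the correct boundary for a Gaussian-blurred
sphere; it recovers blurred-sphere volumes to ~5% at FWHM = radius/2
(f is exposed as a parameter). The recovery curve RC(V) = 1 − e^(−(V/v₀)^b)
is a two-parameter saturating stand-in for a measured recovery-coefficient
table — monotone in volume, → 1 for large objects — calibrated by fitting
generated sphere data; correction divides the background-subtracted
structure mean by RC. PVC is applied to structure means, not voxel-wise.

## Problem sizes and seeds

Cohort-scale checks use 2,000 patients (≈23,000 curve fits, a few minutes on
one CPU); sigmoid parameter recovery uses 5,000 simulated patients (455
groups). All randomness flows through `numpy.random.default_rng` seeds
recorded in configs and manifests; identical config + seed reproduces every
output byte-identically.

## Limitations

* Three-point kinetics make individual fitted parameters noisy (washout
  half-time CV ≈ 30% at 10% noise); cohort medians are the reliable outputs.
* The generator's response model is a convenience; real response mechanisms
  (receptor loss, fibrosis, vascular change) are not modelled.
* The phantom module is a geometric stand-in, not a SPECT simulation: no
  projection/reconstruction physics, scatter, or registration error.
* The SD/PD split is dose-independent by construction, so analyses beyond
  the responder/non-responder dichotomy are not meaningful on synthetic data.
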