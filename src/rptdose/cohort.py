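"""Synthetic multi-cycle dosimetry cohort generator.

Generates patients whose per-cycle tumor and kidney dose-rate samples, lesion
volumes, administered activities and radiologic response labels emulate the
statistical structure of a four-cycle Lu-177 DOTATATE course with SPECT-based
dosimetry at 4, 24 and 72 h after each administration:

* patient-level tumor AD/AA is lognormal with a configurable cycle-1 median
  (default 3.2 Gy/GBq) and declines by an independent multiplicative
  lognormal factor each cycle (default median 0.90, i.e. ~10% per cycle);
* kidney AD/AA is stable across cycles (default median 0.43 Gy/GBq);
* washout half-times are lognormal around 79.5 h (tumor) and 47.2 h (kidney),
  constant per structure across cycles; the uptake half-time defaults to 6 h
  so the 4-h sample sits near the rising edge of the curve;
* dose-rate samples follow the biexponential model with multiplicative
  lognormal noise of configurable coefficient of variation (default 10%);
* administered activity follows either a fixed schedule or the trial's
  kidney-dose adaptation rule (7.4 GBq first cycle, 23 Gy kidney target,
  11.1 GBq cap);
* the binary response label is drawn Bernoulli from a configurable model
  (sigmoid in cAD, or 2D logistic in cAD and dAD/AA) evaluated on the
  patient's TRUE (noise-free) dose metrics; non-responders are split into
  stable and progressive disease at a fixed dose-independent ratio.

The generator is deterministic for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .doserate import BiexpParams, TimedDoseRate, biexp_doserate
from .metrics import adapt_activity
from .response import sigmoid_probability

__all__ = [
    "ResponseModelSpec",
    "CohortConfig",
    "StructureCycle",
    "LesionRecord",
    "PatientRecord",
    "generate_cohort",
    "sample_doserates",
    "assign_response",
    "cohort_to_frame",
]

COHORT_COLUMNS = [
    "patient_id",
    "cycle",
    "structure_id",
    "structure_type",
    "time_h",
    "doserate_gy_per_h",
    "aa_gbq",
    "volume_cm3",
    "response",
]


class ResponseModelSpec(BaseModel):
    """Generative model linking true dose metrics to response probability.

    ``sigmoid_cAD`` uses P_PR = pmax / (1 + exp(-(cAD - dhalf)/k)) (percent
    scale); ``logistic_2d`` uses an inverse-logit in (cAD, dAD/AA). Patients
    not drawn as PR are labelled SD or PD at ``sd_pd_ratio``, independent of
    dose (no dose-dependent model for that split is assumed).
    """

    kind: Literal["sigmoid_cAD", "logistic_2d"] = "logistic_2d"
    # sigmoid parameters (percent / Gy / Gy)
    pmax_pct: float = Field(default=100.0, ge=0.0, le=100.0)
    dhalf_gy: float = 135.0
    k_gy: float = Field(default=58.0, gt=0.0)
    # logistic parameters (dimensionless / per Gy / per %)
    beta0: float = -3.3
    beta1_per_gy: float = 0.02
    beta2_per_pct: float = -0.02
    sd_pd_ratio: tuple[float, float] = (33.0, 12.0)

    def probability_pr(self, cad_gy: float, delta_adaa_pct: float) -> float:
        """Probability of partial response as a fraction in [0, 1]."""
        if self.kind == "sigmoid_cAD":
            p = float(sigmoid_probability(cad_gy, self.pmax_pct, self.dhalf_gy, self.k_gy)) / 100.0
        else:
            z = self.beta0 + self.beta1_per_gy * cad_gy + self.beta2_per_pct * delta_adaa_pct
            p = 1.0 / (1.0 + math.exp(-z))
        if not 0.0 <= p <= 1.0:
            raise RuntimeError(f"response model produced probability {p} outside [0, 1]")
        return p


class CohortConfig(BaseModel):
    """All distributions and effect sizes of the synthetic cohort.

    Medians and half-times default to the calibration targets of the
    emulated trial cohort; lognormal sigmas are dimensionless log-scale
    standard deviations.
    """

    n_patients: int = Field(default=73, ge=1)
    n_cycles: int = Field(default=4, ge=2)
    sample_times_h: tuple[float, ...] = (4.0, 24.0, 72.0)
    lesion_count_mean: float = Field(default=1.9, ge=1.0)
    lesion_count_max: int = Field(default=6, ge=1)
    tumor_adaa_median_c1: float = Field(default=3.2, gt=0.0)
    tumor_adaa_lognormal_sigma: float = Field(default=0.45, ge=0.0)
    lesion_adaa_cv: float = Field(default=0.20, ge=0.0)
    cycle_decline_median: float = Field(default=0.90, gt=0.0, le=1.5)
    cycle_decline_spread: float = Field(default=0.10, ge=0.0)
    kidney_adaa_median: float = Field(default=0.43, gt=0.0)
    kidney_adaa_sigma: float = Field(default=0.15, ge=0.0)
    kidney_cycle_jitter_sigma: float = Field(default=0.05, ge=0.0)
    tumor_washout_halftime_median_h: float = Field(default=79.5, gt=0.0)
    kidney_washout_halftime_median_h: float = Field(default=47.2, gt=0.0)
    washout_halftime_sigma: float = Field(default=0.10, ge=0.0)
    uptake_halftime_h: float = Field(default=6.0, gt=0.0)
    uptake_halftime_sigma: float = Field(default=0.15, ge=0.0)
    noise_cv: float = Field(default=0.10, ge=0.0)
    lesion_volume_median_cm3: float = Field(default=28.4, gt=0.0)
    lesion_volume_sigma: float = Field(default=1.0, ge=0.0)
    lesion_volume_range_cm3: tuple[float, float] = (10.0, 2340.0)
    aa_schedule: Literal["fixed", "adaptive"] = "adaptive"
    first_aa_gbq: float = Field(default=7.4, gt=0.0)
    aa_cap_gbq: float = Field(default=11.1, gt=0.0)
    kidney_target_gy: float = Field(default=23.0, gt=0.0)
    response_model: ResponseModelSpec = Field(default_factory=ResponseModelSpec)
    seed: int = 0

    @model_validator(mode="after")
    def _check_times_and_ranges(self) -> "CohortConfig":
        times = self.sample_times_h
        if len(times) < 3:
            raise ValueError("sample_times_h: need at least 3 sampling times")
        if any(t <= 0 for t in times) or any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("sample_times_h: times must be positive and strictly increasing")
        lo, hi = self.lesion_volume_range_cm3
        if not 0 < lo < hi:
            raise ValueError("lesion_volume_range_cm3: need 0 < low < high")
        return self


@dataclass
class StructureCycle:
    """True kinetics and sampled dose rates of one structure in one cycle."""

    cycle: int  # 1-based
    true_params: BiexpParams
    samples: list[TimedDoseRate]

    @property
    def true_ad_gy(self) -> float:
        return self.true_params.ad_gy


@dataclass
class LesionRecord:
    lesion_id: str
    volume_cm3: float
    cycles: list[StructureCycle]


@dataclass
class PatientRecord:
    patient_id: str
    aa_gbq: list[float]  # per cycle
    lesions: list[LesionRecord]
    kidney_cycles: list[StructureCycle]
    response: str  # PR | SD | PD
    true_cad_gy: float
    true_delta_adaa_pct: float


def _lognormal_cv_sigma(cv: float) -> float:
    """Log-scale sigma of a lognormal with coefficient of variation ``cv``."""
    return math.sqrt(math.log1p(cv * cv))


def sample_doserates(
    true_params: BiexpParams,
    times_h: tuple[float, ...] | list[float],
    noise_cv: float,
    rng: np.random.Generator,
) -> list[TimedDoseRate]:
    """Sample the dose-rate curve with multiplicative lognormal noise.

    The noise factor has median 1 and coefficient of variation ``noise_cv``
    (median-1 rather than mean-1, so that cohort medians of fitted doses stay
    centred on the configured calibration values). ``noise_cv = 0`` returns
    the model curve exactly; all sampled values are strictly positive.
    """
    if any(t <= 0 for t in times_h):
        raise ValueError("sampling times must be positive")
    truth = np.asarray(biexp_doserate(np.asarray(times_h, dtype=float), true_params))
    if noise_cv > 0:
        sigma = _lognormal_cv_sigma(noise_cv)
        factors = np.exp(sigma * rng.standard_normal(truth.size))
        truth = truth * factors
    return [TimedDoseRate(time_h=float(t), doserate=float(d)) for t, d in zip(times_h, truth)]


def assign_response(
    cad_gy: float,
    delta_adaa_pct: float,
    model: ResponseModelSpec,
    rng: np.random.Generator,
) -> str:
    """Draw a response label: PR with the model probability, else SD/PD."""
    p = model.probability_pr(cad_gy, delta_adaa_pct)
    if rng.random() < p:
        return "PR"
    sd, pd_ = model.sd_pd_ratio
    return "SD" if rng.random() < sd / (sd + pd_) else "PD"


def _draw_lesion_count(cfg: CohortConfig, rng: np.random.Generator) -> int:
    # 1 + Poisson(mean - 1), truncated at lesion_count_max: matches a mean of
    # ~1.9 lesions per patient with range 1..6.
    return int(min(1 + rng.poisson(cfg.lesion_count_mean - 1.0), cfg.lesion_count_max))


def _draw_truncated_lognormal(
    median: float, sigma: float, lo: float, hi: float, rng: np.random.Generator
) -> float:
    for _ in range(1000):
        v = median * math.exp(sigma * rng.standard_normal())
        if lo <= v <= hi:
            return v
    raise RuntimeError("truncated lognormal rejection sampling failed")


def _draw_washout_halftime(median_h: float, sigma: float, rng: np.random.Generator) -> float:
    # Effective washout cannot be slower than physical Lu-177 decay; keep the
    # draw strictly inside the feasible region.
    from .doserate import LU177_HALFLIFE_H

    return _draw_truncated_lognormal(median_h, sigma, 1.0, 0.99 * LU177_HALFLIFE_H, rng)


def generate_cohort(config: CohortConfig) -> list[PatientRecord]:
    """Generate the synthetic cohort. Deterministic for a fixed config seed."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    decline_sigma = cfg.cycle_decline_spread
    lesion_sigma = _lognormal_cv_sigma(cfg.lesion_adaa_cv)
    vol_lo, vol_hi = cfg.lesion_volume_range_cm3

    patients: list[PatientRecord] = []
    for i in range(cfg.n_patients):
        pid = f"P{i + 1:04d}"

        # --- patient-level true kinetics -------------------------------
        tumor_adaa_c1 = cfg.tumor_adaa_median_c1 * math.exp(
            cfg.tumor_adaa_lognormal_sigma * rng.standard_normal()
        )
        decline_factors = cfg.cycle_decline_median * np.exp(
            decline_sigma * rng.standard_normal(cfg.n_cycles - 1)
        )
        # patient-level tumor AD/AA by cycle (Gy/GBq)
        tumor_adaa = tumor_adaa_c1 * np.concatenate(([1.0], np.cumprod(decline_factors)))

        kidney_level = cfg.kidney_adaa_median * math.exp(
            cfg.kidney_adaa_sigma * rng.standard_normal()
        )
        kidney_adaa = kidney_level * np.exp(
            cfg.kidney_cycle_jitter_sigma * rng.standard_normal(cfg.n_cycles)
        )

        tumor_washout_h = _draw_washout_halftime(
            cfg.tumor_washout_halftime_median_h, cfg.washout_halftime_sigma, rng
        )
        kidney_washout_h = _draw_washout_halftime(
            cfg.kidney_washout_halftime_median_h, cfg.washout_halftime_sigma, rng
        )
        uptake_h = cfg.uptake_halftime_h * math.exp(
            cfg.uptake_halftime_sigma * rng.standard_normal()
        )

        n_lesions = _draw_lesion_count(cfg, rng)
        # lesion-level multiplicative perturbations, mean 1 so the patient
        # mean stays centred on the patient-level AD/AA
        pert = np.exp(
            lesion_sigma * rng.standard_normal(n_lesions) - 0.5 * lesion_sigma**2
        )
        volumes = [
            _draw_truncated_lognormal(
                cfg.lesion_volume_median_cm3, cfg.lesion_volume_sigma, vol_lo, vol_hi, rng
            )
            for _ in range(n_lesions)
        ]

        # --- administered activity schedule ----------------------------
        aa: list[float] = []
        for c in range(cfg.n_cycles):
            if cfg.aa_schedule == "fixed" or c == 0:
                aa.append(cfg.first_aa_gbq)
            else:
                aa.append(
                    adapt_activity(
                        kidney_adaa_history=kidney_adaa[:c].tolist(),
                        aa_history=aa,
                        n_total_cycles=cfg.n_cycles,
                        kidney_target_gy=cfg.kidney_target_gy,
                        first_aa_gbq=cfg.first_aa_gbq,
                        cap_gbq=cfg.aa_cap_gbq,
                    )
                )

        # --- per-structure per-cycle curves and samples -----------------
        lesions: list[LesionRecord] = []
        for j in range(n_lesions):
            cycles: list[StructureCycle] = []
            for c in range(cfg.n_cycles):
                ad = tumor_adaa[c] * pert[j] * aa[c]
                params = BiexpParams.from_halftimes(ad, tumor_washout_h, uptake_h)
                cycles.append(
                    StructureCycle(
                        cycle=c + 1,
                        true_params=params,
                        samples=sample_doserates(params, cfg.sample_times_h, cfg.noise_cv, rng),
                    )
                )
            lesions.append(LesionRecord(lesion_id=f"{pid}_L{j + 1}", volume_cm3=volumes[j], cycles=cycles))

        kidney_cycles: list[StructureCycle] = []
        for c in range(cfg.n_cycles):
            ad = kidney_adaa[c] * aa[c]
            params = BiexpParams.from_halftimes(ad, kidney_washout_h, uptake_h)
            kidney_cycles.append(
                StructureCycle(
                    cycle=c + 1,
                    true_params=params,
                    samples=sample_doserates(params, cfg.sample_times_h, cfg.noise_cv, rng),
                )
            )

        # --- true dose metrics and response -----------------------------
        # patient-mean lesion AD per cycle; perturbations have mean 1 but a
        # finite lesion sample, so use the actual lesion values
        mean_ad = np.array(
            [np.mean([les.cycles[c].true_ad_gy for les in lesions]) for c in range(cfg.n_cycles)]
        )
        mean_adaa = mean_ad / np.asarray(aa)
        true_cad = float(mean_ad.sum())
        true_delta = float((mean_adaa[-1] - mean_adaa[0]) / mean_adaa[0] * 100.0)
        label = assign_response(true_cad, true_delta, cfg.response_model, rng)

        patients.append(
            PatientRecord(
                patient_id=pid,
                aa_gbq=[float(a) for a in aa],
                lesions=lesions,
                kidney_cycles=kidney_cycles,
                response=label,
                true_cad_gy=true_cad,
                true_delta_adaa_pct=true_delta,
            )
        )
    return patients


def cohort_to_frame(patients: list[PatientRecord]) -> pd.DataFrame:
    """Flatten a cohort into the long per-sample table.

    One row per dose-rate sample, with columns patient_id, cycle,
    structure_id, structure_type, time_h, doserate_gy_per_h, aa_gbq,
    volume_cm3 (NaN for kidneys) and response.
    """
    rows = []
    for p in patients:
        for les in p.lesions:
            for sc in les.cycles:
                for s in sc.samples:
                    rows.append(
                        (p.patient_id, sc.cycle, les.lesion_id, "tumor", s.time_h,
                         s.doserate, p.aa_gbq[sc.cycle - 1], les.volume_cm3, p.response)
                    )
        for sc in p.kidney_cycles:
            for s in sc.samples:
                rows.append(
                    (p.patient_id, sc.cycle, f"{p.patient_id}_K", "kidney", s.time_h,
                     s.doserate, p.aa_gbq[sc.cycle - 1], np.nan, p.response)
                )
    return pd.DataFrame(rows, columns=COHORT_COLUMNS)
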