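"""End-to-end orchestration: cohort -> curve fits -> dose metrics -> dose-response report.

``run_pipeline`` composes the stages into a reproducible run: generate (or
load) a long-format cohort table, fit every structure-cycle dose-rate curve
with the constrained biexponential model, aggregate patient-level dose
metrics, and run the grouped-sigmoid / logistic / SVM dose-response analyses.
All outputs are plain CSV/JSON plus a manifest with the config hash, seed and
library versions; identical config + seed gives identical numerical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from . import __version__
from .cohort import COHORT_COLUMNS, CohortConfig, cohort_to_frame, generate_cohort
from .doserate import TimedDoseRate, fit_biexponential, half_times
from .metrics import (
    VOLUME_ELIGIBILITY_CM3,
    LesionCycleDose,
    summarize_patient,
)
from .response import (
    crossval_auc,
    fit_logistic_2d,
    fit_sigmoid,
    group_patients,
    make_logistic_estimator,
    make_svm_estimator,
    mann_whitney_auc,
    spearman,
    wilcoxon_rank_sum,
)

__all__ = [
    "PipelineConfig",
    "ReportBundle",
    "run_pipeline",
    "read_cohort",
    "write_cohort",
    "fit_cohort_frame",
    "summarize_cohort",
    "dose_response_report",
    "write_report",
]

logger = logging.getLogger("rptdose")

FIT_COLUMNS = [
    "patient_id", "structure_id", "structure_type", "cycle", "A", "lambda1",
    "lambda2", "washout_halftime_h", "uptake_halftime_h", "ad_gy", "aa_gbq",
    "adaa", "volume_cm3", "clamped", "sse", "response",
]


class PipelineConfig(BaseModel):
    """Configuration of a full pipeline run."""

    mode: Literal["generate", "load"] = "generate"
    cohort: CohortConfig = Field(default_factory=CohortConfig)
    input_path: Optional[str] = None
    output_dir: str = "results"
    seed: int = 0
    group_size: int = 11
    run_sigmoid: bool = True
    run_logistic: bool = True
    run_svm: bool = True
    n_folds: int = 5

    @model_validator(mode="after")
    def _check_mode(self) -> "PipelineConfig":
        if self.mode == "load" and not self.input_path:
            raise ValueError("input_path: required when mode='load'")
        return self


@dataclass
class ReportBundle:
    """All tables and model outputs of one pipeline run."""

    cohort: pd.DataFrame
    fits: pd.DataFrame
    summaries: pd.DataFrame
    report: dict
    manifest: dict
    excluded_patients: list[str] = field(default_factory=list)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format cohort CSV."""
    frame = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"cohort CSV is missing required columns: {missing}")
    extra = [c for c in frame.columns if c not in COHORT_COLUMNS]
    if extra:
        logger.warning("ignoring unknown cohort columns: %s", extra)
        frame = frame[COHORT_COLUMNS]
    numeric = ["cycle", "time_h", "doserate_gy_per_h", "aa_gbq"]
    for col in numeric:
        vals = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[vals.isna()]
        if len(bad):
            raise ValueError(f"column {col}: non-numeric value at row {int(bad[0])}")
        frame[col] = vals
    if (frame["doserate_gy_per_h"] <= 0).any():
        row = int(frame.index[frame["doserate_gy_per_h"] <= 0][0])
        raise ValueError(f"non-positive dose rate at row {row}")
    return frame


def write_cohort(frame: pd.DataFrame, path: str | Path) -> None:
    # full-precision floats so read(write(x)) is bit-exact
    frame.to_csv(path, index=False, float_format="%.17g")


def fit_cohort_frame(cohort: pd.DataFrame) -> pd.DataFrame:
    """Fit the constrained biexponential model to every structure-cycle curve."""
    rows = []
    n_clamped = 0
    for (pid, sid, cycle), grp in cohort.groupby(
        ["patient_id", "structure_id", "cycle"], sort=True
    ):
        samples = [
            TimedDoseRate(time_h=float(t), doserate=float(d))
            for t, d in zip(grp["time_h"], grp["doserate_gy_per_h"])
        ]
        params = fit_biexponential(samples)
        wash_h, up_h = half_times(params)
        aa = float(grp["aa_gbq"].iloc[0])
        n_clamped += int(params.clamped)
        rows.append(
            (pid, sid, grp["structure_type"].iloc[0], int(cycle), params.A,
             params.lambda1, params.lambda2, wash_h, up_h, params.ad_gy, aa,
             params.ad_gy / aa, float(grp["volume_cm3"].iloc[0]),
             params.clamped, params.residual_sse, grp["response"].iloc[0])
        )
    logger.info("fitted %d structure-cycle curves (%d clamped)", len(rows), n_clamped)
    return pd.DataFrame(rows, columns=FIT_COLUMNS)


def summarize_cohort(fits: pd.DataFrame) -> tuple[pd.DataFrame, list[str]]:
    """Aggregate fits into per-patient dose summaries.

    Patients with no eligible (>= 10 cm^3) lesion are excluded and returned
    separately. Output has one row per retained patient with per-cycle mean
    AD and AD/AA, cAD, dAD/AA, kidney AD/AA, response and responder flag.
    """
    tumor = fits[fits["structure_type"] == "tumor"]
    kidney = fits[fits["structure_type"] == "kidney"]
    rows = []
    excluded: list[str] = []
    for pid, grp in tumor.groupby("patient_id", sort=True):
        lesion_doses = [
            LesionCycleDose(
                lesion_id=r.structure_id, cycle=int(r.cycle), ad_gy=float(r.ad_gy),
                aa_gbq=float(r.aa_gbq), volume_cm3=float(r.volume_cm3),
            )
            for r in grp.itertuples()
        ]
        if not any(d.volume_cm3 >= VOLUME_ELIGIBILITY_CM3 for d in lesion_doses):
            excluded.append(str(pid))
            continue
        summary = summarize_patient(str(pid), lesion_doses, str(grp["response"].iloc[0]))
        krows = kidney[kidney["patient_id"] == pid].sort_values("cycle")
        row = {
            "patient_id": summary.patient_id,
            "cad_gy": summary.cad_gy,
            "delta_adaa_pct": summary.delta_adaa_pct,
            "response": summary.response,
            "responder": summary.responder,
        }
        for c, (ad, adaa) in enumerate(zip(summary.mean_ad_gy, summary.mean_adaa), start=1):
            row[f"mean_ad_c{c}"] = ad
            row[f"adaa_c{c}"] = adaa
        for r in krows.itertuples():
            row[f"kidney_adaa_c{int(r.cycle)}"] = float(r.adaa)
        rows.append(row)
    if excluded:
        logger.info("excluded %d patients with no eligible lesion", len(excluded))
    return pd.DataFrame(rows), excluded


def dose_response_report(
    summaries: pd.DataFrame,
    seed: int = 0,
    group_size: int = 11,
    run_sigmoid: bool = True,
    run_logistic: bool = True,
    run_svm: bool = True,
    n_folds: int = 5,
) -> dict:
    """Run the dose-response analyses on the patient-summary table."""
    if summaries.empty:
        raise ValueError("no patients to analyze (all excluded by the lesion-volume filter)")
    cad = summaries["cad_gy"].to_numpy()
    delta = summaries["delta_adaa_pct"].to_numpy()
    resp = summaries["responder"].to_numpy(dtype=bool)
    report: dict = {"n_patients": int(len(summaries)), "n_responders": int(resp.sum()), "seed": seed}

    for metric, values in (("cad", cad), ("delta_adaa", delta)):
        groups = group_patients(values, resp, group_size=group_size)
        report[f"groups_{metric}"] = [
            {"n": g.n, "median_metric": g.median_metric, "pct_pr": g.pct_pr} for g in groups
        ]
        if metric == "cad" and run_sigmoid:
            if len(groups) < 3:
                logger.warning("only %d cAD groups; skipping the sigmoid fit", len(groups))
                report["sigmoid"] = {"skipped": f"{len(groups)} groups < 3"}
            else:
                model, quality = fit_sigmoid(groups)
                scores = np.asarray(model.predict(cad))
                report["sigmoid"] = {
                    "pmax_pct": model.pmax, "dhalf_gy": model.dhalf, "k_gy": model.k,
                    "r_squared": quality.r_squared, "rmse_pct": quality.rmse,
                    "n_groups": quality.n_groups,
                    "auc": mann_whitney_auc(scores, resp),
                }

    features = np.column_stack([cad, delta])
    if run_logistic:
        logit = fit_logistic_2d(cad, delta, resp)
        entry = {
            "beta0": logit.beta0, "beta1_per_gy": logit.beta1, "beta2_per_pct": logit.beta2,
            "converged": logit.converged, "separation_flag": logit.separation_flag,
        }
        if resp.sum() >= n_folds and (~resp).sum() >= n_folds:
            ev = crossval_auc(make_logistic_estimator(), features, resp, n_folds=n_folds, seed=seed)
            entry["cv_auc_pooled"] = ev.auc
            entry["cv_auc_per_fold"] = ev.per_fold_auc
        report["logistic_2d"] = entry
    if run_svm:
        entry = {"c_param": 1.0, "gamma": "scale"}
        if resp.sum() >= n_folds and (~resp).sum() >= n_folds:
            ev = crossval_auc(make_svm_estimator(), features, resp, n_folds=n_folds, seed=seed)
            entry["cv_auc_pooled"] = ev.auc
            entry["cv_auc_per_fold"] = ev.per_fold_auc
        report["svm_rbf"] = entry

    if resp.any() and (~resp).any():
        stat, p = wilcoxon_rank_sum(cad[resp], cad[~resp])
        report["ranksum_cad_responders"] = {"statistic": stat, "p_value": p}
        stat, p = wilcoxon_rank_sum(delta[resp], delta[~resp])
        report["ranksum_delta_responders"] = {"statistic": stat, "p_value": p}
    rho, p = spearman(cad, delta)
    report["spearman_cad_vs_delta"] = {"rho": rho, "p_value": p}
    return report


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(config.model_dump_json().encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> ReportBundle:
    """Execute the full pipeline per the configuration."""
    if config.mode == "generate":
        cohort_cfg = config.cohort.model_copy(update={"seed": config.seed})
        patients = generate_cohort(cohort_cfg)
        cohort = cohort_to_frame(patients)
        logger.info("generated cohort: %d patients", cohort_cfg.n_patients)
    else:
        cohort = read_cohort(config.input_path)
        logger.info("loaded cohort from %s: %d rows", config.input_path, len(cohort))

    fits = fit_cohort_frame(cohort)
    summaries, excluded = summarize_cohort(fits)
    report = dose_response_report(
        summaries, seed=config.seed, group_size=config.group_size,
        run_sigmoid=config.run_sigmoid, run_logistic=config.run_logistic,
        run_svm=config.run_svm, n_folds=config.n_folds,
    )
    manifest = {
        "config": json.loads(config.model_dump_json()),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "excluded_patients": excluded,
        "versions": {
            "rptdose": __version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
    }
    return ReportBundle(
        cohort=cohort, fits=fits, summaries=summaries, report=report,
        manifest=manifest, excluded_patients=excluded,
    )


def write_report(bundle: ReportBundle, out_dir: str | Path) -> None:
    """Write all bundle artifacts (CSV tables, report JSON, manifest) to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle.cohort.to_csv(out / "cohort.csv", index=False)
    bundle.fits.to_csv(out / "fits.csv", index=False)
    bundle.summaries.to_csv(out / "patient_summaries.csv", index=False)
    (out / "report.json").write_text(json.dumps(bundle.report, indent=2))
    (out / "manifest.json").write_text(json.dumps(bundle.manifest, indent=2))
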