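"""Dose-response models on the patient summaries.

Groups patients by cAD (and by dAD/AA) into bins of 11, fits the sigmoid
response curve with R^2/RMSE, fits the 2D logistic and RBF-SVM classifiers
on (cAD, dAD/AA) with stratified 5-fold cross-validated AUC, and reports the
rank statistics comparing responders with non-responders.
"""

import json
from pathlib import Path

import pandas as pd

from rptdose.pipeline import dose_response_report

OUT = Path("results")
SEED = 20260

def main() -> None:
    summaries = pd.read_csv(OUT / "patient_summaries.csv")
    report = dose_response_report(summaries, seed=SEED)
    (OUT / "dose_response.json").write_text(json.dumps(report, indent=2))

    sig = report["sigmoid"]
    print(f"{report['n_patients']} patients, {report['n_responders']} responders, "
          f"{len(report['groups_cad'])} cAD groups -> {OUT/'dose_response.json'}")
    print(f"sigmoid: Pmax {sig['pmax_pct']:.0f}%, Dhalf {sig['dhalf_gy']:.0f} Gy, "
          f"k {sig['k_gy']:.0f} Gy; R2 {sig['r_squared']:.2f}, RMSE {sig['rmse_pct']:.1f}%, "
          f"AUC {sig['auc']:.3f}")
    logi = report["logistic_2d"]
    print(f"2D logistic: beta = ({logi['beta0']:.2f}, {logi['beta1_per_gy']:.4f}/Gy, "
          f"{logi['beta2_per_pct']:.4f}/%), CV AUC {logi.get('cv_auc_pooled', float('nan')):.3f}")
    print(f"RBF SVM: CV AUC {report['svm_rbf'].get('cv_auc_pooled', float('nan')):.3f}")
    print(f"Spearman cAD vs dAD/AA: rho {report['spearman_cad_vs_delta']['rho']:.2f} "
          f"(p = {report['spearman_cad_vs_delta']['p_value']:.2f})")

if __name__ == "__main__":
    main()
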