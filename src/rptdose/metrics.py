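"""Patient-level dose metrics and the kidney-dose-driven activity adaptation rule.

Aggregates per-lesion per-cycle absorbed doses into the patient-level
quantities the dose-response analysis runs on:

* per-cycle patient-mean AD (Gy) and AD/AA (Gy/GBq) across eligible lesions,
* cumulative absorbed dose cAD = sum over cycles of the per-cycle mean AD,
* dAD/AA: percent change of the mean AD/AA from cycle 1 to the final cycle,
* per-cycle percent changes versus cycle 1 and versus the previous cycle.

Lesions enter the analysis only if their first-cycle volume is at least
10 cm^3. Lesion means are unweighted arithmetic means; the trial records a
single patient-level value even for multifocal disease.

The activity-adaptation rule mirrors the trial protocol: the first cycle is
standardized to 7.4 GBq, and before each later cycle the activity needed to
bring the cumulative kidney dose to 23 Gy, split evenly over the remaining
cycles and converted through the latest measured kidney AD/AA, is
recommended, capped at 11.1 GBq per cycle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "VOLUME_ELIGIBILITY_CM3",
    "KIDNEY_TARGET_GY",
    "FIRST_CYCLE_AA_GBQ",
    "AA_CAP_GBQ",
    "LesionCycleDose",
    "PatientDoseSummary",
    "eligible_lesions",
    "summarize_patient",
    "cyclic_changes",
    "adapt_activity",
]

VOLUME_ELIGIBILITY_CM3 = 10.0
KIDNEY_TARGET_GY = 23.0
FIRST_CYCLE_AA_GBQ = 7.4
AA_CAP_GBQ = 11.1

RESPONDER_LABELS = frozenset({"PR", "CR"})


@dataclass(frozen=True)
class LesionCycleDose:
    """Absorbed dose of one lesion in one treatment cycle."""

    lesion_id: str
    cycle: int  # 1-based
    ad_gy: float
    aa_gbq: float
    volume_cm3: float  # first-cycle volume, used for eligibility

    def __post_init__(self) -> None:
        if self.ad_gy <= 0:
            raise ValueError(f"ad_gy must be positive, got {self.ad_gy}")
        if self.aa_gbq <= 0:
            raise ValueError(f"aa_gbq must be positive, got {self.aa_gbq}")
        if self.cycle < 1:
            raise ValueError("cycle indices are 1-based")

    @property
    def adaa(self) -> float:
        """Absorbed dose per administered activity, Gy/GBq."""
        return self.ad_gy / self.aa_gbq


@dataclass
class PatientDoseSummary:
    """Patient-level dose metrics over a full course of therapy."""

    patient_id: str
    mean_ad_gy: list[float]  # per cycle, across eligible lesions
    mean_adaa: list[float]  # per cycle, Gy/GBq
    cad_gy: float
    delta_adaa_pct: float  # cycle 1 -> final cycle
    pct_change_vs_c1: list[float]  # cycles 2..n vs cycle 1
    response: str
    responder: bool = field(init=False)

    def __post_init__(self) -> None:
        self.responder = self.response in RESPONDER_LABELS


def eligible_lesions(lesions: Sequence[LesionCycleDose]) -> list[LesionCycleDose]:
    """Keep lesion-cycle records whose first-cycle volume is >= 10 cm^3.

    The boundary is inclusive and the input order is preserved.
    """
    return [les for les in lesions if les.volume_cm3 >= VOLUME_ELIGIBILITY_CM3]


def summarize_patient(
    patient_id: str,
    lesion_doses: Sequence[LesionCycleDose],
    response: str,
) -> PatientDoseSummary:
    """Aggregate eligible-lesion doses into a patient summary.

    Every eligible lesion must carry a record for every cycle present in the
    data; per-cycle means are unweighted across lesions.
    """
    doses = eligible_lesions(lesion_doses)
    if not doses:
        raise ValueError(f"patient {patient_id}: no eligible lesion (>= 10 cm^3)")
    cycles = sorted({d.cycle for d in doses})
    lesion_ids = sorted({d.lesion_id for d in doses})
    by_key = {(d.lesion_id, d.cycle): d for d in doses}
    for lid in lesion_ids:
        for c in cycles:
            if (lid, c) not in by_key:
                raise ValueError(
                    f"patient {patient_id}: lesion {lid} missing cycle {c}"
                )

    mean_ad = [float(np.mean([by_key[(lid, c)].ad_gy for lid in lesion_ids])) for c in cycles]
    mean_adaa = [float(np.mean([by_key[(lid, c)].adaa for lid in lesion_ids])) for c in cycles]
    cad = float(np.sum(mean_ad))
    delta = (mean_adaa[-1] - mean_adaa[0]) / mean_adaa[0] * 100.0
    vs_c1, _ = cyclic_changes(mean_adaa)
    return PatientDoseSummary(
        patient_id=patient_id,
        mean_ad_gy=mean_ad,
        mean_adaa=mean_adaa,
        cad_gy=cad,
        delta_adaa_pct=float(delta),
        pct_change_vs_c1=vs_c1,
        response=response,
    )


def cyclic_changes(per_cycle_values: Sequence[float]) -> tuple[list[float], list[float]]:
    """Percent changes of a per-cycle series vs cycle 1 and vs the previous cycle.

    Returns two vectors of length ``n_cycles - 1``, both in percent.
    """
    vals = np.asarray(per_cycle_values, dtype=float)
    if vals.size < 2:
        raise ValueError("need at least 2 cycles")
    if vals[0] == 0:
        raise ValueError("cycle-1 value is zero; percent change undefined")
    vs_c1 = (vals[1:] - vals[0]) / vals[0] * 100.0
    successive = (vals[1:] - vals[:-1]) / vals[:-1] * 100.0
    return vs_c1.tolist(), successive.tolist()


def adapt_activity(
    kidney_adaa_history: Sequence[float],
    aa_history: Sequence[float],
    n_total_cycles: int = 4,
    kidney_target_gy: float = KIDNEY_TARGET_GY,
    first_aa_gbq: float = FIRST_CYCLE_AA_GBQ,
    cap_gbq: float = AA_CAP_GBQ,
) -> float:
    """Recommend the administered activity (GBq) for the next cycle.

    The kidney dose delivered so far is ``sum(aa_i * adaa_i)``; the dose still
    needed to reach the target is split evenly over the remaining cycles and
    converted to activity through the most recent measured kidney AD/AA,
    then capped. Before the first cycle (empty histories) the standardized
    first-cycle activity is returned.
    """
    if len(kidney_adaa_history) != len(aa_history):
        raise ValueError("kidney_adaa_history and aa_history must have equal length")
    n_done = len(aa_history)
    if n_done == 0:
        return first_aa_gbq
    if n_done >= n_total_cycles:
        raise ValueError("all cycles already delivered")
    adaa = np.asarray(kidney_adaa_history, dtype=float)
    aa = np.asarray(aa_history, dtype=float)
    if np.any(adaa <= 0):
        raise ValueError("kidney AD/AA values must be positive")
    if np.any(aa <= 0):
        raise ValueError("administered activities must be positive")
    delivered = float(adaa @ aa)
    remaining_ad = max(0.0, kidney_target_gy - delivered)
    per_cycle_ad = remaining_ad / (n_total_cycles - n_done)
    return min(cap_gbq, per_cycle_ad / float(adaa[-1]))
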