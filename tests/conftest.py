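"""Shared fixtures.

The default-calibration 2000-patient cohort (generated, curve-fitted and
summarized once per session) backs the cohort-scale calibration and
unbiasedness checks; everything else builds its own small inputs.
"""

from __future__ import annotations

import numpy as np
import pytest

from rptdose.cohort import CohortConfig, cohort_to_frame, generate_cohort
from rptdose.pipeline import fit_cohort_frame, summarize_cohort

CALIBRATION_SEED = 123


@pytest.fixture(scope="session")
def cohort_2000():
    """Default-configuration 2000-patient cohort run through the fit pipeline."""
    cfg = CohortConfig(n_patients=2000, seed=CALIBRATION_SEED)
    patients = generate_cohort(cfg)
    fits = fit_cohort_frame(cohort_to_frame(patients))
    summaries, excluded = summarize_cohort(fits)
    assert not excluded
    return {"config": cfg, "patients": patients, "fits": fits, "summaries": summaries}


@pytest.fixture()
def rng():
    return np.random.default_rng(987)
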