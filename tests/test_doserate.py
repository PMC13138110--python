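"""Constrained biexponential fit and dose integration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.optimize import minimize

from rptdose.doserate import (
    LAMBDA_PHYS,
    LU177_HALFLIFE_H,
    BiexpParams,
    TimedDoseRate,
    biexp_doserate,
    fit_biexponential,
    half_times,
    integrate_dose,
)

TIMES = (4.0, 24.0, 72.0)


def noise_free_samples(ad_gy, washout_h, uptake_h, times=TIMES):
    p = BiexpParams.from_halftimes(ad_gy, washout_h, uptake_h)
    return p, [TimedDoseRate(t, float(biexp_doserate(t, p))) for t in times]


@pytest.mark.parametrize(
    "ad_gy,washout_h,uptake_h",
    [(100.0, 79.5, 6.0), (30.0, 47.2, 6.0), (5.0, 120.0, 12.0), (250.0, 60.0, 2.0)],
)
def test_noise_free_three_point_recovery(ad_gy, washout_h, uptake_h):
    """Three noise-free samples determine the three parameters exactly."""
    truth, samples = noise_free_samples(ad_gy, washout_h, uptake_h)
    fit = fit_biexponential(samples)
    assert fit.A == pytest.approx(truth.A, rel=1e-6)
    assert fit.lambda1 == pytest.approx(truth.lambda1, rel=1e-6)
    assert fit.lambda2 == pytest.approx(truth.lambda2, rel=1e-6)
    assert fit.ad_gy == pytest.approx(ad_gy, rel=1e-6)
    assert not fit.clamped


def test_slow_washout_clamps_to_physical_decay():
    """Data decaying slower than Lu-177 physical decay hit the 159.5-h bound."""
    _, samples = noise_free_samples(100.0, 250.0, 6.0)
    fit = fit_biexponential(samples)
    assert fit.clamped
    assert half_times(fit)[0] == pytest.approx(LU177_HALFLIFE_H, abs=1e-12)


def test_clamp_flag_only_when_bound_violated():
    _, samples = noise_free_samples(100.0, 79.5, 6.0)
    assert not fit_biexponential(samples).clamped


def test_nondecreasing_tail_falls_back_to_clamped():
    """With no washout signal in the tail the fit pins lambda1 at the bound."""
    samples = [TimedDoseRate(4, 0.5), TimedDoseRate(24, 0.8), TimedDoseRate(72, 0.9)]
    fit = fit_biexponential(samples)
    assert fit.clamped
    assert fit.lambda1 == LAMBDA_PHYS


@pytest.mark.parametrize(
    "samples,err",
    [
        ([TimedDoseRate(4, 1.0), TimedDoseRate(24, 0.5)], "3 samples"),
        ([TimedDoseRate(4, 1.0), TimedDoseRate(4, 0.9), TimedDoseRate(24, 0.5)], "3 samples"),
    ],
)
def test_input_errors(samples, err):
    with pytest.raises(ValueError, match=err):
        fit_biexponential(samples)


def test_zero_doserate_rejected():
    samples = [TimedDoseRate(4, 1.0), TimedDoseRate(24, 0.0), TimedDoseRate(72, 0.1)]
    with pytest.raises(ValueError, match="positive"):
        fit_biexponential(samples)


def test_scale_equivariance():
    """Scaling all dose rates by c scales A and AD by c and leaves rates alone."""
    _, samples = noise_free_samples(80.0, 70.0, 5.0)
    rng = np.random.default_rng(5)
    noisy = [
        TimedDoseRate(s.time_h, s.doserate * float(np.exp(0.1 * rng.standard_normal())))
        for s in samples
    ]
    base = fit_biexponential(noisy)
    scaled = fit_biexponential([TimedDoseRate(s.time_h, 3.5 * s.doserate) for s in noisy])
    assert scaled.A == pytest.approx(3.5 * base.A, rel=1e-8)
    assert scaled.ad_gy == pytest.approx(3.5 * base.ad_gy, rel=1e-8)
    assert scaled.lambda1 == pytest.approx(base.lambda1, rel=1e-8)
    assert scaled.lambda2 == pytest.approx(base.lambda2, rel=1e-8)


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    ad=st.floats(1.0, 500.0),
    washout_h=st.floats(10.0, 158.0),
    ratio=st.floats(3.0, 60.0),
)
def test_integral_matches_quadrature(ad, washout_h, ratio):
    """Closed-form AD equals adaptive quadrature of the dose-rate curve."""
    params = BiexpParams.from_halftimes(ad, washout_h, washout_h / ratio)
    upper = 10.0 * washout_h
    body, _ = quad(lambda t: biexp_doserate(t, params), 0.0, upper, limit=200)
    # analytic tail beyond the quadrature window
    tail = params.A * (
        np.exp(-params.lambda1 * upper) / params.lambda1
        - np.exp(-params.lambda2 * upper) / params.lambda2
    )
    assert integrate_dose(params) == pytest.approx(body + tail, rel=1e-6)


def test_integral_instantaneous_uptake_limit():
    p = BiexpParams(A=2.0, lambda1=0.01, lambda2=1e6)
    assert integrate_dose(p) == pytest.approx(2.0 / 0.01, rel=1e-4)


def test_half_times_arithmetic():
    p = BiexpParams(A=1.0, lambda1=2.0 * LAMBDA_PHYS, lambda2=0.2)
    wash, up = half_times(p)
    assert wash == pytest.approx(LU177_HALFLIFE_H / 2.0, rel=1e-12)
    assert up == pytest.approx(np.log(2) / 0.2, rel=1e-12)


def grid_search_oracle(times, rates):
    """Brute-force SSE minimizer honoring the washout bound: dense
    (lambda1, lambda2) grid with profiled amplitude, then Nelder-Mead
    refinement with lambda1 = lambda_phys + exp(x). Independent of the fit
    path."""
    t = np.asarray(times)
    d = np.asarray(rates)

    def sse_of(lam1, lam2):
        s = np.exp(-lam1 * t) - np.exp(-lam2 * t)
        a = max(float(s @ d) / float(s @ s), 0.0)
        return float(np.sum((a * s - d) ** 2))

    best = (np.inf, None)
    for lam1 in np.concatenate(([LAMBDA_PHYS], np.geomspace(LAMBDA_PHYS * 1.0001, 0.5, 120))):
        for mult in np.geomspace(1.01, 500, 120):
            v = sse_of(lam1, lam1 * mult)
            if v < best[0]:
                best = (v, (lam1, lam1 * mult))
    lam1, lam2 = best[1]
    res = minimize(
        lambda x: sse_of(LAMBDA_PHYS + np.exp(x[0]), LAMBDA_PHYS + np.exp(x[0]) + np.exp(x[1])),
        [np.log(max(lam1 - LAMBDA_PHYS, 1e-9)), np.log(lam2 - lam1)],
        method="Nelder-Mead",
        options={"xatol": 1e-12, "fatol": 1e-14, "maxiter": 5000},
    )
    return float(min(best[0], res.fun))


def test_fit_matches_grid_search_oracle():
    """Six noisy samples: fit SSE agrees with a dense grid-search oracle."""
    truth = BiexpParams.from_halftimes(60.0, 85.0, 7.0)
    times = [2.0, 4.0, 12.0, 24.0, 48.0, 72.0]
    rng = np.random.default_rng(11)
    rates = [
        float(biexp_doserate(t, truth)) * float(np.exp(0.1 * rng.standard_normal()))
        for t in times
    ]
    fit = fit_biexponential([TimedDoseRate(t, r) for t, r in zip(times, rates)])
    oracle_sse = grid_search_oracle(times, rates)
    assert fit.residual_sse <= oracle_sse * (1.0 + 1e-6)


def test_cohort_scale_dose_unbiasedness(cohort_2000):
    """Median fitted lesion AD tracks the median true AD within 3% at n=2000."""
    fits = cohort_2000["fits"]
    true_ads = [
        sc.true_ad_gy
        for p in cohort_2000["patients"]
        for les in p.lesions
        for sc in les.cycles
    ]
    fitted = fits.loc[fits.structure_type == "tumor", "ad_gy"].to_numpy()
    assert np.median(fitted) == pytest.approx(np.median(true_ads), rel=0.03)


def test_all_fits_clamped_when_truth_exceeds_bound():
    """Synthetic curves with washout slower than 159.5 h always clamp."""
    rng = np.random.default_rng(3)
    for _ in range(25):
        washout = rng.uniform(170.0, 400.0)
        truth = BiexpParams.from_halftimes(rng.uniform(5, 200), washout, rng.uniform(2, 12))
        samples = [TimedDoseRate(t, float(biexp_doserate(t, truth))) for t in TIMES]
        fit = fit_biexponential(samples)
        assert fit.clamped
        assert fit.lambda1 == LAMBDA_PHYS
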