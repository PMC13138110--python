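"""Constrained biexponential absorbed-dose-rate model.

The per-cycle absorbed-dose-rate curve of a structure (tumor or kidney) after
a Lu-177 administration is modelled as

    Ddot(t) = A * (exp(-lambda1 * t) - exp(-lambda2 * t)),    t in hours,

where ``lambda1`` is the effective washout rate (slow component) and
``lambda2`` the uptake rate (fast component), with ``lambda2 > lambda1``.
Because the effective clearance of the radiopharmaceutical includes physical
decay, the washout half-time cannot exceed the Lu-177 physical half-life of
159.5 h; the fit enforces ``lambda1 >= ln2 / 159.5``.

The total absorbed dose of the cycle is the closed-form time integral

    AD = A * (1/lambda1 - 1/lambda2)   [Gy].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.optimize import least_squares

__all__ = [
    "LU177_HALFLIFE_H",
    "LAMBDA_PHYS",
    "TimedDoseRate",
    "BiexpParams",
    "FitError",
    "biexp_doserate",
    "fit_biexponential",
    "integrate_dose",
    "half_times",
]

#: Physical half-life of Lu-177 in hours.
LU177_HALFLIFE_H = 159.5
#: Physical decay constant of Lu-177 (1/h); lower bound for the washout rate.
LAMBDA_PHYS = float(np.log(2.0) / LU177_HALFLIFE_H)


class FitError(RuntimeError):
    """Raised when the dose-rate curve fit fails to converge."""


@dataclass(frozen=True)
class TimedDoseRate:
    """One measured absorbed-dose-rate sample.

    Attributes
    ----------
    time_h : float
        Time post-injection in hours (> 0).
    doserate : float
        Absorbed-dose rate in Gy/h (>= 0).
    """

    time_h: float
    doserate: float

    def __post_init__(self) -> None:
        if self.time_h <= 0:
            raise ValueError(f"time_h must be positive, got {self.time_h}")
        if self.doserate < 0:
            raise ValueError(f"doserate must be non-negative, got {self.doserate}")


@dataclass
class BiexpParams:
    """Fitted parameters of the biexponential dose-rate model.

    ``ad_gy`` is the closed-form time-integrated dose, ``clamped`` indicates
    that the unconstrained optimum violated the physical-decay bound on the
    washout rate and lambda1 was fixed at ln2/159.5, and ``residual_sse`` is
    the sum of squared residuals in (Gy/h)^2.
    """

    A: float
    lambda1: float
    lambda2: float
    ad_gy: float = field(default=0.0)
    clamped: bool = False
    residual_sse: float = 0.0

    def __post_init__(self) -> None:
        if self.A <= 0:
            raise ValueError(f"amplitude A must be positive, got {self.A}")
        if not self.lambda2 > self.lambda1 > 0:
            raise ValueError(
                f"rates must satisfy lambda2 > lambda1 > 0, got "
                f"lambda1={self.lambda1}, lambda2={self.lambda2}"
            )
        if self.ad_gy == 0.0:
            self.ad_gy = integrate_dose(self)

    @classmethod
    def from_halftimes(
        cls, ad_gy: float, washout_halftime_h: float, uptake_halftime_h: float
    ) -> "BiexpParams":
        """Construct parameters from a target dose and the two half-times."""
        lam1 = np.log(2.0) / washout_halftime_h
        lam2 = np.log(2.0) / uptake_halftime_h
        amplitude = ad_gy / (1.0 / lam1 - 1.0 / lam2)
        return cls(A=amplitude, lambda1=lam1, lambda2=lam2, ad_gy=ad_gy)


def biexp_doserate(t_h: np.ndarray | float, params: BiexpParams) -> np.ndarray | float:
    """Evaluate the model dose rate (Gy/h) at time(s) ``t_h`` (hours)."""
    t = np.asarray(t_h, dtype=float)
    out = params.A * (np.exp(-params.lambda1 * t) - np.exp(-params.lambda2 * t))
    return out if out.ndim else float(out)


def integrate_dose(params: BiexpParams) -> float:
    """Closed-form integral of the dose-rate curve over [0, inf), in Gy."""
    if params.lambda2 <= params.lambda1:
        raise ValueError("lambda2 must exceed lambda1")
    return params.A * (1.0 / params.lambda1 - 1.0 / params.lambda2)


def half_times(params: BiexpParams) -> tuple[float, float]:
    """Return (washout half-time, uptake half-time) in hours."""
    ln2 = np.log(2.0)
    return float(ln2 / params.lambda1), float(ln2 / params.lambda2)


def _shape(t: np.ndarray, lam1: float, lam2: float) -> np.ndarray:
    return np.exp(-lam1 * t) - np.exp(-lam2 * t)


def _profiled_amplitude(t: np.ndarray, d: np.ndarray, lam1: float, lam2: float) -> float:
    # A enters linearly; for fixed rates the least-squares amplitude is the
    # projection of the data onto the shape vector.
    s = _shape(t, lam1, lam2)
    denom = float(s @ s)
    if denom <= 0.0:
        return 0.0
    return float(s @ d) / denom


def _residuals_free(x: np.ndarray, t: np.ndarray, d: np.ndarray) -> np.ndarray:
    # x = (log lambda1, log(lambda2/lambda1 - 1)); amplitude profiled out.
    # exponents clipped to keep exploratory optimizer steps finite
    lam1 = np.exp(np.clip(x[0], -50.0, 50.0))
    lam2 = lam1 * (1.0 + np.exp(np.clip(x[1], -50.0, 50.0)))
    amp = _profiled_amplitude(t, d, lam1, lam2)
    return amp * _shape(t, lam1, lam2) - d


def _residuals_clamped(x: np.ndarray, t: np.ndarray, d: np.ndarray) -> np.ndarray:
    # lambda1 fixed at the physical decay constant; x = (log(lambda2/lambda1 - 1),).
    lam2 = LAMBDA_PHYS * (1.0 + np.exp(np.clip(x[0], -50.0, 50.0)))
    amp = _profiled_amplitude(t, d, LAMBDA_PHYS, lam2)
    return amp * _shape(t, LAMBDA_PHYS, lam2) - d


def _init_lambda1(t: np.ndarray, d: np.ndarray) -> float:
    """Washout-rate guess from the log-linear slope of the last two samples.

    A non-decreasing tail (curve still rising at the last sample, or no
    washout signal at all) carries no slope information; start from twice the
    physical decay constant instead.
    """
    if d[-1] >= d[-2]:
        return 2.0 * LAMBDA_PHYS
    slope = (np.log(d[-2]) - np.log(d[-1])) / (t[-1] - t[-2])
    return float(np.clip(slope, 1e-5, 10.0))


_LSQ_KW = dict(method="lm", xtol=1e-15, ftol=1e-15, gtol=1e-15, max_nfev=2000)


def fit_biexponential(
    samples: Sequence[TimedDoseRate], n_starts: int = 3
) -> BiexpParams:
    """Fit the constrained biexponential model to dose-rate samples.

    A fully unconstrained least-squares fit (amplitude profiled out
    analytically, rates optimized in log space with the ordering
    ``lambda2 > lambda1`` built into the parameterization) is run first from
    ``n_starts`` uptake/washout rate-ratio starting points. If its washout
    rate is slower than Lu-177 physical decay, the fit is redone with
    ``lambda1`` fixed at ln2/159.5 h and the result flagged ``clamped``.

    Parameters
    ----------
    samples : sequence of TimedDoseRate
        At least three samples at distinct positive times, all with strictly
        positive dose rates.
    n_starts : int
        Number of uptake-rate starting ratios for the multistart.

    Raises
    ------
    ValueError
        Fewer than three distinct-time samples, or non-positive dose rates.
    FitError
        Optimizer failure.
    """
    pts = sorted(samples, key=lambda s: s.time_h)
    t = np.array([s.time_h for s in pts], dtype=float)
    d = np.array([s.doserate for s in pts], dtype=float)
    if len(np.unique(t)) < 3:
        raise ValueError("need at least 3 samples at distinct times")
    if np.any(d <= 0):
        raise ValueError("all dose rates must be strictly positive for fitting")

    lam1_init = _init_lambda1(t, d)
    ratios = np.geomspace(3.0, 40.0, n_starts)
    best = None
    for ratio in ratios:
        x0 = np.array([np.log(lam1_init), np.log(ratio - 1.0)])
        try:
            res = least_squares(_residuals_free, x0, args=(t, d), **_LSQ_KW)
        except Exception:  # singular Jacobian at a bad start
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        # free fit intractable; the bound-constrained model is better posed
        return _fit_clamped(t, d, n_starts)

    lam1 = float(np.exp(np.clip(best.x[0], -50.0, 50.0)))
    lam2 = lam1 * (1.0 + float(np.exp(np.clip(best.x[1], -50.0, 50.0))))
    if lam1 < LAMBDA_PHYS:
        return _fit_clamped(t, d, n_starts)

    amp = _profiled_amplitude(t, d, lam1, lam2)
    if amp <= 0:
        raise FitError("fit produced a non-positive amplitude")
    sse = float(np.sum((amp * _shape(t, lam1, lam2) - d) ** 2))
    return BiexpParams(A=amp, lambda1=lam1, lambda2=lam2, clamped=False, residual_sse=sse)


def _fit_clamped(t: np.ndarray, d: np.ndarray, n_starts: int) -> BiexpParams:
    best = None
    for ratio in np.geomspace(3.0, 40.0, n_starts):
        x0 = np.array([np.log(ratio - 1.0)])
        try:
            res = least_squares(_residuals_clamped, x0, args=(t, d), **_LSQ_KW)
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError("clamped biexponential fit did not converge")
    lam2 = LAMBDA_PHYS * (1.0 + float(np.exp(np.clip(best.x[0], -50.0, 50.0))))
    amp = _profiled_amplitude(t, d, LAMBDA_PHYS, lam2)
    if amp <= 0:
        raise FitError("clamped fit produced a non-positive amplitude")
    sse = float(np.sum((amp * _shape(t, LAMBDA_PHYS, lam2) - d) ** 2))
    return BiexpParams(
        A=amp, lambda1=LAMBDA_PHYS, lambda2=lam2, clamped=True, residual_sse=sse
    )
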