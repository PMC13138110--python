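"""Dose-response models and response-classification statistics.

Implements the cohort-level dose-response analyses run on the patient
summaries: sorting patients by a dose metric and binning them into
consecutive groups of 11, fitting a three-parameter sigmoid

    P_PR(cAD) = Pmax / (1 + exp(-(cAD - Dhalf) / k))

to the per-group (median metric, % partial response) points with R^2 and
RMSE goodness-of-fit, an unpenalized two-feature logistic regression on
(cAD, dAD/AA), an RBF-kernel support-vector classifier on the same features,
stratified cross-validated ROC/AUC, and the rank statistics used for the
cohort comparisons (Wilcoxon signed-rank, rank-sum, Spearman).

Proportions are handled in percent (0-100) throughout the sigmoid fit so
that Pmax is bounded between 0% and 100%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import statsmodels.api as sm
from scipy import stats
from scipy.optimize import least_squares
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline, make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

__all__ = [
    "GroupBin",
    "SigmoidModel",
    "FitQuality",
    "LogisticModel",
    "ClassifierEval",
    "sigmoid_probability",
    "group_patients",
    "fit_sigmoid",
    "fit_quality",
    "fit_logistic_2d",
    "fit_svm_rbf",
    "make_logistic_estimator",
    "make_svm_estimator",
    "crossval_auc",
    "mann_whitney_auc",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "spearman",
]

DEFAULT_GROUP_SIZE = 11


@dataclass(frozen=True)
class GroupBin:
    """One bin of consecutively ranked patients."""

    member_indices: tuple[int, ...]
    median_metric: float
    proportion_pr: float  # fraction in [0, 1]

    @property
    def n(self) -> int:
        return len(self.member_indices)

    @property
    def pct_pr(self) -> float:
        return 100.0 * self.proportion_pr


@dataclass(frozen=True)
class SigmoidModel:
    """Parameters of the sigmoid dose-response curve (percent scale)."""

    pmax: float  # % in [0, 100]
    dhalf: float  # Gy
    k: float  # Gy, > 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.pmax <= 100.0:
            raise ValueError(f"pmax must be in [0, 100], got {self.pmax}")
        if self.k <= 0:
            raise ValueError(f"k must be positive, got {self.k}")

    def predict(self, cad: np.ndarray | float) -> np.ndarray | float:
        """Probability of PR in percent at cumulative dose ``cad`` (Gy)."""
        return sigmoid_probability(cad, self.pmax, self.dhalf, self.k)


@dataclass(frozen=True)
class FitQuality:
    """Goodness-of-fit of a grouped dose-response curve."""

    r_squared: float  # nan when the observed values have zero variance
    rmse: float  # same (percent) units as the proportions
    n_groups: int

    @property
    def r2_defined(self) -> bool:
        return not np.isnan(self.r_squared)


@dataclass(frozen=True)
class LogisticModel:
    """Unpenalized two-feature logistic regression on (cAD, dAD/AA)."""

    beta0: float
    beta1: float  # per Gy
    beta2: float  # per %
    converged: bool = True
    separation_flag: bool = False

    def predict_proba(self, cad: np.ndarray, delta_adaa: np.ndarray) -> np.ndarray:
        z = self.beta0 + self.beta1 * np.asarray(cad) + self.beta2 * np.asarray(delta_adaa)
        return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ClassifierEval:
    """Cross-validated classifier evaluation."""

    auc: float  # pooled out-of-fold AUC
    per_fold_auc: list[float]
    scores: np.ndarray  # out-of-fold decision scores, original order
    fold_assignment: np.ndarray  # fold index per sample
    roc_fpr: np.ndarray
    roc_tpr: np.ndarray
    seed: int = 0


def sigmoid_probability(
    cad: np.ndarray | float, pmax: float, dhalf: float, k: float
) -> np.ndarray | float:
    """Sigmoid response probability in percent (0-100)."""
    c = np.asarray(cad, dtype=float)
    out = pmax / (1.0 + np.exp(-(c - dhalf) / k))
    return out if out.ndim else float(out)


def group_patients(
    values: Sequence[float],
    responder: Sequence[bool],
    group_size: int = DEFAULT_GROUP_SIZE,
) -> list[GroupBin]:
    """Sort patients by a dose metric and bin them into consecutive groups.

    Patients are sorted ascending by ``values`` (ties broken by original
    order) and assigned to consecutive groups of ``group_size``, the final
    group holding the remainder. Each bin records the within-group median of
    the metric and the proportion of responders.
    """
    vals = np.asarray(values, dtype=float)
    resp = np.asarray(responder, dtype=bool)
    n = vals.size
    if n < group_size:
        raise ValueError(f"need at least {group_size} patients, got {n}")
    order = np.argsort(vals, kind="stable")
    bins: list[GroupBin] = []
    for start in range(0, n, group_size):
        idx = order[start : start + group_size]
        bins.append(
            GroupBin(
                member_indices=tuple(int(i) for i in idx),
                median_metric=float(np.median(vals[idx])),
                proportion_pr=float(np.mean(resp[idx])),
            )
        )
    return bins


def fit_quality(
    observed_pct: Sequence[float], predicted_pct: Sequence[float]
) -> FitQuality:
    """R^2 and RMSE of predicted vs observed group response percentages.

    R^2 = 1 - SS_res / SS_tot and RMSE = sqrt(mean squared error), both on
    the percent scale of the inputs. When the observed values have zero
    variance R^2 is undefined and returned as NaN.
    """
    obs = np.asarray(observed_pct, dtype=float)
    pred = np.asarray(predicted_pct, dtype=float)
    if obs.shape != pred.shape or obs.size < 2:
        raise ValueError("observed and predicted must have equal length >= 2")
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    rmse = float(np.sqrt(ss_res / obs.size))
    return FitQuality(r_squared=r2, rmse=rmse, n_groups=int(obs.size))


def _sigmoid_residuals(x: np.ndarray, cad: np.ndarray, pct: np.ndarray) -> np.ndarray:
    pmax, dhalf, log_k = x
    return pmax / (1.0 + np.exp(-(cad - dhalf) / np.exp(log_k))) - pct


def fit_sigmoid(groups: Sequence[GroupBin]) -> tuple[SigmoidModel, FitQuality]:
    """Least-squares fit of the sigmoid to grouped (median cAD, % PR) points.

    All groups are weighted equally, including a smaller remainder group.
    Pmax is constrained to [0, 100]; k > 0 is enforced by optimizing log k.
    A small multistart over steepness guards against the fit landing in a
    flat region of the loss.
    """
    if len(groups) < 3:
        raise ValueError("need at least 3 groups to fit the sigmoid")
    cad = np.array([g.median_metric for g in groups], dtype=float)
    pct = np.array([g.pct_pr for g in groups], dtype=float)

    span = float(cad.max() - cad.min())
    if span <= 0:
        raise ValueError("group medians are all identical; cannot fit")
    pmax0 = min(100.0, max(pct.max(), 1.0))
    # Dhalf start: metric value where the response crosses half its maximum.
    half = pmax0 / 2.0
    crossing = cad[np.argmin(np.abs(pct - half))]
    best = None
    for k0 in (span / 10.0, span / 4.0, span):
        x0 = np.array([pmax0, crossing, np.log(k0)])
        res = least_squares(
            _sigmoid_residuals,
            x0,
            args=(cad, pct),
            bounds=([0.0, -np.inf, -np.inf], [100.0, np.inf, np.inf]),
            xtol=1e-15,
            ftol=1e-15,
            gtol=1e-15,
            max_nfev=5000,
        )
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise RuntimeError("sigmoid fit did not converge")
    model = SigmoidModel(pmax=float(best.x[0]), dhalf=float(best.x[1]), k=float(np.exp(best.x[2])))
    quality = fit_quality(pct, np.asarray(model.predict(cad)))
    return model, quality


def fit_logistic_2d(
    cad_values: Sequence[float],
    delta_adaa_values: Sequence[float],
    responder_labels: Sequence[bool],
) -> LogisticModel:
    """Maximum-likelihood two-feature logistic regression (no penalty).

    Complete or quasi-complete separation is flagged rather than raised; the
    returned coefficients are then the (diverging) values at which the
    optimizer stopped and should be treated as directions, not magnitudes.
    """
    y = np.asarray(responder_labels, dtype=float)
    if y.min() == y.max():
        raise ValueError("both responder classes must be present")
    X = sm.add_constant(
        np.column_stack(
            [np.asarray(cad_values, float), np.asarray(delta_adaa_values, float)]
        )
    )
    if not np.all(np.isfinite(X)):
        raise ValueError("features must be finite")
    model = sm.Logit(y, X)
    separation = False
    try:
        fit = model.fit(disp=False, maxiter=200)
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        # Perfect separation makes the MLE diverge; retry with a gradient
        # method and a bounded number of iterations, and flag the result.
        fit = model.fit(
            disp=False, method="bfgs", maxiter=100, skip_hessian=True,
            warn_convergence=False,
        )
        converged = False
        separation = True
    params = np.asarray(fit.params, dtype=float)
    fitted_p = 1.0 / (1.0 + np.exp(-(X @ params)))
    if np.all((fitted_p > 0.999) == (y == 1)) and np.all((fitted_p < 0.001) == (y == 0)):
        separation = True
    return LogisticModel(
        beta0=float(params[0]),
        beta1=float(params[1]),
        beta2=float(params[2]),
        converged=converged,
        separation_flag=separation,
    )


def fit_svm_rbf(
    features: np.ndarray,
    labels: Sequence[bool],
    c_param: float = 1.0,
    gamma: float | str = "scale",
) -> Pipeline:
    """Fit an RBF-kernel SVM on internally standardized features.

    Returns a fitted pipeline whose ``decision_function`` gives margin
    scores with the convention higher = more responder-like.
    """
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if min(np.bincount(y)) < 1:
        raise ValueError("degenerate class")
    pipe = make_pipeline(StandardScaler(), SVC(kernel="rbf", C=c_param, gamma=gamma))
    pipe.fit(np.asarray(features, dtype=float), y)
    return pipe


def make_logistic_estimator() -> Callable[[], object]:
    """Estimator factory for cross-validation: unpenalized logistic model."""

    class _Logistic:
        def fit(self, X: np.ndarray, y: np.ndarray) -> "_Logistic":
            self.model_ = fit_logistic_2d(X[:, 0], X[:, 1], y.astype(bool))
            return self

        def decision_function(self, X: np.ndarray) -> np.ndarray:
            m = self.model_
            return m.beta0 + m.beta1 * X[:, 0] + m.beta2 * X[:, 1]

    return _Logistic


def make_svm_estimator(c_param: float = 1.0, gamma: float | str = "scale"):
    """Estimator factory for cross-validation: standardized RBF SVM."""

    def factory() -> Pipeline:
        return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=c_param, gamma=gamma))

    return factory


def mann_whitney_auc(scores: Sequence[float], labels: Sequence[bool]) -> float:
    """AUC by the rank (Mann-Whitney U) formulation with tie correction.

    Equals the probability that a randomly chosen positive outscores a
    randomly chosen negative, counting ties as 1/2.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute AUC")
    ranks = stats.rankdata(s)  # average ranks handle ties
    u = float(ranks[y].sum()) - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def crossval_auc(
    estimator_factory: Callable[[], object],
    features: np.ndarray,
    labels: Sequence[bool],
    n_folds: int = 5,
    seed: int = 0,
) -> ClassifierEval:
    """Stratified k-fold cross-validated ROC/AUC from pooled out-of-fold scores.

    Folds are class-stratified ("balanced groups") and seeded. Each fold's
    model is fit on the training split; its decision scores on the held-out
    split are pooled and the AUC computed by the rank formulation. Per-fold
    AUCs are also reported.
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=bool)
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < n_folds:
        raise ValueError(
            f"each class needs at least {n_folds} members for {n_folds}-fold "
            f"stratification, got counts {counts.tolist()}"
        )
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.empty(len(y), dtype=float)
    fold_assignment = np.empty(len(y), dtype=int)
    per_fold = []
    for fold, (train, test) in enumerate(skf.split(X, y)):
        est = estimator_factory()
        est.fit(X[train], y[train].astype(int))
        if hasattr(est, "decision_function"):
            s = np.asarray(est.decision_function(X[test]), dtype=float)
        else:
            s = np.asarray(est.predict_proba(X[test])[:, 1], dtype=float)
        scores[test] = s
        fold_assignment[test] = fold
        per_fold.append(mann_whitney_auc(s, y[test]))
    auc = mann_whitney_auc(scores, y)
    fpr, tpr, _ = roc_curve(y.astype(int), scores)
    return ClassifierEval(
        auc=float(auc),
        per_fold_auc=[float(a) for a in per_fold],
        scores=scores,
        fold_assignment=fold_assignment,
        roc_fpr=fpr,
        roc_tpr=tpr,
        seed=seed,
    )


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, bool]:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    Returns (statistic, p_value, all_zero_flag); when every paired
    difference is zero the test is undefined and (nan, 1.0, True) is
    returned.
    """
    diffs = np.asarray(x, dtype=float) - np.asarray(y, dtype=float)
    if np.all(diffs == 0):
        return float("nan"), 1.0, True
    res = stats.wilcoxon(diffs, alternative="two-sided")
    return float(res.statistic), float(res.pvalue), False


def wilcoxon_rank_sum(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test for independent samples."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided")
    return float(res.statistic), float(res.pvalue)


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank-order correlation with two-sided p-value."""
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)
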