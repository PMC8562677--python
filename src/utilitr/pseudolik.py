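"""Maximum pseudo-likelihood estimation with a fixed utility weight.

The model treats the clinician's choice as a noisy signal of patient
utility: each subject is assigned the utility-optimal treatment with
probability expit(x'beta).  Replacing the unknown optimal rule by its
plug-in estimate under a candidate weight omega yields the log
pseudo-likelihood

    l_n(omega, beta) = sum_i [ c_i(omega) x_i'beta - log(1 + exp(x_i'beta)) ],

where c_i(omega) = 1{A_i = d_hat_omega(X_i)} is the optimality indicator.
l_n is a step function of omega (it changes only when some subject's
estimated optimal treatment flips), so omega is found by profiling beta via
logistic regression at each point of a grid and taking the argmax, ties
broken toward the smallest omega.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import add_intercept, expit, sign_pm1
from .cohorts import CohortData
from .qmodels import FixedUtility, QModel, TreatmentRule


def optimality_indicators(data: CohortData, rule) -> np.ndarray:
    """Binary vector with element i equal to 1{A_i = d(X_i)}."""
    return (data.A == rule.decide(data.X)).astype(float)


def pl_loglik(beta: np.ndarray, indicators: np.ndarray, X: np.ndarray) -> float:
    """Log pseudo-likelihood at beta for given indicators.

    `X` is the behavior design *including* its intercept column.  Uses the
    overflow-safe log(1+exp(s)) = logaddexp(0, s).
    """
    s = X @ np.asarray(beta, dtype=float)
    return float(np.sum(indicators * s - np.logaddexp(0.0, s)))


class IdentifiabilityWarning(UserWarning):
    """The fitted behavior model puts some subjects below coin-toss accuracy."""


@dataclass
class ProfileFit:
    beta: np.ndarray
    loglik: float
    separation: bool = False
    converged: bool = True


def _newton_logistic(y: np.ndarray, X: np.ndarray, ridge: float = 0.0,
                     max_iter: int = 60, tol: float = 1e-10,
                     beta0: np.ndarray | None = None) -> tuple[np.ndarray, bool]:
    """Newton/IRLS for the logistic MLE, optionally ridge-penalized.

    Hand-written because the profile step runs inside grid/Metropolis loops
    (order 1e5 fits per experiment); validated against statsmodels Logit in
    the test suite.  `beta0` warm-starts the iteration (the concave
    objective has a unique optimum, so the start affects speed only).
    """
    n, k = X.shape
    beta = np.zeros(k) if beta0 is None else np.array(beta0, dtype=float)
    pen = ridge * np.eye(k)
    ll = pl_loglik(beta, y, X) - 0.5 * ridge * beta @ beta
    for _ in range(max_iter):
        p = expit(X @ beta)
        grad = X.T @ (y - p) - ridge * beta
        wdiag = np.maximum(p * (1.0 - p), 1e-12)
        H = (X * wdiag[:, None]).T @ X + pen
        try:
            step = np.linalg.solve(H, grad)
        except np.linalg.LinAlgError:
            return beta, False
        # backtracking line search on the (penalized) log-likelihood
        t = 1.0
        for _ in range(30):
            cand = beta + t * step
            ll_new = pl_loglik(cand, y, X) - 0.5 * ridge * cand @ cand
            if ll_new >= ll - 1e-12:
                break
            t *= 0.5
        beta, gain, ll = cand, ll_new - ll, ll_new
        if abs(gain) < tol and np.max(np.abs(grad)) < 1e-6 * (1 + np.max(np.abs(beta))):
            return beta, True
        if abs(gain) < tol:
            # flat likelihood: either converged or drifting to infinity
            return beta, bool(np.max(np.abs(grad)) < 1e-4)
    return beta, False


def profile_beta(indicators: np.ndarray, X: np.ndarray,
                 beta0: np.ndarray | None = None) -> ProfileFit:
    """Profiled logistic MLE beta_hat = argmax_beta l_n(omega, beta).

    `X` must include the intercept column.  Complete separation or
    all-constant indicators trigger a ridge-stabilized refit with penalty
    1e-4 * n * ||beta||^2 and set the separation flag; the reported log
    pseudo-likelihood is the unpenalized value at the returned beta.
    """
    y = np.asarray(indicators, dtype=float).ravel()
    n = X.shape[0]
    degenerate = y.min() == y.max()
    if not degenerate:
        beta, ok = _newton_logistic(y, X, beta0=beta0)
        # coefficients this large on a bounded design mean the MLE is
        # drifting to infinity (complete or quasi-complete separation)
        if ok and np.max(np.abs(beta)) < 1e2:
            return ProfileFit(beta=beta, loglik=pl_loglik(beta, y, X))
    beta, ok = _newton_logistic(y, X, ridge=1e-4 * n)
    return ProfileFit(beta=beta, loglik=pl_loglik(beta, y, X),
                      separation=True, converged=ok)


@dataclass
class PLFixedFit:
    """Result of the fixed-utility grid search.

    The trace covers the entire grid; `omega` is the smallest grid point
    attaining the maximum profiled log pseudo-likelihood.
    """

    omega: float
    beta: np.ndarray
    loglik: float
    grid: np.ndarray
    loglik_grid: np.ndarray
    rho: float
    indicators: np.ndarray = field(repr=False)
    separation: bool = False
    behavior: str = "constant"
    betas_grid: np.ndarray | None = field(default=None, repr=False)

    @property
    def optimal_fraction(self) -> float:
        """Fraction of subjects whose observed treatment matches the fitted rule."""
        return float(np.mean(self.indicators))


def default_grid(step: float = 0.01) -> np.ndarray:
    m = int(round(1.0 / step))
    return np.linspace(0.0, 1.0, m + 1)


def behavior_design(data: CohortData, behavior: str) -> np.ndarray:
    """Design matrix for the behavior model: intercept-only or (1, X)."""
    if behavior == "constant":
        return np.ones((data.n, 1))
    if behavior == "covariate":
        return add_intercept(data.X)
    raise ValueError(f"behavior must be 'constant' or 'covariate', got {behavior!r}")


def grid_search_omega(data: CohortData, q_y: QModel, q_z: QModel,
                      grid: np.ndarray | None = None,
                      behavior: str = "constant") -> PLFixedFit:
    """Algorithmic core of the fixed-utility estimator.

    For each omega on the grid, form the plug-in rule from the (fixed,
    pre-fitted) Q-models, compute optimality indicators, profile beta by
    logistic regression, and keep the grid point with the largest profiled
    log pseudo-likelihood.
    """
    grid = default_grid() if grid is None else np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("omega grid must be nonempty")
    if grid.min() < 0 or grid.max() > 1:
        raise ValueError("omega grid must lie in [0, 1]")
    Xb = behavior_design(data, behavior)
    ry = q_y.contrast(data.X)
    rz = q_z.contrast(data.X)
    logliks = np.empty(grid.size)
    betas = np.empty((grid.size, Xb.shape[1]))
    seps = np.zeros(grid.size, dtype=bool)
    for j, w in enumerate(grid):
        ind = (data.A == sign_pm1(w * ry + (1.0 - w) * rz)).astype(float)
        prof = profile_beta(ind, Xb)
        logliks[j] = prof.loglik
        betas[j] = prof.beta
        seps[j] = prof.separation
    j_best = int(np.argmax(logliks))  # first max -> smallest omega tie-break
    w_hat = float(grid[j_best])
    beta_hat = betas[j_best]
    ind_best = (data.A == sign_pm1(w_hat * ry + (1.0 - w_hat) * rz)).astype(float)
    if behavior == "constant":
        rho = float(expit(beta_hat[0]))
    else:
        rho = float(np.mean(expit(Xb @ beta_hat)))
    return PLFixedFit(omega=w_hat, beta=beta_hat, loglik=float(logliks[j_best]),
                      grid=grid, loglik_grid=logliks, rho=rho,
                      indicators=ind_best, separation=bool(seps[j_best]),
                      behavior=behavior, betas_grid=betas)


def coin_toss_diagnostic(Xb: np.ndarray, beta: np.ndarray,
                         warn: bool = False) -> float:
    """Identifiability diagnostic: clinicians should beat a coin toss.

    Returns the fraction of subjects whose fitted optimal-assignment
    probability expit(x'beta) exceeds 1/2; the model is identified under
    the sufficient condition that this holds almost surely.  With
    ``warn=True`` a fraction below 1 raises an IdentifiabilityWarning.
    """
    frac = float(np.mean(expit(Xb @ beta) > 0.5))
    if warn and frac < 1.0:
        warnings.warn(
            f"fitted optimal-assignment probability exceeds 1/2 for only "
            f"{frac:.1%} of subjects; identifiability relies on clinical "
            f"decisions being better than a coin toss",
            IdentifiabilityWarning, stacklevel=3)
    return frac


def fitted_rule(fit: PLFixedFit, q_y: QModel, q_z: QModel) -> TreatmentRule:
    """The plug-in optimal rule at the estimated omega."""
    return TreatmentRule(FixedUtility(fit.omega), q_y, q_z)
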