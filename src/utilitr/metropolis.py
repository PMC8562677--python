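"""Metropolis profile search for patient-specific utility weights.

With w(x; theta) = expit((1,x)'theta) the profiled log pseudo-likelihood

    L~_n(theta) = max_beta l_n(theta, beta)

is a step function of theta (it changes only when a subject's estimated
optimal treatment flips), so gradient methods are useless and a grid over
theta is infeasible beyond one or two dimensions.  Instead a symmetric
Gaussian random walk is run through theta-space, accepting a proposal
theta* with probability min{1, exp(L~_n(theta*) - L~_n(theta))}, and the
maximum pseudo-likelihood estimator is the visited state with the largest
profiled log pseudo-likelihood.  The chain is a stochastic search device,
not a posterior sampler: no burn-in is discarded and no posterior summaries
are formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import expit, sign_pm1
from .cohorts import CohortData
from .qmodels import LogisticUtility, QModel, TreatmentRule
from .pseudolik import (ProfileFit, behavior_design, coin_toss_diagnostic,
                        profile_beta)


class InitializationError(ValueError):
    """Profiled log pseudo-likelihood is non-finite at the starting point."""


class _ProfileCache:
    """Memoized profiled log pseudo-likelihood over theta.

    The random walk re-evaluates the current state after every rejection,
    so the value (and the profiled beta) is cached keyed by theta's bytes.
    """

    def __init__(self, data: CohortData, q_y: QModel, q_z: QModel, behavior: str):
        self._xi = np.column_stack([np.ones(data.n), data.X])
        self._ry = q_y.contrast(data.X)
        self._rz = q_z.contrast(data.X)
        self._a = data.A
        self._xb = behavior_design(data, behavior)
        self._cache: dict[bytes, ProfileFit] = {}
        self._last_beta: np.ndarray | None = None
        self.n_evals = 0

    def profile(self, theta: np.ndarray) -> ProfileFit:
        key = np.ascontiguousarray(theta).tobytes()
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        self.n_evals += 1
        w = expit(self._xi @ theta)
        ind = (self._a == sign_pm1(w * self._ry + (1.0 - w) * self._rz)).astype(float)
        # warm-start from the previous profile: the chain moves locally, so
        # successive indicator vectors differ in a handful of subjects
        fit = profile_beta(ind, self._xb, beta0=self._last_beta)
        if not fit.separation:
            self._last_beta = fit.beta
        self._cache[key] = fit
        return fit

    def indicators(self, theta: np.ndarray) -> np.ndarray:
        w = expit(self._xi @ theta)
        return (self._a == sign_pm1(w * self._ry + (1.0 - w) * self._rz)).astype(float)


def profile_pl_theta(theta: np.ndarray, data: CohortData, q_y: QModel,
                     q_z: QModel, behavior: str = "covariate") -> float:
    """Profiled log pseudo-likelihood L~_n(theta) at a single theta."""
    cache = _ProfileCache(data, q_y, q_z, behavior)
    return cache.profile(np.asarray(theta, dtype=float)).loglik


@dataclass
class PLVariableFit:
    """Result of the Metropolis profile search.

    `theta` is the visited chain state with the largest profiled log
    pseudo-likelihood; `beta` is its profiled logistic fit.  The full
    chain trace is retained for diagnostics.
    """

    theta: np.ndarray
    beta: np.ndarray
    loglik: float
    chain: np.ndarray = field(repr=False)
    chain_loglik: np.ndarray = field(repr=False)
    accepted: np.ndarray = field(repr=False)
    acceptance_rate: float = 0.0
    sigma: float = 1.0
    seed: int | None = None
    separation: bool = False
    coin_toss_fraction: float = 1.0
    behavior: str = "covariate"

    @property
    def utility(self) -> LogisticUtility:
        return LogisticUtility(self.theta)


def tune_sigma(cache: _ProfileCache, theta0: np.ndarray,
               rng: np.random.Generator, pilot: int = 80,
               band: tuple[float, float] = (0.25, 0.5),
               radius: float | None = None) -> float:
    """Choose the proposal SD from a descending ladder of candidate scales.

    Pilot chains are run at sigma = 4, 2, 1, ..., 2^-6; among scales whose
    pilot acceptance falls inside `band` the *smallest* is kept.  The
    profiled pseudo-likelihood has flat saturated ridges far from the
    origin where arbitrarily large proposals are accepted at in-band
    rates, so acceptance is not monotone in sigma and preferring the most
    local in-band scale guards against tuning onto those ridges.  If no
    scale lands in the band the one closest to its midpoint is used.
    """
    d = theta0.size
    ladder = [2.0 ** k for k in range(2, -7, -1)]
    rates = []
    for sigma in ladder:
        theta = theta0.copy()
        ll = cache.profile(theta).loglik
        acc = 0
        for _ in range(pilot):
            prop = theta + sigma * rng.standard_normal(d)
            u = rng.uniform()
            if radius is not None and np.linalg.norm(prop - theta0) > radius:
                continue
            ll_prop = cache.profile(prop).loglik
            if np.log(u) < ll_prop - ll:
                theta, ll = prop, ll_prop
                acc += 1
        rates.append(acc / pilot)
    in_band = [(s, r) for s, r in zip(ladder, rates) if band[0] <= r <= band[1]]
    if in_band:
        return min(s for s, _ in in_band)
    mid = 0.5 * (band[0] + band[1])
    return ladder[int(np.argmin([abs(r - mid) for r in rates]))]


def metropolis_search(data: CohortData, q_y: QModel, q_z: QModel,
                      chain_length: int = 10_000, sigma: float | None = None,
                      seed: int | None = None,
                      theta_init: np.ndarray | None = None,
                      behavior: str = "covariate",
                      acceptance_band: tuple[float, float] = (0.25, 0.5),
                      radius: float | str | None = "auto") -> PLVariableFit:
    """Random-walk maximization of the profiled log pseudo-likelihood.

    Parameters
    ----------
    chain_length : number of Metropolis steps (default 10,000).
    sigma : proposal SD; when None a pilot ladder picks the smallest scale
        whose acceptance proportion falls in `acceptance_band`, then the
        value is frozen for the main chain.
    theta_init : starting point, default the origin (w(x) = 1/2 for all x).
    radius : compact search region {||theta - theta_init|| <= radius},
        making concrete the compact parameter set the identifiability
        theory assumes.  The default "auto" uses 3 / mean||(1, x_i)||, the
        scale beyond which the logistic weight saturates for a typical
        subject: outside it, theta moves along flat ridges where w(x) is
        pinned at 0/1 for almost everyone, the profiled pseudo-likelihood
        carries no information about theta, and an unconstrained search
        drifts without bound.  Pass None for the unconstrained search.
    """
    if chain_length < 1:
        raise ValueError("chain_length must be >= 1")
    d = data.p + 1
    theta0 = (np.zeros(d) if theta_init is None
              else np.asarray(theta_init, dtype=float).ravel())
    if theta0.size != d:
        raise ValueError(f"theta_init must have length p+1={d}")
    if not np.all(np.isfinite(theta0)):
        raise InitializationError(f"theta_init must be finite, got {theta0}")
    ss = np.random.SeedSequence(seed)
    rng_tune, rng_chain = (np.random.default_rng(s) for s in ss.spawn(2))

    cache = _ProfileCache(data, q_y, q_z, behavior)
    ll0 = cache.profile(theta0).loglik
    if not np.isfinite(ll0):
        raise InitializationError(
            f"profiled log pseudo-likelihood is non-finite at theta_init={theta0}")
    if radius == "auto":
        radius = 3.0 / float(np.mean(np.linalg.norm(cache._xi, axis=1)))
    if radius is not None and radius <= 0:
        raise ValueError("radius must be > 0")
    if sigma is None:
        sigma = tune_sigma(cache, theta0, rng_tune, radius=radius)
    elif sigma <= 0:
        raise ValueError("sigma must be > 0")

    chain = np.empty((chain_length, d))
    lls = np.empty(chain_length)
    accepted = np.zeros(chain_length, dtype=bool)
    theta, ll = theta0, ll0
    for b in range(chain_length):
        prop = theta + sigma * rng_chain.standard_normal(d)
        u = rng_chain.uniform()
        if radius is None or np.linalg.norm(prop - theta0) <= radius:
            ll_prop = cache.profile(prop).loglik
            if np.log(u) < ll_prop - ll:
                theta, ll = prop, ll_prop
                accepted[b] = True
        chain[b] = theta
        lls[b] = ll

    rate = float(np.mean(accepted))
    if not acceptance_band[0] <= rate <= acceptance_band[1]:
        warnings.warn(
            f"Metropolis acceptance proportion {rate:.2f} outside "
            f"[{acceptance_band[0]}, {acceptance_band[1]}]; consider adjusting sigma",
            stacklevel=2)

    b_best = int(np.argmax(lls))
    # the starting state counts as visited
    theta_hat = theta0.copy() if ll0 >= lls[b_best] else chain[b_best].copy()
    prof = cache.profile(theta_hat)
    xb = behavior_design(data, behavior)
    frac = coin_toss_diagnostic(xb, prof.beta, warn=True)
    return PLVariableFit(theta=theta_hat, beta=prof.beta, loglik=prof.loglik,
                         chain=chain, chain_loglik=lls, accepted=accepted,
                         acceptance_rate=rate, sigma=float(sigma), seed=seed,
                         separation=prof.separation, coin_toss_fraction=frac,
                         behavior=behavior)


def fitted_rule(fit: PLVariableFit, q_y: QModel, q_z: QModel) -> TreatmentRule:
    """The plug-in optimal rule at the estimated theta."""
    return TreatmentRule(LogisticUtility(fit.theta), q_y, q_z)
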