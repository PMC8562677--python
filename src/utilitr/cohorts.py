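"""Synthetic observational cohorts with known utilities and clinician behavior.

The generative family mirrors a two-outcome precision-medicine setting:
covariates X are independent Gaussians, two real-valued outcomes Y and Z
follow linear models whose effects are pure treatment interactions,

    E[Y | X, A] = A * c_Y'(1, X),      E[Z | X, A] = A * c_Z'(1, X),

and the clinician assigns the utility-optimal treatment d_opt(x) with a
probability that is either constant (rho) or covariate dependent,
expit((1,x)'beta).  The patient utility is u = w(x) y + (1 - w(x)) z with
w either a fixed scalar omega in [0, 1] or a logistic function
expit((1,x)'theta).  Because the truth is known, every estimator in the
package can be scored exactly (error rates, values) without external data.

Draw order per cohort is fixed (X, assignment noise, eps_Y, eps_Z) so that
seeds are portable across the three simulators.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from ._utils import add_intercept, as_cohort_matrix, expit, sign_pm1


class ConfigurationError(ValueError):
    """Invalid generative configuration."""


def _default_coefs_y(p: int) -> np.ndarray:
    c = np.zeros(p + 1)
    k = min(3, p + 1)
    c[:k] = [2.0, 4.0, -2.0][:k]  # A*(4*X1 - 2*X2 + 2)
    return c


def _default_coefs_z(p: int) -> np.ndarray:
    c = np.zeros(p + 1)
    k = min(3, p + 1)
    c[:k] = [-2.0, 2.0, -4.0][:k]  # A*(2*X1 - 4*X2 - 2)
    return c


@dataclass
class GenerativeConfig:
    """Configuration of one synthetic cohort.

    Parameters
    ----------
    n : sample size.
    p : covariate dimension (default 5; only X1, X2 enter the outcomes,
        the remaining covariates are genuine noise).
    covariate_sd, noise_sd : standard deviations of X and of the outcome
        errors (defaults 0.5 each).
    outcome_coefs_y, outcome_coefs_z : length p+1 vectors c (intercept
        first) with E[outcome | X, A] = A * c'(1, X).
    utility : fixed weight omega in [0, 1], or a length p+1 vector theta
        (intercept first) giving w(x) = expit((1,x)'theta).
    behavior : fixed probability rho in (0, 1) of optimal assignment, or a
        length p+1 vector beta giving Pr{A = d_opt(X) | X} = expit((1,x)'beta).
    seed : RNG seed for reproducibility.
    """

    n: int
    p: int = 5
    covariate_sd: float = 0.5
    noise_sd: float = 0.5
    outcome_coefs_y: np.ndarray | None = None
    outcome_coefs_z: np.ndarray | None = None
    utility: float | Sequence[float] = 0.25
    behavior: float | Sequence[float] = 0.6
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1, got {self.n}")
        if self.p < 1:
            raise ConfigurationError(f"p must be >= 1, got {self.p}")
        if self.covariate_sd <= 0 or self.noise_sd <= 0:
            raise ConfigurationError("covariate_sd and noise_sd must be > 0")
        if self.outcome_coefs_y is None:
            self.outcome_coefs_y = _default_coefs_y(self.p)
        if self.outcome_coefs_z is None:
            self.outcome_coefs_z = _default_coefs_z(self.p)
        self.outcome_coefs_y = np.asarray(self.outcome_coefs_y, dtype=float)
        self.outcome_coefs_z = np.asarray(self.outcome_coefs_z, dtype=float)
        for name, c in (("outcome_coefs_y", self.outcome_coefs_y),
                        ("outcome_coefs_z", self.outcome_coefs_z)):
            if c.shape != (self.p + 1,):
                raise ConfigurationError(
                    f"{name} must have length p+1={self.p + 1}, got {c.shape}")
        if np.isscalar(self.utility):
            w = float(self.utility)
            if not 0.0 <= w <= 1.0:
                raise ConfigurationError(f"fixed utility weight must be in [0,1], got {w}")
            self.utility = w
        else:
            self.utility = np.asarray(self.utility, dtype=float)
            if self.utility.shape != (self.p + 1,):
                raise ConfigurationError(
                    f"theta must have length p+1={self.p + 1}, got {self.utility.shape}")
        if np.isscalar(self.behavior):
            r = float(self.behavior)
            if not 0.0 < r < 1.0:
                raise ConfigurationError(f"fixed rho must be in (0,1), got {r}")
            self.behavior = r
        else:
            self.behavior = np.asarray(self.behavior, dtype=float)
            if self.behavior.shape != (self.p + 1,):
                raise ConfigurationError(
                    f"beta must have length p+1={self.p + 1}, got {self.behavior.shape}")

    # --- truth ------------------------------------------------------------

    def utility_weight(self, X: np.ndarray) -> np.ndarray:
        """True utility weight w(x) for each row of X."""
        X = as_cohort_matrix(X)
        if np.isscalar(self.utility):
            return np.full(X.shape[0], float(self.utility))
        return expit(add_intercept(X) @ self.utility)

    def true_contrasts(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """True treatment contrasts R_Y(x), R_Z(x) = Q(x,1) - Q(x,-1)."""
        X = as_cohort_matrix(X)
        Xi = add_intercept(X)
        return 2.0 * Xi @ self.outcome_coefs_y, 2.0 * Xi @ self.outcome_coefs_z

    def optimal_probability(self, X: np.ndarray) -> np.ndarray:
        """Pr{A = d_opt(X) | X} under the behavior model."""
        X = as_cohort_matrix(X)
        if np.isscalar(self.behavior):
            return np.full(X.shape[0], float(self.behavior))
        return expit(add_intercept(X) @ self.behavior)

    def composite(self, X: np.ndarray, Y: np.ndarray, Z: np.ndarray) -> np.ndarray:
        """True composite outcome u(y, z; x) = w(x) y + (1 - w(x)) z."""
        w = self.utility_weight(X)
        return w * np.asarray(Y) + (1.0 - w) * np.asarray(Z)

    def with_(self, **kwargs) -> "GenerativeConfig":
        return replace(self, **kwargs)


@dataclass
class TrueRule:
    """Optimal rule d(x) = sign{w(x) R_Y(x) + (1 - w(x)) R_Z(x)} under the truth."""

    config: GenerativeConfig = field(repr=False)

    def contrast(self, X: np.ndarray) -> np.ndarray:
        ry, rz = self.config.true_contrasts(X)
        w = self.config.utility_weight(X)
        return w * ry + (1.0 - w) * rz

    def decide(self, X: np.ndarray) -> np.ndarray:
        return sign_pm1(self.contrast(X))


def true_optimal_rule(config: GenerativeConfig) -> TrueRule:
    """The oracle treatment rule implied by the generative coefficients."""
    return TrueRule(config)


@dataclass
class CohortData:
    """An observed sample (X, A, Y, Z).

    X stores no intercept column; the convention throughout the package is
    that an intercept is prepended wherever x'beta or x'theta is evaluated.
    """

    X: np.ndarray
    A: np.ndarray
    Y: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.X = as_cohort_matrix(self.X)
        self.A = np.asarray(self.A, dtype=float).ravel()
        self.Y = np.asarray(self.Y, dtype=float).ravel()
        self.Z = np.asarray(self.Z, dtype=float).ravel()
        n = self.X.shape[0]
        if not (self.A.shape[0] == self.Y.shape[0] == self.Z.shape[0] == n):
            raise ValueError("X, A, Y, Z must share the same length")
        for name, v in (("X", self.X), ("A", self.A), ("Y", self.Y), ("Z", self.Z)):
            if not np.all(np.isfinite(v)):
                raise ValueError(f"{name} contains missing or non-finite values")
        if not np.all(np.isin(self.A, (-1.0, 1.0))):
            raise ValueError("A must take values in {-1, +1}")

    @property
    def n(self) -> int:
        return self.X.shape[0]

    @property
    def p(self) -> int:
        return self.X.shape[1]

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"x{j + 1}": self.X[:, j] for j in range(self.p)}
        cols.update(a=self.A.astype(int), y=self.Y, z=self.Z)
        return pd.DataFrame(cols)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "CohortData":
        xcols = [c for c in df.columns if c.startswith("x")]
        return cls(df[xcols].to_numpy(float), df["a"].to_numpy(float),
                   df["y"].to_numpy(float), df["z"].to_numpy(float))

    def swap_outcomes(self) -> "CohortData":
        """Relabel (Y, Z) -> (Z, Y); pairs with w -> 1 - w equivariance."""
        return CohortData(self.X.copy(), self.A.copy(), self.Z.copy(), self.Y.copy())


# --- simulators -----------------------------------------------------------


def _draw(config: GenerativeConfig, rng: np.random.Generator) -> CohortData:
    n = config.n
    X = rng.normal(0.0, config.covariate_sd, size=(n, config.p))
    u_assign = rng.uniform(size=n)
    eps_y = rng.normal(0.0, config.noise_sd, size=n)
    eps_z = rng.normal(0.0, config.noise_sd, size=n)

    d_opt = true_optimal_rule(config).decide(X)
    prob = config.optimal_probability(X)
    A = np.where(u_assign < prob, d_opt, -d_opt)

    Xi = add_intercept(X)
    Y = A * (Xi @ config.outcome_coefs_y) + eps_y
    Z = A * (Xi @ config.outcome_coefs_z) + eps_z
    return CohortData(X, A, Y, Z)


def simulate(config: GenerativeConfig, rng: np.random.Generator | None = None) -> CohortData:
    """Simulate a cohort; dispatches on fixed vs covariate-dependent pieces."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    return _draw(config, rng)


def simulate_fixed(config: GenerativeConfig,
                   rng: np.random.Generator | None = None) -> CohortData:
    """Cohort with fixed utility weight omega and constant optimal probability rho."""
    if not np.isscalar(config.utility) or not np.isscalar(config.behavior):
        raise ConfigurationError("simulate_fixed requires scalar utility and behavior")
    return simulate(config, rng)


def simulate_covariate_propensity(config: GenerativeConfig,
                                  rng: np.random.Generator | None = None) -> CohortData:
    """Fixed omega; Pr{A = d_opt | X} = expit((1,x)'beta)."""
    if not np.isscalar(config.utility) or np.isscalar(config.behavior):
        raise ConfigurationError(
            "simulate_covariate_propensity requires scalar utility and vector behavior")
    return simulate(config, rng)


def simulate_patient_specific(config: GenerativeConfig,
                              rng: np.random.Generator | None = None) -> CohortData:
    """Patient-specific w(x; theta) and covariate-dependent assignment."""
    if np.isscalar(config.utility) or np.isscalar(config.behavior):
        raise ConfigurationError(
            "simulate_patient_specific requires vector utility and vector behavior")
    return simulate(config, rng)


def simulate_under_policy(config: GenerativeConfig, decide,
                          n: int | None = None,
                          rng: np.random.Generator | None = None) -> CohortData:
    """Simulate a cohort with treatment assigned by an arbitrary rule.

    `decide` maps an n x p covariate matrix to a vector in {-1, +1}; used
    for plug-in value estimation of candidate policies.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    cfg = config if n is None else config.with_(n=n)
    m = cfg.n
    X = rng.normal(0.0, cfg.covariate_sd, size=(m, cfg.p))
    rng.uniform(size=m)  # keep the draw order identical to _draw
    eps_y = rng.normal(0.0, cfg.noise_sd, size=m)
    eps_z = rng.normal(0.0, cfg.noise_sd, size=m)
    A = np.asarray(decide(X), dtype=float)
    Xi = add_intercept(X)
    Y = A * (Xi @ cfg.outcome_coefs_y) + eps_y
    Z = A * (Xi @ cfg.outcome_coefs_z) + eps_z
    return CohortData(X, A, Y, Z)
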