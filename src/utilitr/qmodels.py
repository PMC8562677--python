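"""Linear Q-functions, weighted treatment rules, and their influence basis.

Each outcome O in {Y, Z} gets a working model

    Q_O(x, a) = E[O | X = x, A = a] = m'(1, x) + a * g'(1, x)

fit by ordinary least squares on the saturated design (1, X, A, A*X).  The
treatment contrast is R_O(x) = Q_O(x, 1) - Q_O(x, -1) = 2 g'(1, x), so a
candidate rule with utility weight w(x) treats by the sign of the weighted
contrast D(x) = w(x) R_Y(x) + (1 - w(x)) R_Z(x).

The influence basis records the linear expansion governing sqrt(n)
fluctuations of the fitted contrasts: with phi(x) = 2 (1, x)',

    sqrt(n) {R_hat(x) - R(x)} ~ phi(x)' n^{-1/2} sum_i psi_i,

where psi_i is the OLS influence of subject i on the interaction-block
coefficients.  These stacks, together with the behavior-model information
matrix, feed the parametric bootstrap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import statsmodels.api as sm

from ._utils import add_intercept, as_cohort_matrix, expit, sign_pm1
from .cohorts import CohortData


class RankError(np.linalg.LinAlgError):
    """The regression design is rank deficient."""


class UnsupportedFamilyError(TypeError):
    """Influence computation requested for a non-linear Q-model."""


# --- utility models -------------------------------------------------------


@dataclass(frozen=True)
class FixedUtility:
    """Shared utility weight omega for every patient."""

    omega: float

    def __post_init__(self):
        if not 0.0 <= self.omega <= 1.0:
            raise ValueError(f"omega must be in [0, 1], got {self.omega}")

    @property
    def params(self) -> np.ndarray:
        return np.array([self.omega])

    def weight(self, X: np.ndarray) -> np.ndarray:
        return np.full(as_cohort_matrix(X).shape[0], self.omega)

    def gradient(self, X: np.ndarray) -> np.ndarray:
        """d w / d omega = 1 for every patient (column vector)."""
        return np.ones((as_cohort_matrix(X).shape[0], 1))


@dataclass(frozen=True)
class LogisticUtility:
    """Patient-specific weight w(x; theta) = expit((1,x)'theta)."""

    theta: np.ndarray

    def __post_init__(self):
        object.__setattr__(self, "theta", np.asarray(self.theta, dtype=float).ravel())

    @property
    def params(self) -> np.ndarray:
        return self.theta

    def weight(self, X: np.ndarray) -> np.ndarray:
        return expit(add_intercept(X) @ self.theta)

    def gradient(self, X: np.ndarray) -> np.ndarray:
        """d w / d theta = (1,x) w (1 - w), one row per patient."""
        Xi = add_intercept(X)
        w = expit(Xi @ self.theta)
        return Xi * (w * (1.0 - w))[:, None]


UtilityModel = FixedUtility | LogisticUtility


# --- Q-models -------------------------------------------------------------


def _q_design(X: np.ndarray, A: np.ndarray, features) -> tuple[np.ndarray, list[str]]:
    X = as_cohort_matrix(X)
    if features is not None:
        X = X[:, list(features)]
        names = [f"x{j + 1}" for j in features]
    else:
        names = [f"x{j + 1}" for j in range(X.shape[1])]
    Xi = add_intercept(X)
    W = np.column_stack([Xi, A[:, None] * Xi])
    cols = (["const"] + names + ["a"] + [f"a:{nm}" for nm in names])
    return W, cols


@dataclass
class QModel:
    """Fitted outcome regression for one outcome.

    Attributes
    ----------
    params : full coefficient vector on (1, X, A, A*X).
    main, interaction : the two coefficient blocks m and g.
    resid : in-sample residuals.
    gram_inv : (W'W)^{-1} of the design, used for influence computation.
    """

    outcome: str
    params: np.ndarray
    column_names: list[str]
    features: tuple[int, ...] | None
    resid: np.ndarray = field(repr=False)
    gram_inv: np.ndarray = field(repr=False)
    design: np.ndarray = field(repr=False)
    sigma2: float = 0.0

    @property
    def k(self) -> int:
        """Number of columns in the (1, x) block."""
        return self.params.size // 2

    @property
    def main(self) -> np.ndarray:
        return self.params[: self.k]

    @property
    def interaction(self) -> np.ndarray:
        return self.params[self.k:]

    def _xblock(self, X: np.ndarray) -> np.ndarray:
        X = as_cohort_matrix(X)
        if self.features is not None:
            X = X[:, list(self.features)]
        return add_intercept(X)

    def predict(self, X: np.ndarray, a: float | np.ndarray) -> np.ndarray:
        """Q(x, a) for a scalar or per-row a in {-1, +1}."""
        Xi = self._xblock(X)
        a = np.broadcast_to(np.asarray(a, dtype=float), Xi.shape[:1])
        return Xi @ self.main + a * (Xi @ self.interaction)

    def contrast(self, X: np.ndarray) -> np.ndarray:
        """R(x) = Q(x, 1) - Q(x, -1) = 2 (1,x)' g."""
        return 2.0 * self._xblock(X) @ self.interaction

    def basis(self, X: np.ndarray) -> np.ndarray:
        """phi(x) = 2 (1, x): gradient of the contrast in the interaction block."""
        return 2.0 * self._xblock(X)

    def covariance(self, cov_type: str = "nonrobust") -> np.ndarray:
        """Covariance of the interaction-block coefficients.

        "nonrobust" is the model-based homoscedastic OLS form
        sigma^2 (W'W)^{-1}; "HC0" the sandwich built from the empirical
        influence vectors.
        """
        k, n = self.k, self.design.shape[0]
        if cov_type == "nonrobust":
            return self.sigma2 * self.gram_inv[k:, k:]
        if cov_type == "HC0":
            psi = self.influence()
            return (psi.T @ psi) / n ** 2
        raise ValueError(f"cov_type must be 'nonrobust' or 'HC0', got {cov_type!r}")

    def influence(self) -> np.ndarray:
        """Per-subject OLS influence for the interaction-block coefficients.

        psi_i = n (W'W)^{-1} w_i e_i restricted to the interaction rows;
        sample mean is exactly zero by the normal equations.
        """
        n = self.design.shape[0]
        psi_full = n * (self.design @ self.gram_inv) * self.resid[:, None]
        return psi_full[:, self.k:]

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "terms": dict(zip(self.column_names, self.params.tolist())),
        }


def fit_q(data: CohortData, outcome: str, features=None) -> QModel:
    """Least-squares fit of one outcome on (1, X, A, A*X).

    Parameters
    ----------
    outcome : "y" or "z".
    features : optional iterable of covariate indices restricting the
        linear term list (the saturated default uses every covariate).
    """
    o = outcome.lower()
    if o not in ("y", "z"):
        raise ValueError(f"outcome must be 'y' or 'z', got {outcome!r}")
    yvec = data.Y if o == "y" else data.Z
    W, cols = _q_design(data.X, data.A, features)
    n, k2 = W.shape
    if n <= k2:
        raise RankError(f"need n > {k2} observations for the saturated design, got n={n}")
    rank = np.linalg.matrix_rank(W)
    if rank < k2:
        # name the offending columns via pivoted QR
        _, _, piv = scipy.linalg.qr(W, pivoting=True)
        bad = sorted(cols[j] for j in piv[rank:])
        raise RankError(f"design is rank deficient (rank {rank} < {k2}); "
                        f"offending columns: {bad}")
    res = sm.OLS(yvec, W).fit()
    resid = np.asarray(res.resid)
    gram_inv = np.linalg.inv(W.T @ W)
    sigma2 = float(resid @ resid) / max(n - k2, 1)
    return QModel(outcome=o, params=np.asarray(res.params), column_names=cols,
                  features=tuple(features) if features is not None else None,
                  resid=resid, gram_inv=gram_inv, design=W, sigma2=sigma2)


# --- treatment rules ------------------------------------------------------


@dataclass
class TreatmentRule:
    """d(x) = sign{w(x) R_Y(x) + (1 - w(x)) R_Z(x)}, sign(0) = +1."""

    utility: UtilityModel
    q_y: QModel
    q_z: QModel

    def contrast(self, X: np.ndarray) -> np.ndarray:
        w = self.utility.weight(X)
        return w * self.q_y.contrast(X) + (1.0 - w) * self.q_z.contrast(X)

    def decide(self, X: np.ndarray) -> np.ndarray:
        return sign_pm1(self.contrast(X))


def weighted_contrast(rule: TreatmentRule, x: np.ndarray) -> np.ndarray:
    """Estimated weighted contrast D_hat(x); the decision is its sign."""
    return rule.contrast(x)


# --- influence basis ------------------------------------------------------


@dataclass
class InfluenceBasis:
    """Stacked per-subject influence vectors and the behavior information matrix.

    psi_y, psi_z : n x k influence stacks for the two contrast estimates.
    psi_a : n x m stack [1{A_i = d(X_i)} - P_beta(x_i)] (1, x_i).
    info : I_n(beta) = E_n[P(1-P) x x'] over the behavior design (with intercept).
    """

    psi_y: np.ndarray
    psi_z: np.ndarray
    psi_a: np.ndarray
    phi_y: np.ndarray
    phi_z: np.ndarray
    info: np.ndarray


def influence_basis(q_y: QModel, q_z: QModel, data: CohortData,
                    rule: TreatmentRule, beta: np.ndarray,
                    behavior_design: np.ndarray | None = None) -> InfluenceBasis:
    """Assemble the influence stacks needed by the parametric bootstrap.

    `behavior_design` defaults to (1, X); `beta` must match its width.
    Only linear Q-models are supported — the expansion is exact for them.
    """
    for q in (q_y, q_z):
        if not isinstance(q, QModel):
            raise UnsupportedFamilyError(
                f"influence basis requires linear QModel fits, got {type(q).__name__}")
    Xb = add_intercept(data.X) if behavior_design is None else behavior_design
    beta = np.asarray(beta, dtype=float).ravel()
    if beta.size != Xb.shape[1]:
        raise ValueError(f"beta length {beta.size} != behavior design width {Xb.shape[1]}")
    P = expit(Xb @ beta)
    concordant = (data.A == rule.decide(data.X)).astype(float)
    psi_a = (concordant - P)[:, None] * Xb
    info = (Xb * (P * (1.0 - P))[:, None]).T @ Xb / data.n
    return InfluenceBasis(psi_y=q_y.influence(), psi_z=q_z.influence(),
                          psi_a=psi_a, phi_y=q_y.basis(data.X),
                          phi_z=q_z.basis(data.X), info=info)
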