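"""Scoring treatment rules: plug-in value, error rate, cross-validated IPWE.

The value V(d) of a rule d is the mean composite outcome in a population
treated according to d.  On synthetic designs the truth is known, so the
value is estimated by simulating a fresh testing sample with treatment
assigned by the rule and averaging the *true* composite outcome; the error
rate is the fraction of subjects to whom the rule recommends a treatment
different from the true optimal one.  On observed cohorts the value is
estimated by cross-validated inverse-probability weighting: subjects whose
observed treatment agrees with the rule are weighted by the inverse of the
fitted propensity of receiving it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np
from sklearn.model_selection import KFold

from ._utils import add_intercept, expit
from .cohorts import CohortData, GenerativeConfig, simulate, simulate_under_policy
from .pseudolik import profile_beta


def plugin_value(rule, config: GenerativeConfig, n_test: int = 500,
                 seed: int | np.random.Generator | None = None) -> float:
    """Simulation value of a rule under a known generative model.

    Simulates `n_test` subjects, assigns treatment by the rule, and
    averages the true composite outcome u(y, z; x) computed with the
    generative utility weight.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    test = simulate_under_policy(config, rule.decide, n=n_test, rng=rng)
    return float(np.mean(config.composite(test.X, test.Y, test.Z)))


def standard_of_care_value(config: GenerativeConfig, n_test: int = 500,
                           seed: int | np.random.Generator | None = None) -> float:
    """Mean composite outcome under the generative assignment mechanism."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort = simulate(config.with_(n=n_test), rng=rng)
    return float(np.mean(config.composite(cohort.X, cohort.Y, cohort.Z)))


def error_rate(rule, true_rule, X_sample: np.ndarray) -> float:
    """Fraction of subjects for whom the rule disagrees with the true optimum."""
    return float(np.mean(rule.decide(X_sample) != true_rule.decide(X_sample)))


@dataclass
class ValueReport:
    """Cross-validated IPWE values for a fitted policy vs the standard of care."""

    value_y: float
    value_z: float
    value_composite: float
    soc_y: float
    soc_z: float
    soc_composite: float
    pct_improvement: float
    soc_pct_improvement: float  # 0 by construction
    n_test: int
    k_folds: int
    n_truncated: int
    n_excluded_folds: int
    fold_values: np.ndarray = field(repr=False)

    def to_dict(self) -> dict:
        return {k: (v.tolist() if isinstance(v, np.ndarray) else v)
                for k, v in self.__dict__.items()}


def ipwe_mean(outcome: np.ndarray, A: np.ndarray, decisions: np.ndarray,
              pi: np.ndarray, hajek: bool = True) -> float:
    """Inverse-probability-weighted value of a rule from one sample.

    Subjects whose observed treatment matches the rule's decision are
    weighted by 1 / pi (the propensity of the treatment actually
    received); the Hajek form normalizes by the weight total, the
    unnormalized form by the sample size.  Invariant to duplicating every
    subject.
    """
    w = (np.asarray(A) == np.asarray(decisions)).astype(float) / np.asarray(pi)
    if w.sum() == 0:
        return np.nan
    denom = w.sum() if hajek else w.size
    return float(w @ np.asarray(outcome) / denom)


def _fit_propensity(train: CohortData) -> np.ndarray:
    """Logistic regression of 1{A = +1} on (1, X); returns the coefficients."""
    y = (train.A > 0).astype(float)
    return profile_beta(y, add_intercept(train.X)).beta


def ipwe_value_cv(data: CohortData, rule_fitter, k_folds: int = 5,
                  seed: int | None = None, hajek: bool = True,
                  truncation: tuple[float, float] = (0.01, 0.99)) -> ValueReport:
    """K-fold cross-validated inverse-probability-weighted value of a policy.

    Per fold the rule and the propensity model are fit on the training
    part; on the held-out part each subject concordant with the rule
    contributes its outcomes with weight 1 / pi_hat(A_i | X_i).  The
    default estimator is the Hajek (ratio-normalized) form; fitted
    propensities are truncated to `truncation` and truncations counted.
    A fold with no concordant subject is excluded with a warning.
    """
    if k_folds < 2:
        raise ValueError("k_folds must be >= 2")
    kf = KFold(n_splits=k_folds, shuffle=True, random_state=seed)
    fold_vals, n_trunc, excluded = [], 0, 0
    for train_idx, test_idx in kf.split(data.X):
        train = CohortData(data.X[train_idx], data.A[train_idx],
                           data.Y[train_idx], data.Z[train_idx])
        rule = rule_fitter(train)
        eta = _fit_propensity(train)
        Xt = data.X[test_idx]
        At, Yt, Zt = data.A[test_idx], data.Y[test_idx], data.Z[test_idx]
        p_plus = expit(add_intercept(Xt) @ eta)
        pi = np.where(At > 0, p_plus, 1.0 - p_plus)
        lo, hi = truncation
        n_trunc += int(np.sum((pi < lo) | (pi > hi)))
        pi = np.clip(pi, lo, hi)
        dec = rule.decide(Xt)
        if not np.any(At == dec):
            warnings.warn("fold with zero concordant subjects excluded from the IPWE",
                          stacklevel=2)
            excluded += 1
            continue
        w_hat = rule.utility.weight(Xt)
        comp = w_hat * Yt + (1.0 - w_hat) * Zt
        fold_vals.append([ipwe_mean(Yt, At, dec, pi, hajek),
                          ipwe_mean(Zt, At, dec, pi, hajek),
                          ipwe_mean(comp, At, dec, pi, hajek),
                          float(np.mean(comp))])
    if not fold_vals:
        raise RuntimeError("every fold was excluded; IPWE undefined")
    fv = np.asarray(fold_vals)
    value_y, value_z, value_comp = fv[:, 0].mean(), fv[:, 1].mean(), fv[:, 2].mean()
    soc_comp = fv[:, 3].mean()
    soc_y, soc_z = float(np.mean(data.Y)), float(np.mean(data.Z))
    pct = 100.0 * (value_comp - soc_comp) / abs(soc_comp) if soc_comp != 0 else np.nan
    return ValueReport(value_y=float(value_y), value_z=float(value_z),
                       value_composite=float(value_comp), soc_y=soc_y, soc_z=soc_z,
                       soc_composite=float(soc_comp), pct_improvement=float(pct),
                       soc_pct_improvement=0.0, n_test=data.n, k_folds=k_folds,
                       n_truncated=n_trunc, n_excluded_folds=excluded,
                       fold_values=fv)
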