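"""Small shared numerical helpers."""

from __future__ import annotations

import numpy as np
from scipy.special import expit  # noqa: F401  (re-exported)


def sign_pm1(d: np.ndarray | float) -> np.ndarray | float:
    """Sign in {-1, +1} with the tie convention sign(0) = +1.

    Ties are measure-zero under continuous covariates but the convention
    must be fixed so that rules are deterministic.
    """
    return np.where(np.asarray(d) >= 0, 1.0, -1.0)


def add_intercept(X: np.ndarray) -> np.ndarray:
    """Prepend a column of ones: x -> (1, x)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.column_stack([np.ones(X.shape[0]), X])


def as_cohort_matrix(X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(1, -1)
    return X
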