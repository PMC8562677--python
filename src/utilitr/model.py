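"""Model / Results interface for composite-outcome utility estimation.

`CompositeUtilityModel` bundles a cohort with the modelling choices (fixed
vs patient-specific utility weight, intercept-only vs covariate behavior
model, Q-model term list); `fit()` runs the appropriate maximum
pseudo-likelihood search and returns a results object carrying the
estimates, diagnostics and, for the patient-specific model, bootstrap
inference for preference heterogeneity.

Example
-------
>>> from utilitr import CompositeUtilityModel, GenerativeConfig, simulate
>>> cohort = simulate(GenerativeConfig(n=500, utility=0.25, behavior=0.6, seed=1))
>>> res = CompositeUtilityModel(cohort, utility="fixed").fit()
>>> round(res.omega, 2), round(res.rho, 2)  # doctest: +SKIP
(0.25, 0.6)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import bootstrap as _boot
from .cohorts import CohortData
from .evaluation import ipwe_value_cv
from .metropolis import PLVariableFit, metropolis_search
from .pseudolik import (PLFixedFit, behavior_design, coin_toss_diagnostic,
                        default_grid, grid_search_omega)
from .qmodels import FixedUtility, LogisticUtility, QModel, TreatmentRule, fit_q


class CompositeUtilityModel:
    """Pseudo-likelihood model of clinician decisions as noisy utility signals.

    Parameters
    ----------
    data : CohortData (or use `from_dataframe`).
    utility : "fixed" for one shared weight omega, "varying" for the
        logistic patient-specific weight w(x; theta).
    behavior : "constant" for an intercept-only optimal-assignment
        probability (a single rho), "covariate" for expit((1,x)'beta).
    q_features : optional covariate indices restricting the linear
        Q-model term list (default: all covariates, saturated with
        treatment interactions).
    """

    def __init__(self, data: CohortData, utility: str = "fixed",
                 behavior: str | None = None, q_features=None):
        if utility not in ("fixed", "varying"):
            raise ValueError(f"utility must be 'fixed' or 'varying', got {utility!r}")
        if behavior is None:
            behavior = "constant" if utility == "fixed" else "covariate"
        if behavior not in ("constant", "covariate"):
            raise ValueError(f"behavior must be 'constant' or 'covariate', got {behavior!r}")
        self.data = data
        self.utility = utility
        self.behavior = behavior
        self.q_features = q_features
        self._q_y: QModel | None = None
        self._q_z: QModel | None = None

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, **kwargs) -> "CompositeUtilityModel":
        return cls(CohortData.from_dataframe(df), **kwargs)

    @property
    def q_y(self) -> QModel:
        if self._q_y is None:
            self._q_y = fit_q(self.data, "y", features=self.q_features)
        return self._q_y

    @property
    def q_z(self) -> QModel:
        if self._q_z is None:
            self._q_z = fit_q(self.data, "z", features=self.q_features)
        return self._q_z

    def fit(self, grid_step: float = 0.01, chain_length: int = 10_000,
            sigma: float | None = None, seed: int | None = None,
            theta_init: np.ndarray | None = None,
            radius: float | str | None = "auto"):
        """Run the maximum pseudo-likelihood search.

        The fixed-utility model profiles beta by logistic regression on a
        grid of omega values (step `grid_step`); the patient-specific
        model runs a Metropolis random walk of `chain_length` steps over
        theta.  Returns a `FixedUtilityResults` or
        `PatientSpecificUtilityResults` object.
        """
        if self.utility == "fixed":
            fit = grid_search_omega(self.data, self.q_y, self.q_z,
                                    grid=default_grid(grid_step),
                                    behavior=self.behavior)
            return FixedUtilityResults(self, fit)
        fit = metropolis_search(self.data, self.q_y, self.q_z,
                                chain_length=chain_length, sigma=sigma,
                                seed=seed, theta_init=theta_init,
                                behavior=self.behavior, radius=radius)
        return PatientSpecificUtilityResults(self, fit)


@dataclass
class _ResultsBase:
    model: CompositeUtilityModel

    @property
    def data(self) -> CohortData:
        return self.model.data

    def treatment_rule(self) -> TreatmentRule:
        raise NotImplementedError

    @property
    def llf(self) -> float:
        raise NotImplementedError

    def optimal_probabilities(self) -> np.ndarray:
        """Fitted Pr{A = d_opt(X) | X} per subject."""
        xb = behavior_design(self.data, self.model.behavior)
        return 1.0 / (1.0 + np.exp(-(xb @ self.beta)))

    @property
    def coin_toss_fraction(self) -> float:
        xb = behavior_design(self.data, self.model.behavior)
        return coin_toss_diagnostic(xb, self.beta)

    def cross_validated_value(self, k_folds: int = 5, seed: int | None = None,
                              hajek: bool = True):
        """K-fold cross-validated IPWE value of the policy this model fits."""
        model = self.model

        def refit(train: CohortData) -> TreatmentRule:
            m = CompositeUtilityModel(train, utility=model.utility,
                                      behavior=model.behavior,
                                      q_features=model.q_features)
            if model.utility == "fixed":
                return m.fit().treatment_rule()
            return m.fit(chain_length=min(2000, self._fit.chain.shape[0]),
                         seed=seed).treatment_rule()

        return ipwe_value_cv(self.data, refit, k_folds=k_folds, seed=seed,
                             hajek=hajek)


class FixedUtilityResults(_ResultsBase):
    """Results of the fixed-utility grid search."""

    def __init__(self, model: CompositeUtilityModel, fit: PLFixedFit):
        super().__init__(model)
        self._fit = fit

    @property
    def omega(self) -> float:
        return self._fit.omega

    @property
    def beta(self) -> np.ndarray:
        return self._fit.beta

    @property
    def rho(self) -> float:
        """Estimated probability of optimal assignment.

        expit of the profiled intercept for an intercept-only behavior
        design; otherwise the sample average of expit((1,x)'beta_hat).
        """
        return self._fit.rho

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([[self.omega], self.beta])

    @property
    def grid(self) -> np.ndarray:
        return self._fit.grid

    @property
    def profile(self) -> np.ndarray:
        return self._fit.loglik_grid

    @property
    def separation(self) -> bool:
        return self._fit.separation

    def treatment_rule(self) -> TreatmentRule:
        return TreatmentRule(FixedUtility(self.omega), self.model.q_y, self.model.q_z)

    def plot_profile(self, ax=None):
        """Profiled log pseudo-likelihood over the omega grid."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.grid, self.profile, drawstyle="steps-mid")
        ax.axvline(self.omega, color="crimson", ls="--",
                   label=f"$\\hat\\omega$ = {self.omega:.2f}")
        ax.set_xlabel("utility weight $\\omega$")
        ax.set_ylabel("profiled log pseudo-likelihood")
        ax.legend()
        return ax

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Composite-outcome utility model (fixed weight)",
            "=" * 54,
            f"No. observations:        {self.data.n}",
            f"Behavior model:          {self.model.behavior}",
            f"omega grid:              {f.grid.size} points in [0, 1]",
            "-" * 54,
            f"omega_hat                {self.omega:10.4f}",
            f"rho_hat                  {self.rho:10.4f}",
        ]
        for j, b in enumerate(self.beta):
            name = "beta_const" if j == 0 else f"beta_x{j}"
            lines.append(f"{name:<24} {b:10.4f}")
        lines += [
            "-" * 54,
            f"log pseudo-likelihood    {self.llf:10.3f}",
            f"optimal fraction         {f.optimal_fraction:10.4f}",
            f"coin-toss diagnostic     {self.coin_toss_fraction:10.4f}",
            f"separation flag          {str(f.separation):>10}",
        ]
        return "\n".join(lines)


class PatientSpecificUtilityResults(_ResultsBase):
    """Results of the Metropolis profile search for w(x; theta)."""

    def __init__(self, model: CompositeUtilityModel, fit: PLVariableFit):
        super().__init__(model)
        self._fit = fit

    @property
    def theta(self) -> np.ndarray:
        return self._fit.theta

    @property
    def beta(self) -> np.ndarray:
        return self._fit.beta

    @property
    def llf(self) -> float:
        return self._fit.loglik

    @property
    def params(self) -> np.ndarray:
        return np.concatenate([self.theta, self.beta])

    @property
    def acceptance_rate(self) -> float:
        return self._fit.acceptance_rate

    @property
    def chain(self) -> np.ndarray:
        return self._fit.chain

    @property
    def mean_omega(self) -> float:
        """Sample average of the fitted utility weights E_n{w(x; theta_hat)}."""
        return float(np.mean(LogisticUtility(self.theta).weight(self.data.X)))

    def treatment_rule(self) -> TreatmentRule:
        return TreatmentRule(LogisticUtility(self.theta), self.model.q_y,
                             self.model.q_z)

    def asymptotic_components(self) -> _boot.AsymptoticComponents:
        return _boot.estimate_components(self.data, self._fit, self.model.q_y,
                                         self.model.q_z)

    def bootstrap_distribution(self, n_boot: int = 1000, seed: int | None = None):
        """Matrix of bootstrap draws (U~, B~) approximating the sampling law."""
        comp = self.asymptotic_components()
        rng = np.random.default_rng(seed)
        draws = [_boot.bootstrap_draw(comp, rng) for _ in range(n_boot)]
        U = np.array([d.U for d in draws])
        B = np.array([d.B for d in draws])
        return U, B

    def heterogeneity_test(self, n_boot: int = 1000, alpha: float = 0.05,
                           seed: int | None = None) -> _boot.HeterogeneityTest:
        """Parametric-bootstrap test of H0: all patients share one utility weight."""
        return _boot.heterogeneity_test(self.data, self._fit, self.model.q_y,
                                        self.model.q_z, n_boot=n_boot,
                                        alpha=alpha, seed=seed)

    def plot_trace(self, ax=None):
        """Profiled log pseudo-likelihood along the Metropolis chain."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self._fit.chain_loglik, lw=0.7)
        ax.axhline(self.llf, color="crimson", ls="--", label="maximum")
        ax.set_xlabel("chain step")
        ax.set_ylabel("profiled log pseudo-likelihood")
        ax.legend()
        return ax

    def summary(self) -> str:
        f = self._fit
        lines = [
            "Composite-outcome utility model (patient-specific weight)",
            "=" * 58,
            f"No. observations:        {self.data.n}",
            f"Behavior model:          {self.model.behavior}",
            f"Chain length:            {f.chain.shape[0]}  "
            f"(acceptance {f.acceptance_rate:.2f}, sigma {f.sigma:.3g})",
            "-" * 58,
        ]
        for j, t in enumerate(self.theta):
            name = "theta_const" if j == 0 else f"theta_x{j}"
            lines.append(f"{name:<24} {t:10.4f}")
        for j, b in enumerate(self.beta):
            name = "beta_const" if j == 0 else f"beta_x{j}"
            lines.append(f"{name:<24} {b:10.4f}")
        lines += [
            "-" * 58,
            f"mean fitted omega        {self.mean_omega:10.4f}",
            f"log pseudo-likelihood    {self.llf:10.3f}",
            f"coin-toss diagnostic     {f.coin_toss_fraction:10.4f}",
            f"separation flag          {str(f.separation):>10}",
        ]
        return "\n".join(lines)
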