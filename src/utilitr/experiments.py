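"""Monte-Carlo harness for the simulation-study table analogues.

Seven designs are provided, matching the structure of the simulation
study: estimation and value summaries under a fixed utility with constant
or covariate-dependent optimal-assignment probability (tables 1-4),
estimation and value summaries under a patient-specific utility fit by the
Metropolis profile search (tables 5-6), and operating characteristics of
the parametric-bootstrap heterogeneity test on a bivariate-covariate
design (table 7).  Replication counts, sample sizes, chain lengths and
bootstrap sizes are configurable so the full-scale study can be scaled to
desk size; per-replication seeds are spawned from one master seed so every
table regenerates bit-identically.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bootstrap import estimate_components, heterogeneity_test
from .cohorts import GenerativeConfig, simulate, true_optimal_rule
from .evaluation import error_rate, plugin_value, standard_of_care_value
from .metropolis import metropolis_search
from .metropolis import fitted_rule as var_rule
from .pseudolik import default_grid, grid_search_omega
from .pseudolik import fitted_rule as fixed_rule
from .qmodels import FixedUtility, LogisticUtility, TreatmentRule, fit_q

_TABLE5_THETA = (1.0, -0.5, 0.0, 0.0, 0.0, 0.0)
_COV_BETA = (0.5, 1.0, 0.0, 0.0, 0.0, 0.0)
_T7_BETA = (2.5, 1.0, 0.0)


@dataclass
class ExperimentSpec:
    """One table analogue at a chosen scale.

    design : 'table1' .. 'table7'.
    n_values : sample sizes to sweep (defaults to the design's own set).
    reps : Monte-Carlo replications per scenario.
    seed : master seed; per-replication seeds are spawned from it.
    grid_step, chain_length, n_boot, n_test : estimator settings.
    """

    design: str
    n_values: tuple[int, ...] | None = None
    reps: int = 500
    seed: int = 0
    grid_step: float = 0.01
    chain_length: int = 10_000
    n_boot: int = 1000
    n_test: int = 500
    omegas: tuple[float, ...] = (0.25, 0.75)
    rhos: tuple[float, ...] = (0.6, 0.8)
    thetas_t7: tuple[tuple[float, ...], ...] = ((1, 0, 0), (1, 4, 3), (1, 6, 6))
    alpha: float = 0.05

    def __post_init__(self):
        if self.design not in {f"table{i}" for i in range(1, 8)}:
            raise ValueError(f"unknown design {self.design!r}")
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.n_values is None:
            self.n_values = (100, 200, 300, 500)
        self.n_values = tuple(int(n) for n in self.n_values)

    def with_scenario(self, *parts) -> "ExperimentSpec":
        """Scenario-specific clone whose seed folds in the scenario labels.

        Keeps per-scenario replication seeds distinct while remaining a
        pure, platform-stable function of the master seed (no reliance on
        Python's randomized string hashing).
        """
        entropy = [self.seed]
        for p in parts:
            if isinstance(p, str):
                entropy.append(int.from_bytes(p.encode(), "little") % (2 ** 31))
            else:
                entropy.append(int(round(float(p) * 1000)) % (2 ** 31))
        seed = int(np.random.SeedSequence(entropy).generate_state(1, np.uint32)[0] >> 1)
        clone = ExperimentSpec(**self.__dict__)
        clone.seed = seed
        return clone


def _rep_seeds(spec: ExperimentSpec, count: int) -> list[np.random.SeedSequence]:
    return np.random.SeedSequence(spec.seed).spawn(count)


def _mean_sd(x: np.ndarray) -> tuple[float, float]:
    x = np.asarray(x, dtype=float)
    return float(np.mean(x)), (float(np.std(x, ddof=1)) if x.size > 1 else np.nan)


def _err_quartiles(e: np.ndarray) -> tuple[float, float, float]:
    q25, med, q75 = np.percentile(e, [25, 50, 75])
    return float(med), float(q25), float(q75)


def _fit_fixed_rep(config: GenerativeConfig, ss: np.random.SeedSequence,
                   spec: ExperimentSpec, behavior: str):
    """One replication of the fixed-utility pipeline; returns fit + error rate."""
    rng = np.random.default_rng(ss)
    cohort = simulate(config, rng=rng)
    q_y, q_z = fit_q(cohort, "y"), fit_q(cohort, "z")
    fit = grid_search_omega(cohort, q_y, q_z, grid=default_grid(spec.grid_step),
                            behavior=behavior)
    rule = fixed_rule(fit, q_y, q_z)
    x_fresh = rng.normal(0.0, config.covariate_sd, size=(spec.n_test, config.p))
    err = error_rate(rule, true_optimal_rule(config), x_fresh)
    return cohort, q_y, q_z, fit, rule, err, rng


def _value_columns(config: GenerativeConfig, est_rule, q_y, q_z,
                   rng: np.random.Generator, spec: ExperimentSpec) -> dict:
    """Values of optimal / estimated / Y-only / Z-only / standard-of-care policies."""
    truth = true_optimal_rule(config)
    vals = {
        "optimal": plugin_value(truth, config, spec.n_test, rng),
        "estimated": plugin_value(est_rule, config, spec.n_test, rng),
        "y_only": plugin_value(TreatmentRule(FixedUtility(1.0), q_y, q_z),
                               config, spec.n_test, rng),
        "z_only": plugin_value(TreatmentRule(FixedUtility(0.0), q_y, q_z),
                               config, spec.n_test, rng),
        "standard_of_care": standard_of_care_value(config, spec.n_test, rng),
    }
    return vals


def run_table(spec: ExperimentSpec) -> pd.DataFrame:
    """Run one table analogue and return its summary as a DataFrame."""
    runner = {
        "table1": _run_table1, "table2": _run_table2,
        "table3": _run_table3, "table4": _run_table4,
        "table5": _run_table5, "table6": _run_table6,
        "table7": _run_table7,
    }[spec.design]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return runner(spec)


def _summarize_estimates(rows: list[dict], keys: list[str]) -> dict:
    out = {}
    for k in keys:
        vals = np.array([r[k] for r in rows])
        m, s = _mean_sd(vals)
        out[f"{k}_mean"], out[f"{k}_sd"] = m, s
    errs = np.array([r["error_rate"] for r in rows])
    m, s = _mean_sd(errs)
    med, q25, q75 = _err_quartiles(errs)
    out.update(error_rate_mean=m, error_rate_sd=s, error_rate_median=med,
               error_rate_q25=q25, error_rate_q75=q75)
    return out


def _run_table1(spec: ExperimentSpec) -> pd.DataFrame:
    records = []
    for n in spec.n_values:
        for omega in spec.omegas:
            for rho in spec.rhos:
                config = GenerativeConfig(n=n, utility=omega, behavior=rho)
                seeds = _rep_seeds(spec.with_scenario(n, omega, rho), spec.reps)
                rows = []
                for ss in seeds:
                    _, _, _, fit, _, err, _ = _fit_fixed_rep(config, ss, spec, "constant")
                    rows.append({"omega": fit.omega, "rho": fit.rho, "error_rate": err})
                rec = {"n": n, "true_omega": omega, "true_rho": rho,
                       **_summarize_estimates(rows, ["omega", "rho"])}
                records.append(rec)
    return pd.DataFrame(records)


def _run_table2(spec: ExperimentSpec) -> pd.DataFrame:
    records = []
    for n in spec.n_values:
        for omega in spec.omegas:
            for rho in spec.rhos:
                config = GenerativeConfig(n=n, utility=omega, behavior=rho)
                seeds = _rep_seeds(spec.with_scenario(n, omega, rho), spec.reps)
                vals = []
                for ss in seeds:
                    _, q_y, q_z, fit, rule, _, rng = _fit_fixed_rep(
                        config, ss, spec, "constant")
                    vals.append(_value_columns(config, rule, q_y, q_z, rng, spec))
                rec = {"n": n, "true_omega": omega, "true_rho": rho}
                for k in vals[0]:
                    m, s = _mean_sd([v[k] for v in vals])
                    rec[f"{k}_mean"], rec[f"{k}_sd"] = m, s
                records.append(rec)
    return pd.DataFrame(records)


def _cov_config(n: int, omega_or_theta, p: int = 5) -> GenerativeConfig:
    return GenerativeConfig(n=n, p=p, utility=omega_or_theta,
                            behavior=np.array(_COV_BETA[: p + 1]))


def _run_table3(spec: ExperimentSpec) -> pd.DataFrame:
    beta0 = np.array(_COV_BETA)
    records = []
    for n in spec.n_values:
        for omega in spec.omegas:
            config = _cov_config(n, omega)
            seeds = _rep_seeds(spec.with_scenario(n, omega), spec.reps)
            rows, sqerr = [], []
            for ss in seeds:
                _, _, _, fit, _, err, _ = _fit_fixed_rep(config, ss, spec, "covariate")
                rows.append({"omega": fit.omega, "error_rate": err})
                sqerr.append(np.sum((fit.beta - beta0) ** 2))
            rec = {"n": n, "true_omega": omega,
                   **_summarize_estimates(rows, ["omega"]),
                   "beta_rmse": float(np.sqrt(np.mean(sqerr)))}
            records.append(rec)
    return pd.DataFrame(records)


def _run_table4(spec: ExperimentSpec) -> pd.DataFrame:
    records = []
    for n in spec.n_values:
        for omega in spec.omegas:
            config = _cov_config(n, omega)
            seeds = _rep_seeds(spec.with_scenario(n, omega), spec.reps)
            vals = []
            for ss in seeds:
                _, q_y, q_z, fit, rule, _, rng = _fit_fixed_rep(
                    config, ss, spec, "covariate")
                vals.append(_value_columns(config, rule, q_y, q_z, rng, spec))
            rec = {"n": n, "true_omega": omega}
            for k in vals[0]:
                m, s = _mean_sd([v[k] for v in vals])
                rec[f"{k}_mean"], rec[f"{k}_sd"] = m, s
            records.append(rec)
    return pd.DataFrame(records)


def _fit_variable_rep(config: GenerativeConfig, ss: np.random.SeedSequence,
                      spec: ExperimentSpec):
    rng = np.random.default_rng(ss)
    cohort = simulate(config, rng=rng)
    q_y, q_z = fit_q(cohort, "y"), fit_q(cohort, "z")
    chain_seed = int(ss.generate_state(1, dtype=np.uint32)[0] >> 1)
    fit = metropolis_search(cohort, q_y, q_z, chain_length=spec.chain_length,
                            seed=chain_seed, behavior="covariate")
    return cohort, q_y, q_z, fit, rng


def _run_table5(spec: ExperimentSpec) -> pd.DataFrame:
    theta0 = np.array(_TABLE5_THETA)
    beta0 = np.array(_COV_BETA)
    records = []
    for n in spec.n_values:
        config = _cov_config(n, theta0)
        seeds = _rep_seeds(spec.with_scenario(n), spec.reps)
        sq_t, sq_b, errs = [], [], []
        for ss in seeds:
            cohort, q_y, q_z, fit, rng = _fit_variable_rep(config, ss, spec)
            sq_t.append(np.sum((fit.theta - theta0) ** 2))
            sq_b.append(np.sum((fit.beta - beta0) ** 2))
            x_fresh = rng.normal(0.0, config.covariate_sd, size=(spec.n_test, config.p))
            errs.append(error_rate(var_rule(fit, q_y, q_z),
                                   true_optimal_rule(config), x_fresh))
        errs = np.asarray(errs)
        m, s = _mean_sd(errs)
        med, q25, q75 = _err_quartiles(errs)
        records.append({"n": n,
                        "theta_rmse": float(np.sqrt(np.mean(sq_t))),
                        "beta_rmse": float(np.sqrt(np.mean(sq_b))),
                        "error_rate_mean": m, "error_rate_sd": s,
                        "error_rate_median": med, "error_rate_q25": q25,
                        "error_rate_q75": q75})
    return pd.DataFrame(records)


def _run_table6(spec: ExperimentSpec) -> pd.DataFrame:
    theta0 = np.array(_TABLE5_THETA)
    records = []
    for n in spec.n_values:
        config = _cov_config(n, theta0)
        seeds = _rep_seeds(spec.with_scenario(n), spec.reps)
        vals = []
        for ss in seeds:
            cohort, q_y, q_z, fit, rng = _fit_variable_rep(config, ss, spec)
            rule = var_rule(fit, q_y, q_z)
            vals.append(_value_columns(config, rule, q_y, q_z, rng, spec))
        rec = {"n": n}
        for k in vals[0]:
            m, s = _mean_sd([v[k] for v in vals])
            rec[f"{k}_mean"], rec[f"{k}_sd"] = m, s
        records.append(rec)
    return pd.DataFrame(records)


def _run_table7(spec: ExperimentSpec) -> pd.DataFrame:
    """Bootstrap heterogeneity test on the bivariate design.

    The stability column reports, under the null theta0, the average
    agreement between the estimated rule and the rules implied by the
    bootstrap draws theta_hat + U~ / sqrt(n), averaged over draws and a
    fresh covariate sample.
    """
    records = []
    for n in spec.n_values:
        rec = {"n": n}
        for label, theta0 in zip(("type1", "power_h1", "power_h2"), spec.thetas_t7):
            config = GenerativeConfig(n=n, p=2, utility=np.asarray(theta0, float),
                                      behavior=np.array(_T7_BETA))
            seeds = _rep_seeds(spec.with_scenario(n, label), spec.reps)
            rejections, stability = [], []
            for ss in seeds:
                cohort, q_y, q_z, fit, rng = _fit_variable_rep(config, ss, spec)
                comp = estimate_components(cohort, fit, q_y, q_z)
                boot_seed = int(ss.generate_state(2, dtype=np.uint32)[1] >> 1)
                test = heterogeneity_test(cohort, fit, q_y, q_z,
                                          n_boot=spec.n_boot, alpha=spec.alpha,
                                          seed=boot_seed, components=comp)
                rejections.append(test.reject)
                if label == "type1":
                    x_fresh = rng.normal(0.0, config.covariate_sd,
                                         size=(spec.n_test, config.p))
                    base = TreatmentRule(LogisticUtility(fit.theta), q_y, q_z)
                    d0 = base.decide(x_fresh)
                    agree = [np.mean(TreatmentRule(
                        LogisticUtility(fit.theta + u / np.sqrt(n)), q_y, q_z
                    ).decide(x_fresh) == d0) for u in test.draws_U[:100]]
                    stability.append(float(np.mean(agree)))
            rec[label] = float(np.mean(rejections))
            if label == "type1":
                rec["stability"] = float(np.mean(stability))
        records.append(rec)
    return pd.DataFrame(records)


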