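"""Parametric bootstrap for the non-smooth pseudo-likelihood estimators.

The sampling law of sqrt(n)(theta_hat - theta0, beta_hat - beta0) is
non-Gaussian: it is driven by subjects near the decision boundary
D_theta0(X) = 0, where a small perturbation of the fitted contrasts flips
the estimated optimal treatment.  The limit couples a Gaussian vector
(Z_Y, Z_Z, Z_A) — the influence-vector limits of the two contrast fits and
of the behavior score — through a kernel-localized map k and an argmin.

The bootstrap approximates one draw as follows.  Draw Z* ~ N(0, I_r) and
form Z~ = Sigma_hat^{1/2} Z* using a lower-block-triangular square root of
the stacked influence second-moment matrix Sigma_hat.  With bandwidth
h_n = v_hat n^{-1/5} (v_hat the sample SD of the fitted weighted contrast),
define the smoothed boundary average

    k~(Z_Y, Z_Z, u) = E_n[ x (2 P_beta(x) - 1) |T~ + (R_Y - R_Z) w_dot'u|
                           K_h(D_hat) ] / E_n[ K_h(D_hat) ],

where K_h is a Gaussian kernel and T~ collects the contrast perturbations.
Then U~ = argmin_u beta_hat' k~(Z_Y, Z_Z, u) approximates the theta
fluctuation and B~ = I_n(beta_hat)^{-1} {Z_A - k~(U~)} the beta
fluctuation.  Repeated draws give the reference distribution for the
preference-heterogeneity test of H0: ||theta_(1)|| = 0 (all patients share
one utility weight), using the statistic sqrt(n) ||theta_hat_(1)||.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._utils import expit
from .cohorts import CohortData
from .metropolis import PLVariableFit
from .pseudolik import behavior_design
from .qmodels import LogisticUtility, QModel, TreatmentRule, influence_basis

_NORM_CONST = 1.0 / np.sqrt(2.0 * np.pi)


class DegenerateContrastError(ValueError):
    """All fitted weighted contrasts are equal; the bandwidth is undefined."""


class KernelDegeneracyError(ValueError):
    """The kernel mass at the decision boundary is numerically zero."""


class InferenceUnstableError(RuntimeError):
    """Too many bootstrap draws failed to converge."""


def psd_sqrt(M: np.ndarray, inverse: bool = False, tol: float = 1e-10) -> np.ndarray:
    """Symmetric PSD (pseudo-)square root via eigendecomposition.

    Eigenvalues below `tol` times the largest are clipped at zero (and
    excluded from the pseudo-inverse root when ``inverse=True``).
    """
    M = 0.5 * (M + M.T)
    vals, vecs = np.linalg.eigh(M)
    cut = tol * max(vals.max(), 0.0) if vals.size else 0.0
    vals = np.where(vals > cut, vals, 0.0)
    if inverse:
        root = np.where(vals > 0, 1.0 / np.sqrt(np.where(vals > 0, vals, 1.0)), 0.0)
    else:
        root = np.sqrt(vals)
    return (vecs * root) @ vecs.T


def block_sqrt(sigma: np.ndarray, q: int) -> np.ndarray:
    """Lower-block-triangular square root with zero upper-right block.

    The top-left q x q block is the symmetric root of Sigma_1; the
    lower-left block is Sigma_21' Sigma_1^{-1/2}; the lower-right block is
    the symmetric root of the Schur complement.  L L' reproduces Sigma.
    """
    s1 = sigma[:q, :q]
    s21 = sigma[:q, q:]          # upper-right q x p block
    s2 = sigma[q:, q:]
    s1_half = psd_sqrt(s1)
    s1_inv_half = psd_sqrt(s1, inverse=True)
    s1_inv = s1_inv_half @ s1_inv_half
    schur = s2 - s21.T @ s1_inv @ s21
    out = np.zeros_like(sigma)
    out[:q, :q] = s1_half
    out[q:, :q] = s21.T @ s1_inv_half
    out[q:, q:] = psd_sqrt(schur)
    return out


@dataclass
class AsymptoticComponents:
    """Everything the bootstrap map needs, estimated once from the fit."""

    n: int
    theta: np.ndarray
    beta: np.ndarray
    sigma: np.ndarray
    sigma_root: np.ndarray
    info: np.ndarray
    bandwidth: float
    contrast_sd: float
    q1: int
    q2: int
    # per-subject pieces of the kernel average
    x_behavior: np.ndarray = field(repr=False)   # behavior design (with intercept)
    kernel: np.ndarray = field(repr=False)       # h^{-1} phi0(D_hat / h)
    sign_weight: np.ndarray = field(repr=False)  # 2 P_beta(x) - 1
    phi_y: np.ndarray = field(repr=False)
    phi_z: np.ndarray = field(repr=False)
    a_y: np.ndarray = field(repr=False)          # w(x) R_Y(x)
    a_z: np.ndarray = field(repr=False)          # (1 - w(x)) R_Z(x)
    r_diff: np.ndarray = field(repr=False)       # R_Y - R_Z
    omega_dot: np.ndarray = field(repr=False)    # (1,x) w (1 - w)

    @property
    def q(self) -> int:
        return self.q1 + self.q2

    @property
    def r(self) -> int:
        return self.sigma.shape[0]

    @property
    def d(self) -> int:
        return self.theta.size


def estimate_components(data: CohortData, fit: PLVariableFit, q_y: QModel,
                        q_z: QModel) -> AsymptoticComponents:
    """Assemble the plug-in asymptotic components from a fitted model.

    Sigma_hat is the empirical second-moment matrix of the stacked
    per-subject influence vectors (psi_Y, psi_Z, psi_A); the bandwidth is
    h_n = v_hat n^{-1/5} with v_hat the sample SD of the fitted weighted
    contrast D_hat(X_i).
    """
    theta = np.asarray(fit.theta, dtype=float)
    beta = np.asarray(fit.beta, dtype=float)
    utility = LogisticUtility(theta)
    rule = TreatmentRule(utility, q_y, q_z)
    xb = behavior_design(data, fit.behavior)
    basis = influence_basis(q_y, q_z, data, rule, beta, behavior_design=xb)

    stacks = np.hstack([basis.psi_y, basis.psi_z, basis.psi_a])
    sigma = stacks.T @ stacks / data.n
    q1 = basis.psi_y.shape[1]
    q2 = basis.psi_z.shape[1]
    root = block_sqrt(sigma, q1 + q2)

    d_hat = rule.contrast(data.X)
    v_hat = float(np.std(d_hat, ddof=1)) if data.n > 1 else 0.0
    if v_hat <= 0.0:
        raise DegenerateContrastError(
            "all fitted weighted contrasts are equal; bandwidth h_n would be zero")
    h = v_hat * data.n ** (-0.2)

    info = basis.info
    if np.linalg.matrix_rank(info) < info.shape[0]:
        diag = np.diag(info)
        bad = int(np.argmin(diag))
        raise np.linalg.LinAlgError(
            f"behavior information matrix is singular (degenerate column {bad})")

    w = utility.weight(data.X)
    ry = q_y.contrast(data.X)
    rz = q_z.contrast(data.X)
    kern = _NORM_CONST * np.exp(-0.5 * (d_hat / h) ** 2) / h
    return AsymptoticComponents(
        n=data.n, theta=theta, beta=beta, sigma=sigma, sigma_root=root,
        info=info, bandwidth=h, contrast_sd=v_hat, q1=q1, q2=q2,
        x_behavior=xb, kernel=kern, sign_weight=2.0 * expit(xb @ beta) - 1.0,
        phi_y=basis.phi_y, phi_z=basis.phi_z,
        a_y=w * ry, a_z=(1.0 - w) * rz, r_diff=ry - rz,
        omega_dot=utility.gradient(data.X))


def k_tilde(components: AsymptoticComponents, z_y: np.ndarray, z_z: np.ndarray,
            u: np.ndarray) -> np.ndarray:
    """Kernel-smoothed boundary average k~_n(Z_Y, Z_Z, u).

    Ratio of sample means; the numerator weights each subject's behavior
    design vector by (2 P_beta - 1), the absolute perturbation term, and a
    Gaussian kernel concentrating on the decision boundary D_hat ~ 0.
    """
    c = components
    denom = float(np.mean(c.kernel))
    if denom < 1e-12:
        raise KernelDegeneracyError(
            f"kernel mass at the decision boundary is {denom:.2e}")
    t = (c.a_y * (c.phi_y @ np.asarray(z_y, dtype=float))
         + c.a_z * (c.phi_z @ np.asarray(z_z, dtype=float))
         + c.r_diff * (c.omega_dot @ np.asarray(u, dtype=float)))
    numer = (c.x_behavior * (c.sign_weight * c.kernel)[:, None]).T @ np.abs(t)
    return numer / (c.n * denom)


def _nelder_mead(f, x0: np.ndarray, xatol: float = 1e-6, fatol: float = 1e-6,
                 maxfev: int = 2000) -> tuple[np.ndarray, float, bool]:
    """Minimal Nelder-Mead simplex (standard coefficients).

    Equivalent to the textbook algorithm scipy implements, but without the
    per-call overhead of the generic optimizer machinery — the bootstrap
    performs tens of thousands of these low-dimensional minimizations.
    """
    d = x0.size
    sim = np.empty((d + 1, d))
    sim[0] = x0
    for j in range(d):
        y = x0.copy()
        y[j] = y[j] + 0.05 if y[j] != 0 else 0.00025
        sim[j + 1] = y
    fsim = np.array([f(x) for x in sim])
    nfev = d + 1
    converged = False
    while nfev < maxfev:
        order = np.argsort(fsim, kind="stable")
        sim, fsim = sim[order], fsim[order]
        # the objective is piecewise linear in u, so the function-value
        # spread is the meaningful stopping criterion; requiring the
        # simplex itself to collapse would spend hundreds of extra shrink
        # steps locating an exact kink
        if (np.max(np.abs(fsim[1:] - fsim[0])) <= fatol
                or np.max(np.abs(sim[1:] - sim[0])) <= xatol):
            converged = True
            break
        centroid = sim[:-1].mean(axis=0)
        xr = 2.0 * centroid - sim[-1]
        fr = f(xr); nfev += 1
        if fr < fsim[0]:
            xe = 3.0 * centroid - 2.0 * sim[-1]
            fe = f(xe); nfev += 1
            if fe < fr:
                sim[-1], fsim[-1] = xe, fe
            else:
                sim[-1], fsim[-1] = xr, fr
        elif fr < fsim[-2]:
            sim[-1], fsim[-1] = xr, fr
        else:
            if fr < fsim[-1]:
                xc = centroid + 0.5 * (xr - centroid)   # outside contraction
                fc = f(xc); nfev += 1
                if fc <= fr:
                    sim[-1], fsim[-1] = xc, fc
                    continue
            else:
                xc = centroid + 0.5 * (sim[-1] - centroid)  # inside contraction
                fc = f(xc); nfev += 1
                if fc < fsim[-1]:
                    sim[-1], fsim[-1] = xc, fc
                    continue
            sim[1:] = sim[0] + 0.5 * (sim[1:] - sim[0])     # shrink
            fsim[1:] = [f(x) for x in sim[1:]]
            nfev += d
    j = int(np.argmin(fsim))
    return sim[j], float(fsim[j]), converged


@dataclass
class BootstrapDraw:
    """One realization (U~, B~) approximating sqrt(n)(theta_hat-theta0, beta_hat-beta0)."""

    U: np.ndarray
    B: np.ndarray
    objective: float
    converged: bool


def _minimize_u(components: AsymptoticComponents, z_y: np.ndarray,
                z_z: np.ndarray, scale: float = 5.0,
                maxfev: int = 2000) -> tuple[np.ndarray, float, bool]:
    """Multi-start Nelder-Mead over u for beta' k~(Z_Y, Z_Z, u).

    The objective is piecewise smooth (absolute values of affine pieces),
    so a derivative-free simplex from the origin and four axis-shifted
    starts is used; the best converged solution wins.
    """
    c = components
    beta = c.beta
    # constant per-draw pieces: precompute the Z-part of the perturbation
    t0 = c.a_y * (c.phi_y @ z_y) + c.a_z * (c.phi_z @ z_z)
    m = (c.x_behavior * (c.sign_weight * c.kernel)[:, None]) @ beta
    denom = float(np.mean(c.kernel))
    if denom < 1e-12:
        raise KernelDegeneracyError(
            f"kernel mass at the decision boundary is {denom:.2e}")
    rw = c.r_diff[:, None] * c.omega_dot

    def objective(u: np.ndarray) -> float:
        return float(m @ np.abs(t0 + rw @ u)) / (c.n * denom)

    # degenerate direction guard: when the fitted weights are saturated,
    # omega_dot ~ 0 and the objective is flat in u; the argmin is then
    # ill-posed (the limit theory assumes a unique minimum) and we return
    # the origin rather than letting the simplex wander the plateau
    sens = float(np.abs(m) @ np.linalg.norm(rw, axis=1)) / (c.n * denom)
    base = max(1.0, abs(objective(np.zeros(c.d))))
    if sens < 1e-9 * base:
        return np.zeros(c.d), objective(np.zeros(c.d)), True

    d = c.d
    starts = [np.zeros(d)]
    for j in range(min(2, d)):
        e = np.zeros(d)
        e[j] = scale
        starts.extend([e, -e])
    best_u, best_f, any_ok = None, np.inf, False
    for s in starts:
        x, fval, ok = _nelder_mead(objective, s, maxfev=maxfev)
        if fval < best_f:
            best_u, best_f = x, fval
        any_ok = any_ok or ok
    return best_u, best_f, any_ok


def bootstrap_draw(components: AsymptoticComponents,
                   seed: int | np.random.Generator | None = None) -> BootstrapDraw:
    """Draw Z* ~ N(0, I_r), map through the block root, and solve for (U~, B~)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    c = components
    z_star = rng.standard_normal(c.r)
    z_tilde = c.sigma_root @ z_star
    z_y = z_tilde[: c.q1]
    z_z = z_tilde[c.q1: c.q]
    z_a = z_tilde[c.q:]
    u_hat, f_hat, ok = _minimize_u(c, z_y, z_z)
    b_hat = np.linalg.solve(c.info, z_a - k_tilde(c, z_y, z_z, u_hat))
    return BootstrapDraw(U=u_hat, B=b_hat, objective=f_hat, converged=ok)


@dataclass
class HeterogeneityTest:
    """Bootstrap test of H0: ||theta_(1)|| = 0 (one shared utility weight)."""

    statistic: float
    p_value: float
    reject: bool
    alpha: float
    n_boot: int
    n_flagged: int
    u_norms: np.ndarray = field(repr=False)
    draws_U: np.ndarray = field(repr=False)
    draws_B: np.ndarray = field(repr=False)
    #: bootstrap standard errors of theta_hat components: sd(U~) / sqrt(n)
    theta_se: np.ndarray | None = field(default=None, repr=False)


def heterogeneity_test(data: CohortData, fit: PLVariableFit, q_y: QModel,
                       q_z: QModel, n_boot: int = 1000, alpha: float = 0.05,
                       seed: int | None = None,
                       components: AsymptoticComponents | None = None,
                       max_flagged_fraction: float = 0.05,
                       studentized: bool = False) -> HeterogeneityTest:
    """Level-alpha parametric-bootstrap test for preference heterogeneity.

    The statistic is T = sqrt(n) ||theta_hat_(1)|| (theta with the
    intercept removed); its p-value is the proportion of converged
    bootstrap draws with ||U~_(1)|| >= T.  With ``studentized=True`` each
    slope is first divided by its bootstrap standard deviation, weighting
    the components of the norm by their estimated precision.  Draws whose
    inner minimization fails are excluded and counted; more than
    `max_flagged_fraction` of them aborts the test.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    if components is None:
        components = estimate_components(data, fit, q_y, q_z)
    rng = np.random.default_rng(seed)
    draws_u = np.empty((n_boot, components.d))
    draws_b = np.empty((n_boot, components.beta.size))
    flagged = np.zeros(n_boot, dtype=bool)
    for b in range(n_boot):
        draw = bootstrap_draw(components, rng)
        draws_u[b] = draw.U
        draws_b[b] = draw.B
        flagged[b] = not draw.converged
    n_flagged = int(flagged.sum())
    if n_flagged > max_flagged_fraction * n_boot:
        raise InferenceUnstableError(
            f"{n_flagged}/{n_boot} bootstrap draws failed to converge")
    keep = ~flagged
    u_slopes = draws_u[keep][:, 1:]
    t_slopes = np.sqrt(data.n) * fit.theta[1:]
    if studentized:
        scale = u_slopes.std(axis=0, ddof=1)
        scale = np.where(scale > 0, scale, 1.0)
        u_slopes = u_slopes / scale
        t_slopes = t_slopes / scale
    stat = float(np.linalg.norm(t_slopes))
    u_norms = np.linalg.norm(u_slopes, axis=1)
    p = float(np.mean(u_norms >= stat)) if stat > 0 else 1.0
    return HeterogeneityTest(
        statistic=stat, p_value=p, reject=bool(p <= alpha), alpha=alpha,
        n_boot=n_boot, n_flagged=n_flagged, u_norms=u_norms,
        draws_U=draws_u[keep], draws_B=draws_b[keep],
        theta_se=draws_u[keep].std(axis=0, ddof=1) / np.sqrt(data.n))
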