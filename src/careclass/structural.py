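"""Structural (covariate) models for class membership.

Two-step estimation: the measurement model (pi, tau, rho) is fitted first
without covariates; this module then maximizes the same mixture likelihood
over the logistic membership coefficients only, holding the item-response
probabilities rho fixed.  Country-class membership follows a multinomial
logistic model in country covariates Z1; within each country class m,
individual-class membership follows its own multinomial logistic model in
individual covariates Z2 (coefficients are NOT pooled across m — the
published odds-ratio tables are stratified by country class).

The reference category is always the LAST canonical class (the
suboptimal-utilizer / low-coverage class), so positive coefficients mean
higher odds of optimal utilization or high coverage.

Also provided: a random-intercept logistic regression fitted by adaptive
Gauss-Hermite quadrature, and the ICC / median-odds-ratio summaries of its
intercept variance.

Standard errors here ignore step-1 (measurement) uncertainty — the naive
two-step variance; a country-level nonparametric bootstrap is available as
the conservative alternative.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp, expit
from scipy import stats

from .measurement import IndicatorMatrix, MeasurementParams, _record_class_loglik

SEPARATION_LIMIT = 15.0   # |coef| beyond this on the logit scale flags separation


# ---------------------------------------------------------------------------
# weighted multinomial logistic Newton solver (fractional responses allowed)

def _mnl_probs(X: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Class probabilities with reference class last: beta is (C-1, p)."""
    eta = np.column_stack([X @ beta.T, np.zeros(X.shape[0])])
    eta -= eta.max(axis=1, keepdims=True)
    e = np.exp(eta)
    return e / e.sum(axis=1, keepdims=True)


def fit_weighted_multinomial(X: np.ndarray, Y: np.ndarray,
                             sample_weight: np.ndarray | None = None,
                             ridge: float = 1e-6, tol: float = 1e-10,
                             max_iter: int = 100):
    """Newton-Raphson fit of a multinomial logit with fractional targets.

    X: n x p design (include the intercept column yourself).  Y: n x C
    nonnegative class weights per row (rows need not sum to 1; posterior
    masses are fine).  The last class is the reference.  A small ridge
    stabilizes the Hessian; coefficients with |b| > 15 are flagged as
    separated.

    Returns (beta (C-1, p), vcov ((C-1)p x (C-1)p), converged, separated).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    n, p = X.shape
    C = Y.shape[1]
    w = np.ones(n) if sample_weight is None else np.asarray(sample_weight, dtype=float)
    row_tot = Y.sum(axis=1)
    beta = np.zeros((C - 1, p))
    converged = False
    for _ in range(max_iter):
        P = _mnl_probs(X, beta)
        grad = np.empty((C - 1, p))
        for c in range(C - 1):
            grad[c] = X.T @ (w * (Y[:, c] - row_tot * P[:, c]))
        g = grad.ravel()
        Hess = np.empty(((C - 1) * p, (C - 1) * p))
        for c in range(C - 1):
            for d in range(C - 1):
                wcd = w * row_tot * P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
                Hess[c * p:(c + 1) * p, d * p:(d + 1) * p] = -(X.T * wcd) @ X
        Hess -= ridge * np.eye((C - 1) * p)
        step = np.linalg.solve(Hess, g)
        beta = beta - step.reshape(C - 1, p)
        if np.max(np.abs(g)) < tol * (1.0 + np.abs(w @ row_tot)) or np.max(np.abs(step)) < 1e-12:
            converged = True
            break
    P = _mnl_probs(X, beta)
    Hess = np.empty(((C - 1) * p, (C - 1) * p))
    for c in range(C - 1):
        for d in range(C - 1):
            wcd = w * row_tot * P[:, c] * ((1.0 if c == d else 0.0) - P[:, d])
            Hess[c * p:(c + 1) * p, d * p:(d + 1) * p] = -(X.T * wcd) @ X
    vcov = np.linalg.pinv(-Hess + ridge * np.eye((C - 1) * p))
    separated = bool(np.any(np.abs(beta) > SEPARATION_LIMIT))
    return beta, vcov, converged, separated


# ---------------------------------------------------------------------------
# two-step structural EM

@dataclass
class StructuralParams:
    """Membership-model coefficients with the measurement model held fixed.

    alpha: (M-1) x P1 country-level coefficients (reference class M-1).
    gamma: length-M list of (K-1) x P2 individual-level coefficients
    (reference class K-1), one block per country class.
    """

    alpha: np.ndarray
    gamma: list[np.ndarray]
    alpha_vcov: np.ndarray
    gamma_vcov: list[np.ndarray]
    alpha_names: list[str]
    gamma_names: list[str]
    loglik: float
    n_iter: int
    converged: bool
    separated: bool = False

    @property
    def M(self) -> int:
        return self.alpha.shape[0] + 1

    @property
    def K(self) -> int:
        return self.gamma[0].shape[0] + 1


def _with_intercept(Z: np.ndarray | pd.DataFrame | None, n: int):
    if Z is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(Z, pd.DataFrame):
        names = ["intercept"] + [str(c) for c in Z.columns]
        return np.column_stack([np.ones(len(Z)), Z.to_numpy(dtype=float)]), names
    Z = np.asarray(Z, dtype=float)
    if Z.ndim == 1:
        Z = Z[:, None]
    return np.column_stack([np.ones(Z.shape[0]), Z]), \
        ["intercept"] + [f"x{i+1}" for i in range(Z.shape[1])]


def _structural_loglik(data: IndicatorMatrix, rho: np.ndarray,
                       alpha: np.ndarray, gamma: list[np.ndarray],
                       Z1: np.ndarray, Z2: np.ndarray):
    """Mixture log-likelihood with covariate-dependent memberships, plus
    posterior blocks (group_post, joint)."""
    M = alpha.shape[0] + 1
    L = _record_class_loglik(data, rho)                      # N x K
    pi_j = _mnl_probs(Z1, alpha)                             # J x M
    log_a = np.empty((data.n_records, M))
    log_cond = []
    for m in range(M):
        tau_i = _mnl_probs(Z2, gamma[m])                     # N x K
        lt = np.log(np.clip(tau_i, 1e-300, None)) + L
        la = logsumexp(lt, axis=1)
        log_a[:, m] = la
        log_cond.append(lt - la[:, None])
    J = data.n_groups
    group_ll = np.zeros((J, M))
    np.add.at(group_ll, data.group_index, data.weights[:, None] * log_a)
    log_num = np.log(np.clip(pi_j, 1e-300, None)) + group_ll
    log_norm = logsumexp(log_num, axis=1)
    ll = float(log_norm.sum())
    group_post = np.exp(log_num - log_norm[:, None])
    joint = np.stack([group_post[data.group_index, m, None] * np.exp(log_cond[m])
                      for m in range(M)], axis=1)            # N x M x K
    return ll, group_post, joint


def fit_two_step(data: IndicatorMatrix, fixed: MeasurementParams,
                 Z1: np.ndarray | pd.DataFrame | None = None,
                 Z2: np.ndarray | pd.DataFrame | None = None,
                 tol: float = 1e-8, max_iter: int = 200,
                 ridge: float = 1e-6) -> StructuralParams:
    """Step-2 maximization over (alpha, gamma) with rho fixed.

    EM alternates posterior computation (E) with posterior-weighted
    multinomial logistic fits (M): the country-level fit uses group
    posteriors P_jm as fractional responses; each individual-level fit for
    country class m uses the joint posterior mass on (m, k), multiplied by
    the record weight.  The Wald covariance is the inverse numerical observed
    information of the step-2 likelihood at the optimum.

    With intercept-only designs this is a reparameterization of (pi, tau) and
    reproduces the measurement-model membership probabilities exactly.
    """
    M, K = fixed.M, fixed.K
    X1, names1 = _with_intercept(Z1, data.n_groups)
    X2, names2 = _with_intercept(Z2, data.n_records)
    if X1.shape[0] != data.n_groups:
        raise ValueError("Z1 must have one row per group")
    if X2.shape[0] != data.n_records:
        raise ValueError("Z2 must have one row per record")
    # warm start from the measurement proportions (covariate slopes at 0)
    alpha = np.zeros((M - 1, X1.shape[1]))
    alpha[:, 0] = np.log(fixed.pi[:-1] / fixed.pi[-1])
    gamma = []
    for m in range(M):
        g = np.zeros((K - 1, X2.shape[1]))
        g[:, 0] = np.log(fixed.tau[m, :-1] / fixed.tau[m, -1])
        gamma.append(g)

    prev = -np.inf
    converged = False
    separated = False
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        ll, group_post, joint = _structural_loglik(data, fixed.rho, alpha, gamma, X1, X2)
        alpha, _, _, sep_a = fit_weighted_multinomial(X1, group_post, ridge=ridge)
        separated = separated or sep_a
        new_gamma = []
        for m in range(M):
            Ym = data.weights[:, None] * joint[:, m, :]
            g, _, _, sep_g = fit_weighted_multinomial(X2, Ym, ridge=ridge)
            separated = separated or sep_g
            new_gamma.append(g)
        gamma = new_gamma
        if np.isfinite(prev) and ll - prev <= tol * (abs(prev) + 1.0):
            converged = True
            break
        prev = ll
    ll, _, _ = _structural_loglik(data, fixed.rho, alpha, gamma, X1, X2)

    # observed information of the step-2 likelihood by central differences
    p1, p2 = X1.shape[1], X2.shape[1]
    def pack(a, gs):
        return np.concatenate([a.ravel()] + [g.ravel() for g in gs])

    def unpack(theta):
        a = theta[:(M - 1) * p1].reshape(M - 1, p1)
        gs, off = [], (M - 1) * p1
        for _ in range(M):
            gs.append(theta[off:off + (K - 1) * p2].reshape(K - 1, p2))
            off += (K - 1) * p2
        return a, gs

    def f(theta):
        a, gs = unpack(theta)
        return _structural_loglik(data, fixed.rho, a, gs, X1, X2)[0]

    theta0 = pack(alpha, gamma)
    d = theta0.size
    eps = 1e-4
    Hess = np.empty((d, d))
    f0 = f(theta0)
    fp = np.empty(d)
    fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = eps
        fp[i] = f(theta0 + e)
        fm[i] = f(theta0 - e)
        Hess[i, i] = (fp[i] - 2 * f0 + fm[i]) / eps ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            fpp = f(theta0 + ei + ej)
            Hess[i, j] = Hess[j, i] = (fpp - fp[i] - fp[j] + f0) / eps ** 2
    vcov = np.linalg.pinv(-Hess)
    # slice into blocks
    na = (M - 1) * p1
    alpha_vcov = vcov[:na, :na]
    gamma_vcov, off = [], na
    for _ in range(M):
        nb = (K - 1) * p2
        gamma_vcov.append(vcov[off:off + nb, off:off + nb])
        off += nb
    return StructuralParams(alpha=alpha, gamma=gamma, alpha_vcov=alpha_vcov,
                            gamma_vcov=gamma_vcov, alpha_names=names1,
                            gamma_names=names2, loglik=ll, n_iter=n_iter,
                            converged=converged, separated=separated)


def odds_ratio_table(params: StructuralParams, level: float = 0.95,
                     class_labels: dict | None = None) -> pd.DataFrame:
    """Adjusted odds ratios exp(coef) with Wald CIs exp(coef +/- z SE).

    One row per non-reference class and covariate, at both levels; the
    individual-level rows are stratified by country class.  Reference rows
    are implicit (AOR = 1).
    """
    z = stats.norm.ppf(0.5 + level / 2)
    rows = []
    M, K = params.M, params.K
    p1 = len(params.alpha_names)
    se_a = np.sqrt(np.clip(np.diag(params.alpha_vcov), 0, None)).reshape(M - 1, p1)
    for m in range(M - 1):
        for j, name in enumerate(params.alpha_names):
            b, s = params.alpha[m, j], se_a[m, j]
            rows.append({"level": "country", "stratum": "", "class": m,
                         "covariate": name, "coef": b, "SE": s,
                         "AOR": np.exp(b), "CI_low": np.exp(b - z * s),
                         "CI_high": np.exp(b + z * s),
                         "p": 2 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan})
    p2 = len(params.gamma_names)
    for m in range(M):
        se_g = np.sqrt(np.clip(np.diag(params.gamma_vcov[m]), 0, None)).reshape(K - 1, p2)
        stratum = (class_labels or {}).get(m, f"country_class_{m}")
        for k in range(K - 1):
            for j, name in enumerate(params.gamma_names):
                b, s = params.gamma[m][k, j], se_g[k, j]
                rows.append({"level": "individual", "stratum": stratum, "class": k,
                             "covariate": name, "coef": b, "SE": s,
                             "AOR": np.exp(b), "CI_low": np.exp(b - z * s),
                             "CI_high": np.exp(b + z * s),
                             "p": 2 * stats.norm.sf(abs(b) / s) if s > 0 else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# random-intercept logistic regression (adaptive Gauss-Hermite)

@dataclass
class RandomInterceptSummary:
    sigma2: float
    sigma2_ci: tuple[float, float]
    icc: float
    mor: float
    beta: np.ndarray
    beta_se: np.ndarray
    beta_names: list[str]
    loglik: float
    converged: bool
    boundary: bool = False

    def fixed_effects_table(self, level: float = 0.95) -> pd.DataFrame:
        z = stats.norm.ppf(0.5 + level / 2)
        return pd.DataFrame({
            "covariate": self.beta_names,
            "coef": self.beta, "SE": self.beta_se,
            "AOR": np.exp(self.beta),
            "CI_low": np.exp(self.beta - z * self.beta_se),
            "CI_high": np.exp(self.beta + z * self.beta_se),
            "p": 2 * stats.norm.sf(np.abs(self.beta) / np.where(self.beta_se > 0, self.beta_se, np.inf)),
        })


def mor_icc(sigma2: float) -> tuple[float, float]:
    """Latent-scale intraclass correlation and median odds ratio.

    ICC = sigma2 / (sigma2 + pi^2/3) — the share of logit-scale variance
    between groups, using the standard-logistic residual variance pi^2/3.
    MOR = exp(sqrt(2 sigma2) * Phi^-1(0.75)) — the median odds ratio between
    two identical individuals in randomly ordered distinct groups.
    """
    if sigma2 < 0:
        raise ValueError("variance must be nonnegative")
    icc = sigma2 / (sigma2 + np.pi ** 2 / 3)
    mor = float(np.exp(np.sqrt(2 * sigma2) * stats.norm.ppf(0.75)))
    return float(icc), mor


def _aghq_group_loglik(eta: np.ndarray, y: np.ndarray, w: np.ndarray,
                       group_index: np.ndarray, J: int,
                       sigma: float, nodes: np.ndarray, weights: np.ndarray) -> float:
    """Marginal log-likelihood summed over groups, by adaptive Gauss-Hermite.

    Per group the integral over the random intercept b ~ N(0, sigma^2) is
    centered at the posterior mode (found by a vectorized Newton iteration
    across groups) and scaled by the curvature there.
    """
    if sigma < 1e-8:
        ll = w * (y * eta - np.logaddexp(0.0, eta))
        out = np.zeros(J)
        np.add.at(out, group_index, ll)
        return float(out.sum())
    b = np.zeros(J)
    for _ in range(50):
        mu = expit(eta + b[group_index])
        g1 = np.zeros(J)
        np.add.at(g1, group_index, w * (y - mu))
        g1 -= b / sigma ** 2
        g2 = np.zeros(J)
        np.add.at(g2, group_index, w * mu * (1 - mu))
        g2 += 1.0 / sigma ** 2
        step = g1 / g2
        b += step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu = expit(eta + b[group_index])
    h = np.zeros(J)
    np.add.at(h, group_index, w * mu * (1 - mu))
    h += 1.0 / sigma ** 2                      # curvature of -log integrand
    scale = np.sqrt(2.0 / h)                   # J
    # evaluate log integrand at shifted/scaled nodes
    B = b[:, None] + scale[:, None] * nodes[None, :]          # J x Q
    per_rec = np.zeros((J, len(nodes)))
    eb = eta[:, None] + B[group_index]                         # N x Q
    contrib = w[:, None] * (y[:, None] * eb - np.logaddexp(0.0, eb))
    np.add.at(per_rec, group_index, contrib)
    log_prior = -0.5 * np.log(2 * np.pi * sigma ** 2) - B ** 2 / (2 * sigma ** 2)
    log_f = per_rec + log_prior + nodes[None, :] ** 2 + np.log(weights)[None, :]
    ll_j = np.log(scale) + logsumexp(log_f, axis=1)
    return float(ll_j.sum())


def fit_random_intercept_logistic(y: np.ndarray, groups: np.ndarray,
                                  X: np.ndarray | pd.DataFrame | None = None,
                                  weights: np.ndarray | None = None,
                                  n_quad: int = 15,
                                  level: float = 0.95) -> RandomInterceptSummary:
    """Random-intercept logistic regression by adaptive Gauss-Hermite
    quadrature (default 15 nodes), maximizing over fixed effects and
    log(sigma) with BFGS.

    Returns the intercept variance sigma^2 with a Wald CI on the log-variance
    scale, the derived ICC and MOR, and the fixed-effect table.  sigma^2
    estimates below 1e-4 are flagged as boundary solutions.
    """
    from scipy.optimize import minimize
    from numpy.polynomial.hermite import hermgauss

    y = np.asarray(y, dtype=float)
    n = len(y)
    labels, gidx = np.unique(np.asarray(groups), return_inverse=True)
    J = len(labels)
    if J < 2:
        raise ValueError("need at least 2 groups")
    Xd, names = _with_intercept(X, n)
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    nodes, qw = hermgauss(n_quad)

    def negll(theta):
        beta, log_sigma = theta[:-1], theta[-1]
        sigma = np.exp(log_sigma)
        eta = Xd @ beta
        return -_aghq_group_loglik(eta, y, w, gidx, J, sigma, nodes, qw)

    # start from a plain logistic fit and a modest variance
    beta0, _, _, _ = fit_weighted_multinomial(Xd, np.column_stack([y, 1 - y]), sample_weight=w)
    theta0 = np.concatenate([beta0.ravel(), [np.log(0.5)]])
    res = minimize(negll, theta0, method="BFGS",
                   options={"gtol": 1e-6, "maxiter": 500})
    # BFGS can report precision loss at the optimum; accept a flat gradient
    grad_ok = np.max(np.abs(res.jac)) < 1e-3 * (1.0 + abs(res.fun))
    beta = res.x[:-1]
    sigma = float(np.exp(res.x[-1]))
    sigma2 = sigma ** 2
    # numerical Hessian at the optimum for Wald SEs
    d = len(res.x)
    eps = 1e-4
    H = np.empty((d, d))
    f0 = negll(res.x)
    fp = np.empty(d); fm = np.empty(d)
    for i in range(d):
        e = np.zeros(d); e[i] = eps
        fp[i] = negll(res.x + e); fm[i] = negll(res.x - e)
        H[i, i] = (fp[i] - 2 * f0 + fm[i]) / eps ** 2
    for i in range(d):
        for j in range(i + 1, d):
            ei = np.zeros(d); ei[i] = eps
            ej = np.zeros(d); ej[j] = eps
            H[i, j] = H[j, i] = (negll(res.x + ei + ej) - fp[i] - fp[j] + f0) / eps ** 2
    cov = np.linalg.pinv(H)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    z = stats.norm.ppf(0.5 + level / 2)
    # CI for sigma2 from the log-sigma scale: log sigma2 = 2 log sigma
    se_log_s2 = 2 * se[-1]
    ci = (sigma2 * np.exp(-z * se_log_s2), sigma2 * np.exp(z * se_log_s2))
    icc, mor = mor_icc(sigma2)
    return RandomInterceptSummary(
        sigma2=sigma2, sigma2_ci=(float(ci[0]), float(ci[1])), icc=icc, mor=mor,
        beta=beta, beta_se=se[:-1], beta_names=names,
        loglik=-float(res.fun), converged=bool(res.success or grad_ok),
        boundary=sigma2 < 1e-4,
    )
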