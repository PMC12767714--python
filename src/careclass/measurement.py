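"""Two-level latent class measurement model estimated by EM.

The model groups women (lower level, K classes ``C_i``) nested in countries
(higher level, M classes ``W_j``).  Conditional on a woman's class, the H
binary service indicators are independent Bernoulli draws with item-response
probabilities ``rho[k, h]``; conditional on a country's class, women's class
memberships are iid with probabilities ``tau[m, k]``; country classes are iid
with probabilities ``pi[m]``.  The marginal likelihood of a country's data is

    P(y_j) = sum_m pi_m  prod_{i in j}  sum_k tau_{k|m} prod_h Bern(y_ijh; rho_hk)

All mixture sums are evaluated in log space (log-sum-exp over k per record and
over m per group).  Missing indicator cells contribute no likelihood factor,
which is valid when missingness is at random given the latent class.
Record weights enter as frequency weights on log-likelihood contributions and
on M-step sufficient statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import logsumexp

RHO_CLIP = (1e-6, 1.0 - 1e-6)


@dataclass
class IndicatorMatrix:
    """N x H binary service-receipt matrix with group structure.

    Parameters
    ----------
    values : ndarray, shape (N, H)
        Float array with entries in {0, 1, nan}; nan marks a missing cell.
    group_ids : ndarray, shape (N,)
        Group (country) label per record; any hashable labels, factorized
        internally to a contiguous 0..J-1 index.
    weights : ndarray, shape (N,), optional
        Positive per-record frequency weights; default all ones.
    indicator_names : list of str, optional
    """

    values: np.ndarray
    group_ids: np.ndarray
    weights: np.ndarray | None = None
    indicator_names: list[str] | None = None
    # populated in __post_init__
    group_index: np.ndarray = field(init=False, repr=False)
    group_labels: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D array")
        n = self.values.shape[0]
        observed = ~np.isnan(self.values)
        if not np.isin(self.values[observed], (0.0, 1.0)).all():
            raise ValueError("indicator entries must be 0, 1 or missing (nan)")
        gid = np.asarray(self.group_ids)
        if gid.shape != (n,):
            raise ValueError("group_ids length must match number of records")
        labels, index = np.unique(gid, return_inverse=True)
        self.group_labels = labels
        self.group_index = index.astype(np.intp)
        if self.weights is None:
            self.weights = np.ones(n)
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (n,) or (self.weights <= 0).any():
            raise ValueError("weights must be positive, one per record")
        if self.indicator_names is not None and len(self.indicator_names) != self.H:
            raise ValueError("indicator_names length must equal H")

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def H(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.group_labels)


@dataclass
class MeasurementParams:
    """Probability blocks of the two-level mixture.

    pi[m] = P(W_j = m); tau[m, k] = P(C_i = k | W_j = m);
    rho[k, h] = P(y_ih = 1 | C_i = k).
    """

    pi: np.ndarray
    tau: np.ndarray
    rho: np.ndarray

    def __post_init__(self) -> None:
        self.pi = np.asarray(self.pi, dtype=float)
        self.tau = np.asarray(self.tau, dtype=float)
        self.rho = np.asarray(self.rho, dtype=float)
        if self.pi.ndim != 1 or self.tau.ndim != 2 or self.rho.ndim != 2:
            raise ValueError("pi must be 1-D; tau and rho 2-D")
        if self.tau.shape != (self.M, self.K):
            raise ValueError("tau must have shape (M, K)")
        if self.rho.shape[0] != self.K:
            raise ValueError("rho must have shape (K, H)")
        if not np.isclose(self.pi.sum(), 1.0, atol=1e-10):
            raise ValueError("pi must sum to 1")
        if not np.allclose(self.tau.sum(axis=1), 1.0, atol=1e-10):
            raise ValueError("each tau row must sum to 1")
        if ((self.rho < 0) | (self.rho > 1)).any():
            raise ValueError("rho entries must lie in [0, 1]")
        self.rho = np.clip(self.rho, *RHO_CLIP)

    @property
    def M(self) -> int:
        return self.pi.shape[0]

    @property
    def K(self) -> int:
        return self.tau.shape[1]

    @property
    def H(self) -> int:
        return self.rho.shape[1]

    @property
    def n_params(self) -> int:
        return (self.M - 1) + self.M * (self.K - 1) + self.K * self.H


@dataclass
class PosteriorSet:
    """Posterior class probabilities and MAP assignments at both levels."""

    group_post: np.ndarray      # J x M
    joint_post: np.ndarray      # N x M x K
    indiv_post: np.ndarray      # N x K, marginal over m
    map_group: np.ndarray       # J, argmax with ties to the lower index
    map_indiv: np.ndarray       # N

    @property
    def K(self) -> int:
        return self.indiv_post.shape[1]

    @property
    def M(self) -> int:
        return self.group_post.shape[1]


@dataclass
class FitResult:
    params: MeasurementParams
    posteriors: PosteriorSet
    loglik: float
    n_iter: int
    converged: bool
    best_of: int
    seed: int | None
    loglik_path: np.ndarray | None = None


def _record_class_loglik(data: IndicatorMatrix, rho: np.ndarray) -> np.ndarray:
    """log P(y_i | C_i = k) as an N x K matrix; missing cells contribute 0."""
    y = data.values
    obs = ~np.isnan(y)
    y0 = np.where(obs, y, 0.0)
    log_rho = np.log(rho)            # K x H
    log_1mrho = np.log1p(-rho)
    # N x K: sum over observed h of y*log rho + (1-y)*log(1-rho)
    return (y0 * obs) @ log_rho.T + ((1.0 - y0) * obs) @ log_1mrho.T


def _estep(data: IndicatorMatrix, params: MeasurementParams):
    """E-step quantities and the weighted log-likelihood.

    Returns (loglik, group_post JxM, joint NxMxK, cond NxMxK) where cond is
    P(C_i = k | W = m, y_i).
    """
    L = _record_class_loglik(data, params.rho)                 # N x K
    log_tau = np.log(np.clip(params.tau, 1e-300, None))        # M x K
    # per record, per m: log sum_k tau_{k|m} f(y_i|k)
    log_a = logsumexp(L[:, None, :] + log_tau[None, :, :], axis=2)   # N x M
    log_cond = L[:, None, :] + log_tau[None, :, :] - log_a[:, :, None]
    J, M = data.n_groups, params.M
    group_ll = np.zeros((J, M))
    np.add.at(group_ll, data.group_index, data.weights[:, None] * log_a)
    log_num = np.log(np.clip(params.pi, 1e-300, None))[None, :] + group_ll
    log_norm = logsumexp(log_num, axis=1)
    loglik = float(log_norm.sum())
    group_post = np.exp(log_num - log_norm[:, None])
    joint = group_post[data.group_index, :, None] * np.exp(log_cond)
    return loglik, group_post, joint, np.exp(log_cond)


def loglik(data: IndicatorMatrix, params: MeasurementParams) -> float:
    """Weighted marginal log-likelihood of the data under ``params``."""
    if params.H != data.H:
        raise ValueError("indicator count mismatch between data and params")
    return _estep(data, params)[0]


def compute_posteriors(data: IndicatorMatrix, params: MeasurementParams) -> PosteriorSet:
    """Bayes-rule posteriors at both levels plus MAP assignments.

    The joint posterior over (m, k) for record i factorizes as
    P(W=m | all data in i's group) * P(C_i=k | W=m, y_i); the marginal
    individual posterior sums the joint over m.  MAP ties break toward the
    lower class index.
    """
    _, group_post, joint, _ = _estep(data, params)
    indiv = joint.sum(axis=1)
    return PosteriorSet(
        group_post=group_post,
        joint_post=joint,
        indiv_post=indiv,
        map_group=np.argmax(group_post, axis=1),
        map_indiv=np.argmax(indiv, axis=1),
    )


def _mstep(data: IndicatorMatrix, group_post: np.ndarray, joint: np.ndarray) -> MeasurementParams:
    w = data.weights
    # each country counts once: pi is the share of countries in class m
    pi = group_post.mean(axis=0)
    wj = w[:, None, None] * joint                              # N x M x K
    tau_num = wj.sum(axis=0)                                   # M x K
    tau = tau_num / np.clip(tau_num.sum(axis=1, keepdims=True), 1e-300, None)
    indiv = joint.sum(axis=1)                                  # N x K
    obs = ~np.isnan(data.values)
    y0 = np.where(obs, data.values, 0.0)
    wk = w[:, None] * indiv                                    # N x K
    num = wk.T @ (y0 * obs)                                    # K x H
    den = wk.T @ obs.astype(float)
    rho = np.clip(num / np.clip(den, 1e-300, None), *RHO_CLIP)
    return MeasurementParams(pi=pi / pi.sum(), tau=tau, rho=rho)


def canonicalize(params: MeasurementParams) -> MeasurementParams:
    """Order classes deterministically for reporting and comparison.

    Lower-level classes sort by descending mean item probability (the first
    class is the "optimal utilizers"); ties break on the first indicator.
    Higher-level classes then sort by descending tau[., optimal] (the first is
    "high coverage").
    """
    key = np.round(params.rho.mean(axis=1), 12)
    order_k = np.lexsort((-params.rho[:, 0], -key))
    tau = params.tau[:, order_k]
    rho = params.rho[order_k]
    key_m = np.round(tau[:, 0], 12)
    order_m = np.lexsort((-params.pi, -key_m))
    return MeasurementParams(pi=params.pi[order_m], tau=tau[order_m], rho=rho)


def _random_init(data: IndicatorMatrix, K: int, M: int, rng: np.random.Generator) -> MeasurementParams:
    obs = ~np.isnan(data.values)
    y0 = np.where(obs, data.values, 0.0)
    w = data.weights[:, None] * obs
    means = (data.weights[:, None] * y0 * obs).sum(axis=0) / np.clip(w.sum(axis=0), 1e-12, None)
    rho = np.clip(means[None, :] + rng.uniform(-0.3, 0.3, size=(K, data.H)), 0.02, 0.98)
    pi = rng.dirichlet(np.ones(M) * 2.0)
    tau = rng.dirichlet(np.ones(K) * 2.0, size=M)
    return MeasurementParams(pi=pi, tau=tau, rho=rho)


def fit_measurement(
    data: IndicatorMatrix,
    K: int,
    M: int,
    n_starts: int = 20,
    tol: float = 1e-8,
    max_iter: int = 1000,
    seed: int | None = None,
    canonical: bool = True,
) -> FitResult:
    """Maximum-likelihood fit of the measurement model by multi-start EM.

    EM alternates posterior computation (E) with closed-form weighted updates
    of pi, tau, rho (M); the weighted log-likelihood is non-decreasing every
    iteration.  The best of ``n_starts`` random initializations is returned,
    with classes canonically ordered (optimal utilizers first, high-coverage
    countries first) unless ``canonical=False``.

    ``tol`` is the relative log-likelihood change declaring convergence.
    """
    if K < 1 or M < 1:
        raise ValueError("K and M must be >= 1")
    if data.n_records < K:
        raise ValueError("need at least K records")
    rng = np.random.default_rng(seed)
    best: tuple[float, MeasurementParams, int, bool, np.ndarray] | None = None
    for _ in range(n_starts):
        params = _random_init(data, K, M, rng)
        prev = -np.inf
        path = []
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            ll, group_post, joint, _ = _estep(data, params)
            path.append(ll)
            params = _mstep(data, group_post, joint)
            if np.isfinite(prev) and ll - prev <= tol * (abs(prev) + 1.0):
                converged = True
                break
            prev = ll
        ll = loglik(data, params)
        path.append(ll)
        if best is None or ll > best[0]:
            best = (ll, params, n_iter, converged, np.array(path))
    assert best is not None
    ll, params, n_iter, converged, path = best
    if canonical:
        params = canonicalize(params)
    posteriors = compute_posteriors(data, params)
    return FitResult(
        params=params,
        posteriors=posteriors,
        loglik=ll,
        n_iter=n_iter,
        converged=converged,
        best_of=n_starts,
        seed=seed,
        loglik_path=path,
    )


def summarize_classes(posteriors: PosteriorSet, weights: np.ndarray | None = None,
                      group_labels: np.ndarray | None = None):
    """Class-proportion tables from fitted posteriors.

    Returns a dict with:

    - ``higher_shares``: length-M posterior-mean share of countries per class;
    - ``conditional_shares``: M x K posterior-weighted share of women in each
      lower class given the country class (the Table-3 analog);
    - ``overall_lower_shares``: length-K weighted marginal shares;
    - ``group_assignments``: per-group MAP class listing.
    """
    import pandas as pd

    n = posteriors.indiv_post.shape[0]
    w = np.ones(n) if weights is None else np.asarray(weights, dtype=float)
    higher = posteriors.group_post.mean(axis=0)
    wj = w[:, None, None] * posteriors.joint_post
    cond_num = wj.sum(axis=0)
    cond = cond_num / np.clip(cond_num.sum(axis=1, keepdims=True), 1e-300, None)
    overall = (w[:, None] * posteriors.indiv_post).sum(axis=0) / w.sum()
    labels = (np.arange(posteriors.group_post.shape[0])
              if group_labels is None else np.asarray(group_labels))
    assignments = pd.DataFrame({
        "group": labels,
        "map_class": posteriors.map_group,
        **{f"P_m{m}": posteriors.group_post[:, m] for m in range(posteriors.M)},
    })
    return {
        "higher_shares": higher,
        "conditional_shares": cond,
        "overall_lower_shares": overall,
        "group_assignments": assignments,
    }


def align_to(reference: MeasurementParams, params: MeasurementParams) -> MeasurementParams:
    """Permute classes of ``params`` to best match ``reference`` (min rho RMSE)."""
    from itertools import permutations

    best = None
    for pk in permutations(range(params.K)):
        rho = params.rho[list(pk)]
        cost_k = np.mean((rho - reference.rho) ** 2)
        for pm in permutations(range(params.M)):
            tau = params.tau[np.ix_(list(pm), list(pk))]
            cost = cost_k + np.mean((tau - reference.tau) ** 2) + np.mean(
                (params.pi[list(pm)] - reference.pi) ** 2)
            if best is None or cost < best[0]:
                best = (cost, MeasurementParams(pi=params.pi[list(pm)], tau=tau, rho=rho))
    assert best is not None
    return best[1]
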