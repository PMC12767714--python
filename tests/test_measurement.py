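"""Measurement-model likelihood, EM, posteriors, and class summaries.

The brute-force oracle below maximizes the K=2, M=1 mixture likelihood by
lattice search over (tau, rho): a 0.05-step sweep of the four rho entries
(with the mixture weight on a 0.01 grid) followed by a 0.01-step local
refinement around the incumbent.  It shares no code with the EM path.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from careclass import (IndicatorMatrix, MeasurementParams, loglik,
                       fit_measurement, compute_posteriors, summarize_classes,
                       canonicalize, align_to, PUBLISHED_PI, PUBLISHED_TAU)


def _mat(values, groups=None, weights=None):
    values = np.asarray(values, dtype=float)
    if groups is None:
        groups = np.zeros(len(values), dtype=int)
    return IndicatorMatrix(values=values, group_ids=np.asarray(groups), weights=weights)


# ---------------------------------------------------------------------------
# brute-force lattice oracle (independent of the EM implementation)

def grid_oracle_loglik(values: np.ndarray) -> float:
    """Maximized K=2, M=1 log-likelihood over a (tau, rho) lattice."""
    values = np.asarray(values, dtype=float)
    patterns, counts = np.unique(values, axis=0, return_counts=True)

    def pattern_lik(rho_grid):
        # (G, H) rho combos -> (G, P) likelihood per pattern
        lik = np.ones((rho_grid.shape[0], len(patterns)))
        for h in range(patterns.shape[1]):
            y = patterns[:, h]
            lik *= np.where(y[None, :] == 1, rho_grid[:, h][:, None],
                            1 - rho_grid[:, h][:, None])
        return lik

    def combos_from(per_dim_vals):
        grids = np.meshgrid(*per_dim_vals, indexing="ij")
        return np.column_stack([g.ravel() for g in grids])

    def search(combos1, combos2, tau_vals):
        lik1 = pattern_lik(np.clip(combos1, 1e-6, 1 - 1e-6))        # G1 x P
        lik2 = pattern_lik(np.clip(combos2, 1e-6, 1 - 1e-6))        # G2 x P
        best = (-np.inf, None)
        for t in tau_vals:
            mix = t * lik1[:, None, :] + (1 - t) * lik2[None, :, :]
            ll = (counts[None, None, :] * np.log(np.clip(mix, 1e-300, None))).sum(axis=2)
            i = np.unravel_index(np.argmax(ll), ll.shape)
            if ll[i] > best[0]:
                best = (ll[i], (t, combos1[i[0]], combos2[i[1]]))
        return best

    H = values.shape[1]
    coarse_combos = combos_from([np.arange(0.0, 1.0001, 0.05)] * H)
    taus = np.arange(0.0, 1.0001, 0.01)
    coarse, (t0, r1, r2) = search(coarse_combos, coarse_combos, taus)
    fine1 = combos_from([np.clip(np.arange(v - 0.05, v + 0.0501, 0.01), 0, 1)
                         for v in r1])
    fine2 = combos_from([np.clip(np.arange(v - 0.05, v + 0.0501, 0.01), 0, 1)
                         for v in r2])
    refined, _ = search(fine1, fine2, taus)
    return max(coarse, refined)


def test_em_matches_grid_oracle_on_tiny_instances():
    """On <= 8 records the EM maximum is at least the lattice optimum - 1e-4."""
    rng = np.random.default_rng(0)
    for trial in range(3):
        values = rng.binomial(1, 0.5, size=(6, 2)).astype(float)
        groups = np.repeat([0, 1], 3)
        data = _mat(values, groups)
        fit = fit_measurement(data, K=2, M=1, n_starts=40, seed=trial, tol=1e-12)
        oracle = grid_oracle_loglik(values)
        assert fit.loglik >= oracle - 1e-4
        assert abs(fit.loglik - oracle) < 0.02   # lattice resolution slack


# ---------------------------------------------------------------------------
# log-likelihood closed forms

def test_loglik_single_bernoulli():
    data = _mat([[1.0]])
    params = MeasurementParams(pi=[1.0], tau=[[1.0]], rho=[[0.7]])
    assert loglik(data, params) == pytest.approx(np.log(0.7), abs=1e-10)


def test_loglik_symmetric_mixture():
    data = _mat([[1.0]])
    params = MeasurementParams(pi=[1.0], tau=[[0.5, 0.5]], rho=[[0.9], [0.1]])
    assert loglik(data, params) == pytest.approx(np.log(0.5), abs=1e-10)


def test_loglik_collapses_when_tau_rows_identical():
    rng = np.random.default_rng(3)
    data = _mat(rng.binomial(1, 0.5, (10, 3)), groups=np.repeat([0, 1], 5))
    rho = rng.uniform(0.2, 0.8, (2, 3))
    m1 = MeasurementParams(pi=[1.0], tau=[[0.6, 0.4]], rho=rho)
    for pi in ([0.5, 0.5], [0.9, 0.1]):
        m2 = MeasurementParams(pi=pi, tau=[[0.6, 0.4], [0.6, 0.4]], rho=rho)
        assert loglik(data, m2) == pytest.approx(loglik(data, m1), abs=1e-10)


def test_loglik_missing_cells_contribute_no_factor():
    params = MeasurementParams(pi=[1.0], tau=[[1.0]], rho=[[0.7, 0.4]])
    full = _mat([[1.0, np.nan]])
    assert loglik(full, params) == pytest.approx(np.log(0.7), abs=1e-12)


def test_loglik_dimension_mismatch_raises():
    with pytest.raises(ValueError):
        loglik(_mat([[1.0, 0.0]]), MeasurementParams(pi=[1.0], tau=[[1.0]], rho=[[0.5]]))


# ---------------------------------------------------------------------------
# EM behaviour

def test_k1_m1_reduces_to_weighted_bernoulli_mle():
    rng = np.random.default_rng(1)
    values = rng.binomial(1, [0.3, 0.8], size=(50, 2)).astype(float)
    w = rng.uniform(0.5, 2.0, 50)
    data = _mat(values, weights=w)
    fit = fit_measurement(data, K=1, M=1, n_starts=1, seed=0)
    mle = (w[:, None] * values).sum(0) / w.sum()
    assert np.allclose(fit.params.rho[0], mle, atol=1e-6)
    expected = float((w[:, None] * (values * np.log(mle) +
                                    (1 - values) * np.log(1 - mle))).sum())
    assert fit.loglik == pytest.approx(expected, rel=1e-9)


def test_em_loglik_monotone(profile_sim):
    _, data, _, _ = profile_sim
    sub = IndicatorMatrix(values=data.values[:2000], group_ids=data.group_index[:2000])
    fit = fit_measurement(sub, K=2, M=2, n_starts=3, seed=11)
    path = fit.loglik_path
    assert np.all(np.diff(path) >= -1e-7 * (np.abs(path[:-1]) + 1))


def test_permutation_invariance():
    rng = np.random.default_rng(9)
    values = rng.binomial(1, 0.4, (60, 4)).astype(float)
    groups = np.repeat(np.arange(6), 10)
    f1 = fit_measurement(_mat(values, groups), K=2, M=2, n_starts=10, seed=2, tol=1e-11)
    perm = rng.permutation(60)
    f2 = fit_measurement(_mat(values[perm], groups[perm]), K=2, M=2,
                         n_starts=10, seed=2, tol=1e-11)
    assert f1.loglik == pytest.approx(f2.loglik, abs=1e-5)
    assert np.allclose(f1.params.rho, f2.params.rho, atol=1e-3)


def test_parameter_recovery_from_published_profile(profile_sim, profile_fit):
    """RMSE(rho) < 0.02 and MAP agreement with truth > 95% at both levels."""
    cfg, data, _, truth = profile_sim
    est = align_to(MeasurementParams(pi=cfg.pi, tau=cfg.tau, rho=cfg.rho),
                   profile_fit.params)
    assert np.sqrt(np.mean((est.rho - cfg.rho) ** 2)) < 0.02
    assert np.sqrt(np.mean((est.tau - cfg.tau) ** 2)) < 0.05
    assert np.abs(est.pi - cfg.pi).max() < 3 * np.sqrt(cfg.pi[0] * cfg.pi[1] / cfg.J)
    post = profile_fit.posteriors
    assert (post.map_indiv == truth.C).mean() > 0.95
    assert (post.map_group == truth.W).mean() > 0.95


# ---------------------------------------------------------------------------
# posteriors

def test_posteriors_hand_bayes():
    params = MeasurementParams(pi=[1.0], tau=[[0.6, 0.4]],
                               rho=[[0.9, 0.8], [0.2, 0.3]])
    post = compute_posteriors(_mat([[1.0, 1.0]]), params)
    assert post.indiv_post[0, 0] == pytest.approx(0.432 / 0.456, abs=1e-9)


def test_posteriors_uniform_for_identical_classes():
    params = MeasurementParams(pi=[0.5, 0.5], tau=[[0.5, 0.5], [0.5, 0.5]],
                               rho=[[0.6, 0.3], [0.6, 0.3]])
    data = _mat([[1.0, 0.0], [0.0, 1.0]], groups=[0, 1])
    post = compute_posteriors(data, params)
    assert np.allclose(post.indiv_post, 0.5, atol=1e-9)
    assert np.allclose(post.group_post, 0.5, atol=1e-9)


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=25, deadline=None)
def test_posterior_rows_normalized(seed):
    rng = np.random.default_rng(seed)
    n, H, K, M, J = 12, 3, 2, 2, 3
    values = rng.binomial(1, 0.5, (n, H)).astype(float)
    values[rng.random((n, H)) < 0.2] = np.nan
    groups = rng.integers(0, J, n)
    pi = rng.dirichlet(np.ones(M))
    tau = rng.dirichlet(np.ones(K), size=M)
    rho = rng.uniform(0.05, 0.95, (K, H))
    post = compute_posteriors(_mat(values, groups),
                              MeasurementParams(pi=pi, tau=tau, rho=rho))
    assert np.allclose(post.group_post.sum(axis=1), 1.0, atol=1e-8)
    assert np.allclose(post.indiv_post.sum(axis=1), 1.0, atol=1e-8)
    assert np.allclose(post.joint_post.sum(axis=(1, 2)), 1.0, atol=1e-8)


# ---------------------------------------------------------------------------
# summaries and canonical ordering

def test_summaries_recover_tau_and_closed_form_overall(profile_fit, profile_sim):
    cfg, data, _, _ = profile_sim
    summ = summarize_classes(profile_fit.posteriors, data.weights, data.group_labels)
    assert np.allclose(summ["conditional_shares"].sum(axis=1), 1.0, atol=1e-8)
    assert summ["overall_lower_shares"].sum() == pytest.approx(1.0, abs=1e-8)
    assert np.abs(summ["conditional_shares"] - cfg.tau).max() < 0.05
    # equal group sizes: overall optimal share near the mixture closed form
    closed = PUBLISHED_PI[0] * PUBLISHED_TAU[0][0] + PUBLISHED_PI[1] * PUBLISHED_TAU[1][0]
    assert closed == pytest.approx(0.702, abs=0.001)
    assert abs(summ["overall_lower_shares"][0] - closed) < 0.06


def test_canonicalize_orders_optimal_first():
    params = MeasurementParams(
        pi=[0.3, 0.7],
        tau=[[0.5, 0.5], [0.2, 0.8]],
        rho=[[0.1, 0.2], [0.8, 0.9]])   # class 1 has higher mean rho
    canon = canonicalize(params)
    assert canon.rho[0].mean() >= canon.rho[1].mean()
    assert canon.tau[0, 0] >= canon.tau[1, 0]
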