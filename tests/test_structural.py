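"""Two-step covariate regressions, odds-ratio tables, and the
random-intercept logistic summaries (ICC, MOR)."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from careclass import (published_profile_config, simulate, fit_measurement,
                       fit_two_step, odds_ratio_table,
                       fit_random_intercept_logistic, mor_icc)
from careclass.structural import StructuralParams, _mnl_probs


# ---------------------------------------------------------------------------
# closed forms

def test_icc_closed_form_matches_printed_value():
    icc, _ = mor_icc(1.10)
    assert round(100 * icc, 2) == 25.06


def test_mor_closed_form():
    _, mor = mor_icc(1.10)
    assert mor == pytest.approx(np.exp(np.sqrt(2.2) * 0.6744898), abs=1e-4)
    assert mor == pytest.approx(2.72, abs=0.005)


def test_icc_mor_null_and_monotonicity():
    assert mor_icc(0.0) == (0.0, 1.0)
    iccs, mors = zip(*(mor_icc(s) for s in [0.1, 0.5, 1.0, 2.0]))
    assert np.all(np.diff(iccs) > 0) and np.all(np.diff(mors) > 0)
    assert all(0 <= i < 1 for i in iccs) and all(m >= 1 for m in mors)
    with pytest.raises(ValueError):
        mor_icc(-0.5)


def test_or_table_math():
    params = StructuralParams(
        alpha=np.array([[0.0]]), gamma=[np.array([[np.log(2)]]), np.array([[0.0]])],
        alpha_vcov=np.array([[0.04]]), gamma_vcov=[np.array([[0.01]]), np.array([[0.09]])],
        alpha_names=["intercept"], gamma_names=["intercept"],
        loglik=0.0, n_iter=1, converged=True)
    tab = odds_ratio_table(params)
    null = tab[(tab.level == "country")].iloc[0]
    assert null.AOR == 1.0 and null.CI_low < 1 < null.CI_high
    row = tab[(tab.level == "individual") & (tab.stratum == "country_class_0")].iloc[0]
    assert row.AOR == pytest.approx(2.0, rel=1e-9)
    assert row.CI_low == pytest.approx(np.exp(np.log(2) - 1.96 * 0.1), abs=1e-3)
    assert row.CI_high == pytest.approx(np.exp(np.log(2) + 1.96 * 0.1), abs=1e-3)


# ---------------------------------------------------------------------------
# two-step estimation

@pytest.fixture(scope="module")
def planted_effect_fit():
    """Data with a planted individual-level log-odds effect of ln 2 on the
    optimal class in both country strata, N = 15,000."""
    cfg = published_profile_config(J=30, n_per_group=500, seed=3)
    cfg.covariate_spec = {"individual": {"xbin": {"dist": "bernoulli", "p": 0.5}}}
    g = np.zeros((2, 1, 2))
    g[0] = [[np.log(0.827 / 0.173), np.log(2)]]
    g[1] = [[np.log(0.465 / 0.535), np.log(2)]]
    cfg.gamma = g
    data, covs, truth = simulate(cfg)
    fit = fit_measurement(data, K=2, M=2, n_starts=6, seed=1)
    sp = fit_two_step(data, fit.params, Z1=None, Z2=covs.individual)
    return cfg, data, covs, fit, sp


def test_two_step_recovers_planted_log_odds(planted_effect_fit):
    *_, sp = planted_effect_fit
    tab = odds_ratio_table(sp)
    rows = tab[tab.covariate == "xbin"]
    assert len(rows) == 2
    for _, r in rows.iterrows():
        assert r.CI_low < 2.0 < r.CI_high
        assert r.AOR == pytest.approx(2.0, abs=0.35)


def test_two_step_intercept_only_is_reparameterization(planted_effect_fit):
    """With no covariates, the step-2 optimum reproduces the measurement
    model's tau and pi (the intercepts are a bijective reparameterization)."""
    _, data, _, fit, _ = planted_effect_fit
    tight = fit_measurement(data, K=2, M=2, n_starts=1, seed=None, tol=1e-14,
                            max_iter=5000)
    sp0 = fit_two_step(data, tight.params, Z1=None, Z2=None, tol=1e-12)
    one = np.ones((1, 1))
    pi_hat = _mnl_probs(one, sp0.alpha)[0]
    assert np.abs(pi_hat - tight.params.pi).max() < 1e-5
    for m in range(2):
        tau_hat = _mnl_probs(one, sp0.gamma[m])[0]
        assert np.abs(tau_hat - tight.params.tau[m]).max() < 1e-5


def test_two_step_loglik_not_below_measurement(planted_effect_fit):
    """Covariates can only raise the maximized step-2 likelihood above the
    intercept-only (measurement) value."""
    _, data, covs, fit, sp = planted_effect_fit
    sp0 = fit_two_step(data, fit.params, Z1=None, Z2=None)
    assert sp.loglik >= sp0.loglik - 1e-6


def test_null_effect_aor_near_one():
    cfg = published_profile_config(J=25, n_per_group=200, seed=17)
    cfg.covariate_spec = {"individual": {"xnull": {"dist": "bernoulli", "p": 0.5}}}
    data, covs, _ = simulate(cfg)
    fit = fit_measurement(data, K=2, M=2, n_starts=4, seed=2)
    sp = fit_two_step(data, fit.params, Z2=covs.individual)
    rows = odds_ratio_table(sp)
    rows = rows[rows.covariate == "xnull"]
    for _, r in rows.iterrows():
        assert r.CI_low < 1.0 < r.CI_high


# ---------------------------------------------------------------------------
# random-intercept logistic

def _simulate_ri(sigma2, J, n_per, seed, beta=(0.3, 0.7)):
    rng = np.random.default_rng(seed)
    b = rng.normal(0, np.sqrt(sigma2), J) if sigma2 > 0 else np.zeros(J)
    groups = np.repeat(np.arange(J), n_per)
    x = rng.binomial(1, 0.5, J * n_per)
    eta = beta[0] + beta[1] * x + b[groups]
    y = rng.binomial(1, expit(eta))
    return y, groups, x


def test_random_intercept_recovers_variance():
    y, groups, x = _simulate_ri(1.1, J=80, n_per=150, seed=6)
    fit = fit_random_intercept_logistic(y, groups, x)
    assert fit.converged
    assert fit.sigma2_ci[0] < 1.1 < fit.sigma2_ci[1]
    assert fit.icc == pytest.approx(fit.sigma2 / (fit.sigma2 + np.pi ** 2 / 3), abs=1e-10)


def test_random_intercept_null_variance():
    y, groups, x = _simulate_ri(0.0, J=50, n_per=200, seed=7)
    fit = fit_random_intercept_logistic(y, groups, x)
    assert fit.sigma2 < 0.05


def test_quadrature_node_doubling_stable():
    y, groups, x = _simulate_ri(1.1, J=30, n_per=100, seed=9)
    f15 = fit_random_intercept_logistic(y, groups, x, n_quad=15)
    f30 = fit_random_intercept_logistic(y, groups, x, n_quad=30)
    assert abs(f15.loglik - f30.loglik) < 1e-3
    assert abs(f15.sigma2 - f30.sigma2) < 1e-3


def test_random_intercept_single_group_errors():
    with pytest.raises(ValueError):
        fit_random_intercept_logistic(np.array([0, 1, 1]), np.zeros(3), None)


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript unavailable")
def test_random_intercept_matches_lme4(tmp_path):
    """Independent oracle: lme4::glmer with nAGQ=15 on the same data."""
    y, groups, x = _simulate_ri(0.8, J=40, n_per=60, seed=4)
    df = pd.DataFrame({"y": y, "g": groups, "x": x})
    csv = tmp_path / "ri.csv"
    df.to_csv(csv, index=False)
    script = (
        f'd <- read.csv("{csv}"); suppressMessages(library(lme4));'
        'm <- glmer(y ~ x + (1|g), data=d, family=binomial, nAGQ=15);'
        'cat(fixef(m), as.data.frame(VarCorr(m))$vcov, sep="\\n")'
    )
    out = subprocess.run(["Rscript", "-e", script], capture_output=True,
                         text=True, timeout=300)
    assert out.returncode == 0, out.stderr
    b0, b1, s2 = map(float, out.stdout.strip().split("\n")[-3:])
    fit = fit_random_intercept_logistic(y, groups, x)
    assert fit.beta[0] == pytest.approx(b0, abs=5e-3)
    assert fit.beta[1] == pytest.approx(b1, abs=5e-3)
    assert fit.sigma2 == pytest.approx(s2, abs=1e-2)
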