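"""Mixed-model correctness against independent oracles (statsmodels,
adaptive quadrature, closed-form contingency identities)."""

import math

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
import statsmodels.formula.api as smf

from pairguard.glmm import (ModelSpec, build_design, diurnal_terms, fit_glmm,
                            marginal_loglik_quadrature, marginal_mean,
                            select_quadratic)


@pytest.fixture(scope="module")
def rng():
    return np.random.default_rng(2024)


def test_gaussian_no_group_matches_ols(rng):
    n = 200
    x = rng.normal(size=n)
    y = 1.5 + 0.7 * x + rng.normal(scale=0.8, size=n)
    df = pd.DataFrame({"y": y, "x": x})
    fit = fit_glmm(df, ModelSpec("gaussian", "y", ("x",)))
    ols = sm.OLS(y, sm.add_constant(x)).fit()
    np.testing.assert_allclose(fit.beta.to_numpy(), ols.params, atol=1e-6)
    assert fit.converged


def test_binomial_no_group_matches_glm(rng):
    n = 300
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.2 + 0.9 * x)))
    tot = rng.integers(3, 20, size=n)
    succ = rng.binomial(tot, p)
    df = pd.DataFrame({"s": succ.astype(float), "n": tot.astype(float),
                       "x": x})
    fit = fit_glmm(df, ModelSpec("binomial", ("s", "n"), ("x",)))
    glm = sm.GLM(np.column_stack([succ, tot - succ]),
                 sm.add_constant(x), family=sm.families.Binomial()).fit()
    np.testing.assert_allclose(fit.beta.to_numpy(), glm.params, atol=1e-6)


def test_binomial_reduction_matches_contingency_log_odds():
    # a single binary factor: coefficients are the 2x2 table log-odds
    df = pd.DataFrame({
        "s": [40.0, 10.0], "n": [100.0, 100.0], "grp": ["a", "b"]})
    fit = fit_glmm(df, ModelSpec("binomial", ("s", "n"), ("grp",)))
    lo_a = math.log(40 / 60)
    lo_b = math.log(10 / 90)
    assert fit.beta["intercept"] == pytest.approx(lo_a, abs=1e-6)
    term = [t for t in fit.beta.index if t != "intercept"][0]
    assert fit.beta[term] == pytest.approx(lo_b - lo_a, abs=1e-6)


def test_gaussian_mixedlm_random_intercept_and_slope(rng):
    G, m = 25, 20
    g = np.repeat(np.arange(G), m)
    x = rng.normal(size=G * m)
    u0 = rng.normal(scale=0.9, size=G)
    u1 = rng.normal(scale=0.4, size=G)
    y = 2.0 + 0.5 * x + u0[g] + u1[g] * x + rng.normal(scale=1.1, size=G * m)
    df = pd.DataFrame({"y": y, "x": x, "grp": g.astype(str)})
    fit = fit_glmm(df, ModelSpec("gaussian", "y", ("x",), group="grp",
                                 random_slope="x"))
    md = smf.mixedlm("y ~ x", df, groups=df["grp"],
                     re_formula="~x").fit(reml=False)
    np.testing.assert_allclose(fit.beta.to_numpy(), md.fe_params.to_numpy(),
                               atol=1e-4)
    np.testing.assert_allclose(fit.loglik, md.llf, atol=1e-3)
    assert fit.converged


def test_binomial_laplace_close_to_quadrature(rng):
    G, m = 15, 12
    g = np.repeat(np.arange(G), m)
    x = rng.normal(size=G * m)
    u = rng.normal(scale=1.0, size=G)
    p = 1 / (1 + np.exp(-(0.3 + 0.6 * x + u[g])))
    tot = rng.integers(5, 30, size=G * m)
    succ = rng.binomial(tot, p)
    df = pd.DataFrame({"s": succ.astype(float), "n": tot.astype(float),
                       "x": x, "grp": g.astype(str)})
    spec = ModelSpec("binomial", ("s", "n"), ("x",), group="grp")
    fit = fit_glmm(df, spec)
    sd = math.sqrt(fit.re_cov[0, 0])
    ll_q = marginal_loglik_quadrature(df, spec, fit.beta.to_numpy(), sd)
    assert abs(fit.loglik - ll_q) / abs(ll_q) < 1e-3


def test_beta_binomial_dispersion_recovery_and_quadrature(rng):
    G, m, phi = 30, 25, 8.0
    g = np.repeat(np.arange(G), m)
    x = rng.normal(size=G * m)
    u = rng.normal(scale=0.8, size=G)
    p = 1 / (1 + np.exp(-(0.2 + 0.7 * x + u[g])))
    pp = rng.beta(phi * p, phi * (1 - p))
    tot = rng.integers(8, 40, size=G * m)
    succ = rng.binomial(tot, pp)
    df = pd.DataFrame({"s": succ.astype(float), "n": tot.astype(float),
                       "x": x, "grp": g.astype(str)})
    spec = ModelSpec("beta_binomial", ("s", "n"), ("x",), group="grp")
    fit = fit_glmm(df, spec)
    assert fit.converged
    assert 0.6 * phi < fit.dispersion < 1.6 * phi
    assert abs(fit.beta["x"] - 0.7) < 0.15
    sd = math.sqrt(fit.re_cov[0, 0])
    ll_q = marginal_loglik_quadrature(df, spec, fit.beta.to_numpy(), sd,
                                      dispersion=fit.dispersion)
    assert abs(fit.loglik - ll_q) / abs(ll_q) < 1e-3


def test_design_quadratic_and_categorical():
    df = pd.DataFrame({"x": [1.0, 2.0], "f": ["a", "b"]})
    X, info = build_design(df, ("x", "x^2", "f"), None)
    assert list(info.names) == ["intercept", "x", "x^2", "f[b]"]
    np.testing.assert_allclose(X[:, 2], [1.0, 4.0])
    np.testing.assert_allclose(X[:, 3], [0.0, 1.0])


def test_select_quadratic_drops_null_term(rng):
    n = 400
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.1 + 0.8 * x)))      # no true quadratic
    tot = np.full(n, 25)
    succ = rng.binomial(tot, p)
    df = pd.DataFrame({"s": succ.astype(float), "n": tot.astype(float),
                       "x": x})
    spec = ModelSpec("binomial", ("s", "n"), ("x", "x^2"))
    final_spec, final_fit, fit0 = select_quadratic(df, spec)
    if fit0.p["x^2"] >= 0.05:
        assert "x^2" not in final_spec.fixed
        assert "x^2" not in final_fit.beta.index
    else:       # unlucky draw: the rule keeps a significant term
        assert "x^2" in final_spec.fixed


def test_select_quadratic_keeps_real_term(rng):
    n = 500
    x = rng.normal(size=n)
    p = 1 / (1 + np.exp(-(0.1 + 0.3 * x - 0.6 * x ** 2)))
    tot = np.full(n, 25)
    succ = rng.binomial(tot, p)
    df = pd.DataFrame({"s": succ.astype(float), "n": tot.astype(float),
                       "x": x})
    final_spec, _, _ = select_quadratic(
        df, ModelSpec("binomial", ("s", "n"), ("x", "x^2")))
    assert "x^2" in final_spec.fixed


def test_marginal_mean_inverse_link():
    df = pd.DataFrame({"s": [30.0, 60.0], "n": [100.0, 100.0],
                       "x": [0.0, 1.0]})
    fit = fit_glmm(df, ModelSpec("binomial", ("s", "n"), ("x",)))
    m0, se0 = marginal_mean(fit, {"x": 0.0})
    m1, se1 = marginal_mean(fit, {"x": 1.0})
    assert m0 == pytest.approx(0.30, abs=1e-4)
    assert m1 == pytest.approx(0.60, abs=1e-4)
    assert se0 > 0 and se1 > 0


def test_diurnal_terms_period():
    t = pd.Series(pd.to_datetime(["2019-06-10 00:00", "2019-06-10 06:00",
                                  "2019-06-10 12:00"]))
    terms = diurnal_terms(t)
    np.testing.assert_allclose(terms["sin_time"],
                               [0.0, 1.0, 0.0], atol=1e-12)
    np.testing.assert_allclose(terms["cos_time"],
                               [1.0, 0.0, -1.0], atol=1e-12)


def test_random_effects_need_two_groups():
    df = pd.DataFrame({"y": [1.0, 2.0], "x": [0.0, 1.0], "g": ["a", "a"]})
    with pytest.raises(ValueError):
        fit_glmm(df, ModelSpec("gaussian", "y", ("x",), group="g"))
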