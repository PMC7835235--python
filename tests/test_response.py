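"""Proportional-odds fitting, the univariate screen, and the ordered LASSO."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from mcrc import response as resp


def _simulate(n, beta, thresholds=(-0.5, 1.0), seed=0, p=None):
    rng = np.random.default_rng(seed)
    beta = np.atleast_1d(np.asarray(beta, dtype=float))
    p = p or len(beta)
    X = rng.normal(size=(n, p))
    eta = X[:, : len(beta)] @ beta
    u = rng.random(n)
    y = np.where(
        u < expit(thresholds[0] - eta), 0,
        np.where(u < expit(thresholds[1] - eta), 1, 2),
    )
    return y, pd.DataFrame(X, columns=[f"f{i}" for i in range(p)])


def test_binary_outcome_reduces_to_logistic_regression():
    import statsmodels.api as sm

    y, X = _simulate(400, [0.8, -0.4], seed=1)
    yb = (y > 0).astype(int)
    fit = resp.OrdinalResponseModel(yb, X).fit()
    oracle = sm.Logit(yb, sm.add_constant(X.to_numpy())).fit(disp=False)
    assert np.allclose(fit.beta.to_numpy(), np.asarray(oracle.params)[1:], atol=1e-6)


def test_newton_fit_matches_independent_ordinal_oracle():
    from statsmodels.miscmodels.ordinal_model import OrderedModel

    y, X = _simulate(500, [1.0, -0.5], seed=2)
    fit = resp.OrdinalResponseModel(y, X).fit()
    oracle = OrderedModel(y, X.to_numpy(), distr="logit").fit(
        method="bfgs", disp=False
    )
    assert fit.converged and not fit.separation
    assert np.allclose(fit.beta.to_numpy(), np.asarray(oracle.params)[:2], atol=1e-4)
    assert fit.llf >= oracle.llf - 1e-6


def test_score_matches_finite_differences():
    y, X = _simulate(120, [0.5], seed=3)
    model = resp.OrdinalResponseModel(y, X)
    w = model._start_params() + 0.05
    w[:2] = np.sort(w[:2])
    grad = model.score(w)
    eps = 1e-6
    for i in range(len(w)):
        d = np.zeros_like(w)
        d[i] = eps
        fd = (model.loglike(w + d) - model.loglike(w - d)) / (2 * eps)
        assert grad[i] == pytest.approx(fd, abs=1e-4)


def test_hessian_matches_finite_differences():
    y, X = _simulate(120, [0.5], seed=4)
    model = resp.OrdinalResponseModel(y, X)
    w = model._start_params()
    H = model.hessian(w)
    eps = 1e-5
    for i in range(len(w)):
        d = np.zeros_like(w)
        d[i] = eps
        fd = (model.score(w + d) - model.score(w - d)) / (2 * eps)
        assert np.allclose(H[i], fd, atol=1e-4)


def test_null_feature_p_values_are_uniform():
    from scipy.stats import kstest

    rng = np.random.default_rng(5)
    ps = []
    for i in range(300):
        y, X = _simulate(200, [0.0], seed=1000 + i)
        fit = resp.OrdinalResponseModel(y, X).fit()
        ps.append(float(fit.pvalues.iloc[0]))
    assert kstest(ps, "uniform").pvalue > 0.01


def test_planted_coefficient_recovered():
    y, X = _simulate(3000, [1.0], seed=6)
    fit = resp.OrdinalResponseModel(y, X).fit()
    assert abs(float(fit.beta.iloc[0]) - 1.0) < 0.15
    assert fit.theta[0] < fit.theta[1]


def test_separation_is_flagged():
    y = np.array([0] * 20 + [2] * 20)
    x = pd.DataFrame({"f0": np.r_[np.zeros(20), np.ones(20)]})
    fit = resp.OrdinalResponseModel(y, x).fit()
    assert fit.separation


def test_outcome_needs_two_levels():
    with pytest.raises(ValueError, match="2 observed levels"):
        resp.OrdinalResponseModel(np.zeros(30), pd.DataFrame({"x": np.arange(30)}))


def test_missing_rows_dropped_with_count():
    y = pd.Series(pd.Categorical(["PD", "SD", "PR", None, "SD"],
                                 categories=["PD", "SD", "PR"], ordered=True))
    X = pd.DataFrame({"x": [1.0, 2.0, np.nan, 4.0, 5.0]})
    model = resp.OrdinalResponseModel(y, X)
    assert model.n == 3 and model.n_dropped == 2


def test_summary_mentions_fit_quality():
    y, X = _simulate(200, [0.6], seed=7)
    text = resp.OrdinalResponseModel(y, X).fit().summary()
    assert "log-likelihood" in text and "theta_1" in text


def test_screen_min_events_boundary():
    rng = np.random.default_rng(8)
    n = 120
    y = np.repeat([0, 1, 2], 40)
    X = pd.DataFrame(
        {
            "rare": np.r_[np.ones(4), np.zeros(n - 4)],       # 4 events in PD only
            "ok": rng.random(n) < 0.4,
            "cont": rng.normal(size=n),
        }
    ).astype(float)
    screen = resp.univariate_screen(y, X, min_events=5)
    assert "rare" not in screen.eligible
    assert "cont" in screen.eligible  # min-events rule is for binary flags
    table = screen.table.set_index("feature")
    assert not table.loc["rare", "eligible"]


def test_screen_selection_is_strict_and_order_invariant():
    y, X = _simulate(400, [1.2, 0.0, 0.0], seed=9)
    screen = resp.univariate_screen(y, X)
    assert "f0" in screen.selected
    shuffled = X[["f2", "f0", "f1"]]
    screen2 = resp.univariate_screen(y, shuffled)
    assert set(screen.selected) == set(screen2.selected)
    assert set(screen.eligible) == set(screen2.eligible)


def test_lasso_large_penalty_matches_intercept_only_fit():
    y, X = _simulate(300, [1.0, -0.5], seed=10)
    pen = resp.OrdinalResponseModel(y, X).fit_regularized(lam=10.0, tol=1e-12)
    assert np.allclose(pen.beta, 0.0)
    intercept_only = resp.OrdinalResponseModel(
        y, pd.DataFrame(index=range(len(y)))
    ).fit()
    assert np.allclose(pen.theta, intercept_only.theta, atol=1e-4)


def test_lasso_zero_penalty_matches_newton():
    from mcrc.validation import lasso_unpenalized_max_diff

    assert lasso_unpenalized_max_diff(seed=0) < 1e-4


def test_lasso_path_sparsity_monotone_in_penalty():
    y, X = _simulate(400, [1.0, -0.6, 0.3, 0.0, 0.0], seed=11)
    model = resp.OrdinalResponseModel(y, X)
    nonzeros = []
    for lam in (0.3, 0.1, 0.03, 0.01, 0.0):
        pen = model.fit_regularized(lam=lam, tol=1e-11)
        nonzeros.append(int((np.abs(pen.beta) > 1e-8).sum()))
    assert nonzeros == sorted(nonzeros)


def test_lasso_cv_recovers_sparse_truth():
    y, X = _simulate(600, [1.2, -0.9, 0.0, 0.0, 0.0, 0.0], seed=12)
    fit = resp.ordinal_lasso(y, X, seed=0)
    nz = set(fit.nonzero(atol=1e-3).index)
    assert {"f0", "f1"} <= nz
    assert fit.cv_table is not None and len(fit.cv_table) >= 5


def test_lasso_coefficients_reported_on_original_scale():
    y, X = _simulate(800, [0.8], seed=13)
    X = X.copy()
    X["f0"] = X["f0"] * 10  # rescaled feature: coefficient shrinks 10x
    newton = resp.OrdinalResponseModel(y, X).fit()
    pen = resp.OrdinalResponseModel(y, X).fit_regularized(
        lam=0.0, tol=1e-13, maxiter=300_000
    )
    assert pen.beta[0] == pytest.approx(float(newton.beta.iloc[0]), abs=1e-4)


def test_ordinal_lasso_requires_two_features():
    y, X = _simulate(100, [0.5], seed=14)
    with pytest.raises(ValueError, match="at least 2"):
        resp.ordinal_lasso(y, X[["f0"]])
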