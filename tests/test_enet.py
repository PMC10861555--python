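"""Solver-level tests for the adaptive elastic net.

The coordinate-descent solver is checked against closed forms
(orthonormal design), an independent proximal-gradient oracle, and the
OLS limit; the estimator wrapper is checked for recovery, determinism,
and its documented error behavior.
"""

import numpy as np
import pytest

from aden.enet import (
    AdaptiveElasticNet,
    EnetConfig,
    FitResult,
    _cd_solve,
    _lambda_path,
    _objective,
    _path_fit,
    adaptive_weights,
    bootstrap_significance,
    fit_adaptive_enet,
    fit_enet,
    r2_score,
    soft_threshold,
)


def pgd_oracle(G, c, yty, lam1, lam2_abs, w, n_steps=10_000):
    """Proximal-gradient minimizer of
    ||y - X b||^2 + lam2_abs ||b||^2 + lam1 sum_j w_j |b_j|
    given G = X'X, c = X'y, yty = y'y. Independent of the CD solver."""
    p = len(c)
    L = 2.0 * (np.linalg.eigvalsh(G).max() + lam2_abs)
    step = 1.0 / L
    beta = np.zeros(p)
    for _ in range(n_steps):
        grad = 2.0 * (G @ beta - c) + 2.0 * lam2_abs * beta
        z = beta - step * grad
        beta = soft_threshold(z, step * lam1 * w)
    return beta


def _random_problem(rng, n=50, p=8):
    X = rng.normal(size=(n, p))
    beta_true = np.zeros(p)
    beta_true[: p // 2] = rng.normal(scale=2.0, size=p // 2)
    y = X @ beta_true + rng.normal(size=n)
    Xs = X - X.mean(axis=0)
    Xs /= Xs.std(axis=0)
    yc = y - y.mean()
    return Xs, yc


def test_orthonormal_design_matches_soft_threshold_closed_form(rng):
    p = 8
    G = np.eye(p)
    c = rng.normal(scale=2.0, size=p)
    w = rng.uniform(0.5, 2.0, p)
    for lam1 in (0.0, 0.5, 2.0):
        for lam2_abs in (0.0, 0.3):
            beta = _cd_solve(G, c, lam1, lam2_abs, w)
            expected = soft_threshold(c, lam1 * w / 2.0) / (1.0 + lam2_abs)
            assert np.max(np.abs(beta - expected)) < 1e-8


def test_cd_objective_matches_proximal_gradient_oracle(rng):
    for _ in range(20):
        Xs, yc = _random_problem(rng)
        G = Xs.T @ Xs
        c = Xs.T @ yc
        yty = yc @ yc
        lam_max = 2.0 * np.abs(c).max()
        lam1 = rng.uniform(0.05, 0.5) * lam_max
        lam2_abs = 0.25 * lam1
        w = rng.uniform(0.5, 2.0, len(c))
        beta_cd = _cd_solve(G, c, lam1, lam2_abs, w)
        beta_pg = pgd_oracle(G, c, yty, lam1, lam2_abs, w)
        obj_cd = _objective(G, c, yty, beta_cd, lam1, lam2_abs, w)
        obj_pg = _objective(G, c, yty, beta_pg, lam1, lam2_abs, w)
        assert abs(obj_cd - obj_pg) < 1e-6


def test_cd_reduces_to_ols_without_penalty(rng):
    Xs, yc = _random_problem(rng)
    G = Xs.T @ Xs
    c = Xs.T @ yc
    beta = _cd_solve(G, c, 0.0, 0.0, np.ones(len(c)))
    beta_ols = np.linalg.solve(G, c)
    assert np.allclose(beta, beta_ols, atol=1e-8)


def test_duplicated_predictors_share_the_coefficient(rng):
    # strict convexity from the ridge term forces exactly equal
    # coefficients on identical columns
    n = 60
    x = rng.normal(size=n)
    X = np.column_stack([x, x, rng.normal(size=n)])
    y = 2.0 * x + rng.normal(scale=0.1, size=n)
    Xs = X - X.mean(axis=0)
    yc = y - y.mean()
    G = Xs.T @ Xs
    c = Xs.T @ yc
    beta = _cd_solve(G, c, 1.0, 1.0, np.ones(3))
    assert abs(beta[0] - beta[1]) < 1e-6
    assert beta[0] > 0


def test_lambda_path_starts_at_the_all_zero_solution(rng):
    Xs, yc = _random_problem(rng)
    G = Xs.T @ Xs
    c = Xs.T @ yc
    w = np.ones(len(c))
    lambdas = _lambda_path(c, w, 10, 1e-3)
    betas = _path_fit(G, c, lambdas, 0.25, w)
    assert np.all(betas[:, 0] == 0.0)  # lam_max kills every coefficient
    # the smallest penalty keeps at least as many predictors as the largest
    assert np.count_nonzero(betas[:, -1]) >= np.count_nonzero(betas[:, 0])


def test_adaptive_weight_law_and_zero_exclusion():
    beta = np.array([0.5, -2.0, 0.0, 0.1])
    w, kept = adaptive_weights(beta, gamma=1.0)
    assert kept.tolist() == [0, 1, 3]
    assert np.allclose(w, [1 / 0.5, 1 / 2.0, 1 / 0.1])
    w2, kept2 = adaptive_weights(beta, gamma=2.0)
    assert np.allclose(w2, np.abs(beta[kept2]) ** -2.0)
    with pytest.raises(ValueError):
        adaptive_weights(beta, gamma=0.0)


def test_estimator_recovers_a_planted_sparse_model(rng):
    n, p = 400, 12
    X = rng.normal(size=(n, p))
    beta_true = np.zeros(p)
    beta_true[[1, 4, 7]] = [2.0, -1.5, 1.0]
    y = 3.0 + X @ beta_true + rng.normal(scale=0.3, size=n)
    est = AdaptiveElasticNet(l2_weight=0.25, n_boot=50, random_state=0)
    est.fit(X, y)
    support = set(np.nonzero(est.coef_)[0])
    assert {1, 4, 7} <= support
    assert np.allclose(est.coef_[[1, 4, 7]], [2.0, -1.5, 1.0], atol=0.15)
    assert abs(est.intercept_ - 3.0) < 0.15
    assert est.r2_ > 0.95
    # bootstrap inference flags the true predictors
    assert est.significant_[[1, 4, 7]].all()
    assert np.all(est.pvalues_[[1, 4, 7]] < 0.05)


def test_estimator_is_deterministic_for_a_fixed_seed(rng):
    X = rng.normal(size=(80, 6))
    y = X[:, 0] - 0.5 * X[:, 3] + rng.normal(scale=0.5, size=80)
    a = AdaptiveElasticNet(n_boot=20, random_state=5).fit(X, y)
    b = AdaptiveElasticNet(n_boot=20, random_state=5).fit(X, y)
    assert np.array_equal(a.coef_, b.coef_)
    assert np.array_equal(a.pvalues_, b.pvalues_, equal_nan=True)
    assert a.intercept_ == b.intercept_ and a.lambda1_ == b.lambda1_


def test_estimator_input_validation(rng):
    X = rng.normal(size=(5, 3))
    y = rng.normal(size=5)
    with pytest.raises(ValueError, match="cv_folds"):
        AdaptiveElasticNet(cv_folds=10).fit(X, y)
    with pytest.raises(ValueError, match="n_boot"):
        AdaptiveElasticNet(n_boot=1, cv_folds=2).fit(X, y)
    with pytest.raises(ValueError):
        AdaptiveElasticNet(cv_folds=2).fit(X, y[:3])


def test_constant_response_yields_an_empty_model(rng):
    X = rng.normal(size=(40, 4))
    y = np.full(40, 2.5)
    with pytest.warns(UserWarning, match="constant response"):
        est = AdaptiveElasticNet().fit(X, y)
    assert np.all(est.coef_ == 0)
    assert est.intercept_ == 2.5
    assert not est.significant_.any()


def test_fit_result_roundtrip_and_prediction(rng):
    X = rng.normal(size=(200, 5))
    y = 1.0 + 2.0 * X[:, 2] + rng.normal(scale=0.2, size=200)
    cfg = EnetConfig(n_boot=30, seed=3)
    fit = fit_adaptive_enet(X, y, cfg, gene_id="g",
                            predictor_ids=list("abcde"))
    assert isinstance(fit, FitResult)
    assert "c" in fit.predictor_ids
    Xsel = X[:, [list("abcde").index(p) for p in fit.predictor_ids]]
    pred = fit.predict(Xsel)
    assert r2_score(y, pred) > 0.9
    assert fit.n_nonzero == len(fit.predictor_ids)


def test_bootstrap_filter_drops_pure_noise_predictors(rng):
    n = 300
    X = rng.normal(size=(n, 6))
    y = 1.5 * X[:, 0] + rng.normal(scale=0.5, size=n)
    cfg = EnetConfig(n_boot=0, seed=1)
    fit = fit_adaptive_enet(X, y, cfg)
    cfg_b = EnetConfig(n_boot=100, seed=1)
    filtered = bootstrap_significance(X[:, [int(p[1:]) for p in
                                            fit.predictor_ids]],
                                      y, fit, cfg_b)
    assert "x0" in filtered.predictor_ids
    assert np.all(filtered.pvalue < 0.05)
    with pytest.raises(ValueError, match="n_boot"):
        bootstrap_significance(X, y, fit, EnetConfig(n_boot=0))


def test_pilot_enet_shrinks_relative_to_ols(rng):
    X = rng.normal(size=(100, 4))
    y = X @ np.array([1.0, 0.0, -2.0, 0.0]) + rng.normal(scale=0.4, size=100)
    pilot = fit_enet(X, y, EnetConfig(seed=2))
    ols = np.linalg.lstsq(np.column_stack([np.ones(100), X]), y, rcond=None)[0][1:]
    assert np.sum(np.abs(pilot)) <= np.sum(np.abs(ols)) + 1e-9


def test_r2_score_definition_and_errors():
    y = np.array([1.0, 2.0, 3.0])
    assert r2_score(y, y) == 1.0
    assert abs(r2_score(y, np.full(3, 2.0))) < 1e-12
    with pytest.raises(ValueError):
        r2_score(np.ones(3), np.ones(3))  # zero variance
    with pytest.raises(ValueError):
        r2_score(np.array([1.0]), np.array([1.0]))
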