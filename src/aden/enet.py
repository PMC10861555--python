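"""Adaptive elastic-net regression with bootstrap coefficient inference.

The estimator solves, for response ``y`` (pseudocell or cell expression of
one target gene) and predictors ``X`` (peak accessibility or TF
expression),

    beta_hat = (1 + lambda2_abs/n) * argmin_beta
        ||y - X beta||_2^2 + lambda2_abs ||beta||_2^2
        + lambda1 * sum_j w_j |beta_j|

in two stages: a pilot elastic net (all ``w_j = 1``) whose coefficients
define adaptive weights ``w_j = |beta_j(pilot)|^(-gamma)`` (zero pilot
coefficients are excluded outright), followed by the adaptive-weighted
fit. Both stages select their L1 level by K-fold cross-validation along a
geometric path; ``l2_weight`` sets the ridge penalty relative to the L1
term (``lambda2_abs = lambda * l2_weight``), so smaller values give
sparser fits. Coefficient standard errors come from refitting the
selected model on bootstrap resamples of the rows; two-sided normal
p-values filter the final selection at ``alpha_sig``.

Predictors are z-standardized internally; reported coefficients are on
the original predictor scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numba import njit
from scipy.stats import norm
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.model_selection import KFold
from sklearn.utils.validation import check_array, check_is_fitted

__all__ = [
    "EnetConfig",
    "FitResult",
    "AdaptiveElasticNet",
    "fit_enet",
    "adaptive_weights",
    "fit_adaptive_enet",
    "bootstrap_significance",
    "r2_score",
]

_DEGENERATE_SE = 1e-12


@dataclass
class EnetConfig:
    """Hyperparameters shared by both modeling stages.

    l2_weight is the ridge weight relative to the adaptive L1 term
    (0.25 for the CRE stage, 0.5 for the TF stage); gamma is the
    adaptive-weight exponent; alpha_sig the bootstrap retention level.
    """

    l2_weight: float = 0.25
    gamma: float = 1.0
    cv_folds: int = 10
    n_boot: int = 100
    alpha_sig: float = 0.05
    seed: int = 0
    lambda_rule: str = "min"  # "min" | "1se"
    n_lambda: int = 50
    lambda_min_ratio: float = 1e-3

    def __post_init__(self):
        if self.l2_weight < 0:
            raise ValueError("l2_weight must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if self.n_boot < 0:
            raise ValueError("n_boot must be >= 0")


@dataclass
class FitResult:
    """One gene's fitted regulatory model (selected predictors only)."""

    gene_id: str
    predictor_ids: list[str]
    beta: np.ndarray
    intercept: float
    se: np.ndarray | None
    pvalue: np.ndarray | None
    lambda1: float
    lambda2: float
    r2: float
    n_obs: int
    adaptive_weights: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if len(self.predictor_ids) != len(self.beta):
            raise ValueError("predictor_ids and beta length mismatch")
        for arr in (self.se, self.pvalue):
            if arr is not None and len(arr) != len(self.beta):
                raise ValueError("se/pvalue length mismatch")

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.beta))

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        return self.intercept + X @ self.beta


def soft_threshold(z: float | np.ndarray, t: float | np.ndarray):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


@njit(cache=False)
def _cd_kernel(G, c, lam1, lam2_abs, w, beta, max_iter, tol):  # pragma: no cover
    p = c.shape[0]
    g = G @ beta
    for _ in range(max_iter):
        delta_max = 0.0
        for j in range(p):
            denom = G[j, j] + lam2_abs
            if denom <= 0.0:  # constant (zero-variance) predictor
                continue
            rho = c[j] - g[j] + G[j, j] * beta[j]
            thr = 0.5 * lam1 * w[j]
            if rho > thr:
                new = (rho - thr) / denom
            elif rho < -thr:
                new = (rho + thr) / denom
            else:
                new = 0.0
            d = new - beta[j]
            if d != 0.0:
                for k in range(p):
                    g[k] += G[k, j] * d
                beta[j] = new
                ad = abs(d)
                if ad > delta_max:
                    delta_max = ad
        if delta_max < tol:
            break
    return beta


def _cd_solve(G, c, lam1, lam2_abs, w, beta0=None, tol=1e-12, max_iter=10_000):
    """Cyclic coordinate descent on the Gram system.

    Minimizes ||y - X b||^2 + lam2_abs ||b||^2 + lam1 * sum_j w_j |b_j|
    given G = X'X and c = X'y. Per-coordinate closed form:
    b_j = S(c_j - sum_{k!=j} G_jk b_k, lam1 w_j / 2) / (G_jj + lam2_abs).
    """
    p = len(c)
    beta = np.zeros(p) if beta0 is None else np.array(beta0, dtype=float)
    return _cd_kernel(
        np.ascontiguousarray(G, dtype=float),
        np.ascontiguousarray(c, dtype=float),
        float(lam1), float(lam2_abs),
        np.ascontiguousarray(w, dtype=float),
        beta, max_iter, tol,
    )


def _objective(G, c, yty, beta, lam1, lam2_abs, w):
    rss = yty - 2.0 * c @ beta + beta @ G @ beta
    return rss + lam2_abs * beta @ beta + lam1 * np.sum(w * np.abs(beta))


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd_safe = np.where(sd > 0, sd, 1.0)
    return (X - mu) / sd_safe, mu, sd, sd_safe


def _lambda_path(c, w, n_lambda, min_ratio):
    finite = w > 0
    with np.errstate(divide="ignore"):
        lam_max = np.max(np.where(finite, 2.0 * np.abs(c) / w, 0.0))
    if lam_max <= 0:
        lam_max = 1.0
    return np.geomspace(lam_max, lam_max * min_ratio, n_lambda)


def _path_fit(G, c, lambdas, l2_weight, w, tol=1e-10):
    """Warm-started fits along a decreasing L1 path; returns p x L betas."""
    p = len(c)
    betas = np.zeros((p, len(lambdas)))
    beta = np.zeros(p)
    for i, lam in enumerate(lambdas):
        beta = _cd_solve(G, c, lam, lam * l2_weight, w, beta0=beta, tol=tol)
        betas[:, i] = beta
    return betas


def _cv_select(X_std, y, lambdas, l2_weight, w, cv_folds, rule, seed):
    """K-fold CV of the penalized fit; returns (index, mean_mse, se_mse)."""
    n = len(y)
    kf = KFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    mse = np.zeros((cv_folds, len(lambdas)))
    for f, (tr, va) in enumerate(kf.split(X_std)):
        Xt, Xv = X_std[tr], X_std[va]
        yt, yv = y[tr], y[va]
        mu = Xt.mean(axis=0)
        Xt = Xt - mu
        yt_c = yt - yt.mean()
        G = Xt.T @ Xt
        c = Xt.T @ yt_c
        betas = _path_fit(G, c, lambdas, l2_weight, w, tol=1e-8)
        pred = yt.mean() + (Xv - mu) @ betas
        mse[f] = np.mean((yv[:, None] - pred) ** 2, axis=0)
    mean_mse = mse.mean(axis=0)
    se_mse = mse.std(axis=0, ddof=1) / np.sqrt(cv_folds)
    best = int(np.argmin(mean_mse))
    if rule == "1se":
        cutoff = mean_mse[best] + se_mse[best]
        ok = np.nonzero(mean_mse <= cutoff)[0]
        best = int(ok[0])  # largest lambda within one SE (path is decreasing)
    return best, mean_mse, se_mse


def r2_score(y, y_hat) -> float:
    """Proportion of variance explained, 1 - RSS/TSS; may be negative.

    Raises on fewer than 2 observations or zero total sum of squares."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size < 2:
        raise ValueError("need matched y / y_hat with >= 2 observations")
    tss = np.sum((y - y.mean()) ** 2)
    if tss == 0:
        raise ValueError("r2 undefined: response has zero variance")
    return float(1.0 - np.sum((y - y_hat) ** 2) / tss)


def adaptive_weights(beta_enet, gamma: float):
    """Adaptive penalty weights w_j = |beta_j|^(-gamma).

    Returns (weights, kept_index): predictors with a zero pilot
    coefficient carry an infinite penalty and are excluded outright.
    """
    if gamma <= 0:
        raise ValueError("gamma must be > 0")
    beta_enet = np.asarray(beta_enet, dtype=float)
    kept = np.nonzero(beta_enet != 0)[0]
    weights = np.abs(beta_enet[kept]) ** (-gamma)
    return weights, kept


class AdaptiveElasticNet(RegressorMixin, BaseEstimator):
    """Two-stage adaptive elastic-net regressor (see module docstring).

    Parameters mirror :class:`EnetConfig`. ``n_boot=0`` skips inference;
    with ``n_boot >= 2`` the fitted model carries bootstrap standard
    errors, p-values, and a significance mask at ``alpha_sig``.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (p,) final coefficients on the original predictor scale
        (zero outside the selected set), including the (1 + lambda2_abs/n)
        elastic-net rescale.
    intercept_ : float
    lambda1_ : selected L1 level of the adaptive stage (standardized scale)
    lambda2_abs_ : absolute ridge level lambda1_ * l2_weight
    pilot_coef_ : pilot elastic-net coefficients (original scale)
    se_, pvalues_ : (p,) bootstrap SEs / two-sided normal p-values
        (NaN outside the selected set; only with n_boot >= 2)
    significant_ : (p,) bool mask, nonzero coefficient and p < alpha_sig
    r2_ : training-data proportion of variance explained
    """

    def __init__(self, l2_weight=0.25, gamma=1.0, cv_folds=10, n_boot=0,
                 alpha_sig=0.05, lambda_rule="min", n_lambda=50,
                 lambda_min_ratio=1e-3, random_state=None):
        self.l2_weight = l2_weight
        self.gamma = gamma
        self.cv_folds = cv_folds
        self.n_boot = n_boot
        self.alpha_sig = alpha_sig
        self.lambda_rule = lambda_rule
        self.n_lambda = n_lambda
        self.lambda_min_ratio = lambda_min_ratio
        self.random_state = random_state

    # ------------------------------------------------------------------
    def fit(self, X, y):
        X = check_array(X, dtype=float)
        y = np.asarray(y, dtype=float).ravel()
        n, p = X.shape
        if len(y) != n:
            raise ValueError("X and y have inconsistent numbers of rows")
        if self.l2_weight < 0 or self.gamma <= 0:
            raise ValueError("require l2_weight >= 0 and gamma > 0")
        if self.n_boot == 1:
            raise ValueError("n_boot must be 0 or >= 2")
        if n < self.cv_folds:
            raise ValueError(
                f"{n} rows is fewer than cv_folds={self.cv_folds}"
            )
        self.n_features_in_ = p
        seed = 0 if self.random_state is None else int(self.random_state)

        if np.all(y == y[0]):
            warnings.warn("constant response: returning all-zero coefficients")
            return self._empty_fit(X, y)

        X_std, mu, sd, sd_safe = _standardize(X)
        y_mean = y.mean()
        y_c = y - y_mean
        G = X_std.T @ X_std
        c = X_std.T @ y_c

        # ---- stage 1: pilot elastic net (unit weights) ----
        w1 = np.ones(p)
        lambdas1 = _lambda_path(c, w1, self.n_lambda, self.lambda_min_ratio)
        i1, _, _ = _cv_select(X_std, y, lambdas1, self.l2_weight, w1,
                              self.cv_folds, self.lambda_rule, seed)
        lam_pilot = lambdas1[i1]
        beta_pilot = _cd_solve(G, c, lam_pilot, lam_pilot * self.l2_weight, w1)
        self.pilot_coef_ = beta_pilot / sd_safe
        self.pilot_lambda1_ = float(lam_pilot)

        w_ad, kept = adaptive_weights(beta_pilot, self.gamma)
        if kept.size == 0:
            return self._empty_fit(X, y)

        # ---- stage 2: adaptive-weighted elastic net on kept predictors ----
        Xk = X_std[:, kept]
        Gk = G[np.ix_(kept, kept)]
        ck = c[kept]
        lambdas2 = _lambda_path(ck, w_ad, self.n_lambda, self.lambda_min_ratio)
        i2, _, _ = _cv_select(Xk, y, lambdas2, self.l2_weight, w_ad,
                              self.cv_folds, self.lambda_rule, seed + 1)
        lam_ad = lambdas2[i2]
        lam2_abs = lam_ad * self.l2_weight
        beta_ad = _cd_solve(Gk, ck, lam_ad, lam2_abs, w_ad)
        rescale = 1.0 + lam2_abs / n
        beta_ad_rescaled = beta_ad * rescale

        coef = np.zeros(p)
        coef[kept] = beta_ad_rescaled / sd_safe[kept]
        self.coef_ = coef
        self.intercept_ = float(y_mean - coef @ mu)
        self.lambda1_ = float(lam_ad)
        self.lambda2_abs_ = float(lam2_abs)
        self.kept_ = kept
        self.adaptive_weights_ = w_ad
        self.r2_ = r2_score(y, self.intercept_ + X @ coef)

        if self.n_boot >= 2:
            se, pval = self._bootstrap(X_std, y, mu, sd_safe, kept, w_ad,
                                       lam_ad, lam2_abs, rescale, seed)
            self.se_ = se
            self.pvalues_ = pval
            self.significant_ = (coef != 0) & (
                np.nan_to_num(pval, nan=1.0) < self.alpha_sig
            )
        else:
            self.se_ = None
            self.pvalues_ = None
            self.significant_ = coef != 0
        return self

    # ------------------------------------------------------------------
    def _empty_fit(self, X, y):
        p = X.shape[1]
        self.coef_ = np.zeros(p)
        self.intercept_ = float(np.mean(y))
        self.lambda1_ = float("nan")
        self.lambda2_abs_ = 0.0
        self.kept_ = np.array([], dtype=int)
        self.adaptive_weights_ = np.array([])
        self.pilot_coef_ = getattr(self, "pilot_coef_", np.zeros(p))
        self.r2_ = 0.0
        self.se_ = None
        self.pvalues_ = None
        self.significant_ = np.zeros(p, dtype=bool)
        return self

    # ------------------------------------------------------------------
    def _bootstrap(self, X_std, y, mu, sd_safe, kept, w_ad, lam_ad,
                   lam2_abs, rescale, seed):
        """Resample rows, refit at the selected (lambda1, weights)."""
        n, p = X_std.shape
        rng = np.random.default_rng(seed + 2_000_003)
        Xk = X_std[:, kept]
        boot = np.zeros((self.n_boot, kept.size))
        for b in range(self.n_boot):
            idx = rng.integers(0, n, n)
            Xb = Xk[idx]
            yb = y[idx]
            mub = Xb.mean(axis=0)
            Xb = Xb - mub
            yb_c = yb - yb.mean()
            Gb = Xb.T @ Xb
            cb = Xb.T @ yb_c
            boot[b] = _cd_solve(Gb, cb, lam_ad, lam2_abs, w_ad, tol=1e-9)
        boot *= rescale
        boot /= sd_safe[kept]  # original scale
        se = np.full(p, np.nan)
        pval = np.full(p, np.nan)
        se_k = boot.std(axis=0, ddof=1)
        beta_k = self.coef_[kept]
        p_k = np.empty(kept.size)
        for j in range(kept.size):
            if se_k[j] < _DEGENERATE_SE:
                p_k[j] = 0.0 if beta_k[j] != 0 else 1.0
            else:
                p_k[j] = 2.0 * (1.0 - norm.cdf(abs(beta_k[j]) / se_k[j]))
        se[kept] = se_k
        pval[kept] = p_k
        return se, pval

    # ------------------------------------------------------------------
    def predict(self, X):
        check_is_fitted(self, "coef_")
        X = check_array(X, dtype=float)
        return self.intercept_ + X @ self.coef_

    def to_fit_result(self, gene_id: str, predictor_ids, n_obs: int,
                      significant_only: bool = True) -> FitResult:
        """Package the fitted model for one gene as a FitResult."""
        check_is_fitted(self, "coef_")
        mask = self.significant_ if significant_only else self.coef_ != 0
        sel = np.nonzero(mask)[0]
        ids = [predictor_ids[j] for j in sel]
        pos_in_kept = {j: i for i, j in enumerate(self.kept_)}
        w = np.array([self.adaptive_weights_[pos_in_kept[j]] for j in sel]) \
            if sel.size else np.array([])
        return FitResult(
            gene_id=gene_id,
            predictor_ids=ids,
            beta=self.coef_[sel],
            intercept=self.intercept_,
            se=None if self.se_ is None else self.se_[sel],
            pvalue=None if self.pvalues_ is None else self.pvalues_[sel],
            lambda1=self.lambda1_,
            lambda2=self.l2_weight,
            r2=self.r2_,
            n_obs=n_obs,
            adaptive_weights=w,
        )


# ----------------------------------------------------------------------
# thin functional wrappers over the estimator


def _estimator(config: EnetConfig, n_boot=None) -> AdaptiveElasticNet:
    return AdaptiveElasticNet(
        l2_weight=config.l2_weight, gamma=config.gamma,
        cv_folds=config.cv_folds,
        n_boot=config.n_boot if n_boot is None else n_boot,
        alpha_sig=config.alpha_sig, lambda_rule=config.lambda_rule,
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        random_state=config.seed,
    )


def fit_enet(X, y, config: EnetConfig) -> np.ndarray:
    """Pilot (non-adaptive) elastic-net coefficients, original scale."""
    est = _estimator(config, n_boot=0)
    est.fit(X, y)
    return est.pilot_coef_


def fit_adaptive_enet(X, y, config: EnetConfig, gene_id: str = "gene",
                      predictor_ids=None) -> FitResult:
    """Full two-stage fit with bootstrap filtering (if config.n_boot >= 2)."""
    X = np.asarray(X, dtype=float)
    if predictor_ids is None:
        predictor_ids = [f"x{j}" for j in range(X.shape[1])]
    est = _estimator(config)
    est.fit(X, y)
    return est.to_fit_result(gene_id, list(predictor_ids), n_obs=len(y))


def bootstrap_significance(X, y, fit: FitResult, config: EnetConfig) -> FitResult:
    """Bootstrap SEs/p-values for an already-selected model, then filter.

    Rows of (X, y) are resampled with replacement config.n_boot times and
    the model is refit at the fixed (lambda1, adaptive weights) recorded
    in ``fit``; predictors with p >= config.alpha_sig are removed.
    """
    if config.n_boot < 2:
        raise ValueError("n_boot must be >= 2 for bootstrap inference")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    if fit.adaptive_weights is None or not len(fit.predictor_ids):
        return fit
    if not np.isfinite(fit.lambda1):
        raise ValueError("fit carries no selected lambda1")
    n = len(y)
    rng = np.random.default_rng(config.seed + 2_000_003)
    lam2_abs = fit.lambda1 * fit.lambda2
    rescale = 1.0 + lam2_abs / n
    X_std, mu, sd, sd_safe = _standardize(X)
    boot = np.zeros((config.n_boot, X.shape[1]))
    for b in range(config.n_boot):
        idx = rng.integers(0, n, n)
        Xb = X_std[idx]
        yb = y[idx]
        Xb = Xb - Xb.mean(axis=0)
        yb_c = yb - yb.mean()
        boot[b] = _cd_solve(Xb.T @ Xb, Xb.T @ yb_c, fit.lambda1, lam2_abs,
                            fit.adaptive_weights, tol=1e-9)
    boot *= rescale
    boot /= sd_safe
    se = boot.std(axis=0, ddof=1)
    pval = np.empty_like(se)
    for j in range(len(se)):
        if se[j] < _DEGENERATE_SE:
            pval[j] = 0.0 if fit.beta[j] != 0 else 1.0
        else:
            pval[j] = 2.0 * (1.0 - norm.cdf(abs(fit.beta[j]) / se[j]))
    keep = (pval < config.alpha_sig) & (fit.beta != 0)
    return FitResult(
        gene_id=fit.gene_id,
        predictor_ids=[pid for pid, k in zip(fit.predictor_ids, keep) if k],
        beta=fit.beta[keep],
        intercept=fit.intercept,
        se=se[keep],
        pvalue=pval[keep],
        lambda1=fit.lambda1,
        lambda2=fit.lambda2,
        r2=fit.r2,
        n_obs=fit.n_obs,
        adaptive_weights=fit.adaptive_weights[keep],
    )
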