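"""Stage 2: fit each gene's expression on its candidate TFs' expression.

Single cells are preferred here (aggregation can average regulatory
heterogeneity away); the adaptive elastic net runs with ridge weight 0.5
and 100 bootstraps at full scale. Bootstrap-significant TFs become the
signed, weighted edges of the TF -> gene regulatory network.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .containers import OmicsMatrix
from .enet import AdaptiveElasticNet, EnetConfig, FitResult
from .enet import r2_score as _r2

__all__ = ["TfLink", "fit_gene_tfs", "predict_expression", "r2_score"]


@dataclass
class TfLink:
    tf_id: str
    gene_id: str
    beta: float
    se: float
    pvalue: float


def fit_gene_tfs(gene_id: str, expr: OmicsMatrix, candidates: list[str],
                 config: EnetConfig, allow_autoregulation: bool = False,
                 ) -> tuple[FitResult | None, list[TfLink]]:
    """Regress one gene's expression on its nominated TFs.

    Self-loops (the gene predicting itself) are removed unless
    ``allow_autoregulation``; constant-zero candidate columns are dropped.
    Returns (None, []) when no usable candidate remains.
    """
    cand = list(dict.fromkeys(candidates))  # dedupe, keep order
    if not allow_autoregulation:
        cand = [c for c in cand if c != gene_id]
    cand = [c for c in cand if expr.has_feature(c)]
    if not cand:
        warnings.warn(f"{gene_id}: no candidate TFs, gene skipped")
        return None, []
    X = expr.submatrix(cand)
    nonconst = ~np.all(X == X[0, :], axis=0)
    cand = [c for c, k in zip(cand, nonconst) if k]
    if not cand:
        warnings.warn(f"{gene_id}: all candidate TFs constant, gene skipped")
        return None, []
    X = X[:, nonconst]
    y = expr.feature_column(gene_id)
    if np.all(y == y[0]):
        warnings.warn(f"{gene_id}: constant expression, gene skipped")
        return None, []
    est = AdaptiveElasticNet(
        l2_weight=config.l2_weight, gamma=config.gamma,
        cv_folds=config.cv_folds, n_boot=config.n_boot,
        alpha_sig=config.alpha_sig, lambda_rule=config.lambda_rule,
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        random_state=config.seed,
    )
    est.fit(X, y)
    fit = est.to_fit_result(gene_id, cand, n_obs=len(y))
    links = [
        TfLink(
            tf_id=pid, gene_id=gene_id, beta=float(fit.beta[j]),
            se=float(fit.se[j]) if fit.se is not None else float("nan"),
            pvalue=float(fit.pvalue[j]) if fit.pvalue is not None
            else float("nan"),
        )
        for j, pid in enumerate(fit.predictor_ids)
    ]
    return fit, links


def predict_expression(fit: FitResult, tf_expr: OmicsMatrix) -> np.ndarray:
    """Per-cell prediction y_hat = intercept + sum_p beta_p * TF_p."""
    missing = [p for p in fit.predictor_ids if not tf_expr.has_feature(p)]
    if missing:
        raise KeyError(f"predictors missing from expression: {missing}")
    if not fit.predictor_ids:
        return np.full(tf_expr.n_cells, fit.intercept)
    X = tf_expr.submatrix(fit.predictor_ids)
    return fit.predict(X)


def r2_score(y, y_hat) -> float:
    """Proportion of variance explained (1 - RSS/TSS; may be negative)."""
    return _r2(y, y_hat)
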