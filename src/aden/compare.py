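"""Model selection (AIC) and set-overlap (Jaccard) utilities.

The distal-CRE question -- does a gene's full cis-coaccessibility network
add information over its promoter peaks alone? -- is answered by fitting
both configurations and comparing Akaike Information Criteria:
AIC = -2 l(beta_hat | data) + 2k with a Gaussian log-likelihood and k the
number of nonzero slope coefficients. delta_AIC = AIC_full - AIC_promoter
is negative when the distal model is more likely; exp(delta_AIC / 2)
converts it to a relative probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .enet import FitResult

__all__ = ["ModelComparison", "aic", "compare_models", "jaccard"]

_VAR_FLOOR = 1e-12  # keeps the log-likelihood finite on perfect fits


@dataclass
class ModelComparison:
    gene_id: str
    aic_full: float
    aic_promoter: float

    @property
    def delta_aic(self) -> float:
        return self.aic_full - self.aic_promoter

    @property
    def rel_probability(self) -> float:
        return float(np.exp(self.delta_aic / 2.0))


def aic(fit: FitResult, X, y) -> float:
    """AIC of a fitted model under a Gaussian error model.

    sigma^2 is the MLE max(RSS/n, 1e-12); k counts nonzero slope
    coefficients (the intercept, present in every model, is excluded so
    promoter-only and full models are compared on equal footing).
    """
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 2:
        raise ValueError("need at least 2 observations")
    y_hat = fit.predict(np.asarray(X, dtype=float)) if fit.predictor_ids \
        else np.full(n, fit.intercept)
    rss = float(np.sum((y - y_hat) ** 2))
    sigma2 = max(rss / n, _VAR_FLOOR)
    loglik = -0.5 * n * np.log(2.0 * np.pi * sigma2) - rss / (2.0 * sigma2)
    return float(-2.0 * loglik + 2.0 * fit.n_nonzero)


def compare_models(fit_full: FitResult, fit_promoter: FitResult,
                   X_full, X_prom, y) -> ModelComparison:
    """AIC comparison of the full CRE-network model against the
    promoter-only model for the same response; negative delta_aic favors
    the full model."""
    return ModelComparison(
        gene_id=fit_full.gene_id,
        aic_full=aic(fit_full, X_full, y),
        aic_promoter=aic(fit_promoter, X_prom, y),
    )


def jaccard(set_a, set_b) -> float:
    """|A intersect B| / |A union B|; two empty sets are identical (1)."""
    a, b = set(set_a), set(set_b)
    union = a | b
    if not union:
        warnings.warn("jaccard of two empty sets defined as 1")
        return 1.0
    return len(a & b) / len(union)
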