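"""Stage 1: link accessible peaks to target genes by regularized regression.

For each modeled gene, every accessible peak whose interval overlaps the
+/- 500 kb window around the TSS is a candidate cis-regulatory element
(CRE). The gene's (pseudocell) expression is regressed on the raw,
non-binarized accessibility of those candidates with the adaptive
elastic net (ridge weight 0.25, 1000 bootstraps at full scale);
bootstrap-significant peaks become CRE links carrying the signed
coefficient, the signed TSS distance, and a promoter / gene-body /
intergenic annotation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import GeneAnnotation, OmicsMatrix, PeakSet
from .enet import AdaptiveElasticNet, EnetConfig, FitResult

__all__ = ["CreLink", "candidate_peaks", "fit_gene_cres", "classify_cres",
           "score_cres"]

WINDOW_BP = 500_000       # candidate window half-width around the TSS
PROMOTER_LABEL_BP = 2_000  # +/- window for the promoter CRE-class label


@dataclass
class CreLink:
    gene_id: str
    peak_id: str
    beta: float
    se: float
    pvalue: float
    distance_to_tss: int  # signed; negative = upstream on the gene strand
    annotation: str       # promoter | gene_body | intergenic

    def __post_init__(self):
        if abs(self.distance_to_tss) > WINDOW_BP:
            raise ValueError(
                f"{self.peak_id}: distance {self.distance_to_tss} exceeds "
                f"the {WINDOW_BP} bp window"
            )
        if self.annotation not in ("promoter", "gene_body", "intergenic"):
            raise ValueError(f"bad annotation {self.annotation!r}")


def candidate_peaks(gene: pd.Series, peaks: PeakSet,
                    window: int = WINDOW_BP) -> list[str]:
    """Peaks overlapping [tss - window, tss + window), ordered by position.

    Membership is any-overlap of the peak interval with the window, so
    boundary peaks are retained. Returns [] for genes on chromosomes
    absent from the peak set.
    """
    df = peaks.df
    tss = int(gene["tss"])
    lo, hi = tss - window, tss + window
    sel = df[(df["chrom"] == gene["chrom"]) &
             (df["end"] > lo) & (df["start"] < hi)]
    sel = sel.sort_values(["start", "end"])
    return sel["peak_id"].tolist()


def _annotate_peak(gene: pd.Series, chrom: str, start: int, end: int
                   ) -> tuple[int, str]:
    """Signed TSS distance (peak midpoint, gene-strand oriented) and class."""
    tss = int(gene["tss"])
    mid = (start + end) // 2
    dist = mid - tss if gene["strand"] == "+" else tss - mid
    # promoter label: peak interval within +/- 2 kb of the TSS (any overlap)
    if start < tss + PROMOTER_LABEL_BP and end > tss - PROMOTER_LABEL_BP:
        ann = "promoter"
    elif start < int(gene["body_end"]) and end > int(gene["body_start"]):
        ann = "gene_body"
    else:
        ann = "intergenic"
    return int(dist), ann


def fit_gene_cres(gene_id: str, expr: OmicsMatrix, acc: OmicsMatrix,
                  peaks: PeakSet, annotation: GeneAnnotation,
                  config: EnetConfig, window: int = WINDOW_BP,
                  ) -> tuple[FitResult | None, list[CreLink]]:
    """Fit one gene's expression on candidate-peak accessibility.

    ``expr`` and ``acc`` must be row-aligned (same pseudocells, same
    order). Returns (FitResult over significant peaks, CRE links); a gene
    with no candidate peaks or constant expression yields (None, []).
    """
    if expr.cell_ids != acc.cell_ids:
        raise ValueError("expression and accessibility rows are not aligned")
    gene = annotation.gene(gene_id)
    cand = candidate_peaks(gene, peaks, window)
    if not cand:
        warnings.warn(f"{gene_id}: no candidate peaks in window")
        return None, []
    y = expr.feature_column(gene_id)
    if np.all(y == y[0]):
        warnings.warn(f"{gene_id}: constant expression, no CREs")
        return None, []
    X = acc.submatrix(cand)
    est = AdaptiveElasticNet(
        l2_weight=config.l2_weight, gamma=config.gamma,
        cv_folds=config.cv_folds, n_boot=config.n_boot,
        alpha_sig=config.alpha_sig, lambda_rule=config.lambda_rule,
        n_lambda=config.n_lambda, lambda_min_ratio=config.lambda_min_ratio,
        random_state=config.seed,
    )
    est.fit(X, y)
    fit = est.to_fit_result(gene_id, cand, n_obs=len(y))

    coord = {pid: peaks.coords(pid) for pid in fit.predictor_ids}
    links = []
    for j, pid in enumerate(fit.predictor_ids):
        chrom, start, end = coord[pid]
        dist, ann = _annotate_peak(gene, chrom, start, end)
        links.append(CreLink(
            gene_id=gene_id, peak_id=pid, beta=float(fit.beta[j]),
            se=float(fit.se[j]) if fit.se is not None else float("nan"),
            pvalue=float(fit.pvalue[j]) if fit.pvalue is not None
            else float("nan"),
            distance_to_tss=dist, annotation=ann,
        ))
    return fit, links


def classify_cres(links: list[CreLink], deg: pd.DataFrame) -> pd.DataFrame:
    """Label each CRE link as promoting one of the two contrasted states.

    ``deg`` has columns (gene_id, direction) with direction s_g = +1 for
    stateA-up and -1 for stateB-up. A link is stateA-promoting iff
    sign(beta) * s_g > 0 (it enhances a stateA-up gene or represses a
    stateB-up gene), otherwise stateB-promoting.
    """
    dirs = dict(zip(deg["gene_id"], deg["direction"]))
    rows = []
    for link in links:
        if link.gene_id not in dirs:
            raise KeyError(f"gene {link.gene_id} missing from DEG table")
        if link.beta == 0:
            raise ValueError(
                f"{link.gene_id}/{link.peak_id}: zero-coefficient link "
                "should have been filtered upstream"
            )
        s = dirs[link.gene_id]
        if s not in (1, -1):
            raise ValueError(f"direction for {link.gene_id} must be +/-1")
        label = "stateA-promoting" if np.sign(link.beta) * s > 0 \
            else "stateB-promoting"
        rows.append({"gene_id": link.gene_id, "peak_id": link.peak_id,
                     "beta": link.beta, "label": label})
    return pd.DataFrame(rows, columns=["gene_id", "peak_id", "beta", "label"])


def score_cres(links: list[CreLink], acc: OmicsMatrix,
               group: list[str] | None = None) -> pd.DataFrame:
    """Per-peak regulatory score: sum over target genes of beta x mean
    accessibility in the cell group; |score| tertiles support ranking.

    Returns a table (peak_id, score, abs_score, tertile) sorted by
    decreasing |score|; tertile 1 holds the largest-|score| third.
    """
    if group is not None and len(group) == 0:
        raise ValueError("empty cell group")
    mean_acc = acc.mean_per_feature(group)
    scores: dict[str, float] = {}
    for link in links:
        if link.peak_id not in mean_acc.index:
            raise KeyError(f"peak {link.peak_id} absent from accessibility")
        scores[link.peak_id] = scores.get(link.peak_id, 0.0) + \
            link.beta * float(mean_acc[link.peak_id])
    df = pd.DataFrame(
        {"peak_id": list(scores), "score": list(scores.values())}
    )
    df["abs_score"] = df["score"].abs()
    df = df.sort_values("abs_score", ascending=False, kind="mergesort")
    df = df.reset_index(drop=True)
    n = len(df)
    if n:
        df["tertile"] = (df.index * 3) // n + 1
    return df
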