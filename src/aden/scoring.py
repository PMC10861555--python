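"""Ranked biology from per-gene fits: TF scores, centrality, perturbation.

A TF's axis score sums its regulatory coefficients over the genes of a
two-state contrast, each weighted by the gene's direction (+1 for
stateA-up, -1 for stateB-up), times the TF's mean expression in the
relevant population -- positive scores mark stateA-promoting TFs.
Cell-type scores do the same over marker-gene sets. The signed, weighted
TF -> gene graph supports PageRank (on the edge-reversed graph, so
heavily-targeted regulators rank highly) and betweenness (with
distance = 1/weight), plus one-step in-silico TF perturbation projected
into a caller-supplied low-dimensional embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .containers import OmicsMatrix
from .enet import FitResult
from .tf import TfLink

__all__ = ["PerturbationSpec", "tf_axis_score", "tf_celltype_scores",
           "build_graph", "pagerank", "betweenness", "simulate_perturbation"]


@dataclass
class PerturbationSpec:
    """Per-TF perturbation rules for in-silico knockdown/upregulation.

    rules maps tf_id -> ("knockdown_to_zero",) | ("scale", factor)
    | ("set_to_quantile", q).
    """

    rules: dict[str, tuple] = field(default_factory=dict)

    def __post_init__(self):
        for tf, rule in self.rules.items():
            kind = rule[0]
            if kind == "knockdown_to_zero":
                continue
            if kind == "scale":
                if rule[1] < 0:
                    raise ValueError(f"{tf}: scale factor must be >= 0")
            elif kind == "set_to_quantile":
                if not 0.0 <= rule[1] <= 1.0:
                    raise ValueError(f"{tf}: quantile must be in [0, 1]")
            else:
                raise ValueError(f"{tf}: unknown rule {kind!r}")


def tf_axis_score(links: list[TfLink], deg: pd.DataFrame,
                  mean_expr: dict[str, float] | pd.Series) -> pd.DataFrame:
    """score(TF) = mean_expr(TF) * sum_g s_g * beta_{TF,g}, sorted
    descending (positive = stateA-promoting)."""
    dirs = dict(zip(deg["gene_id"], deg["direction"]))
    sums: dict[str, float] = {}
    for link in links:
        if link.gene_id not in dirs:
            raise KeyError(f"gene {link.gene_id} missing from DEG table")
        s = dirs[link.gene_id]
        if s not in (1, -1):
            raise ValueError(f"direction for {link.gene_id} must be +/-1")
        sums[link.tf_id] = sums.get(link.tf_id, 0.0) + s * link.beta
    rows = []
    for tf, total in sums.items():
        if tf not in mean_expr:
            raise KeyError(f"mean expression missing for TF {tf}")
        rows.append({"tf_id": tf, "score": float(mean_expr[tf]) * total})
    df = pd.DataFrame(rows, columns=["tf_id", "score"])
    return df.sort_values("score", ascending=False,
                          kind="mergesort").reset_index(drop=True)


def tf_celltype_scores(links: list[TfLink],
                       markers: dict[str, list[str]],
                       mean_expr: dict[str, dict[str, float]]
                       ) -> pd.DataFrame:
    """TF x cell-type score matrix.

    score(TF, c) = mean_expr[c][TF] * sum over the cell type's marker
    genes of beta_{TF,g}. Marker sets may overlap across cell types.
    """
    unknown = set(mean_expr) - set(markers)
    if unknown:
        raise KeyError(f"unknown cell types: {sorted(unknown)}")
    tfs = sorted({l.tf_id for l in links})
    cols = {}
    for ct, genes in markers.items():
        gset = set(genes)
        sums = {tf: 0.0 for tf in tfs}
        for link in links:
            if link.gene_id in gset:
                sums[link.tf_id] += link.beta
        me = mean_expr.get(ct, {})
        cols[ct] = [me.get(tf, 0.0) * sums[tf] for tf in tfs]
    return pd.DataFrame(cols, index=tfs)


def top_k(scores: pd.Series | pd.DataFrame, k: int, column=None) -> set[str]:
    """Top-k index labels by score (for Jaccard comparisons)."""
    s = scores[column] if column is not None else scores
    return set(s.sort_values(ascending=False).head(k).index)


def build_graph(links: list[TfLink],
                mean_expr: dict[str, float] | pd.Series) -> nx.DiGraph:
    """Directed TF -> gene graph; weight = |beta| * mean TF expression,
    sign = sign(beta). Parallel links to the same gene are summed on beta
    before weighting."""
    g = nx.DiGraph()
    for link in links:
        if link.tf_id not in mean_expr:
            raise KeyError(f"mean expression missing for TF {link.tf_id}")
        w = abs(link.beta) * float(mean_expr[link.tf_id])
        g.add_node(link.tf_id, role="tf")
        if link.gene_id not in g or g.nodes[link.gene_id].get("role") != "tf":
            g.add_node(link.gene_id,
                       role=g.nodes.get(link.gene_id, {}).get("role", "gene"))
        g.add_edge(link.tf_id, link.gene_id, weight=w,
                   sign=int(np.sign(link.beta)), beta=link.beta)
    return g


def pagerank(graph: nx.DiGraph, damping: float = 0.85,
             direction: str = "reversed") -> pd.Series:
    """Weighted PageRank; by default on the edge-reversed graph so that
    regulators accrue rank from their targets. Scores sum to 1."""
    if graph.number_of_edges() == 0:
        raise ValueError("empty graph")
    g = graph.reverse() if direction == "reversed" else graph
    pr = nx.pagerank(g, alpha=damping, weight="weight", tol=1e-12,
                     max_iter=500)
    return pd.Series(pr).sort_values(ascending=False)


def betweenness(graph: nx.DiGraph) -> pd.Series:
    """Betweenness centrality on the original directed graph with edge
    strength converted to distance = 1/weight."""
    if graph.number_of_edges() == 0:
        raise ValueError("empty graph")
    g = graph.copy()
    for _, _, d in g.edges(data=True):
        w = d.get("weight", 1.0)
        d["distance"] = 1.0 / w if w > 0 else np.inf
    bc = nx.betweenness_centrality(g, weight="distance")
    return pd.Series(bc).sort_values(ascending=False)


def simulate_perturbation(spec: PerturbationSpec, tf_expr: OmicsMatrix,
                          fits: list[FitResult],
                          loadings: pd.DataFrame,
                          center: pd.Series | None = None,
                          scale: pd.Series | None = None):
    """One-step in-silico TF perturbation projected into an embedding.

    The perturbed predictor matrix X_perturb applies the perturbation rules to
    the TF columns; every modeled gene's expression is re-predicted as
    y_hat = X_perturb beta_hat. Baseline profiles substitute the models'
    unperturbed predictions for the same genes (so an identity
    perturbation moves nothing); unmodeled features keep observed values
    in both. Profiles are centered/scaled as the embedding was built and
    projected through ``loadings`` (features x dims).

    Returns (baseline_coords, perturbed_coords, displacement) as
    cells x dims DataFrames.
    """
    modeled = [f for f in fits if f is not None]
    known_tfs = {p for f in modeled for p in f.predictor_ids}
    unknown = [tf for tf in spec.rules if tf not in known_tfs]
    if unknown:
        raise KeyError(f"perturbed TFs appear in no fit: {unknown}")

    feat_index = {f: j for j, f in enumerate(tf_expr.feature_ids)}
    base_vals = np.asarray(tf_expr.values.todense(), dtype=float)
    pert_vals = base_vals.copy()
    for tf, rule in spec.rules.items():
        if tf not in feat_index:
            raise KeyError(f"perturbed TF {tf} absent from expression matrix")
        j = feat_index[tf]
        col = pert_vals[:, j]
        if rule[0] == "knockdown_to_zero":
            pert_vals[:, j] = 0.0
        elif rule[0] == "scale":
            pert_vals[:, j] = col * rule[1]
        elif rule[0] == "set_to_quantile":
            pert_vals[:, j] = np.quantile(base_vals[:, j], rule[1])

    profile_base = base_vals.copy()
    profile_pert = pert_vals.copy()
    for fit in modeled:
        g = fit.gene_id
        if g not in feat_index:
            continue
        cols = [feat_index[p] for p in fit.predictor_ids]
        gj = feat_index[g]
        profile_base[:, gj] = fit.intercept + base_vals[:, cols] @ fit.beta
        profile_pert[:, gj] = fit.intercept + pert_vals[:, cols] @ fit.beta

    feats = [f for f in tf_expr.feature_ids if f in loadings.index]
    if not feats:
        raise ValueError("loadings cover none of the expression features")
    L = loadings.loc[feats].to_numpy()
    idx = [feat_index[f] for f in feats]
    mu = center.loc[feats].to_numpy() if center is not None \
        else np.zeros(len(feats))
    sd = scale.loc[feats].to_numpy() if scale is not None \
        else np.ones(len(feats))
    zb = (profile_base[:, idx] - mu) / sd
    zp = (profile_pert[:, idx] - mu) / sd
    dims = list(loadings.columns)
    coords_b = pd.DataFrame(zb @ L, index=list(tf_expr.cell_ids), columns=dims)
    coords_p = pd.DataFrame(zp @ L, index=list(tf_expr.cell_ids), columns=dims)
    return coords_b, coords_p, coords_p - coords_b
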