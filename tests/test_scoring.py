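"""Axis scores, graph centralities, and in-silico perturbation."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from aden.containers import OmicsMatrix
from aden.enet import FitResult
from aden.scoring import (
    PerturbationSpec,
    betweenness,
    build_graph,
    pagerank,
    simulate_perturbation,
    tf_axis_score,
    tf_celltype_scores,
    top_k,
)
from aden.tf import TfLink


def _links():
    return [
        TfLink("TF1", "gA", 0.5, 0.1, 0.01),
        TfLink("TF1", "gB", -0.2, 0.1, 0.01),
        TfLink("TF2", "gA", 1.0, 0.1, 0.01),
    ]


DEG = pd.DataFrame({"gene_id": ["gA", "gB"], "direction": [1, -1]})
MEAN = pd.Series({"TF1": 2.0, "TF2": 0.5})


def test_axis_score_matches_hand_computation():
    out = tf_axis_score(_links(), DEG, MEAN).set_index("tf_id")["score"]
    # TF1: 2.0 * (+1*0.5 + (-1)*(-0.2)) = 1.4 ; TF2: 0.5 * 1.0 = 0.5
    assert out["TF1"] == pytest.approx(1.4)
    assert out["TF2"] == pytest.approx(0.5)


def test_reversing_deg_directions_negates_every_axis_score():
    flipped = DEG.assign(direction=-DEG["direction"])
    a = tf_axis_score(_links(), DEG, MEAN).set_index("tf_id")["score"]
    b = tf_axis_score(_links(), flipped, MEAN).set_index("tf_id")["score"]
    assert np.allclose(a.values, -b.loc[a.index].values)


def test_axis_score_validates_inputs():
    with pytest.raises(KeyError, match="missing from DEG"):
        tf_axis_score([TfLink("TF1", "unknown", 1.0, 0.1, 0.01)], DEG, MEAN)
    with pytest.raises(KeyError, match="mean expression"):
        tf_axis_score(_links(), DEG, pd.Series({"TF1": 1.0}))
    bad = DEG.assign(direction=[2, -1])
    with pytest.raises(ValueError, match="direction"):
        tf_axis_score(_links(), bad, MEAN)


def test_celltype_scores_and_topk():
    markers = {"ctA": ["gA"], "ctB": ["gA", "gB"]}
    me = {"ctA": {"TF1": 1.0, "TF2": 1.0}, "ctB": {"TF1": 2.0, "TF2": 0.0}}
    out = tf_celltype_scores(_links(), markers, me)
    assert out.loc["TF1", "ctA"] == pytest.approx(0.5)
    assert out.loc["TF1", "ctB"] == pytest.approx(2.0 * (0.5 - 0.2))
    assert out.loc["TF2", "ctB"] == 0.0
    assert top_k(out["ctA"], 1) == {"TF2"}
    with pytest.raises(KeyError, match="unknown cell types"):
        tf_celltype_scores(_links(), {"ctA": []}, me)


def test_graph_weights_and_reversed_pagerank_rank_regulators():
    g = build_graph(_links(), MEAN)
    assert g["TF1"]["gA"]["weight"] == pytest.approx(0.5 * 2.0)
    assert g["TF1"]["gB"]["sign"] == -1
    pr = pagerank(g)
    assert abs(pr.sum() - 1.0) < 1e-9
    # on the reversed graph the heavily-targeted regulators outrank genes
    assert pr["TF1"] > pr["gB"]
    fwd = pagerank(g, direction="forward")
    assert abs(fwd.sum() - 1.0) < 1e-9
    assert fwd["gA"] > fwd["TF1"]  # forward flow accumulates at targets
    with pytest.raises(ValueError, match="empty graph"):
        pagerank(nx.DiGraph())


def test_three_cycle_pagerank_is_uniform_and_matches_power_iteration():
    links = [TfLink("a", "b", 1.0, 0, 0), TfLink("b", "c", 2.0, 0, 0),
             TfLink("c", "a", 0.5, 0, 0)]
    mean = pd.Series({"a": 1.0, "b": 1.0, "c": 1.0})
    g = build_graph(links, mean)
    pr = pagerank(g)
    assert np.allclose(pr.values, 1.0 / 3.0, atol=1e-9)

    # independent power iteration on the reversed, row-normalized graph
    rg = g.reverse()
    nodes = sorted(rg.nodes)
    W = np.zeros((3, 3))
    for u, v, d in rg.edges(data=True):
        W[nodes.index(u), nodes.index(v)] = d["weight"]
    W = W / W.sum(axis=1, keepdims=True)
    r = np.full(3, 1.0 / 3.0)
    for _ in range(10_000):
        r = 0.15 / 3.0 + 0.85 * (r @ W)
    assert np.max(np.abs(pr.loc[nodes].values - r)) < 1e-10


def test_star_graph_betweenness_puts_the_hub_on_every_path():
    links = [TfLink("hub", leaf, 1.0, 0, 0) for leaf in ["x", "y", "z"]] + \
        [TfLink("src", "hub", 1.0, 0, 0)]
    mean = pd.Series({"hub": 1.0, "src": 1.0})
    bc = betweenness(build_graph(links, mean))
    assert bc["hub"] > 0
    assert bc[["x", "y", "z"]].max() == 0.0


def test_identity_perturbation_produces_exactly_zero_displacement():
    rng = np.random.default_rng(0)
    n = 50
    tf = rng.uniform(0.5, 2.0, n)
    gene = 1.0 + 2.0 * tf + rng.normal(scale=0.1, size=n)
    expr = OmicsMatrix(
        values=sparse.csc_matrix(np.column_stack([gene, tf])),
        cell_ids=[f"c{i}" for i in range(n)],
        feature_ids=["g", "TF1"], modality="rna")
    fit = FitResult(gene_id="g", predictor_ids=["TF1"],
                    beta=np.array([2.0]), intercept=1.0, se=None,
                    pvalue=None, lambda1=0.1, lambda2=0.5, r2=0.99,
                    n_obs=n)
    loadings = pd.DataFrame(rng.normal(size=(2, 2)), index=["g", "TF1"],
                            columns=["d1", "d2"])
    spec = PerturbationSpec(rules={"TF1": ("scale", 1.0)})  # identity
    base, pert, disp = simulate_perturbation(spec, expr, [fit], loadings)
    assert np.all(disp.to_numpy() == 0.0)


def test_knockdown_moves_cells_against_the_regulated_direction():
    rng = np.random.default_rng(1)
    n = 100
    tf = rng.uniform(1.0, 2.0, n)
    gene = 3.0 * tf + rng.normal(scale=0.05, size=n)
    expr = OmicsMatrix(
        values=sparse.csc_matrix(np.column_stack([gene, tf])),
        cell_ids=[f"c{i}" for i in range(n)],
        feature_ids=["g", "TF1"], modality="rna")
    fit = FitResult(gene_id="g", predictor_ids=["TF1"],
                    beta=np.array([3.0]), intercept=0.0, se=None,
                    pvalue=None, lambda1=0.1, lambda2=0.5, r2=0.99,
                    n_obs=n)
    loadings = pd.DataFrame([[1.0], [0.0]], index=["g", "TF1"],
                            columns=["d1"])  # dim 1 reads out the gene
    spec = PerturbationSpec(rules={"TF1": ("knockdown_to_zero",)})
    _, _, disp = simulate_perturbation(spec, expr, [fit], loadings)
    assert np.all(disp["d1"].to_numpy() < 0)  # predicted expression drops
    assert np.allclose(disp["d1"].to_numpy(), -3.0 * tf)


def test_perturbation_spec_validation():
    with pytest.raises(ValueError, match="scale factor"):
        PerturbationSpec(rules={"t": ("scale", -1.0)})
    with pytest.raises(ValueError, match="quantile"):
        PerturbationSpec(rules={"t": ("set_to_quantile", 2.0)})
    with pytest.raises(ValueError, match="unknown rule"):
        PerturbationSpec(rules={"t": ("overexpress",)})
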