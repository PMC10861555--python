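"""Stage-1 geometry (candidate windows, annotations) and CRE utilities."""

import numpy as np
import pandas as pd
import pytest
from scipy import sparse

from aden.containers import GeneAnnotation, OmicsMatrix, PeakSet
from aden.cre import (
    CreLink,
    WINDOW_BP,
    _annotate_peak,
    candidate_peaks,
    classify_cres,
    fit_gene_cres,
    score_cres,
)
from aden.enet import EnetConfig


def _gene(tss, strand="+", chrom="chr1", body=20_000):
    if strand == "+":
        bs, be = tss, tss + body
    else:
        bs, be = tss - body + 1, tss + 1
    return pd.Series({"gene_id": "g", "chrom": chrom, "strand": strand,
                      "tss": tss, "body_start": bs, "body_end": be})


def _peakset(rows):
    return PeakSet(pd.DataFrame(rows,
                                columns=["chrom", "start", "end", "peak_id"]))


def test_candidate_window_uses_any_overlap_with_half_open_bounds():
    tss = 1_000_000
    lo, hi = tss - WINDOW_BP, tss + WINDOW_BP
    ps = _peakset([
        ("chr1", lo - 400, lo, "ends_at_lo"),        # end == lo: out
        ("chr1", lo - 1, lo + 1, "spans_lo"),        # one base inside: in
        ("chr1", tss - 10, tss + 10, "at_tss"),
        ("chr1", hi - 1, hi + 400, "spans_hi"),      # starts inside: in
        ("chr1", hi, hi + 400, "starts_at_hi"),      # start == hi: out
        ("chr2", tss, tss + 100, "wrong_chrom"),
    ])
    got = candidate_peaks(_gene(tss), ps)
    assert got == ["spans_lo", "at_tss", "spans_hi"]


def test_candidate_order_is_positional():
    tss = 1_000_000
    ps = _peakset([
        ("chr1", tss + 100, tss + 200, "b"),
        ("chr1", tss - 300, tss - 100, "a"),
    ])
    assert candidate_peaks(_gene(tss), ps) == ["a", "b"]


def test_tss_distance_is_strand_oriented():
    # midpoint of [9_500, 9_998) is 9_749
    dist_plus, _ = _annotate_peak(_gene(8_999, "+"), "chr1", 9_500, 9_998)
    assert dist_plus == 9_749 - 8_999
    dist_minus, _ = _annotate_peak(_gene(8_999, "-"), "chr1", 9_500, 9_998)
    assert dist_minus == 8_999 - 9_749  # downstream of a '-' gene is upstream


def test_peak_annotation_classes():
    g = _gene(100_000, "+")
    _, ann = _annotate_peak(g, "chr1", 99_500, 100_500)
    assert ann == "promoter"  # overlaps +/- 2 kb of the TSS
    _, ann = _annotate_peak(g, "chr1", 110_000, 110_500)
    assert ann == "gene_body"  # inside [tss, tss + 20 kb)
    _, ann = _annotate_peak(g, "chr1", 300_000, 300_500)
    assert ann == "intergenic"
    # boundary: peak ending exactly at tss - 2000 is not a promoter
    _, ann = _annotate_peak(g, "chr1", 97_500, 98_000)
    assert ann == "intergenic"


def test_cre_link_validates_window_and_annotation():
    with pytest.raises(ValueError, match="window"):
        CreLink("g", "p", 1.0, 0.1, 0.01, WINDOW_BP + 1, "intergenic")
    with pytest.raises(ValueError, match="annotation"):
        CreLink("g", "p", 1.0, 0.1, 0.01, 0, "enhancer")


def test_fit_gene_cres_recovers_a_planted_peak():
    rng = np.random.default_rng(0)
    n = 300
    tss = 1_000_000
    ps = _peakset([
        ("chr1", tss - 100, tss + 400, "prom"),
        ("chr1", tss + 50_000, tss + 50_500, "distal"),
        ("chr1", tss - 200_000, tss - 199_500, "noise"),
    ])
    acc_vals = rng.uniform(0.5, 2.0, (n, 3))
    y = 1.0 + 2.0 * acc_vals[:, 1] + rng.normal(scale=0.1, size=n)
    cells = [f"c{i}" for i in range(n)]
    expr = OmicsMatrix(values=sparse.csc_matrix(y[:, None]), cell_ids=cells,
                       feature_ids=["g"], modality="rna")
    acc = OmicsMatrix(values=sparse.csc_matrix(acc_vals), cell_ids=cells,
                      feature_ids=ps.peak_ids, modality="atac")
    ann = GeneAnnotation(pd.DataFrame([_gene(tss)]))
    fit, links = fit_gene_cres("g", expr, acc, ps, ann,
                               EnetConfig(n_boot=50, seed=1))
    assert [l.peak_id for l in links] == ["distal"]
    assert abs(links[0].beta - 2.0) < 0.1
    assert links[0].annotation == "intergenic"  # beyond the 20 kb gene body
    assert links[0].distance_to_tss == 50_250  # midpoint minus tss
    with pytest.raises(ValueError, match="aligned"):
        fit_gene_cres("g", expr, OmicsMatrix(
            values=acc.values, cell_ids=list(reversed(cells)),
            feature_ids=ps.peak_ids, modality="atac"), ps, ann,
            EnetConfig(n_boot=0))


def test_classification_follows_the_sign_product_rule():
    links = [
        CreLink("up_gene", "p1", 0.8, 0.1, 0.01, 0, "promoter"),
        CreLink("up_gene", "p2", -0.5, 0.1, 0.01, 0, "intergenic"),
        CreLink("down_gene", "p3", 0.6, 0.1, 0.01, 0, "intergenic"),
    ]
    deg = pd.DataFrame({"gene_id": ["up_gene", "down_gene"],
                        "direction": [1, -1]})
    out = classify_cres(links, deg)
    assert out.set_index("peak_id")["label"].to_dict() == {
        "p1": "stateA-promoting",   # enhances a stateA-up gene
        "p2": "stateB-promoting",   # represses a stateA-up gene
        "p3": "stateB-promoting",   # enhances a stateB-up gene
    }
    with pytest.raises(KeyError):
        classify_cres([CreLink("missing", "p", 1.0, 0.1, 0.01, 0,
                               "intergenic")], deg)
    with pytest.raises(ValueError, match="zero-coefficient"):
        classify_cres([CreLink("up_gene", "p", 0.0, 0.1, 0.9, 0,
                               "intergenic")], deg)


def test_cre_scores_aggregate_and_rank_into_tertiles():
    cells = ["c0", "c1"]
    acc = OmicsMatrix(
        values=sparse.csc_matrix(np.array([[1.0, 2.0, 4.0],
                                           [3.0, 2.0, 4.0]])),
        cell_ids=cells, feature_ids=["pa", "pb", "pc"], modality="atac")
    links = [
        CreLink("g1", "pa", 1.0, 0.1, 0.01, 0, "intergenic"),
        CreLink("g2", "pa", 0.5, 0.1, 0.01, 0, "intergenic"),
        CreLink("g1", "pb", -2.0, 0.1, 0.01, 0, "intergenic"),
        CreLink("g1", "pc", 0.1, 0.1, 0.01, 0, "intergenic"),
    ]
    out = score_cres(links, acc)
    scores = out.set_index("peak_id")["score"]
    assert scores["pa"] == pytest.approx(1.5 * 2.0)   # summed over genes
    assert scores["pb"] == pytest.approx(-2.0 * 2.0)
    assert out["peak_id"].tolist() == ["pb", "pa", "pc"]  # by |score|
    assert out["tertile"].tolist() == [1, 2, 3]
    with pytest.raises(ValueError, match="empty cell group"):
        score_cres(links, acc, group=[])
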