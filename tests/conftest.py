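"""Shared fixtures: small/default synthetic datasets and the canonical
end-to-end pipeline run (computed once per session)."""

from dataclasses import replace

import numpy as np
import pytest

from aden import simulate_multiome
from aden.containers import estimate_size_factors, library_size_normalize
from aden.motifs import expressed_tf_set
from aden.pipeline import (
    STAGE1_CONFIG,
    STAGE2_CONFIG,
    nominate_tfs,
    run_stage1,
    run_stage2,
)


@pytest.fixture(scope="session")
def sim_small():
    return simulate_multiome(n_cells=300, n_genes=6, n_tfs=8,
                             peaks_per_gene=12, true_cres_per_gene=3,
                             seed=11)


@pytest.fixture(scope="session")
def sim_default():
    return simulate_multiome(seed=7)


@pytest.fixture(scope="session")
def e2e(sim_default):
    """Canonical end-to-end run on the default regime: pooled-depth
    normalization, stage 1 (n_boot scaled to 100), TF nomination,
    stage 2 (n_boot scaled to 50)."""
    sim = sim_default
    factors = estimate_size_factors(sim.expr, sim.acc)
    expr = library_size_normalize(sim.expr, factors)
    acc = library_size_normalize(sim.acc, factors)
    cfg1 = replace(STAGE1_CONFIG, n_boot=100, seed=7)
    cfg2 = replace(STAGE2_CONFIG, n_boot=50, seed=7)
    fits1, cre_links = run_stage1(sim.gene_ids, expr, acc, sim.peaks,
                                  sim.genes, cfg1)
    expressed = expressed_tf_set(expr, sim.tf_ids)
    candidates = nominate_tfs(sim.gene_ids, cre_links, sim.hits, sim.peaks,
                              sim.genes, expressed)
    fits2, tf_links = run_stage2(candidates, expr, cfg2)
    return {
        "sim": sim,
        "expr": expr,
        "acc": acc,
        "fits1": fits1,
        "cre_links": cre_links,
        "candidates": candidates,
        "fits2": fits2,
        "tf_links": tf_links,
        "expressed": expressed,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
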