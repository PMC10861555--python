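"""High-level orchestration of the two-stage network inference.

Per-gene fits are independent; each gene draws its RNG stream from the
global seed plus a stable hash of its id, so gene order (and any
parallel scheduling) cannot perturb results.
"""

from __future__ import annotations

import zlib
from dataclasses import replace

import numpy as np
import pandas as pd

from .containers import GeneAnnotation, OmicsMatrix, PeakSet
from .cre import CreLink, fit_gene_cres
from .enet import EnetConfig, FitResult
from .motifs import PeakMotifHits, candidate_tfs, promoter_peaks
from .tf import TfLink, fit_gene_tfs

__all__ = ["gene_seed", "run_stage1", "nominate_tfs", "run_stage2"]

STAGE1_CONFIG = EnetConfig(l2_weight=0.25, n_boot=1000)
STAGE2_CONFIG = EnetConfig(l2_weight=0.5, n_boot=100)


def gene_seed(global_seed: int, gene_id: str) -> int:
    """Deterministic per-gene seed below 2^31."""
    return (int(global_seed) + zlib.crc32(gene_id.encode())) % (2**31 - 1)


def run_stage1(gene_ids, expr: OmicsMatrix, acc: OmicsMatrix,
               peaks: PeakSet, annotation: GeneAnnotation,
               config: EnetConfig = STAGE1_CONFIG, window: int = 500_000,
               ) -> tuple[dict[str, FitResult], list[CreLink]]:
    """CRE models for every gene; returns ({gene: fit}, all links)."""
    fits: dict[str, FitResult] = {}
    links: list[CreLink] = []
    for gid in gene_ids:
        cfg = replace(config, seed=gene_seed(config.seed, gid))
        fit, gene_links = fit_gene_cres(gid, expr, acc, peaks, annotation,
                                        cfg, window=window)
        if fit is not None:
            fits[gid] = fit
        links.extend(gene_links)
    return fits, links


def nominate_tfs(gene_ids, cre_links: list[CreLink], hits: PeakMotifHits,
                 peaks: PeakSet, annotation: GeneAnnotation,
                 expressed_tfs: set[str]) -> dict[str, list[str]]:
    """Candidate TFs per gene from motifs in significant CREs/promoters."""
    by_gene: dict[str, list[CreLink]] = {}
    for link in cre_links:
        by_gene.setdefault(link.gene_id, []).append(link)
    out = {}
    for gid in gene_ids:
        prom = promoter_peaks(annotation.gene(gid), peaks)
        out[gid] = candidate_tfs(gid, by_gene.get(gid, []), hits, prom,
                                 expressed_tfs)
    return out


def run_stage2(candidates: dict[str, list[str]], expr: OmicsMatrix,
               config: EnetConfig = STAGE2_CONFIG,
               ) -> tuple[dict[str, FitResult], list[TfLink]]:
    """TF models for every gene with a nonempty candidate list."""
    fits: dict[str, FitResult] = {}
    links: list[TfLink] = []
    for gid, cand in candidates.items():
        if not cand:
            continue
        cfg = replace(config, seed=gene_seed(config.seed, gid))
        fit, gene_links = fit_gene_tfs(gid, expr, cand, cfg)
        if fit is not None:
            fits[gid] = fit
        links.extend(gene_links)
    return fits, links


def links_to_frame(links) -> pd.DataFrame:
    rows = [vars(l).copy() for l in links]
    return pd.DataFrame(rows)
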