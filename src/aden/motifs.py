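"""TF nomination: motif scanning, promoter intervals, and enrichment.

Significant CREs from stage 1 and the target gene's promoter (the
strand-aware 2 kb immediately upstream of the TSS) are annotated with TF
binding motifs; any expressed TF with a motif in that peak set becomes a
stage-2 candidate regulator. An optional stricter variant keeps only TFs
whose motifs are enriched in the gene's CRE set relative to a GC-matched
background (one-sided Fisher exact test, Benjamini-Hochberg adjusted
p < 0.05).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact
from statsmodels.stats.multitest import multipletests

from .containers import GeneAnnotation, Motif, MotifSet, PeakSet
from .cre import CreLink

__all__ = ["PeakMotifHits", "scan_motifs", "promoter_interval",
           "candidate_tfs", "enriched_tfs"]

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PeakMotifHits:
    """Binary peak x motif incidence from log-odds scanning (both strands)."""

    hits: pd.DataFrame  # index: peak ids, columns: motif ids, values {0,1}
    scan_threshold: float = 0.8
    motif_to_tf: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        vals = self.hits.to_numpy()
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("hit matrix must be binary")
        self.hits = self.hits.astype(int)

    def peaks_with_motif(self, motif_id: str) -> list[str]:
        col = self.hits[motif_id]
        return col.index[col > 0].tolist()

    def motifs_in_peaks(self, peak_ids) -> list[str]:
        present = [p for p in peak_ids if p in self.hits.index]
        if not present:
            return []
        sub = self.hits.loc[present]
        return sub.columns[(sub.sum(axis=0) > 0)].tolist()

    def tfs_in_peaks(self, peak_ids) -> list[str]:
        tfs = {self.motif_to_tf.get(m, m) for m in self.motifs_in_peaks(peak_ids)}
        return sorted(tfs)


def _log_odds_matrix(motif: Motif) -> np.ndarray:
    """5 x width score matrix (log2 odds); row 4 (N) scores the
    background-expected value of the column."""
    pfm = motif.pfm
    probs = (pfm + 1e-3) / (pfm.sum(axis=0, keepdims=True) + 4e-3)
    bg = motif.background[:, None]
    lods = np.log2(probs / bg)
    expected = (motif.background[:, None] * lods).sum(axis=0, keepdims=True)
    return np.vstack([lods, expected])


def _encode(seq: str) -> np.ndarray:
    return np.array([_BASE_INDEX.get(b, 4) for b in seq.upper()], dtype=np.int64)


def _best_window_score(code: np.ndarray, lods: np.ndarray) -> float:
    w = lods.shape[1]
    L = code.size
    if L < w:
        return -np.inf
    # per-position scores for all windows via a strided view
    windows = np.lib.stride_tricks.sliding_window_view(code, w)
    scores = lods[windows, np.arange(w)].sum(axis=1)
    return float(scores.max())


def scan_motifs(sequences: dict[str, str], motifs: MotifSet,
                rel_threshold: float = 0.8) -> PeakMotifHits:
    """Scan named peak sequences for motif hits on both strands.

    A peak hits a motif iff the best window's log-odds score, rescaled so
    the minimum achievable score maps to 0 and the maximum to 1, reaches
    ``rel_threshold``. Ambiguous bases (N) score their background
    expectation. A motif wider than a sequence simply cannot hit it.
    """
    if not sequences:
        raise ValueError("empty sequence set")
    if not 0.0 <= rel_threshold <= 1.0:
        raise ValueError("rel_threshold must be in [0, 1]")
    peak_ids = list(sequences)
    codes = {p: _encode(s) for p, s in sequences.items()}
    rc_codes = {p: _encode(s.translate(_COMPLEMENT)[::-1])
                for p, s in sequences.items()}
    out = np.zeros((len(peak_ids), len(motifs)), dtype=int)
    for mj, motif in enumerate(motifs):
        lods = _log_odds_matrix(motif)
        smax = lods[:4].max(axis=0).sum()
        smin = lods[:4].min(axis=0).sum()
        span = smax - smin
        if span <= 0:
            continue
        cutoff = smin + rel_threshold * span
        for pi, pid in enumerate(peak_ids):
            best = max(_best_window_score(codes[pid], lods),
                       _best_window_score(rc_codes[pid], lods))
            if best >= cutoff:
                out[pi, mj] = 1
    hits = pd.DataFrame(out, index=peak_ids, columns=motifs.motif_ids)
    return PeakMotifHits(hits=hits, scan_threshold=rel_threshold,
                         motif_to_tf={m.motif_id: m.tf_name for m in motifs})


def promoter_interval(gene: pd.Series, upstream: int = 2000,
                      downstream: int = 0) -> tuple[str, int, int]:
    """Strand-aware promoter window covering ``upstream`` bases before the
    TSS through ``downstream`` bases after it (half-open).

    '+' strand, tss t: [t - upstream, t + downstream);
    '-' strand: the reflected interval [t + 1 - downstream, t + 1 + upstream).
    """
    tss = int(gene["tss"])
    if gene["strand"] == "+":
        return gene["chrom"], tss - upstream, tss + downstream
    return gene["chrom"], tss + 1 - downstream, tss + 1 + upstream


def promoter_peaks(gene: pd.Series, peaks: PeakSet, upstream: int = 2000,
                   downstream: int = 0) -> list[str]:
    """Peaks overlapping the promoter interval (empty window -> none)."""
    chrom, lo, hi = promoter_interval(gene, upstream, downstream)
    if lo >= hi:
        return []
    df = peaks.df
    sel = df[(df["chrom"] == chrom) & (df["end"] > lo) & (df["start"] < hi)]
    return sel["peak_id"].tolist()


def candidate_tfs(gene_id: str, cre_links: list[CreLink],
                  hits: PeakMotifHits, promoter_peak_ids: list[str],
                  expressed_tfs: set[str]) -> list[str]:
    """TFs with a motif in a significant CRE or a promoter peak of the
    gene, restricted to expressed TFs; deduplicated, sorted."""
    peak_ids = {l.peak_id for l in cre_links if l.gene_id == gene_id}
    peak_ids |= set(promoter_peak_ids)
    tfs = set(hits.tfs_in_peaks(sorted(peak_ids)))
    return sorted(tfs & set(expressed_tfs))


def expressed_tf_set(expr, tf_ids, min_fraction: float = 0.01) -> set[str]:
    """TFs with nonzero expression in at least ``min_fraction`` of cells."""
    out = set()
    for tf in tf_ids:
        if not expr.has_feature(tf):
            continue
        col = expr.feature_column(tf)
        if np.count_nonzero(col) >= min_fraction * len(col):
            out.add(tf)
    return out


def enriched_tfs(gene_id: str, cre_peaks: list[str], all_peaks: PeakSet,
                 hits: PeakMotifHits, gc: dict[str, float],
                 n_background: int = 200, seed: int = 0,
                 alpha: float = 0.05) -> list[str]:
    """TFs whose motifs are over-represented in the gene's CRE set
    relative to a GC-matched background of non-CRE peaks.

    Background peaks are drawn without replacement from GC-decile bins
    matching the CRE set's decile histogram; each motif gets a one-sided
    Fisher exact test (greater) on hit counts, BH-adjusted across motifs.
    """
    if not cre_peaks:
        raise ValueError(f"{gene_id}: empty CRE set")
    missing = [p for p in all_peaks.peak_ids if p not in gc]
    if missing:
        raise ValueError(f"GC content missing for peaks: {missing[:5]}")
    rng = np.random.default_rng(seed)
    cre_set = set(cre_peaks)
    pool = [p for p in all_peaks.peak_ids if p not in cre_set]
    if not pool:
        return []
    gc_vals = np.array([gc[p] for p in all_peaks.peak_ids])
    edges = np.quantile(gc_vals, np.linspace(0, 1, 11))
    edges[0], edges[-1] = -np.inf, np.inf

    def decile(p):
        return int(np.searchsorted(edges, gc[p], side="right") - 1)

    pool_by_bin: dict[int, list[str]] = {}
    for p in pool:
        pool_by_bin.setdefault(decile(p), []).append(p)
    cre_bins = pd.Series([decile(p) for p in cre_peaks]).value_counts()
    background: list[str] = []
    for b, cnt in cre_bins.items():
        want = int(round(n_background * cnt / len(cre_peaks)))
        avail = pool_by_bin.get(b, [])
        take = min(want, len(avail))
        if take:
            chosen = rng.choice(len(avail), size=take, replace=False)
            background.extend(avail[i] for i in chosen)
    if not background:
        return []

    motif_ids = hits.hits.columns
    present_cre = [p for p in cre_peaks if p in hits.hits.index]
    present_bg = [p for p in background if p in hits.hits.index]
    cre_counts = hits.hits.loc[present_cre].sum(axis=0)
    bg_counts = hits.hits.loc[present_bg].sum(axis=0)
    n_cre, n_bg = len(present_cre), len(present_bg)
    pvals = []
    for m in motif_ids:
        a = int(cre_counts[m])
        b = int(bg_counts[m])
        table = [[a, n_cre - a], [b, n_bg - b]]
        pvals.append(fisher_exact(table, alternative="greater")[1])
    reject, _, _, _ = multipletests(pvals, alpha=alpha, method="fdr_bh")
    kept = [hits.motif_to_tf.get(m, m)
            for m, r in zip(motif_ids, reject) if r]
    return sorted(set(kept))


def gc_fraction(sequences: dict[str, str]) -> dict[str, float]:
    out = {}
    for pid, seq in sequences.items():
        s = seq.upper()
        denom = sum(s.count(b) for b in "ACGT")
        out[pid] = (s.count("G") + s.count("C")) / denom if denom else 0.0
    return out
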