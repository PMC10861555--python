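"""In-memory domain containers shared by all pipeline stages.

Coordinates are 0-based half-open (BED-native) everywhere inside the
package; any 1-based input format must be converted at the I/O boundary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse


def _check_unique(ids, what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Series(list(ids)).value_counts()
        dupes = dupes[dupes > 1].index.tolist()[:5]
        raise ValueError(f"duplicate {what}: {dupes}")


@dataclass
class OmicsMatrix:
    """Cells (or pseudocells) x features numeric matrix.

    Serves both as response source (gene expression, ``modality='rna'``)
    and predictor source (peak accessibility, ``modality='atac'``; TF
    expression). ``values`` is kept sparse feature-major; densification
    happens per gene at fit time.
    """

    values: sparse.csc_matrix
    cell_ids: list[str]
    feature_ids: list[str]
    modality: str  # "rna" | "atac"
    raw_counts: bool = False
    _feature_index: dict = field(default=None, repr=False, compare=False)

    def __post_init__(self):
        if self.modality not in ("rna", "atac"):
            raise ValueError(f"unknown modality {self.modality!r}")
        if not sparse.issparse(self.values):
            self.values = sparse.csc_matrix(np.asarray(self.values, dtype=float))
        else:
            self.values = self.values.tocsc().astype(float)
        n, p = self.values.shape
        if n != len(self.cell_ids):
            raise ValueError(
                f"matrix has {n} rows but {len(self.cell_ids)} cell ids"
            )
        if p != len(self.feature_ids):
            raise ValueError(
                f"matrix has {p} columns but {len(self.feature_ids)} feature ids"
            )
        _check_unique(self.cell_ids, "cell ids")
        _check_unique(self.feature_ids, "feature ids")
        if self.raw_counts and self.values.nnz and self.values.data.min() < 0:
            raise ValueError("negative entries in a matrix declared as raw counts")
        self._feature_index = {f: j for j, f in enumerate(self.feature_ids)}

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def feature_column(self, feature_id: str) -> np.ndarray:
        """Dense 1-D column for one feature."""
        j = self._feature_index.get(feature_id)
        if j is None:
            raise KeyError(f"feature {feature_id!r} not in matrix")
        return np.asarray(self.values[:, j].todense()).ravel()

    def submatrix(self, feature_ids: list[str]) -> np.ndarray:
        """Dense cells x len(feature_ids) block, column order preserved."""
        idx = []
        for f in feature_ids:
            j = self._feature_index.get(f)
            if j is None:
                raise KeyError(f"feature {f!r} not in matrix")
            idx.append(j)
        return np.asarray(self.values[:, idx].todense())

    def has_feature(self, feature_id: str) -> bool:
        return feature_id in self._feature_index

    def mean_per_feature(self, cell_subset: list[str] | None = None) -> pd.Series:
        """Mean value of every feature over the given cells (default: all)."""
        if cell_subset is None:
            m = np.asarray(self.values.mean(axis=0)).ravel()
        else:
            pos = {c: i for i, c in enumerate(self.cell_ids)}
            rows = [pos[c] for c in cell_subset if c in pos]
            if not rows:
                raise ValueError("empty cell subset")
            m = np.asarray(self.values[rows, :].mean(axis=0)).ravel()
        return pd.Series(m, index=list(self.feature_ids))


def estimate_size_factors(*matrices: "OmicsMatrix") -> np.ndarray:
    """Per-cell depth factors from the pooled row totals of one or more
    matrices over the same cells (same order), relative to the median
    cell.

    Per-cell depth acts as a global multiplicative confounder: it makes
    every pair of features positively correlated, so unrelated predictors
    would look associated with every response. Pooling paired assays
    (e.g. RNA + ATAC from the same cells) gives many more features per
    cell and hence a far more precise estimate than either assay alone,
    and keeps any single feature's own noise a negligible share of the
    total.
    """
    if not matrices:
        raise ValueError("need at least one matrix")
    cells = matrices[0].cell_ids
    totals = np.zeros(len(cells))
    for m in matrices:
        if m.cell_ids != cells:
            raise ValueError("matrices must share the same cells in order")
        totals += np.asarray(m.values.sum(axis=1)).ravel()
    if np.any(totals <= 0):
        raise ValueError("cannot estimate depth for cells with zero total signal")
    return totals / np.median(totals)


def library_size_normalize(matrix: "OmicsMatrix",
                           factors: np.ndarray | None = None,
                           log1p: bool = False) -> "OmicsMatrix":
    """Divide each cell's row by its depth factor (default: estimated
    from this matrix's own totals via :func:`estimate_size_factors`),
    removing per-cell depth variation that would otherwise correlate
    every feature with every other; optionally apply log1p afterwards."""
    if factors is None:
        factors = estimate_size_factors(matrix)
    factors = np.asarray(factors, dtype=float)
    if factors.shape != (matrix.n_cells,):
        raise ValueError("factors must have one entry per cell")
    if np.any(factors <= 0):
        raise ValueError("size factors must be positive")
    inv = sparse.diags(1.0 / factors)
    vals = sparse.csc_matrix(inv @ matrix.values)
    if log1p:
        vals = vals.copy()
        vals.data = np.log1p(vals.data)
    return OmicsMatrix(values=vals, cell_ids=list(matrix.cell_ids),
                       feature_ids=list(matrix.feature_ids),
                       modality=matrix.modality)


def peak_id_from_coords(chrom: str, start: int, end: int) -> str:
    return f"{chrom}:{start}-{end}"


def parse_peak_id(peak_id: str) -> tuple[str, int, int]:
    chrom, _, span = peak_id.rpartition(":")
    start_s, _, end_s = span.partition("-")
    if not chrom or not start_s or not end_s:
        raise ValueError(f"cannot parse peak id {peak_id!r}")
    return chrom, int(start_s), int(end_s)


@dataclass
class PeakSet:
    """Genomic intervals (candidate CRE universe), 0-based half-open."""

    df: pd.DataFrame  # columns: chrom, start, end, peak_id

    def __post_init__(self):
        required = {"chrom", "start", "end", "peak_id"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"PeakSet missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True).copy()
        df["start"] = df["start"].astype(int)
        df["end"] = df["end"].astype(int)
        bad = df["start"] >= df["end"]
        if bad.any():
            row = df[bad].iloc[0]
            raise ValueError(
                f"peak {row.peak_id}: start {row.start} >= end {row.end}"
            )
        _check_unique(df["peak_id"].tolist(), "peak ids")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def peak_ids(self) -> list[str]:
        return self.df["peak_id"].tolist()

    def coords(self, peak_id: str) -> tuple[str, int, int]:
        row = self.df[self.df["peak_id"] == peak_id]
        if row.empty:
            raise KeyError(peak_id)
        r = row.iloc[0]
        return r["chrom"], int(r["start"]), int(r["end"])


@dataclass
class GeneAnnotation:
    """Strand-aware gene coordinates; TSS anchors the candidate window.

    strand '+' implies tss == body_start; strand '-' implies
    tss == body_end - 1 (last covered base of the interval).
    """

    df: pd.DataFrame  # columns: gene_id, chrom, strand, tss, body_start, body_end

    def __post_init__(self):
        required = {"gene_id", "chrom", "strand", "tss", "body_start", "body_end"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"GeneAnnotation missing columns: {sorted(missing)}")
        df = self.df.reset_index(drop=True).copy()
        for c in ("tss", "body_start", "body_end"):
            df[c] = df[c].astype(int)
        if not df["strand"].isin(["+", "-"]).all():
            raise ValueError("strand must be '+' or '-'")
        out = (df["tss"] < df["body_start"]) | (df["tss"] >= df["body_end"])
        if out.any():
            g = df[out].iloc[0]
            raise ValueError(f"gene {g.gene_id}: tss outside gene body")
        _check_unique(df["gene_id"].tolist(), "gene ids")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def gene(self, gene_id: str) -> pd.Series:
        row = self.df[self.df["gene_id"] == gene_id]
        if row.empty:
            raise KeyError(gene_id)
        return row.iloc[0]

    @property
    def gene_ids(self) -> list[str]:
        return self.df["gene_id"].tolist()


@dataclass
class Motif:
    motif_id: str
    tf_name: str
    pfm: np.ndarray  # 4 x width, rows A, C, G, T
    background: np.ndarray = field(
        default_factory=lambda: np.full(4, 0.25)
    )

    def __post_init__(self):
        self.pfm = np.asarray(self.pfm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pfm.shape[0] != 4:
            raise ValueError(f"motif {self.motif_id}: pfm must have 4 rows")
        if self.pfm.shape[1] < 4:
            raise ValueError(f"motif {self.motif_id}: width must be >= 4")
        if np.any(self.pfm < 0):
            raise ValueError(f"motif {self.motif_id}: negative pfm entries")
        if np.any(self.pfm.sum(axis=0) <= 0):
            raise ValueError(f"motif {self.motif_id}: zero-sum pfm column")
        if abs(self.background.sum() - 1.0) > 1e-9:
            raise ValueError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def width(self) -> int:
        return self.pfm.shape[1]


@dataclass
class MotifSet:
    motifs: list[Motif]

    def __post_init__(self):
        _check_unique([m.motif_id for m in self.motifs], "motif ids")

    def __len__(self) -> int:
        return len(self.motifs)

    def __iter__(self):
        return iter(self.motifs)

    @property
    def motif_ids(self) -> list[str]:
        return [m.motif_id for m in self.motifs]

    def tf_of(self, motif_id: str) -> str:
        for m in self.motifs:
            if m.motif_id == motif_id:
                return m.tf_name
        raise KeyError(motif_id)
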