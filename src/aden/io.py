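"""Readers and writers for every external format the pipeline touches.

All readers validate strictly and return the in-memory containers from
:mod:`aden.containers`; all numeric writer/reader pairs round-trip to
<= 1e-12. BED coordinates stay 0-based half-open end to end.
"""

from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO, motifs as bio_motifs
from scipy import io as spio
from scipy import sparse

from .containers import (
    GeneAnnotation,
    Motif,
    MotifSet,
    OmicsMatrix,
    PeakSet,
    peak_id_from_coords,
)

# float format that round-trips IEEE doubles exactly
_FLOAT_FMT = "%.17g"


def _read_id_list(path) -> list[str]:
    with open(path) as fh:
        ids = [line.strip().split("\t")[0] for line in fh if line.strip()]
    return ids


def read_sparse_counts(matrix_path, features_path, barcodes_path,
                       modality: str, raw_counts: bool = False) -> OmicsMatrix:
    """Load a MatrixMarket triplet matrix (cells x features) plus id lists.

    Rows are barcodes/cells, columns are features; input ordering of both
    id lists is preserved.
    """
    mat = spio.mmread(str(matrix_path))
    mat = sparse.csc_matrix(mat)
    features = _read_id_list(features_path)
    barcodes = _read_id_list(barcodes_path)
    n, p = mat.shape
    if n != len(barcodes):
        raise ValueError(
            f"{matrix_path}: {n} matrix rows but {len(barcodes)} barcodes"
        )
    if p != len(features):
        raise ValueError(
            f"{matrix_path}: {p} matrix columns but {len(features)} features"
        )
    return OmicsMatrix(values=mat, cell_ids=barcodes, feature_ids=features,
                       modality=modality, raw_counts=raw_counts)


def write_sparse_counts(matrix: OmicsMatrix, matrix_path, features_path,
                        barcodes_path) -> None:
    spio.mmwrite(str(matrix_path), sparse.coo_matrix(matrix.values))
    Path(features_path).write_text("\n".join(matrix.feature_ids) + "\n")
    Path(barcodes_path).write_text("\n".join(matrix.cell_ids) + "\n")


def read_bed_peaks(path) -> PeakSet:
    """Parse BED3/BED4 into a PeakSet; ids synthesized as chrom:start-end
    when the name column is absent."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric coordinates"
                ) from exc
            if start >= end:
                raise ValueError(
                    f"{path}:{lineno}: start {start} >= end {end}"
                )
            pid = parts[3] if len(parts) >= 4 and parts[3] else \
                peak_id_from_coords(chrom, start, end)
            rows.append((chrom, start, end, pid))
    return PeakSet(pd.DataFrame(rows, columns=["chrom", "start", "end", "peak_id"]))


def write_bed_peaks(peaks: PeakSet, path) -> None:
    peaks.df[["chrom", "start", "end", "peak_id"]].to_csv(
        path, sep="\t", header=False, index=False
    )


def read_gene_annotation(path) -> GeneAnnotation:
    """Tab-separated gene table. Either (gene_id, chrom, strand, tss) with
    an optional body_start/body_end pair, or (gene_id, chrom, strand,
    body_start, body_end) with the TSS derived from strand."""
    df = pd.read_csv(path, sep="\t")
    cols = set(df.columns)
    if not {"gene_id", "chrom", "strand"} <= cols:
        raise ValueError(f"{path}: need gene_id, chrom, strand columns")
    if "tss" not in cols:
        if not {"body_start", "body_end"} <= cols:
            raise ValueError(f"{path}: need tss or body_start/body_end")
        df["tss"] = np.where(df["strand"] == "+", df["body_start"],
                             df["body_end"] - 1)
    if "body_start" not in cols:
        df["body_start"] = df["tss"]
        df["body_end"] = df["tss"] + 1
    return GeneAnnotation(df[["gene_id", "chrom", "strand", "tss",
                              "body_start", "body_end"]])


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    genes.df.to_csv(path, sep="\t", index=False)


def read_motifs_jaspar(path) -> MotifSet:
    """JASPAR PFM file -> MotifSet (rows A, C, G, T; uniform background)."""
    with open(path) as fh:
        parsed = bio_motifs.parse(fh, "jaspar")
    out = []
    for m in parsed:
        pfm = np.array([m.counts[b] for b in "ACGT"], dtype=float)
        tf = m.name if m.name else m.matrix_id
        out.append(Motif(motif_id=m.matrix_id or tf, tf_name=tf, pfm=pfm))
    if not out:
        raise ValueError(f"{path}: no motifs parsed")
    return MotifSet(out)


def write_motifs_jaspar(motif_set: MotifSet, path) -> None:
    with open(path, "w") as fh:
        for m in motif_set:
            fh.write(f">{m.motif_id}\t{m.tf_name}\n")
            for base, row in zip("ACGT", m.pfm):
                vals = " ".join(_FLOAT_FMT % v for v in row)
                fh.write(f"{base}  [ {vals} ]\n")


def read_fasta(path) -> dict[str, str]:
    """Named sequence set; names and order preserved."""
    seqs = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
        seqs[rec.id] = str(rec.seq).upper()
    if not seqs:
        raise ValueError(f"{path}: no FASTA records")
    return seqs


def write_fasta(seqs: dict[str, str], path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq}\n")


def write_fit_results(fits, path) -> None:
    """Long-format TSV: one row per (gene, element) coefficient with its
    bootstrap SE and p-value. ``fits`` is an iterable of FitResult."""
    rows = []
    for fit in fits:
        for j, pid in enumerate(fit.predictor_ids):
            rows.append({
                "gene_id": fit.gene_id,
                "element_id": pid,
                "beta": fit.beta[j],
                "se": fit.se[j] if fit.se is not None else np.nan,
                "pvalue": fit.pvalue[j] if fit.pvalue is not None else np.nan,
                "intercept": fit.intercept,
                "lambda1": fit.lambda1,
                "lambda2": fit.lambda2,
                "r2": fit.r2,
                "n_obs": fit.n_obs,
            })
    df = pd.DataFrame(rows, columns=["gene_id", "element_id", "beta", "se",
                                     "pvalue", "intercept", "lambda1",
                                     "lambda2", "r2", "n_obs"])
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_fit_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"gene_id", "element_id", "beta"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: missing columns {required - set(df.columns)}")
    return df


def write_edge_table(graph, path) -> None:
    """Attributed edge list (TSV: source, target, weight, sign)."""
    rows = [
        {"source": u, "target": v,
         "weight": d.get("weight", 1.0), "sign": d.get("sign", 1)}
        for u, v, d in graph.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight", "sign"]).to_csv(
        path, sep="\t", index=False, float_format=_FLOAT_FMT
    )


def read_edge_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if not {"source", "target", "weight"} <= set(df.columns):
        raise ValueError(f"{path}: not an edge table")
    return df
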