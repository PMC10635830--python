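"""Downsampling, per-cell QC, log-normalization, and pseudobulk correlation.

UMI downsampling is without replacement across a cell's UMI mass
(multivariate hypergeometric), matching count-level thinning semantics;
read downsampling is binomial per read before UMI collapse. TPM for UMI
counts carries no gene-length term: UMIs are molecule end-counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .quant import CountMatrix, UmiRecord

__all__ = [
    "QCMetrics",
    "downsample_umis",
    "downsample_cells_and_reads",
    "qc_metrics",
    "normalize_log",
    "pseudobulk",
    "pseudobulk_correlate",
]


@dataclass
class QCMetrics:
    per_barcode: pd.DataFrame  # total_umis, genes_detected, mito_fraction, zero_total
    median_umis: float
    median_genes: float
    median_mito_fraction: float

    def to_dict(self) -> dict:
        return {
            "median_umis": self.median_umis,
            "median_genes": self.median_genes,
            "median_mito_fraction": self.median_mito_fraction,
            "n_barcodes": int(len(self.per_barcode)),
        }


def downsample_umis(
    cm: CountMatrix,
    target_per_cell: int | None = None,
    fraction: float | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Downsample each cell's counts to a fixed UMI total (or fraction of it)
    by uniform sampling without replacement across that cell's UMI mass.

    Cells already at or below the target keep all their counts. Deterministic
    under `seed`.
    """
    if (target_per_cell is None) == (fraction is None):
        raise ValueError("provide exactly one of target_per_cell or fraction")
    if fraction is not None and not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    dense_rows = []
    mat = cm.matrix.tocsr()
    for i in range(mat.shape[0]):
        row = np.asarray(mat[i].toarray(), dtype=np.int64).ravel()
        total = int(row.sum())
        target = (target_per_cell if target_per_cell is not None
                  else int(round(fraction * total)))
        if total <= target:
            dense_rows.append(row)
        else:
            dense_rows.append(rng.multivariate_hypergeometric(row, target))
    out = sp.csr_matrix(np.vstack(dense_rows))
    return CountMatrix(out, cm.barcodes, cm.features)


def downsample_cells_and_reads(
    records: list[UmiRecord],
    n_cells: int | None = None,
    thinning: float | None = None,
    reads_per_cell: int | None = None,
    seed: int = 0,
) -> list[UmiRecord]:
    """Reduce a UMI-record stream to a random cell subset and/or thinned
    read depth (binomial per read multiplicity, applied before UMI collapse).

    `reads_per_cell` sets per-cell thinning probabilities target/total
    (cells below target unthinned); `thinning` applies one global
    probability. Records whose multiplicity thins to zero are dropped.
    """
    rng = np.random.default_rng(seed)
    barcodes = sorted({r.barcode for r in records})
    if n_cells is not None:
        if n_cells > len(barcodes):
            raise ValueError(f"n_cells {n_cells} > {len(barcodes)} barcodes")
        keep = set(rng.choice(barcodes, size=n_cells, replace=False))
        records = [r for r in records if r.barcode in keep]
    if thinning is not None and reads_per_cell is not None:
        raise ValueError("give thinning or reads_per_cell, not both")
    p_by_bc: dict[str, float] | None = None
    if reads_per_cell is not None:
        totals: dict[str, int] = {}
        for r in records:
            totals[r.barcode] = totals.get(r.barcode, 0) + r.multiplicity
        p_by_bc = {bc: min(1.0, reads_per_cell / t) for bc, t in totals.items()}
    if thinning is not None or p_by_bc is not None:
        if thinning is not None and not (0 < thinning <= 1):
            raise ValueError("thinning probability must be in (0, 1]")
        out = []
        for r in records:
            p = thinning if thinning is not None else p_by_bc[r.barcode]
            m = int(rng.binomial(r.multiplicity, p))
            if m > 0:
                out.append(UmiRecord(r.barcode, r.umi, r.feature_id, m))
        records = out
    return records


def qc_metrics(cm: CountMatrix, mito_features: list[str] | None = None) -> QCMetrics:
    """Per-barcode totals, genes detected, and mitochondrial fraction, with
    dataset medians. Zero-total barcodes get mito fraction 0 and a flag."""
    if mito_features is None:
        mito_features = cm.features.loc[cm.features["mito"], "feature_id"].tolist()
    unknown = set(mito_features) - set(cm.features["feature_id"])
    if unknown:
        raise ValueError(f"mito labels not in features: {sorted(unknown)}")
    mat = cm.matrix.tocsr()
    totals = np.asarray(mat.sum(axis=1)).ravel()
    genes = np.asarray((mat > 0).sum(axis=1)).ravel()
    mito_mask = cm.features["feature_id"].isin(mito_features).to_numpy()
    mito_counts = np.asarray(mat[:, mito_mask].sum(axis=1)).ravel()
    zero = totals == 0
    mito_frac = np.where(zero, 0.0, mito_counts / np.where(zero, 1, totals))
    df = pd.DataFrame({
        "barcode": cm.barcodes,
        "total_umis": totals.astype(int),
        "genes_detected": genes.astype(int),
        "mito_fraction": mito_frac,
        "zero_total": zero,
    })
    return QCMetrics(
        per_barcode=df,
        median_umis=float(np.median(totals)),
        median_genes=float(np.median(genes)),
        median_mito_fraction=float(np.median(mito_frac)),
    )


def normalize_log(cm: CountMatrix, scale: float = 10_000.0) -> sp.csr_matrix:
    """ln(1 + scale * count / cell_total); zero-total cells stay zero."""
    mat = cm.matrix.tocsr().astype(np.float64)
    totals = np.asarray(mat.sum(axis=1)).ravel()
    inv = np.where(totals > 0, 1.0 / np.where(totals > 0, totals, 1), 0.0)
    scaled = sp.diags(inv * scale) @ mat
    scaled.data = np.log1p(scaled.data)
    return scaled.tocsr()


def pseudobulk(cm: CountMatrix, groups: dict[str, str] | pd.Series) -> pd.DataFrame:
    """Sum counts per gene within barcode groups -> genes x groups frame."""
    groups = pd.Series(groups)
    out = {}
    for label in sorted(groups.unique()):
        bcs = [b for b in cm.barcodes if groups.get(b) == label]
        if not bcs:
            continue
        sub = cm.subset_barcodes(bcs)
        out[label] = np.asarray(sub.matrix.sum(axis=0)).ravel()
    return pd.DataFrame(out, index=cm.features["feature_id"])


def pseudobulk_correlate(pb: pd.DataFrame, group_a: str, group_b: str
                         ) -> tuple[float, float]:
    """Pearson r and OLS slope of group B on group A, on log(1 + TPM).

    TPM = counts / group_total * 1e6 (UMI counts, no length term).
    """
    a, b = pb[group_a].to_numpy(float), pb[group_b].to_numpy(float)
    if (a.sum() == 0) or (b.sum() == 0):
        raise ValueError("a group has zero total counts")
    la = np.log1p(a / a.sum() * 1e6)
    lb = np.log1p(b / b.sum() * 1e6)
    if np.allclose(la, la[0]) or np.allclose(lb, lb[0]):
        raise ValueError("constant pseudobulk vector; correlation undefined")
    r, _ = stats.pearsonr(la, lb)
    slope = float(np.polyfit(la, lb, 1)[0])
    return float(r), slope
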