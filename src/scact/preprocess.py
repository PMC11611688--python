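"""Quality control, normalization and feature selection.

RNA side: cells with fewer than 200 total counts or flagged as doublets are
dropped, the matrix is library-size normalized to the median per-cell total
and log1p-transformed, and the top 3,000 most variable genes are kept.

ATAC side: cells with TSS enrichment below 2.0, sequencing depth below 1,000
or a doublet flag are dropped (both QC statistics are inputs, not computed
here), the matrix is TF-IDF weighted, the 100,000 most informative peaks are
retained, and the output is re-binarized for training.

All selections are deterministic, with ties broken by ascending feature
index.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .data_model import ATAC, RNA, OmicsMatrix


def _row_sums(values) -> np.ndarray:
    if sp.issparse(values):
        return np.asarray(values.sum(axis=1)).ravel()
    return np.asarray(values).sum(axis=1)


def _doublet_mask(m: OmicsMatrix) -> np.ndarray:
    """True for cells flagged as doublets; missing column or NaN means False."""
    if "doublet_flag" not in m.cell_meta.columns:
        return np.zeros(m.n_cells, dtype=bool)
    col = m.cell_meta["doublet_flag"]
    return col.fillna(False).astype(bool).to_numpy()


def qc_filter_rna(m: OmicsMatrix, min_counts: int = 200) -> OmicsMatrix:
    """Drop RNA cells with insufficient total counts (< min_counts) or doublets."""
    if m.modality != RNA:
        raise ValueError("qc_filter_rna expects an RNA matrix")
    totals = _row_sums(m.values)
    if sp.issparse(m.values):
        has_neg = m.values.data.size and m.values.data.min() < 0
    else:
        has_neg = np.asarray(m.values).min(initial=0) < 0
    if has_neg:
        raise ValueError("negative counts in RNA matrix")
    keep = (totals >= min_counts) & ~_doublet_mask(m)
    return m.subset_cells(keep)


def log_normalize(m: OmicsMatrix) -> OmicsMatrix:
    """Scale each cell to the median library size, then log1p.

    Outputs are finite and non-negative.  Zero-count cells are rejected:
    run :func:`qc_filter_rna` first.
    """
    x = m.to_dense().astype(np.float64)
    totals = x.sum(axis=1)
    if np.any(totals <= 0):
        raise ValueError(
            "zero-count cell encountered; run qc_filter_rna before "
            "log_normalize")
    target = float(np.median(totals))
    x = np.log1p(x * (target / totals)[:, None])
    out = m.copy()
    out.values = x
    return out


def select_hvg(m: OmicsMatrix, n_genes: int = 3000) -> OmicsMatrix:
    """Keep the ``n_genes`` most variable genes of a log-normalized matrix.

    Variance of the (log-normalized) expression is the dispersion statistic;
    ties at the cut boundary are broken by ascending feature index, and the
    input gene order is preserved in the output.
    """
    if n_genes <= 0:
        raise ValueError("n_genes must be positive")
    x = m.to_dense()
    var = x.var(axis=0)
    # stable sort on descending variance -> ascending index within ties
    order = np.argsort(-var, kind="stable")
    keep = np.sort(order[:min(n_genes, m.n_features)])
    return m.subset_features(keep)


def qc_filter_atac(m: OmicsMatrix, min_tss: float = 2.0,
                   min_depth: int = 1000) -> OmicsMatrix:
    """Drop ATAC cells failing TSS enrichment or depth thresholds, and doublets."""
    if m.modality != ATAC:
        raise ValueError("qc_filter_atac expects an ATAC matrix")
    if "tss_enrichment" not in m.cell_meta.columns:
        raise ValueError("cell_meta lacks required 'tss_enrichment' column")
    if "depth" not in m.cell_meta.columns:
        raise ValueError("cell_meta lacks required 'depth' column")
    tss = m.cell_meta["tss_enrichment"].to_numpy(dtype=float)
    depth = m.cell_meta["depth"].to_numpy(dtype=float)
    keep = (tss >= min_tss) & (depth >= min_depth) & ~_doublet_mask(m)
    return m.subset_cells(keep)


def tfidf_scores(x: np.ndarray) -> np.ndarray:
    """Per-peak informativeness: column sums of the TF-IDF-weighted matrix.

    TF is each cell's count divided by its total; IDF for peak j is
    ``log(1 + n_cells / (1 + n_cells_with_peak_j))``.  Zero-total cells
    contribute zero TF.
    """
    x = np.asarray(x, dtype=np.float64)
    totals = x.sum(axis=1)
    safe = np.where(totals > 0, totals, 1.0)
    tf = x / safe[:, None]
    df = (x > 0).sum(axis=0)
    idf = np.log(1.0 + x.shape[0] / (1.0 + df))
    return (tf * idf[None, :]).sum(axis=0)


def tfidf_select_peaks(m: OmicsMatrix, n_peaks: int = 100000) -> OmicsMatrix:
    """Keep the ``n_peaks`` most informative peaks by TF-IDF weight mass.

    All-zero peaks score zero and rank last; ties are broken by ascending
    index; the retained matrix is re-binarized.
    """
    if n_peaks <= 0:
        raise ValueError("n_peaks must be positive")
    scores = tfidf_scores(m.to_dense())
    order = np.argsort(-scores, kind="stable")
    keep = np.sort(order[:min(n_peaks, m.n_features)])
    return binarize(m.subset_features(keep))


def binarize(m: OmicsMatrix) -> OmicsMatrix:
    """Map values > 0 to 1, else 0 (idempotent)."""
    out = m.copy()
    if sp.issparse(out.values):
        v = out.values.tocsr()
        v.data = (v.data > 0).astype(np.float64)
        v.eliminate_zeros()
        out.values = v
    else:
        out.values = (np.asarray(out.values) > 0).astype(np.float64)
    return out
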