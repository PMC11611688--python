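"""Benchmarking statistics for alignment, translation and linkage.

Alignment quality in the joint latent space is measured globally (silhouette
on cosine distance, ARI/AMI of a k-means clustering against labels) and
locally (within-cell-type pairwise cosine distances; the modality mixing
score).  Translation quality uses AUCROC over (cell, peak) entries for the
probabilistic RNA->ATAC direction and squared Pearson correlation of
per-feature pseudo-bulk signals for either direction.  Regulatory readouts
are the motif activation score (weighted mean accessibility of peaks within
750 kb upstream of a TSS) and peak-to-gene linkage (Pearson correlation of
pseudo-bulk accessibility with pseudo-bulk expression for peaks within
100 kb of the gene).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.metrics import (adjusted_mutual_info_score, adjusted_rand_score,
                             roc_auc_score, silhouette_score)

from .data_model import ATAC, RNA, Embedding, OmicsMatrix, PeakAnnotation


# ---------------------------------------------------------------------------
# local homogeneity
# ---------------------------------------------------------------------------

def _cosine_distances(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    an = a / np.maximum(np.linalg.norm(a, axis=1, keepdims=True), 1e-12)
    bn = b / np.maximum(np.linalg.norm(b, axis=1, keepdims=True), 1e-12)
    return 1.0 - an @ bn.T


def mixing_score_from_counts(c_a: int, c_r: int) -> float:
    """1 - |c_A/(c_A + c_R) - 0.5|: 1 for a balanced neighborhood, 0.5 at
    either all-one-modality extreme."""
    return 1.0 - abs(c_a / (c_a + c_r) - 0.5)


def modality_mixing_score(emb_joint: Embedding, modality_labels,
                          cell_type_labels, n_neighbors: int = 1000,
                          n_draws: int = 50, seed: int = 0) -> pd.Series:
    """Per-cell-type neighborhood balance of the two modalities.

    For each cell type, a random member cell's ``n_neighbors`` nearest cells
    (cosine distance, self excluded) are counted by modality and scored with
    :func:`mixing_score_from_counts`; the score is averaged over ``n_draws``
    seeded draws.  Values lie in [0.5, 1].
    """
    modality_labels = np.asarray(modality_labels)
    cell_type_labels = np.asarray(cell_type_labels)
    z = emb_joint.values
    rng = np.random.default_rng(seed)
    out = {}
    for ct in pd.unique(cell_type_labels):
        members = np.flatnonzero(cell_type_labels == ct)
        if z.shape[0] - 1 < n_neighbors:
            warnings.warn(
                f"only {z.shape[0] - 1} candidate neighbors (< {n_neighbors}); "
                "using all available cells")
        scores = []
        for _ in range(n_draws):
            probe = int(rng.choice(members))
            d = _cosine_distances(z[probe:probe + 1], z).ravel()
            d[probe] = np.inf
            kk = min(n_neighbors, z.shape[0] - 1)
            nn = np.argpartition(d, kk - 1)[:kk]
            c_a = int(np.sum(modality_labels[nn] == ATAC))
            c_r = int(np.sum(modality_labels[nn] == RNA))
            scores.append(mixing_score_from_counts(c_a, c_r))
        out[ct] = float(np.mean(scores))
    return pd.Series(out, name="mixing_score")


def global_homogeneity(emb_joint: Embedding, labels, seed: int = 0) -> dict:
    """Silhouette (cosine) of labels plus ARI/AMI of k-means vs labels."""
    labels = np.asarray(labels)
    uniq = pd.unique(labels)
    if len(uniq) < 2:
        raise ValueError("silhouette undefined for a single label")
    z = emb_joint.values
    sil = float(silhouette_score(z, labels, metric="cosine"))
    km = KMeans(n_clusters=len(uniq), n_init=10, random_state=seed)
    pred = km.fit_predict(z)
    return {"silhouette": sil,
            "ari": float(adjusted_rand_score(labels, pred)),
            "ami": float(adjusted_mutual_info_score(labels, pred))}


def pairwise_cosine_test(emb_a: Embedding, emb_b: Embedding, labels,
                         max_pairs: int = 20000, seed: int = 0):
    """Within-type pairwise cosine distance distributions for two embeddings,
    compared with a two-sample t-test and a variance-ratio F-test.

    ``emb_a`` and ``emb_b`` are the same cells embedded by two methods (in a
    common space); types with fewer than 2 cells are skipped.  Pair sets are
    subsampled to ``max_pairs`` per type with a seeded generator.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    rows = {}
    dists = {}
    for ct in pd.unique(labels):
        idx = np.flatnonzero(labels == ct)
        n = len(idx)
        if n < 2:
            continue
        n_pairs = n * (n - 1) // 2
        if n_pairs > max_pairs:
            ii = rng.integers(0, n, size=max_pairs)
            jj = rng.integers(0, n - 1, size=max_pairs)
            jj = np.where(jj >= ii, jj + 1, jj)  # avoid self pairs
            pairs = (idx[ii], idx[jj])
        else:
            tri = np.triu_indices(n, k=1)
            pairs = (idx[tri[0]], idx[tri[1]])
        da = _paired_cosine(emb_a.values, *pairs)
        db = _paired_cosine(emb_b.values, *pairs)
        if len(da) >= 2 and (np.std(da) > 0 or np.std(db) > 0):
            t_stat, t_p = stats.ttest_ind(da, db, equal_var=False)
            f_stat = np.var(da, ddof=1) / max(np.var(db, ddof=1), 1e-300)
            f_p = 2 * min(stats.f.cdf(f_stat, len(da) - 1, len(db) - 1),
                          stats.f.sf(f_stat, len(da) - 1, len(db) - 1))
        else:
            t_stat = t_p = f_stat = f_p = np.nan
        dists[ct] = (da, db)
        rows[ct] = {"mean_a": float(da.mean()), "mean_b": float(db.mean()),
                    "t_stat": float(t_stat), "t_p": float(t_p),
                    "f_stat": float(f_stat), "f_p": float(f_p)}
    return pd.DataFrame(rows).T, dists


def _paired_cosine(z: np.ndarray, ii: np.ndarray, jj: np.ndarray) -> np.ndarray:
    zn = z / np.maximum(np.linalg.norm(z, axis=1, keepdims=True), 1e-12)
    return 1.0 - np.sum(zn[ii] * zn[jj], axis=1)


# ---------------------------------------------------------------------------
# translation accuracy
# ---------------------------------------------------------------------------

def translation_auroc(p_matrix: np.ndarray, truth: np.ndarray,
                      group_labels=None) -> dict:
    """AUCROC over all (cell, peak) entries, plus per cell type if labels given.

    Degenerate truth (all ones or all zeros) yields ``None``.
    """
    p_matrix = np.asarray(p_matrix)
    truth = np.asarray(truth)
    if p_matrix.shape != truth.shape:
        raise ValueError("shape mismatch between probabilities and truth")

    def _auc(p, t):
        t = t.ravel()
        if t.min() == t.max():
            return None
        return float(roc_auc_score(t, p.ravel()))

    out = {"overall": _auc(p_matrix, truth)}
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        per_type = {}
        for ct in pd.unique(group_labels):
            idx = np.flatnonzero(group_labels == ct)
            per_type[ct] = _auc(p_matrix[idx], truth[idx])
        out["per_type"] = per_type
    return out


def translation_r2(pred: np.ndarray, truth: np.ndarray, group_labels=None,
                   level: str = "celltype") -> dict:
    """Squared Pearson correlation of per-feature mean signals.

    ``level='celltype'`` correlates feature means within each group and also
    overall; ``level='cell'`` correlates per-cell feature vectors and averages.
    Zero-variance vectors yield ``None``.
    """
    pred = np.asarray(pred, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if pred.shape != truth.shape:
        raise ValueError("shape mismatch between prediction and truth")

    def _r2(a, b):
        if np.std(a) == 0 or np.std(b) == 0:
            return None
        return float(np.corrcoef(a, b)[0, 1] ** 2)

    if level == "cell":
        vals = [_r2(pred[i], truth[i]) for i in range(pred.shape[0])]
        vals = [v for v in vals if v is not None]
        return {"overall": float(np.mean(vals)) if vals else None}
    out = {"overall": _r2(pred.mean(axis=0), truth.mean(axis=0))}
    if group_labels is not None:
        group_labels = np.asarray(group_labels)
        per_type = {}
        for ct in pd.unique(group_labels):
            idx = np.flatnonzero(group_labels == ct)
            per_type[ct] = _r2(pred[idx].mean(axis=0), truth[idx].mean(axis=0))
        out["per_type"] = per_type
    return out


# ---------------------------------------------------------------------------
# regulatory readouts
# ---------------------------------------------------------------------------

def _upstream_window(tss: PeakAnnotation, window_bp: int):
    """Strand-aware upstream interval; symmetric fallback when unstranded."""
    pos = tss.start
    if tss.strand == "+":
        return tss.chrom, pos - window_bp, pos
    if tss.strand == "-":
        return tss.chrom, pos, pos + window_bp
    warnings.warn(f"unstranded TSS for window at {tss.chrom}:{pos}; "
                  "using symmetric window")
    return tss.chrom, pos - window_bp, pos + window_bp


def peaks_in_window(annotations, chrom: str, lo: int, hi: int) -> np.ndarray:
    """Indices of peaks overlapping [lo, hi) on ``chrom``."""
    hits = [i for i, a in enumerate(annotations)
            if a.chrom == chrom and a.start < hi and a.end > lo]
    return np.asarray(hits, dtype=int)


def motif_activation_score(atac: OmicsMatrix, tss: dict, weights="uniform",
                           window_bp: int = 750000,
                           cell_type_labels=None) -> pd.DataFrame:
    """Weighted mean accessibility of peaks within ``window_bp`` upstream of
    each gene's TSS, averaged within cell type.

    ``tss`` maps gene -> :class:`PeakAnnotation` (TSS at ``start``);
    ``weights`` is "uniform" (every in-window peak weight 1) or a per-peak
    weight vector aligned to the ATAC feature set.  Genes with no in-window
    peak yield NaN with a warning.
    """
    x = atac.to_dense()
    anns = atac.feature_meta
    if anns is None:
        raise ValueError("ATAC matrix lacks peak annotations")
    if cell_type_labels is None:
        cell_type_labels = np.array(["all"] * atac.n_cells)
    cell_type_labels = np.asarray(cell_type_labels)
    lam = None if isinstance(weights, str) else np.asarray(weights, dtype=float)
    rows = {}
    for gene, t in tss.items():
        chrom, lo, hi = _upstream_window(t, window_bp)
        idx = peaks_in_window(anns, chrom, lo, hi)
        row = {}
        if len(idx) == 0:
            warnings.warn(f"no peaks within {window_bp} bp upstream of {gene}")
            for ct in pd.unique(cell_type_labels):
                row[ct] = np.nan
        else:
            w = np.ones(len(idx)) if lam is None else lam[idx]
            for ct in pd.unique(cell_type_labels):
                cells = np.flatnonzero(cell_type_labels == ct)
                acc = x[np.ix_(cells, idx)].mean(axis=0)
                row[ct] = float((w * acc).sum() / len(idx))
        rows[gene] = row
    return pd.DataFrame(rows).T


def peak_gene_linkage(atac: OmicsMatrix, rna: OmicsMatrix, gene: str,
                      gene_tss: PeakAnnotation, span_bp: int = 100000,
                      cell_groups_atac=None, cell_groups_rna=None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Pseudo-bulk Pearson linkage of nearby peaks to one gene.

    Accessibility and expression are averaged per cell group (cell type);
    for each peak within ``span_bp`` of the gene's TSS, the correlation of
    the group-level profiles is tested.  Requires at least 3 groups.
    Constant accessibility yields a null correlation row.
    """
    if gene not in rna.feature_ids:
        raise KeyError(f"gene {gene!r} not in RNA features")
    groups_a = np.asarray(cell_groups_atac)
    groups_r = np.asarray(cell_groups_rna)
    shared = [g for g in pd.unique(groups_a) if g in set(groups_r)]
    if len(shared) < 3:
        raise ValueError("need >= 3 shared cell groups for a Pearson test")
    anns = atac.feature_meta
    idx = peaks_in_window(anns, gene_tss.chrom,
                          gene_tss.start - span_bp, gene_tss.start + span_bp)
    x_a = atac.to_dense()
    expr = rna.to_dense()[:, rna.feature_ids.index(gene)]
    acc_bulk = np.stack([x_a[groups_a == g].mean(axis=0) for g in shared])
    expr_bulk = np.array([expr[groups_r == g].mean() for g in shared])
    rows = []
    for i in idx:
        acc = acc_bulk[:, i]
        if np.std(acc) == 0 or np.std(expr_bulk) == 0:
            r, p_val = np.nan, np.nan
        else:
            r, p_val = stats.pearsonr(acc, expr_bulk)
        rows.append({"peak_index": int(i), "peak": anns[i].name,
                     "r": float(r) if np.isfinite(r) else np.nan,
                     "p_value": float(p_val) if np.isfinite(p_val) else np.nan,
                     "significant": bool(np.isfinite(p_val)
                                         and p_val < alpha)})
    return pd.DataFrame(rows)
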