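"""Cross-modality translation through the encoder-mapper-decoder path.

ATAC -> RNA: ``x_A -> F_EncA -> g -> F_DecR`` yields a real-valued expression
matrix.  RNA -> ATAC: ``x_R -> F_EncR -> f -> F_DecA`` yields per-peak
accessibility probabilities; an optional seeded Bernoulli sampling step
produces a binarized ATAC-like matrix.  The probability matrix is always
returned alongside the sample because ROC-style evaluation needs it.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor
from .data_model import ATAC, RNA, Embedding, OmicsMatrix
from .model_core import ScactModel


def joint_embedding(model: ScactModel, rna: OmicsMatrix, atac: OmicsMatrix,
                    space: str = "atac"):
    """Embed both modalities into one latent space for alignment metrics.

    ``space='atac'`` (default): ATAC cells at z_A, RNA cells at f(z_R); the
    sigmoid-bounded ATAC latent keeps both clouds on comparable scales, which
    conditions cosine neighborhoods well.  ``space='rna'``: RNA cells at z_R,
    ATAC cells at g(z_A).  Returns ``(Embedding, modality_labels)`` with RNA
    cells first.
    """
    z_r = model.encode_rna_t(Tensor(rna.to_dense())).data
    z_a = model.encode_atac_t(Tensor(atac.to_dense())).data
    if space == "rna":
        z_a = model.map_ar_t(Tensor(z_a)).data
    elif space == "atac":
        z_r = model.map_ra_t(Tensor(z_r)).data
    else:
        raise ValueError("space must be 'rna' or 'atac'")
    values = np.vstack([z_r, z_a])
    labels = np.array([RNA] * rna.n_cells + [ATAC] * atac.n_cells)
    emb = Embedding(values=values, source_modality=RNA if space == "rna"
                    else ATAC,
                    cell_ids=list(rna.cell_ids) + list(atac.cell_ids),
                    mapped=True)
    return emb, labels


def translate_atac_to_rna(model: ScactModel, atac: OmicsMatrix,
                          gene_ids=None) -> OmicsMatrix:
    """Translate ATAC cells into RNA expression space (deterministic)."""
    if atac.n_features != model.p:
        raise ValueError(
            f"peak set mismatch: model expects {model.p} peaks, "
            f"matrix has {atac.n_features}")
    z_a = model.encode_atac_t(Tensor(atac.to_dense()))
    x_ar = model.decode_rna_t(model.map_ar_t(z_a)).data
    ids = list(gene_ids) if gene_ids is not None \
        else [f"gene{i}" for i in range(model.q)]
    return OmicsMatrix(values=x_ar, modality=RNA,
                       cell_ids=list(atac.cell_ids), feature_ids=ids,
                       cell_meta=atac.cell_meta.copy())


def translate_rna_to_atac(model: ScactModel, rna: OmicsMatrix,
                          sample: bool = False, seed: int = 0,
                          peak_ids=None, peak_meta=None):
    """Translate RNA cells into ATAC space.

    Returns ``(p_matrix, sampled)``: the per-peak accessibility probabilities
    and, if ``sample``, an elementwise Bernoulli draw from them (else None).
    """
    if rna.n_features != model.q:
        raise ValueError(
            f"gene set mismatch: model expects {model.q} genes, "
            f"matrix has {rna.n_features}")
    z_r = model.encode_rna_t(Tensor(rna.to_dense()))
    p = model.decode_atac_t(model.map_ra_t(z_r)).data
    ids = list(peak_ids) if peak_ids is not None \
        else [f"peak{i}" for i in range(model.p)]
    sampled = None
    if sample:
        rng = np.random.default_rng(seed)
        x = (rng.random(p.shape) < p).astype(np.float64)
        sampled = OmicsMatrix(values=x, modality=ATAC,
                              cell_ids=list(rna.cell_ids), feature_ids=ids,
                              cell_meta=rna.cell_meta.copy(),
                              feature_meta=peak_meta)
    return p, sampled
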