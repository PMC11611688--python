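"""Paired multiome simulator with known ground truth.

Each cell carries a latent program determined by its cell type (a point in a
low-dimensional program space, types separated by ``type_separation``) plus
isotropic noise.  RNA counts are negative-binomial with log-mean driven by
gene loadings on the program, a per-batch gene shift, and a log library-size
offset; ATAC peaks are Bernoulli with logits driven by peak loadings and a
global base accessibility logit.  Peaks occupy contiguous coordinate blocks
per chromosome, so chromosome-masked architectures and TSS-window statistics
are exercised realistically.  Planted peak -> gene links add a dependence of
a gene's log-mean on a specific peak's program activity, giving attribution
and linkage methods a recoverable causal signal.

Both modalities are generated for the *same* cells; :func:`unpair` re-keys
the barcodes so no pairing is inferable from ids, while the returned truth
table retains the correspondence for evaluation only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_model import ATAC, RNA, OmicsMatrix, PeakAnnotation

_PEAK_LEN = 500
_PEAK_SPACING = 2000


@dataclass
class SimConfig:
    """Study conditions of the desk-scale synthetic multiome.

    Defaults give a fixture that trains in minutes on one CPU: 600 cells per
    modality, 300 genes, 1,000 peaks, 4 cell types, 3 chromosomes, 2 batches.
    """

    n_cells: int = 600
    n_genes: int = 300
    n_peaks: int = 1000
    n_types: int = 4
    n_chroms: int = 3
    n_batches: int = 2
    latent_dim: int = 10
    type_separation: float = 2.0
    latent_noise: float = 0.5          # within-type sd per latent dimension
    batch_effect_size: float = 0.3
    depth_dispersion: float = 0.4      # sd of log library size
    rna_noise: float = 0.5             # NB dispersion (1/size); larger = noisier
    atac_base_logit: float = -2.0
    atac_scale: float = 2.0            # strength of program -> peak logits
    planted_links: list = field(default_factory=list)  # (peak, gene, effect)
    seed: int = 0

    def __post_init__(self):
        for name in ("n_cells", "n_genes", "n_peaks", "n_types", "n_chroms",
                     "n_batches", "latent_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_peaks < self.n_chroms:
            raise ValueError("need at least one peak per chromosome")
        for pk, g, eff in self.planted_links:
            if not (0 <= pk < self.n_peaks and 0 <= g < self.n_genes):
                raise ValueError("planted link indices out of range")
            if not np.isfinite(eff):
                raise ValueError("planted link effect must be finite")


def chrom_layout_for(cfg: SimConfig) -> dict:
    """Contiguous peak-index blocks per chromosome (remainder spread evenly)."""
    bounds = np.linspace(0, cfg.n_peaks, cfg.n_chroms + 1).astype(int)
    return {f"chr{c + 1}": (int(bounds[c]), int(bounds[c + 1]))
            for c in range(cfg.n_chroms)}


def peak_annotations_for(cfg: SimConfig) -> list:
    """Contiguous, evenly spaced peaks per chromosome."""
    layout = chrom_layout_for(cfg)
    anns = []
    for chrom, (s, e) in sorted(layout.items(), key=lambda t: t[1][0]):
        for i in range(e - s):
            start = i * _PEAK_SPACING
            anns.append(PeakAnnotation(chrom, start, start + _PEAK_LEN))
    return anns


def simulate_multiome(cfg: SimConfig):
    """Generate ``(rna, atac, truth)`` for one paired cohort.

    ``truth`` is a dict with the pairing table (one row per cell: RNA and
    ATAC barcodes, cell type, batch, depth), the per-cell latent factors,
    the chromosome layout, gene TSS annotations, and the planted links.
    """
    rng = np.random.default_rng(cfg.seed)
    d = cfg.latent_dim

    # cell-type program centers, pushed apart by type_separation
    centers = rng.normal(size=(cfg.n_types, d))
    centers = cfg.type_separation * centers / np.maximum(
        np.linalg.norm(centers, axis=1, keepdims=True), 1e-12)
    types = rng.integers(0, cfg.n_types, size=cfg.n_cells)
    latent = centers[types] + cfg.latent_noise * rng.normal(
        size=(cfg.n_cells, d))
    batches = rng.integers(0, cfg.n_batches, size=cfg.n_cells)

    # RNA: negative binomial via gamma-Poisson
    gene_load = rng.normal(size=(cfg.n_genes, d)) / np.sqrt(d)
    batch_shift = rng.normal(scale=cfg.batch_effect_size,
                             size=(cfg.n_batches, cfg.n_genes))
    log_depth = rng.normal(loc=0.0, scale=cfg.depth_dispersion,
                           size=cfg.n_cells)
    log_mu = latent @ gene_load.T + batch_shift[batches] + log_depth[:, None]

    # ATAC: Bernoulli-logit
    peak_load = rng.normal(size=(cfg.n_peaks, d)) / np.sqrt(d)
    logits = cfg.atac_scale * (latent @ peak_load.T) + cfg.atac_base_logit

    # planted links: the peak becomes strongly specific to the first cell
    # type's program (accessible in-type, closed out-of-type, like a marker
    # gene's driver peak), and the gene's log-mean follows that program
    for pk, g, eff in cfg.planted_links:
        direction = centers[0] - centers.mean(axis=0)
        direction = direction / np.maximum(np.linalg.norm(direction), 1e-12)
        peak_load[pk] = 3.0 * direction
        logits[:, pk] = cfg.atac_scale * (latent @ peak_load[pk]) \
            + cfg.atac_base_logit
        drive = latent @ peak_load[pk]
        log_mu[:, g] = log_mu[:, g] + eff * (drive - drive.mean()) \
            / max(drive.std(), 1e-12)

    mu = np.exp(np.clip(log_mu, -30, 8))
    size = 1.0 / max(cfg.rna_noise, 1e-6)
    lam = rng.gamma(shape=size, scale=mu / size)
    rna_counts = rng.poisson(lam).astype(np.float64)
    atac_binary = (rng.random(logits.shape)
                   < 1.0 / (1.0 + np.exp(-logits))).astype(np.float64)

    barcodes = [f"cell{i:05d}" for i in range(cfg.n_cells)]
    type_names = [f"type{t}" for t in types]
    depth_rna = rna_counts.sum(axis=1)
    meta_common = pd.DataFrame({
        "cell_type": type_names,
        "batch": [f"batch{b}" for b in batches],
    }, index=pd.Index(barcodes, name="cell_id"))
    rna_meta = meta_common.copy()
    rna_meta["depth"] = depth_rna
    atac_meta = meta_common.copy()
    atac_meta["depth"] = atac_binary.sum(axis=1) * 50 + 1000
    atac_meta["tss_enrichment"] = rng.gamma(shape=8.0, scale=1.0,
                                            size=cfg.n_cells)

    rna = OmicsMatrix(values=rna_counts, modality=RNA, cell_ids=barcodes,
                      feature_ids=[f"gene{i}" for i in range(cfg.n_genes)],
                      cell_meta=rna_meta)
    anns = peak_annotations_for(cfg)
    atac = OmicsMatrix(values=atac_binary, modality=ATAC,
                       cell_ids=list(barcodes),
                       feature_ids=[a.name for a in anns],
                       cell_meta=atac_meta, feature_meta=anns)

    # gene TSS: genes placed along the chromosomes round-robin, strand +
    layout = chrom_layout_for(cfg)
    chroms = sorted(layout, key=lambda c: layout[c][0])
    tss = {}
    for i in range(cfg.n_genes):
        chrom = chroms[i % len(chroms)]
        pos = 10000 + (i // len(chroms)) * 5000
        tss[f"gene{i}"] = PeakAnnotation(chrom, pos, pos + 1, strand="+")

    truth = {
        "pairing": pd.DataFrame({
            "rna_barcode": barcodes, "atac_barcode": barcodes,
            "cell_type": type_names,
            "batch": [f"batch{b}" for b in batches],
            "depth": depth_rna,
        }),
        "latent": latent,
        "centers": centers,
        "chrom_layout": layout,
        "gene_tss": tss,
        "planted_links": list(cfg.planted_links),
    }
    return rna, atac, truth


def unpair(rna: OmicsMatrix, atac: OmicsMatrix, truth: dict, seed: int = 0):
    """Re-key barcodes disjointly and shuffle ATAC cell order.

    The returned truth table maps the new barcodes back to the original
    pairing; nothing in the matrices themselves reveals it.
    """
    rng = np.random.default_rng(seed)
    perm = rng.permutation(atac.n_cells)
    rna2 = rna.copy()
    rna2.cell_ids = [f"R_{rng.integers(0, 2**32):08x}_{i}"
                     for i in range(rna.n_cells)]
    rna2.cell_meta = rna.cell_meta.set_axis(rna2.cell_ids)
    atac2 = atac.subset_cells(perm)
    new_a = [f"A_{rng.integers(0, 2**32):08x}_{i}"
             for i in range(atac.n_cells)]
    atac2.cell_ids = new_a
    atac2.cell_meta = atac2.cell_meta.set_axis(new_a)

    pairing = truth["pairing"].copy()
    # original index i -> new rna barcode; original atac row perm[j] -> row j
    pairing["rna_barcode"] = rna2.cell_ids
    inv = np.empty_like(perm)
    inv[perm] = np.arange(len(perm))
    pairing["atac_barcode"] = [new_a[inv[i]] for i in range(len(perm))]
    pairing["atac_row"] = inv
    truth2 = dict(truth)
    truth2["pairing"] = pairing
    return rna2, atac2, truth2
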