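# scact

Cycle-consistent adversarial alignment, cross-modality translation, and
in-silico perturbation for **unpaired** single-cell multiome data.

Single-cell assays measure one molecular layer per cell: scRNA-seq gives a
cell-by-gene expression matrix, scATAC-seq a cell-by-peak chromatin
accessibility matrix. Co-assay (paired) data is scarce, so most cohorts of
the same tissue come as two disjoint sets of cells with no shared barcodes.
`scact` learns to relate such cohorts without any cell-level pairing, for
researchers who want to (i) place both cohorts in one latent space, (ii)
predict one modality from the other, and (iii) ask which peaks drive a
gene's predicted expression.

## Model

Given X_R ∈ R^{m×q} (log-normalized expression) and X_A ∈ {0,1}^{n×p}
(binarized accessibility), two autoencoders learn k = 20-dimensional
embeddings z_R, z_A. The ATAC networks are chromosome-masked: each
chromosome's peaks have their own sub-network (hidden widths 128/64/32) and
no weight crosses chromosomes before the final latent projection. Mapper
MLPs f : z_R ↦ z_A-space and g : z_A ↦ z_R-space translate between latent
spaces, and per-cell-type discriminator pairs (D_A^t, D_R^t) give weakly
supervised adversarial feedback. Training minimizes

```
L = L_rec + γ·L_adv + λ·L_con
```

where L_rec = MSE(X_R, X_R→R) + BCE(X_A, X_A→A); L_adv combines the
per-type GAN log-likelihood (discriminators ascend) with the cycle term
−log D(mapped) + BCE(f(g(z_A)), z_A) + MSE(g(f(z_R)), z_R) (generators
descend); and L_con is a mutual-information surrogate that penalizes, for
each batch/depth stratum, the KL divergence between the stratum's
moment-matched Gaussian and the pooled batch. Translation to ATAC produces
per-peak probabilities p_R→A with an optional Bernoulli sampling step;
attribution uses integrated gradients of the A→R map with an all-zeros
(closed-chromatin) baseline and a completeness check.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

The built-in simulator generates a paired multiome cohort with known cell
types, chromosome structure, batch effects, and a planted peak→gene link
(peak 10 = `chr1:20000-20500` drives `gene5` in cell type `type0`), then
hides the pairing. Training and evaluation take about a minute on one CPU:

```python
import numpy as np
from scact import (SimConfig, simulate_multiome, TrainConfig, train,
                   build_model, log_normalize, translate_rna_to_atac,
                   group_attribution, rank_peaks, joint_embedding)
from scact.synthetic import chrom_layout_for
from scact import evaluate as ev

cfg = SimConfig(seed=2, planted_links=[(10, 5, 2.0)])   # desk-scale preset
rna, atac, truth = simulate_multiome(cfg)
rna = log_normalize(rna)

types = sorted(set(rna.cell_meta["cell_type"]))
model = build_model(rna.n_features, atac.n_features,
                    chrom_layout_for(cfg), types, seed=2)
model, history = train(model, rna, atac, TrainConfig(seed=2))
print(f"reconstruction loss: {history[0].rec:.3f} -> {history[-1].rec:.3f}")

emb, modalities = joint_embedding(model, rna, atac)
cell_types = np.concatenate([rna.cell_meta["cell_type"],
                             atac.cell_meta["cell_type"]])
mixing = ev.modality_mixing_score(emb, modalities, cell_types,
                                  n_neighbors=100, n_draws=20, seed=0)
print("mixing score per type:",
      {k: round(v, 3) for k, v in sorted(mixing.items())})

p, _ = translate_rna_to_atac(model, rna)
auc = ev.translation_auroc(p, atac.to_dense())["overall"]
print(f"RNA->ATAC translation AUCROC vs hidden pairing: {auc:.3f}")

labels = atac.cell_meta["cell_type"].to_numpy()
attrs, access = group_attribution(model, atac, "gene5", labels,
                                  gene_ids=rna.feature_ids, n_steps=32,
                                  top_n=3)
table = rank_peaks(attrs["type0"], top_n=3, annotations=atac.feature_meta)
print(table[["rank", "peak", "score"]].to_string(index=False))
print("mean accessibility of the top peak, per type:")
print(access[table["peak_index"].iloc[0]].round(3).to_string())
```

Output:

```
reconstruction loss: 2.466 -> 0.768
mixing score per type: {'type0': 0.806, 'type1': 0.819, 'type2': 0.748, 'type3': 0.676}
RNA->ATAC translation AUCROC vs hidden pairing: 0.765
 rank               peak    score
    1   chr1:20000-20500 0.069071
    2 chr1:254000-254500 0.067462
    3   chr2:68000-68500 0.067110
mean accessibility of the top peak, per type:
group
type1    0.344
type3    0.047
type2    0.000
type0    1.000
```

Reading the numbers: reconstruction loss falls during training; the
modality mixing score (0.5 = modalities fully separated, 1 = perfectly
interleaved neighborhoods) shows both cohorts mingling in every cell type;
the AUCROC scores predicted accessibility probabilities against the hidden
paired truth; and the planted driver peak ranks first for its target gene
in the driving cell type, with the in-group (1.000) vs out-group (≤0.344)
accessibility contrast that marks a cell-type-specific regulatory element.

## Command line

The same pipeline is available as subcommands, each writing a manifest
(config, seed, version, input checksums) for reproducibility:

```
scact simulate   --out data --seed 1 --planted-link 10:5:2.0
scact preprocess --input data/rna  --out prep_rna  --modality RNA
scact preprocess --input data/atac --out prep_atac --modality ATAC
scact train      --rna prep_rna --atac prep_atac --checkpoint-out model.npz
scact translate  --checkpoint model.npz --input prep_rna --direction r2a --out r2a
scact evaluate   --checkpoint model.npz --rna prep_rna --atac prep_atac --out report
scact perturb    --checkpoint model.npz --atac prep_atac --gene gene5 --out attr
```

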