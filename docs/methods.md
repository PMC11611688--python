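# Methods

## Problem setting

Two single-cell cohorts from the same tissue are profiled with different
assays: a log-normalized cell-by-gene expression matrix X_R ∈ R^{m×q}
(scRNA-seq) and a binarized cell-by-peak accessibility matrix X_A ∈ {0,1}^{n×p}
(scATAC-seq). No cell is measured in both assays, so there is no shared
barcode and no row correspondence. The package aligns the two cohorts in
linked latent spaces, translates cells across modalities, and attributes a
gene's translated expression to individual peaks. Cell-type labels, batch
assignments, sequencing depths, TSS-enrichment values and doublet flags are
inputs (in practice produced by standard annotation pipelines); this package
does not cluster, call peaks, or detect doublets.

## Model

Two autoencoders learn modality-specific embeddings of dimension k = 20:

* z_R = F_EncR(x_R), reconstructed by F_DecR — an unmasked MLP with hidden
  widths 256, 64 and a linear latent/output (the architecture of the RNA
  branch is a free design choice; these widths are exposed in config).
* z_A = F_EncA(x_A), reconstructed by F_DecA — chromosome-masked: each
  chromosome's peaks pass through their own sub-network with hidden widths
  128, 64, 32; the per-chromosome outputs are concatenated and linearly
  projected to the latent. The decoder mirrors this in reverse with a
  sigmoid per peak. No weight connects a peak to another chromosome's
  sub-network, so inter-chromosomal entries of the first encoder stage and
  last decoder stage are exact structural zeros at all times, including
  after every optimizer update.

The ATAC latent uses a sigmoid activation, so z_A ∈ (0,1)^k. This is the
one reading under which the cycle-consistency BCE term below is well-posed
(BCE requires targets in [0,1]).

Two mapper MLPs translate between latent spaces: f : z_R → z_A-space (two
hidden layers of width 2k, sigmoid output so the image lies in the ATAC
latent's box) and g : z_A → z_R-space (same widths, linear output). One
discriminator pair (D_A^t, D_R^t) per cell type t (MLPs of hidden width k,
sigmoid output) provides weakly supervised adversarial feedback: D_A^t
separates real z_A from mapped f(z_R) among cells of type t, and D_R^t
separates z_R from g(z_A).

### Loss terms

* Reconstruction: `L_rec = MSE(X_R, X_R→R) + BCE(X_A, X_A→A)`, both
  mean-reduced over matrix entries. Mean (not sum) reduction keeps γ and λ
  comparable across dataset sizes.
* Confounder penalty `L_con`: a mutual-information surrogate between the
  embedding and each confounder (batch as categories; depth binned into
  quartiles). For each confounder stratum s the penalty adds
  KL( N(μ_s, diag σ_s²) ‖ N(μ, diag σ²) ), the divergence between the
  stratum's moment-matched diagonal Gaussian and that of the pooled batch,
  summed over strata and confounders. It is non-negative, zero when all
  strata share moments, differentiable, and closed-form. Strata with fewer
  than two cells contribute zero. A variance floor of 1e-6 guards empty
  directions.
* Adversarial (discriminator objective, maximized):
  per type t, `E[log D_A(z_A)] + E[log(1−D_A(f(z_R)))] + E[log D_R(z_R)]
  + E[log(1−D_R(g(z_A)))]`, expectations over cells of that type, summed
  over types.
* Cycle (generator objective, minimized): per type t, over ATAC cells
  `−log D_R(g(z_A)) + BCE(f(g(z_A)), z_A)` and over RNA cells
  `−log D_A(f(z_R)) + MSE(g(f(z_R)), z_R)`.
* Total: `L = L_rec + γ·L_adv + λ·L_con`.

All probabilities are clamped to [1e-7, 1−1e-7] before any logarithm;
gradients do not flow through the clamp outside the interval.

### Training

Phase 1 pretrains the autoencoders on `L_rec + λ·L_con` so the latent
geometry stabilizes before any adversarial pressure. Phase 2 alternates,
per minibatch, one discriminator ascent step (touching only discriminator
parameters, on detached embeddings) with one generator descent step on
`L_rec + γ·cycle + λ·L_con` (touching only encoder/decoder/mapper
parameters). Adam (β = 0.9/0.999) optimizes everything; all shuffling and
initialization derive from a single seed, so runs are bit-reproducible.
A naive GAN objective is used rather than a Wasserstein variant.

Defaults: γ = 0.2, λ = 0.1, learning rate 1e-3, batch 128, 30 pretraining +
150 adversarial epochs. γ and λ were fixed by the prescribed uniform grid
over [0.1, 2] on the desk-scale synthetic preset, selecting by converged
total loss; learning rate and batch size by a grid over [1e-5, 1e-3] ×
[16, 256]. A caveat worth knowing: at desk scale, γ ≥ 0.5 reliably induces
mode collapse of the mapper g — every cell of a type is mapped to one point,
which fools the per-type discriminators while paying only a small cycle
penalty (the within-type latent variance). Small γ keeps the cycle term
dominant in the generator's gradient and preserves within-type structure.
Optional early stopping halts a phase when the relative change of the total
loss stays below 1e-4 for 10 consecutive epochs.

The networks are implemented on a compact reverse-mode automatic
differentiation core (`scact.autodiff`) written on numpy; its gradients are
verified against central finite differences in the test suite, and the same
machinery supplies the input gradients that integrated-gradients attribution
needs.

## Translation

ATAC → RNA: `x_A→R = F_DecR(g(F_EncA(x_A)))`, deterministic. RNA → ATAC:
`p_R→A = F_DecA(f(F_EncR(x_R)))` gives per-peak accessibility probabilities;
an optional seeded Bernoulli draw produces a binary matrix. The probability
matrix is always returned because ROC evaluation needs scores, not samples;
sampling is opt-in.

## Alignment metrics

The joint embedding places ATAC cells at z_A and RNA cells at f(z_R)
(ATAC-latent space, default): the sigmoid-bounded box keeps the two clouds
on comparable scales for cosine neighborhoods. The RNA-space variant
(z_R vs g(z_A)) is available.

* Modality mixing score: for a cell type, sample a member cell and count
  its 1,000 nearest cells (cosine) by modality; the score is
  `1 − |c_A/(c_A + c_R) − 0.5|` ∈ [0.5, 1], equal to 1 exactly when the
  neighborhood is balanced. Scores are averaged over 50 seeded draws by
  default (a single draw is a high-variance estimate).
* Global homogeneity: silhouette on cosine distance against labels; ARI and
  AMI between a k-means clustering of the embedding and the labels.
* Pairwise cosine distances within each cell type, subsampled to a cap,
  with Welch t and variance-ratio F statistics for method comparisons.
* Translation: AUCROC over all (cell, peak) entries of p_R→A against the
  binary truth (overall and per type; degenerate truth reported as null),
  and squared Pearson correlation of per-feature pseudo-bulk signals.

## Regulatory readouts

* Motif activation score: mean (or λ_p-weighted) accessibility of peaks
  within 750 kb upstream of a gene's TSS, per cell type. Upstream is
  strand-aware; unstranded genes fall back to a symmetric window with a
  warning. The per-peak weights default to uniform; a distance-decay option
  exp(−d/τ) is available.
* Peak-to-gene linkage: for peaks within 100 kb of the TSS, Pearson
  correlation between per-cell-type pseudo-bulk accessibility and
  pseudo-bulk expression, with the test p-value and a 0.05 significance
  flag. Pseudo-bulk is used because per-cell binary accessibility makes
  per-cell Pearson degenerate; at least 3 groups are required.

## In-silico perturbation

For a target gene, the attributed function is the deterministic A→R map
`F(x) = [F_DecR(g(F_EncA(x)))]_gene` (no sampling inside attribution —
gradients of sampled outputs are undefined). Integrated gradients with an
all-zeros baseline ("fully closed chromatin") are computed by a midpoint
Riemann sum; starting from 64 steps, the step count doubles until the
completeness identity Σ_i IG_i = F(x) − F(baseline) holds to 1% relative
(capped at 1024 steps; the achieved gap is reported on the result). On a
piecewise-linear (ReLU) network a fixed 64-step rule typically leaves a
~2% gap, hence the refine-and-check loop. Group-level scores default to
the mean of per-cell attributions; attributing the group's pseudo-bulk
profile is available behind a flag. Alongside the ranked peaks, the mean
observed accessibility of the top peaks per group is reported, enabling the
in-group vs out-group contrast used to interpret driver peaks.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes: a
shared low-dimensional program drives both modalities of each cell. Cell
types are separated program centers (`type_separation`, default 2.0, in
units such that a kNN classifier on the true program recovers the type at
>0.9 accuracy; within-type program noise has sd `latent_noise` = 0.5 per
dimension). RNA counts are negative-binomial (gamma-Poisson, dispersion
`rna_noise` = 0.5) with log-mean = gene loadings · program + a per-batch
gene shift (`batch_effect_size` = 0.3) + a log library-size offset
(`depth_dispersion` = 0.4). ATAC peaks are Bernoulli with logits =
`atac_scale` · peak loadings · program + `atac_base_logit` (−2.0, giving
realistic sparsity). Peaks occupy contiguous coordinate blocks per
chromosome. The desk-scale preset — 600 cells per modality, 300 genes,
1,000 peaks, 4 types, 3 chromosomes, 2 batches — trains in about half a
minute on one CPU; these sizes are the package's default study conditions.

A planted link (peak, gene, effect) makes the peak an almost perfectly
type-specific element of the first type's program (loading 3× along the
type's direction — the phenotype of a marker gene's driver peak, accessible
in-type and closed elsewhere) and adds `effect` × the peak's standardized
program activity to the gene's log-mean. This gives attribution and linkage
methods a known causal signal to recover.

`unpair` re-keys barcodes disjointly and shuffles the ATAC cell order; the
returned truth table alone retains the correspondence, for evaluation only.

What the simulator does *not* emulate: read-level noise, fragment-length
structure, sequence content, doublets, ambient contamination, or realistic
gene/peak count scales. Passing tests therefore demonstrate that the
implementation recovers the structure the model assumes, at desk scale —
not that the method attains any particular accuracy on real tissue.

## Robustness conventions in the test suite

End-to-end recovery checks (trained-vs-untrained mixing and translation,
AUCROC above a 5-standard-error null bound, planted-peak top-5 attribution)
are stochastic under GAN training at desk scale; they are run over three
seeds and each property must hold in at least two of the three.

## Known limitations

* The per-type discriminators require the same label set in both cohorts;
  labels are trusted, not inferred.
* Mode collapse of the mappers at larger γ is a real failure mode at small
  sample sizes (see Training); the loss history and the within-type spread
  of mapped embeddings are the diagnostics to watch.
* The confounder penalty is a surrogate, not a bound on true mutual
  information for non-Gaussian embeddings.
* Attribution reflects what the trained network uses, which under weak
  training concentrates on type-discriminative peaks; causal peaks that are
  redundant with many correlated peaks may share credit.
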