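"""Networks and loss terms of the cycle-consistent adversarial aligner.

Two autoencoders learn modality-specific latent embeddings of dimension
``k`` (default 20).  The ATAC autoencoder respects chromosome structure:
its first encoder stage (and the mirrored last decoder stage) is a set of
per-chromosome sub-networks with hidden widths 128, 64, 32, so no weight
connects a peak on one chromosome to another chromosome's sub-network;
the sub-network outputs are concatenated and linearly projected to the
latent space.  Two mapper MLPs ``f`` (RNA latent -> ATAC latent) and ``g``
(ATAC latent -> RNA latent) translate between latent spaces, and one pair
of discriminators per cell type provides weakly supervised adversarial
feedback.

Loss terms:

* reconstruction — MSE for RNA, BCE for the binary ATAC matrix;
* confounder penalty — a mutual-information surrogate: for each confounder
  stratum, the KL divergence between the moment-matched diagonal Gaussian of
  the stratum's embeddings and that of the pooled batch;
* adversarial (discriminator) — the per-cell-type GAN log-likelihood the
  discriminator step maximizes;
* cycle — per-cell-type generator loss combining the fool-the-discriminator
  terms with latent cycle-consistency (MSE on the RNA side, BCE on the
  sigmoid-bounded ATAC side).

The total objective is ``rec + gamma * adv + lambda_con * con``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .autodiff import Tensor, concat, relu, sigmoid
from .data_model import ATAC, RNA, Embedding, OmicsMatrix

EPS = 1e-7  # probability clamp before any log


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Linear:
    """Dense layer with He-normal init; activation in {None,'relu','sigmoid'}."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 activation: str | None = "relu"):
        scale = np.sqrt(2.0 / max(n_in, 1))
        self.W = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True)
        self.activation = activation

    def __call__(self, x: Tensor) -> Tensor:
        h = x @ self.W + self.b
        if self.activation == "relu":
            return relu(h)
        if self.activation == "sigmoid":
            return sigmoid(h)
        return h

    @property
    def params(self) -> list:
        return [self.W, self.b]


class MLP:
    def __init__(self, widths: list, rng: np.random.Generator,
                 out_activation: str | None = None):
        self.layers = []
        for i in range(len(widths) - 1):
            last = i == len(widths) - 2
            self.layers.append(Linear(widths[i], widths[i + 1], rng,
                                      activation=out_activation if last
                                      else "relu"))

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x

    @property
    def params(self) -> list:
        return [p for layer in self.layers for p in layer.params]


class LayoutError(ValueError):
    """Chromosome layout does not partition the peak index range."""


def _validate_layout(chrom_layout: dict, p: int) -> list:
    """Check the layout partitions [0, p); return (chrom, start, end) sorted."""
    ranges = sorted(((c, int(s), int(e)) for c, (s, e) in chrom_layout.items()),
                    key=lambda t: t[1])
    cursor = 0
    for c, s, e in ranges:
        if s != cursor or e <= s:
            raise LayoutError(
                f"chromosome layout does not partition [0,{p}): "
                f"{c} spans [{s},{e}) but expected start {cursor}")
        cursor = e
    if cursor != p:
        raise LayoutError(
            f"chromosome layout covers [0,{cursor}) but matrix has {p} peaks")
    return ranges


class ChromBlockStage:
    """Per-chromosome sub-networks applied to disjoint peak slices.

    Direction 'enc': each chromosome's peaks go through widths
    ``p_c -> 128 -> 64 -> 32``; outputs are concatenated.
    Direction 'dec': the mirrored stack maps a per-chromosome 32-block back to
    that chromosome's peaks with a sigmoid output.
    """

    def __init__(self, ranges: list, rng: np.random.Generator,
                 widths=(128, 64, 32), direction: str = "enc"):
        self.ranges = ranges
        self.widths = tuple(widths)
        self.direction = direction
        self.blocks = []
        for _, s, e in ranges:
            p_c = e - s
            if direction == "enc":
                self.blocks.append(MLP([p_c, *widths], rng,
                                       out_activation="relu"))
            else:
                self.blocks.append(MLP([*widths[::-1], p_c], rng,
                                       out_activation="sigmoid"))

    def __call__(self, x: Tensor) -> Tensor:
        outs = []
        if self.direction == "enc":
            for (chrom, s, e), block in zip(self.ranges, self.blocks):
                outs.append(block(x[:, s:e]))
        else:
            w = self.widths[-1]
            for i, block in enumerate(self.blocks):
                outs.append(block(x[:, i * w:(i + 1) * w]))
        return concat(outs, axis=1)

    @property
    def out_width(self) -> int:
        return self.widths[-1] * len(self.blocks)

    @property
    def params(self) -> list:
        return [p for b in self.blocks for p in b.params]

    def first_layer_weight(self) -> np.ndarray:
        """Materialize the block-diagonal peak-side weight matrix.

        Encoder: (p, n_chrom*w0) with zeros wherever a peak of one chromosome
        would connect to another chromosome's sub-network.  Decoder: the
        transposely shaped final stage.  Inter-chromosomal entries are exact
        zeros by construction.
        """
        w0 = self.widths[0]
        p = self.ranges[-1][2]
        full = np.zeros((p, w0 * len(self.blocks)))
        for i, ((chrom, s, e), block) in enumerate(zip(self.ranges,
                                                       self.blocks)):
            layer = block.layers[0] if self.direction == "enc" \
                else block.layers[-1]
            W = layer.W.data
            if self.direction == "enc":
                full[s:e, i * w0:(i + 1) * w0] = W
            else:
                full[s:e, i * w0:(i + 1) * w0] = W.T
        return full


# ---------------------------------------------------------------------------
# the model bundle
# ---------------------------------------------------------------------------

@dataclass
class ScactModel:
    """Trained parameter bundle: autoencoders, mappers, discriminators."""

    q: int
    p: int
    k: int
    chrom_layout: dict
    cell_types: list
    gamma: float
    lambda_con: float
    seed: int
    rna_hidden: tuple = (256, 64)
    atac_hidden: tuple = (128, 64, 32)
    # optional feature vocabularies, carried through checkpoints so that
    # downstream stages can name genes/peaks without re-reading the inputs
    rna_feature_ids: list = None
    atac_feature_ids: list = None
    enc_rna: MLP = field(default=None, repr=False)
    dec_rna: MLP = field(default=None, repr=False)
    enc_atac_blocks: ChromBlockStage = field(default=None, repr=False)
    enc_atac_proj: Linear = field(default=None, repr=False)
    dec_atac_proj: Linear = field(default=None, repr=False)
    dec_atac_blocks: ChromBlockStage = field(default=None, repr=False)
    mapper_ra: MLP = field(default=None, repr=False)
    mapper_ar: MLP = field(default=None, repr=False)
    discriminators: dict = field(default=None, repr=False)

    # ---- forward passes -------------------------------------------------
    def encode_rna_t(self, x: Tensor) -> Tensor:
        return self.enc_rna(x)

    def decode_rna_t(self, z: Tensor) -> Tensor:
        return self.dec_rna(z)

    def encode_atac_t(self, x: Tensor) -> Tensor:
        return self.enc_atac_proj(self.enc_atac_blocks(x))

    def decode_atac_t(self, z: Tensor) -> Tensor:
        return self.dec_atac_blocks(self.dec_atac_proj(z))

    def map_ra_t(self, z: Tensor) -> Tensor:
        return self.mapper_ra(z)

    def map_ar_t(self, z: Tensor) -> Tensor:
        return self.mapper_ar(z)

    # ---- parameter groups -----------------------------------------------
    @property
    def autoencoder_params(self) -> list:
        return (self.enc_rna.params + self.dec_rna.params
                + self.enc_atac_blocks.params + self.enc_atac_proj.params
                + self.dec_atac_proj.params + self.dec_atac_blocks.params)

    @property
    def mapper_params(self) -> list:
        return self.mapper_ra.params + self.mapper_ar.params

    @property
    def generator_params(self) -> list:
        return self.autoencoder_params + self.mapper_params

    @property
    def discriminator_params(self) -> list:
        return [p for (da, dr) in self.discriminators.values()
                for p in da.params + dr.params]

    def atac_encoder_first_layer(self) -> np.ndarray:
        return self.enc_atac_blocks.first_layer_weight()

    def atac_decoder_last_layer(self) -> np.ndarray:
        return self.dec_atac_blocks.first_layer_weight()


def build_model(q: int, p: int, chrom_layout: dict, cell_types: list,
                k: int = 20, seed: int = 0,
                rna_hidden=(256, 64), atac_hidden=(128, 64, 32),
                gamma: float = 1.0, lambda_con: float = 1.0) -> ScactModel:
    """Construct a seed-deterministic model for q genes and p peaks.

    The RNA autoencoder is an unmasked MLP (hidden widths ``rna_hidden``);
    the ATAC autoencoder is chromosome-blocked with ``atac_hidden`` widths
    per chromosome and a linear projection to the sigmoid-bounded latent.
    Mappers are MLPs of width 2k; ``f`` has a sigmoid output so mapped RNA
    embeddings live in the ATAC latent's (0,1) box, ``g`` is linear.  One
    discriminator pair per cell type, hidden width k.
    """
    if not cell_types:
        raise ValueError("cell_types must be non-empty")
    ranges = _validate_layout(chrom_layout, p)
    rng = np.random.default_rng(seed)
    m = ScactModel(q=q, p=p, k=k, chrom_layout=dict(chrom_layout),
                   cell_types=list(cell_types), gamma=gamma,
                   lambda_con=lambda_con, seed=seed,
                   rna_hidden=tuple(rna_hidden), atac_hidden=tuple(atac_hidden))
    m.enc_rna = MLP([q, *rna_hidden, k], rng, out_activation=None)
    m.dec_rna = MLP([k, *rna_hidden[::-1], q], rng, out_activation=None)
    m.enc_atac_blocks = ChromBlockStage(ranges, rng, atac_hidden, "enc")
    m.enc_atac_proj = Linear(m.enc_atac_blocks.out_width, k, rng,
                             activation="sigmoid")
    m.dec_atac_proj = Linear(k, m.enc_atac_blocks.out_width, rng,
                             activation="relu")
    m.dec_atac_blocks = ChromBlockStage(ranges, rng, atac_hidden, "dec")
    m.mapper_ra = MLP([k, 2 * k, 2 * k, k], rng, out_activation="sigmoid")
    m.mapper_ar = MLP([k, 2 * k, 2 * k, k], rng, out_activation=None)
    m.discriminators = {}
    for t in cell_types:
        da = MLP([k, k, k, 1], rng, out_activation="sigmoid")
        dr = MLP([k, k, k, 1], rng, out_activation="sigmoid")
        m.discriminators[t] = (da, dr)
    return m


# ---------------------------------------------------------------------------
# encode / decode / map (public, ndarray in-out)
# ---------------------------------------------------------------------------

def encode(model: ScactModel, m: OmicsMatrix) -> Embedding:
    """Embed all cells of one modality into the k-dimensional latent."""
    x = Tensor(m.to_dense())
    if m.modality == RNA:
        if m.n_features != model.q:
            raise ValueError(f"expected {model.q} genes, got {m.n_features}")
        z = model.encode_rna_t(x)
    else:
        if m.n_features != model.p:
            raise ValueError(f"expected {model.p} peaks, got {m.n_features}")
        z = model.encode_atac_t(x)
    return Embedding(values=z.data, source_modality=m.modality,
                     cell_ids=list(m.cell_ids), mapped=False)


def decode(model: ScactModel, z: Embedding, target_modality: str) -> np.ndarray:
    """Decode a latent embedding into the target modality's feature space.

    RNA decoding returns a real-valued matrix; ATAC decoding returns
    per-peak accessibility probabilities in [0,1].
    """
    if z.k != model.k:
        raise ValueError(f"embedding dim {z.k} != model latent dim {model.k}")
    zt = Tensor(z.values)
    if target_modality == RNA:
        return model.decode_rna_t(zt).data
    return model.decode_atac_t(zt).data


def map_embedding(model: ScactModel, z: Embedding, direction: str) -> Embedding:
    """Apply mapper f ('RA') or g ('AR') to a latent embedding."""
    zt = Tensor(z.values)
    if direction == "RA":
        out = model.map_ra_t(zt)
        src = z.source_modality
    elif direction == "AR":
        out = model.map_ar_t(zt)
        src = z.source_modality
    else:
        raise ValueError("direction must be 'RA' or 'AR'")
    return Embedding(values=out.data, source_modality=src,
                     cell_ids=list(z.cell_ids), mapped=True)


# ---------------------------------------------------------------------------
# loss terms (tensor core + float wrappers)
# ---------------------------------------------------------------------------

def mse_t(target: Tensor, pred: Tensor) -> Tensor:
    return ((pred - target) ** 2).mean()

def bce_t(target: Tensor, pred: Tensor) -> Tensor:
    p = pred.clip(EPS, 1.0 - EPS)
    return -(target * p.log() + (1.0 - target) * (1.0 - p).log()).mean()


def loss_reconstruction(xr, xr_hat, xa, xa_hat) -> float:
    """MSE(X_R, X_R->R) + BCE(X_A, X_A->A), each mean-reduced over entries."""
    return float((mse_t(Tensor(xr), Tensor._wrap(xr_hat))
                  + bce_t(Tensor(xa), Tensor._wrap(xa_hat))).data)


def _strata_indices(confounders: pd.DataFrame, n_bins: int = 4) -> list:
    """Index groups per confounder column; continuous columns quartile-binned."""
    groups = []
    for col in confounders.columns:
        s = confounders[col]
        vals = s.to_numpy()
        if np.issubdtype(np.asarray(vals).dtype, np.number) \
                and pd.Series(vals).nunique() > n_bins * 2:
            binned = pd.qcut(vals, q=n_bins, duplicates="drop",
                             labels=False)
        else:
            binned = pd.factorize(s, use_na_sentinel=True)[0]
        col_groups = [np.flatnonzero(binned == b)
                      for b in np.unique(binned) if b >= 0]
        groups.append(col_groups)
    return groups


def confounder_loss_t(z: Tensor, strata: list, var_floor: float = 1e-6) -> Tensor:
    """Sum over confounders and strata of KL(N(mu_s, S_s) || N(mu, S)).

    Moments are diagonal-Gaussian, moment-matched within the batch (population
    variance).  Strata with fewer than 2 cells contribute 0.
    """
    mu = z.mean(axis=0, keepdims=True)
    var = ((z - mu) ** 2).mean(axis=0, keepdims=True) + var_floor
    total = Tensor(0.0)
    for col_groups in strata:
        for idx in col_groups:
            if len(idx) < 2:
                continue
            zs = z[idx]
            mu_s = zs.mean(axis=0, keepdims=True)
            var_s = ((zs - mu_s) ** 2).mean(axis=0, keepdims=True) + var_floor
            kl = 0.5 * ((var / var_s).log()
                        + (var_s + (mu_s - mu) ** 2) / var
                        - 1.0).sum()
            total = total + kl
    return total


def loss_confounder(model: ScactModel, z: Embedding,
                    confounders: pd.DataFrame) -> float:
    """MI surrogate between latent embedding and confounder strata (>= 0)."""
    strata = _strata_indices(confounders)
    return float(confounder_loss_t(Tensor(z.values), strata).data)


def _log(p: Tensor) -> Tensor:
    return p.clip(EPS, 1.0 - EPS).log()


def discriminator_loss_t(model: ScactModel, z_r: Tensor, z_a: Tensor,
                         z_ra: Tensor, z_ar: Tensor,
                         labels_r: np.ndarray, labels_a: np.ndarray) -> Tensor:
    """Per-cell-type GAN log-likelihood; the discriminator step MAXIMIZES this.

    For each cell type t with members in the batch:
    E[log D_A(z_A)] + E[log(1-D_A(z_R->A))] + E[log D_R(z_R)]
    + E[log(1-D_R(z_A->R))], expectations over cells of that type.
    """
    labels_r = np.asarray(labels_r)
    labels_a = np.asarray(labels_a)
    total = Tensor(0.0)
    for t, (da, dr) in model.discriminators.items():
        ia = np.flatnonzero(labels_a == t)
        ir = np.flatnonzero(labels_r == t)
        if len(ia) == 0 and len(ir) == 0:
            continue
        if len(ia):
            total = total + _log(da(z_a[ia])).mean()
            total = total + _log(1.0 - dr(z_ar[ia])).mean()
        if len(ir):
            total = total + _log(1.0 - da(z_ra[ir])).mean()
            total = total + _log(dr(z_r[ir])).mean()
    return total


def cycle_loss_t(model: ScactModel, z_r: Tensor, z_a: Tensor,
                 z_ra: Tensor, z_ar: Tensor,
                 labels_r: np.ndarray, labels_a: np.ndarray) -> Tensor:
    """Per-cell-type generator loss; the generator step MINIMIZES this.

    ATAC cells of type t: -log D_R(z_A->R) plus BCE between the cycled
    latent f(g(z_A)) and the sigmoid-bounded z_A.  RNA cells: -log D_A(z_R->A)
    plus MSE between g(f(z_R)) and z_R.  Per-cell reductions are means over
    the k latent coordinates; expectations are means over cells of the type.
    """
    labels_r = np.asarray(labels_r)
    labels_a = np.asarray(labels_a)
    z_cycle_a = model.map_ra_t(z_ar)   # f(g(z_A))
    z_cycle_r = model.map_ar_t(z_ra)   # g(f(z_R))
    total = Tensor(0.0)
    for t, (da, dr) in model.discriminators.items():
        ia = np.flatnonzero(labels_a == t)
        ir = np.flatnonzero(labels_r == t)
        if len(ia):
            adv = -_log(dr(z_ar[ia])).mean()
            target = z_a[ia].clip(EPS, 1.0 - EPS)
            pred = z_cycle_a[ia].clip(EPS, 1.0 - EPS)
            bce = -(target * pred.log()
                    + (1.0 - target) * (1.0 - pred).log()).mean()
            total = total + adv + bce
        if len(ir):
            adv = -_log(da(z_ra[ir])).mean()
            mse = ((z_cycle_r[ir] - z_r[ir]) ** 2).mean()
            total = total + adv + mse
    return total


def loss_discriminator(model: ScactModel, z_r: Embedding, z_a: Embedding,
                       z_ra: Embedding, z_ar: Embedding,
                       labels, labels_atac=None) -> float:
    la = labels if labels_atac is None else labels_atac
    return float(discriminator_loss_t(
        model, Tensor(z_r.values), Tensor(z_a.values),
        Tensor(z_ra.values), Tensor(z_ar.values),
        np.asarray(labels), np.asarray(la)).data)


def loss_cycle(model: ScactModel, z_r: Embedding, z_a: Embedding,
               z_ra: Embedding, z_ar: Embedding,
               labels, labels_atac=None) -> float:
    la = labels if labels_atac is None else labels_atac
    return float(cycle_loss_t(
        model, Tensor(z_r.values), Tensor(z_a.values),
        Tensor(z_ra.values), Tensor(z_ar.values),
        np.asarray(labels), np.asarray(la)).data)


@dataclass
class LossReport:
    """Per-step/epoch loss decomposition."""

    rec: float
    con: float
    adv_g: float
    adv_d: float
    gamma: float
    lambda_con: float

    @property
    def total(self) -> float:
        return (self.rec + self.gamma * (self.adv_g + self.adv_d)
                + self.lambda_con * self.con)


def loss_total(rec: float, adv_g: float, adv_d: float, con: float,
               gamma: float, lambda_con: float) -> LossReport:
    """Combine the loss terms into the overall weighted objective."""
    if gamma < 0 or lambda_con < 0:
        raise ValueError("loss weights must be non-negative")
    return LossReport(rec=rec, con=con, adv_g=adv_g, adv_d=adv_d,
                      gamma=gamma, lambda_con=lambda_con)


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def _param_tree(model: ScactModel) -> dict:
    tree = {}
    groups = {
        "enc_rna": model.enc_rna.params,
        "dec_rna": model.dec_rna.params,
        "enc_atac_blocks": model.enc_atac_blocks.params,
        "enc_atac_proj": model.enc_atac_proj.params,
        "dec_atac_proj": model.dec_atac_proj.params,
        "dec_atac_blocks": model.dec_atac_blocks.params,
        "mapper_ra": model.mapper_ra.params,
        "mapper_ar": model.mapper_ar.params,
    }
    for t_i, t in enumerate(model.cell_types):
        da, dr = model.discriminators[t]
        groups[f"disc_a_{t_i}"] = da.params
        groups[f"disc_r_{t_i}"] = dr.params
    for name, params in groups.items():
        for i, p in enumerate(params):
            tree[f"{name}__{i}"] = p
    return tree


def save_model(model: ScactModel, path: str) -> None:
    """Save all parameters and hyperparameters to a single .npz archive."""
    meta = {
        "q": model.q, "p": model.p, "k": model.k,
        "chrom_layout": {c: [int(s), int(e)]
                         for c, (s, e) in model.chrom_layout.items()},
        "cell_types": list(model.cell_types),
        "gamma": model.gamma, "lambda_con": model.lambda_con,
        "seed": model.seed,
        "rna_hidden": list(model.rna_hidden),
        "atac_hidden": list(model.atac_hidden),
        "rna_feature_ids": model.rna_feature_ids,
        "atac_feature_ids": model.atac_feature_ids,
    }
    arrays = {k: t.data for k, t in _param_tree(model).items()}
    np.savez(path, __meta__=np.frombuffer(
        json.dumps(meta).encode(), dtype=np.uint8), **arrays)


def load_model(path: str) -> ScactModel:
    """Rebuild a model bit-exactly from a checkpoint archive."""
    with np.load(path) as npz:
        meta = json.loads(bytes(npz["__meta__"]).decode())
        model = build_model(
            q=meta["q"], p=meta["p"],
            chrom_layout={c: tuple(v) for c, v in meta["chrom_layout"].items()},
            cell_types=meta["cell_types"], k=meta["k"], seed=meta["seed"],
            rna_hidden=tuple(meta["rna_hidden"]),
            atac_hidden=tuple(meta["atac_hidden"]),
            gamma=meta["gamma"], lambda_con=meta["lambda_con"])
        model.rna_feature_ids = meta.get("rna_feature_ids")
        model.atac_feature_ids = meta.get("atac_feature_ids")
        for key, tensor in _param_tree(model).items():
            tensor.data = npz[key].copy()
    return model
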