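"""Two-phase alternating optimization.

Phase 1 pretrains the two autoencoders on reconstruction plus the confounder
penalty, giving the latent spaces a stable geometry before any adversarial
signal is applied.  Phase 2 alternates, per minibatch, a discriminator ascent
step on the per-cell-type GAN log-likelihood with a generator descent step on
``rec + gamma * cycle + lambda_con * con``.  Discriminator steps touch only
discriminator parameters and generator steps only encoder/decoder/mapper
parameters.  All randomness (shuffling, init) is seeded, so a run is exactly
reproducible.

The two key loss weights gamma and lambda are tuned by a uniform grid search
over [0.1, 2]; learning rate and batch size are searched over [1e-5, 1e-3]
and [16, 256].
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .data_model import OmicsMatrix
from .model_core import (LossReport, ScactModel, bce_t, build_model,
                         confounder_loss_t, cycle_loss_t,
                         discriminator_loss_t, mse_t, _strata_indices)

GAMMA_RANGE = (0.1, 2.0)
LAMBDA_RANGE = (0.1, 2.0)
LR_RANGE = (1e-5, 1e-3)
BATCH_RANGE = (16, 256)


@dataclass
class TrainConfig:
    gamma: float = 0.2
    lambda_con: float = 0.1
    lr: float = 1e-3
    batch_size: int = 128
    pretrain_epochs: int = 30
    adversarial_epochs: int = 150
    d_steps_per_g_step: int = 1
    seed: int = 0
    k: int = 20
    # early stopping: relative change of total loss < plateau_tol over
    # plateau_patience consecutive epochs
    plateau_tol: float = 1e-4
    plateau_patience: int = 10
    early_stop: bool = False
    confounder_cols: tuple = ("batch", "depth")

    def __post_init__(self):
        if self.batch_size < 2:
            raise ValueError("batch_size must be >= 2 (stratum moments)")
        for name in ("gamma", "lambda_con", "lr"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


def _confounder_frame(m: OmicsMatrix, cols) -> pd.DataFrame:
    present = [c for c in cols if c in m.cell_meta.columns]
    return m.cell_meta[present]


def _labels(m: OmicsMatrix) -> np.ndarray:
    if "cell_type" not in m.cell_meta.columns:
        raise ValueError("cell_type column required for training")
    return m.cell_meta["cell_type"].to_numpy()


def train(model: ScactModel, rna: OmicsMatrix, atac: OmicsMatrix,
          cfg: TrainConfig):
    """Train in place; returns ``(model, history)`` with per-epoch LossReports."""
    labels_r, labels_a = _labels(rna), _labels(atac)
    set_r, set_a = set(labels_r), set(labels_a)
    if set_r != set_a:
        raise ValueError(
            "cell-type label sets differ between modalities: "
            f"{sorted(set_r ^ set_a)}")
    x_r = rna.to_dense()
    x_a = atac.to_dense()
    conf_r = _confounder_frame(rna, cfg.confounder_cols)
    conf_a = _confounder_frame(atac, cfg.confounder_cols)
    rng = np.random.default_rng(cfg.seed)

    opt_ae = Adam(model.autoencoder_params, lr=cfg.lr)
    opt_g = Adam(model.generator_params, lr=cfg.lr)
    opt_d = Adam(model.discriminator_params, lr=cfg.lr)

    history: list[LossReport] = []

    def batches(n_r, n_a):
        order_r = rng.permutation(n_r)
        order_a = rng.permutation(n_a)
        n_steps = max(1, min(n_r, n_a) // cfg.batch_size)
        for s in range(n_steps):
            br = order_r[s * cfg.batch_size:(s + 1) * cfg.batch_size]
            ba = order_a[s * cfg.batch_size:(s + 1) * cfg.batch_size]
            if len(br) < 2 or len(ba) < 2:
                continue
            yield br, ba

    def epoch(adversarial: bool) -> LossReport:
        sums = np.zeros(4)  # rec, con, adv_g, adv_d
        count = 0
        for br, ba in batches(len(x_r), len(x_a)):
            xr_t, xa_t = Tensor(x_r[br]), Tensor(x_a[ba])
            lr_b, la_b = labels_r[br], labels_a[ba]
            strata_r = _strata_indices(conf_r.iloc[br]) if conf_r.shape[1] else []
            strata_a = _strata_indices(conf_a.iloc[ba]) if conf_a.shape[1] else []

            adv_d_val = 0.0
            if adversarial:
                for _ in range(cfg.d_steps_per_g_step):
                    # discriminator ascent on detached embeddings
                    z_r = Tensor(model.encode_rna_t(xr_t).data)
                    z_a = Tensor(model.encode_atac_t(xa_t).data)
                    z_ra = Tensor(model.map_ra_t(z_r).data)
                    z_ar = Tensor(model.map_ar_t(z_a).data)
                    d_obj = discriminator_loss_t(model, z_r, z_a, z_ra, z_ar,
                                                 lr_b, la_b)
                    opt_d.zero_grad()
                    (-d_obj).backward()
                    opt_d.step()
                    adv_d_val = float(d_obj.data)

            # generator / autoencoder step
            z_r = model.encode_rna_t(xr_t)
            z_a = model.encode_atac_t(xa_t)
            rec = mse_t(xr_t, model.decode_rna_t(z_r)) \
                + bce_t(xa_t, model.decode_atac_t(z_a))
            con = Tensor(0.0)
            if strata_r:
                con = con + confounder_loss_t(z_r, strata_r)
            if strata_a:
                con = con + confounder_loss_t(z_a, strata_a)
            if adversarial:
                z_ra = model.map_ra_t(z_r)
                z_ar = model.map_ar_t(z_a)
                adv_g = cycle_loss_t(model, z_r, z_a, z_ra, z_ar, lr_b, la_b)
                loss = rec + cfg.gamma * adv_g + cfg.lambda_con * con
                opt = opt_g
            else:
                adv_g = Tensor(0.0)
                loss = rec + cfg.lambda_con * con
                opt = opt_ae
            opt.zero_grad()
            opt_d.zero_grad()
            loss.backward()
            opt.step()
            sums += [float(rec.data), float(con.data),
                     float(adv_g.data), adv_d_val]
            count += 1
        count = max(count, 1)
        return LossReport(rec=sums[0] / count, con=sums[1] / count,
                          adv_g=sums[2] / count, adv_d=sums[3] / count,
                          gamma=cfg.gamma, lambda_con=cfg.lambda_con)

    def plateaued(totals: list) -> bool:
        if not cfg.early_stop or len(totals) <= cfg.plateau_patience:
            return False
        window = totals[-(cfg.plateau_patience + 1):]
        base = abs(window[0]) + 1e-12
        return all(abs(window[i + 1] - window[i]) / base < cfg.plateau_tol
                   for i in range(len(window) - 1))

    totals: list[float] = []
    for _ in range(cfg.pretrain_epochs):
        rep = epoch(adversarial=False)
        history.append(rep)
        totals.append(rep.total)
        if plateaued(totals):
            break
    totals = []
    for _ in range(cfg.adversarial_epochs):
        rep = epoch(adversarial=True)
        history.append(rep)
        totals.append(rep.total)
        if plateaued(totals):
            break
    model.gamma = cfg.gamma
    model.lambda_con = cfg.lambda_con
    return model, history


def _grid(lo: float, hi: float, n: int, log: bool = False) -> np.ndarray:
    """Uniform grid including endpoints; n=1 gives the (geometric) midpoint."""
    if n == 1:
        return np.array([np.sqrt(lo * hi) if log else (lo + hi) / 2.0])
    if log:
        return np.geomspace(lo, hi, n)
    return np.linspace(lo, hi, n)


def grid_search(rna: OmicsMatrix, atac: OmicsMatrix, cfg: TrainConfig,
                n_points: int = 5, chrom_layout=None,
                search_epochs: int | None = None) -> TrainConfig:
    """Uniform grid search: first over (gamma, lambda), then (lr, batch size).

    Each candidate trains a fresh model from the shared seed for a reduced
    number of epochs; the configuration minimizing the converged total loss
    wins.  Returned values always lie inside the stated search ranges.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    if chrom_layout is None:
        raise ValueError("grid_search needs the chromosome layout to "
                         "build candidate models")
    cell_types = sorted(set(_labels(rna)) | set(_labels(atac)))
    pe = max(1, cfg.pretrain_epochs // 4) if search_epochs is None \
        else search_epochs
    ae = max(1, cfg.adversarial_epochs // 4) if search_epochs is None \
        else search_epochs

    def run(c: TrainConfig) -> float:
        model = build_model(rna.n_features, atac.n_features, chrom_layout,
                            cell_types, k=c.k, seed=c.seed,
                            gamma=c.gamma, lambda_con=c.lambda_con)
        _, hist = train(model, rna, atac,
                        replace(c, pretrain_epochs=pe, adversarial_epochs=ae))
        return hist[-1].total

    best = replace(cfg)
    best_val = np.inf
    for g in _grid(*GAMMA_RANGE, n_points):
        for lam in _grid(*LAMBDA_RANGE, n_points):
            cand = replace(cfg, gamma=float(g), lambda_con=float(lam))
            val = run(cand)
            if val < best_val:
                best, best_val = cand, val
    best_val = np.inf
    chosen = best
    for lr in _grid(*LR_RANGE, n_points, log=True):
        for bs in _grid(*BATCH_RANGE, n_points, log=True):
            cand = replace(chosen, lr=float(lr), batch_size=int(round(bs)))
            val = run(cand)
            if val < best_val:
                best, best_val = cand, val
    return best
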