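"""Architecture contracts and loss-term oracles."""

import numpy as np
import pytest

from scact.autodiff import Adam, Tensor, sigmoid
from scact.data_model import ATAC, RNA, Embedding, OmicsMatrix
from scact.model_core import (EPS, LayoutError, LossReport, build_model,
                              decode, encode, load_model, loss_confounder,
                              loss_cycle, loss_discriminator,
                              loss_reconstruction, loss_total, map_embedding,
                              save_model)
import pandas as pd

LAYOUT = {"chr1": (0, 5), "chr2": (5, 12)}


def small_model(k=4, q=6, cell_types=("a", "b"), seed=0):
    return build_model(q=q, p=12, chrom_layout=LAYOUT,
                       cell_types=list(cell_types), k=k, seed=seed,
                       rna_hidden=(8, 6), atac_hidden=(6, 4, 3))


class StubD:
    """Discriminator stub with a constant output probability."""

    def __init__(self, value):
        self.value = value
        self.params = []

    def __call__(self, z):
        return Tensor(np.full((z.shape[0], 1), self.value))


class StubMap:
    def __init__(self, fn):
        self.fn = fn
        self.params = []

    def __call__(self, z):
        return Tensor(self.fn(z.data))


class TestBuild:
    def test_atac_embedding_has_latent_dimension(self):
        model = build_model(q=6, p=12, chrom_layout=LAYOUT,
                            cell_types=["a"], k=20, seed=0,
                            atac_hidden=(6, 4, 3))
        m = OmicsMatrix(values=np.ones((1, 12)), modality=ATAC,
                        cell_ids=["c"], feature_ids=[str(j) for j in range(12)])
        assert encode(model, m).values.shape == (1, 20)

    def test_inter_chromosomal_weights_are_zero(self):
        model = small_model()
        W_enc = model.atac_encoder_first_layer()
        W_dec = model.atac_decoder_last_layer()
        w0 = model.atac_hidden[0]
        # chr1 peaks (rows 0:5) must not touch chr2's sub-network columns
        assert np.all(W_enc[0:5, w0:] == 0)
        assert np.all(W_enc[5:12, :w0] == 0)
        assert np.all(W_dec[0:5, w0:] == 0)
        assert np.all(W_dec[5:12, :w0] == 0)
        # intra-chromosomal blocks are dense
        assert np.all(W_enc[0:5, :w0] != 0)

    def test_same_seed_identical_parameters(self):
        a, b = small_model(seed=3), small_model(seed=3)
        for pa, pb in zip(a.generator_params + a.discriminator_params,
                          b.generator_params + b.discriminator_params):
            assert np.array_equal(pa.data, pb.data)

    @pytest.mark.parametrize("layout", [
        {"chr1": (0, 5), "chr2": (5, 10)},         # incomplete
        {"chr1": (0, 7), "chr2": (5, 12)},         # overlapping
        {"chr1": (2, 7), "chr2": (7, 12)},         # gap at origin
    ])
    def test_bad_layouts_rejected(self, layout):
        with pytest.raises(LayoutError):
            build_model(q=6, p=12, chrom_layout=layout, cell_types=["a"],
                        k=4, seed=0)

    def test_one_discriminator_pair_per_cell_type(self):
        model = small_model(cell_types=("x", "y", "z"))
        assert set(model.discriminators) == {"x", "y", "z"}


class TestEncodeDecode:
    def test_zero_input_zero_final_layer_gives_zero_embedding(self):
        model = small_model()
        last = model.enc_rna.layers[-1]
        last.W.data[:] = 0.0
        last.b.data[:] = 0.0
        m = OmicsMatrix(values=np.zeros((2, 6)), modality=RNA,
                        cell_ids=["a", "b"],
                        feature_ids=[f"g{j}" for j in range(6)])
        assert np.all(encode(model, m).values == 0)

    def test_batch_row_equals_single_cell(self, rng):
        model = small_model()
        x = rng.random((3, 12))
        ids = [f"p{j}" for j in range(12)]
        batch = OmicsMatrix(values=x, modality=ATAC,
                            cell_ids=list("abc"), feature_ids=ids)
        single = OmicsMatrix(values=x[1:2], modality=ATAC,
                             cell_ids=["b"], feature_ids=ids)
        zb = encode(model, batch).values
        zs = encode(model, single).values
        assert np.allclose(zb[1], zs[0], atol=1e-12)

    def test_atac_decode_in_unit_interval(self, rng):
        model = small_model()
        z = Embedding(values=rng.normal(size=(4, 4)), source_modality=ATAC,
                      cell_ids=list("abcd"))
        out = decode(model, z, ATAC)
        assert out.shape == (4, 12)
        assert np.all((out >= 0) & (out <= 1))

    def test_decoder_chromosome_blocks_are_independent(self, rng):
        model = small_model()
        base = rng.normal(size=(1, model.dec_atac_blocks.out_width // 1))
        stage = model.dec_atac_blocks
        h = rng.normal(size=(1, stage.widths[-1] * 2))
        out1 = stage(Tensor(h)).data
        h2 = h.copy()
        h2[0, stage.widths[-1]:] += 1.0  # perturb only chr2's latent block
        out2 = stage(Tensor(h2)).data
        assert np.allclose(out1[0, 0:5], out2[0, 0:5])   # chr1 unchanged
        assert not np.allclose(out1[0, 5:], out2[0, 5:])

    def test_overfit_five_cell_toy_reconstructs(self, rng):
        model = small_model(k=5)
        x_r = rng.random((5, 6))
        x_a = (rng.random((5, 12)) < 0.4).astype(float)
        opt = Adam(model.autoencoder_params, lr=1e-2)
        from scact.model_core import bce_t, mse_t
        for _ in range(800):
            xr_t, xa_t = Tensor(x_r), Tensor(x_a)
            rec = mse_t(xr_t, model.decode_rna_t(model.encode_rna_t(xr_t))) \
                + bce_t(xa_t, model.decode_atac_t(model.encode_atac_t(xa_t)))
            opt.zero_grad()
            rec.backward()
            opt.step()
        recon = model.decode_rna_t(model.encode_rna_t(Tensor(x_r))).data
        assert ((recon - x_r) ** 2).mean() < 1e-2


class TestMapEmbedding:
    def test_relu_pair_identity_mapper_preserves_embedding(self, rng):
        model = small_model(k=4)
        k = 4
        g = model.mapper_ar
        g.layers[0].W.data = np.hstack([np.eye(k), -np.eye(k)])
        g.layers[0].b.data[:] = 0
        g.layers[1].W.data = np.eye(2 * k)
        g.layers[1].b.data[:] = 0
        g.layers[2].W.data = np.vstack([np.eye(k), -np.eye(k)])
        g.layers[2].b.data[:] = 0
        z = Embedding(values=rng.normal(size=(5, k)), source_modality=ATAC,
                      cell_ids=list("abcde"))
        out = map_embedding(model, z, "AR")
        assert out.mapped
        assert np.allclose(out.values, z.values, atol=1e-12)

    def test_shape_preserved(self, rng):
        model = small_model(k=4)
        z = Embedding(values=rng.normal(size=(7, 4)), source_modality=RNA,
                      cell_ids=[f"c{i}" for i in range(7)])
        assert map_embedding(model, z, "RA").values.shape == (7, 4)


class TestReconstructionLoss:
    def test_analytic_bce_at_half(self, rng):
        xr = rng.normal(size=(3, 4))
        xa = (rng.random((3, 5)) < 0.5).astype(float)
        val = loss_reconstruction(xr, xr, xa, np.full((3, 5), 0.5))
        assert val == pytest.approx(np.log(2), rel=1e-9)

    def test_perfect_reconstruction_near_zero(self):
        xa = np.array([[0.0, 1.0]])
        val = loss_reconstruction(np.ones((1, 2)), np.ones((1, 2)),
                                  xa, xa)
        assert val == pytest.approx(0.0, abs=1e-6)

    def test_elementwise_oracle(self, rng):
        xr, xrh = rng.normal(size=(3, 4)), rng.normal(size=(3, 4))
        xa = (rng.random((3, 4)) < 0.5).astype(float)
        xah = rng.random((3, 4))
        mse = np.mean([(xr[i, j] - xrh[i, j]) ** 2
                       for i in range(3) for j in range(4)])
        bce = np.mean([-(xa[i, j] * np.log(xah[i, j])
                         + (1 - xa[i, j]) * np.log(1 - xah[i, j]))
                       for i in range(3) for j in range(4)])
        assert loss_reconstruction(xr, xrh, xa, xah) == \
            pytest.approx(mse + bce, abs=1e-10)


class TestConfounderLoss:
    def _emb(self, values):
        v = np.atleast_2d(values)
        return Embedding(values=v, source_modality=RNA,
                         cell_ids=[f"c{i}" for i in range(v.shape[0])])

    def test_identical_strata_give_zero(self):
        model = small_model()
        z = self._emb(np.array([[1.0], [3.0], [1.0], [3.0]]))
        conf = pd.DataFrame({"batch": ["a", "a", "b", "b"]})
        assert loss_confounder(model, z, conf) == pytest.approx(0.0, abs=1e-9)

    def test_shifted_strata_closed_form(self):
        # strata {-1,+1} and {d-1, d+1}: each stratum has unit variance,
        # pooled variance 1 + d^2/4, KL sums to log(1 + d^2/4)
        model = small_model()
        d = 1.7
        z = self._emb(np.array([[-1.0], [1.0], [d - 1.0], [d + 1.0]]))
        conf = pd.DataFrame({"batch": ["a", "a", "b", "b"]})
        val = loss_confounder(model, z, conf)
        assert val == pytest.approx(np.log(1 + d * d / 4), rel=1e-4)

    def test_random_two_strata_match_kl_oracle(self, rng):
        model = small_model()
        z = rng.normal(size=(12, 3))
        groups = np.array([0] * 5 + [1] * 7)
        conf = pd.DataFrame({"batch": groups})
        floor = 1e-6
        mu, var = z.mean(0), z.var(0) + floor
        expected = 0.0
        for g in (0, 1):
            zs = z[groups == g]
            mu_s, var_s = zs.mean(0), zs.var(0) + floor
            expected += 0.5 * np.sum(np.log(var / var_s)
                                     + (var_s + (mu_s - mu) ** 2) / var - 1)
        assert loss_confounder(model, z := self._emb(z), conf) == \
            pytest.approx(expected, rel=1e-9)

    def test_invariant_to_permutation_within_stratum(self, rng):
        model = small_model()
        vals = rng.normal(size=(10, 4))
        conf = pd.DataFrame({"batch": [0] * 5 + [1] * 5})
        base = loss_confounder(model, self._emb(vals), conf)
        perm = np.r_[rng.permutation(5), 5 + rng.permutation(5)]
        assert loss_confounder(model, self._emb(vals[perm]), conf) == \
            pytest.approx(base, rel=1e-12)

    def test_singleton_stratum_contributes_zero(self):
        model = small_model()
        z = self._emb(np.array([[0.0], [1.0], [2.0]]))
        conf = pd.DataFrame({"batch": ["a", "a", "b"]})
        conf2 = pd.DataFrame({"batch": ["a", "a", "a"]})
        v1 = loss_confounder(model, z, conf)
        # stratum b is a singleton: only stratum a contributes
        mu, var = z.values.mean(), z.values.var() + 1e-6
        za = z.values[:2]
        mu_s, var_s = za.mean(), za.var() + 1e-6
        expected = 0.5 * (np.log(var / var_s)
                          + (var_s + (mu_s - mu) ** 2) / var - 1)
        assert v1 == pytest.approx(expected, rel=1e-9)


def _embed(values, modality=RNA):
    v = np.atleast_2d(values)
    return Embedding(values=v, source_modality=modality,
                     cell_ids=[f"c{i}" for i in range(v.shape[0])])


class TestDiscriminatorLoss:
    def test_all_outputs_half_gives_4log_half_per_type(self, rng):
        model = small_model(cell_types=("a", "b"))
        for t in model.discriminators:
            model.discriminators[t] = (StubD(0.5), StubD(0.5))
        z = _embed(rng.normal(size=(4, 4)))
        labels = ["a", "a", "b", "b"]
        val = loss_discriminator(model, z, z, z, z, labels)
        assert val == pytest.approx(2 * 4 * np.log(0.5), rel=1e-9)

    def test_perfect_discriminator_attains_maximum_zero(self, rng):
        model = small_model(cell_types=("a",))
        # perfect: 1 on real, 0 on mapped (clamped internally)
        class PerfectPair:
            def __init__(self, real_ids):
                self.real = real_ids
            def __call__(self, z):
                # identify "real" embeddings by a marker coordinate
                return Tensor((z.data[:, :1] > 0).astype(float))
        model.discriminators["a"] = (PerfectPair(None), PerfectPair(None))
        real = _embed(np.ones((2, 4)))
        fake = _embed(-np.ones((2, 4)))
        val = loss_discriminator(model, real, real, fake, fake, ["a", "a"])
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_hand_summed_oracle_two_types(self, rng):
        model = small_model(cell_types=("a", "b"))
        z_r = _embed(rng.normal(size=(4, 4)))
        z_a = _embed(rng.normal(size=(4, 4)))
        z_ra = _embed(rng.normal(size=(4, 4)))
        z_ar = _embed(rng.normal(size=(4, 4)))
        labels = np.array(["a", "b", "a", "b"])

        def fwd(mlp, x):  # independent numpy forward pass
            h = x
            for i, layer in enumerate(mlp.layers):
                h = h @ layer.W.data + layer.b.data
                if i < len(mlp.layers) - 1:
                    h = np.maximum(h, 0)
                else:
                    h = 1 / (1 + np.exp(-h))
            return np.clip(h, EPS, 1 - EPS).ravel()

        expected = 0.0
        for t in ("a", "b"):
            da, dr = model.discriminators[t]
            idx = np.flatnonzero(labels == t)
            expected += np.mean(np.log(fwd(da, z_a.values[idx])))
            expected += np.mean(np.log(1 - fwd(da, z_ra.values[idx])))
            expected += np.mean(np.log(fwd(dr, z_r.values[idx])))
            expected += np.mean(np.log(1 - fwd(dr, z_ar.values[idx])))
        val = loss_discriminator(model, z_r, z_a, z_ra, z_ar, labels)
        assert val == pytest.approx(expected, abs=1e-10)

    def test_absent_type_skipped(self, rng):
        model = small_model(cell_types=("a", "b"))
        for t in model.discriminators:
            model.discriminators[t] = (StubD(0.5), StubD(0.5))
        z = _embed(rng.normal(size=(2, 4)))
        val = loss_discriminator(model, z, z, z, z, ["a", "a"])
        assert val == pytest.approx(4 * np.log(0.5), rel=1e-9)


class TestCycleLoss:
    def test_identity_mappers_and_fooled_discriminator(self):
        model = small_model(cell_types=("a",))
        model.mapper_ra = StubMap(lambda z: z)
        model.mapper_ar = StubMap(lambda z: z)
        model.discriminators["a"] = (StubD(1.0), StubD(1.0))
        z_a = _embed(np.array([[0.0, 1.0, 1.0, 0.0]]), ATAC)
        z_r = _embed(np.ones((1, 4)))
        val = loss_cycle(model, z_r, z_a, z_r, z_a, ["a"], ["a"])
        assert val == pytest.approx(0.0, abs=1e-5)

    def test_uniform_offset_gives_delta_squared(self, rng):
        model = small_model(cell_types=("a",))
        delta = 0.37
        model.mapper_ra = StubMap(lambda z: z)            # f
        model.mapper_ar = StubMap(lambda z: z + delta)    # g
        model.discriminators["a"] = (StubD(1.0), StubD(1.0))
        z_r = _embed(rng.normal(size=(3, 4)))
        z_ra = _embed(model.mapper_ra(Tensor(z_r.values)).data)
        # only RNA cells typed: ATAC side skipped
        val = loss_cycle(model, z_r, z_r, z_ra, z_ra,
                         ["a", "a", "a"], ["zz", "zz", "zz"])
        assert val == pytest.approx(delta ** 2, abs=1e-5)

    def test_fixed_tensor_oracle(self, rng):
        model = small_model(cell_types=("a",))
        model.mapper_ra = StubMap(lambda z: 1 / (1 + np.exp(-z)))
        model.mapper_ar = StubMap(lambda z: 2.0 * z)
        model.discriminators["a"] = (StubD(0.3), StubD(0.6))
        z_r = _embed(rng.normal(size=(2, 4)))
        z_a = _embed(rng.random((2, 4)), ATAC)
        z_ra = _embed(1 / (1 + np.exp(-z_r.values)))
        z_ar = _embed(2.0 * z_a.values)
        labels = ["a", "a"]
        # independent recomputation
        fg = 1 / (1 + np.exp(-2.0 * z_a.values))          # f(g(z_A))
        gf = 2.0 / (1 + np.exp(-z_r.values))              # g(f(z_R))
        t = np.clip(z_a.values, EPS, 1 - EPS)
        p = np.clip(fg, EPS, 1 - EPS)
        bce = -(t * np.log(p) + (1 - t) * np.log(1 - p)).mean()
        mse = ((gf - z_r.values) ** 2).mean()
        expected = -np.log(0.6) + bce - np.log(0.3) + mse
        val = loss_cycle(model, z_r, z_a, z_ra, z_ar, labels, labels)
        assert val == pytest.approx(expected, abs=1e-10)


class TestTotalLoss:
    def test_zero_weights_reduce_to_reconstruction(self):
        rep = loss_total(rec=1.7, adv_g=5.0, adv_d=2.0, con=9.0,
                         gamma=0.0, lambda_con=0.0)
        assert rep.total == pytest.approx(1.7)

    def test_arithmetic_example(self):
        rep = loss_total(rec=1.0, adv_g=2.0, adv_d=0.0, con=3.0,
                         gamma=0.5, lambda_con=0.1)
        assert rep.total == pytest.approx(2.3)

    def test_linearity_in_weights(self, rng):
        rec, ag, ad, con = rng.random(4)
        g1, l1 = rng.random(2)
        base = loss_total(rec, ag, ad, con, g1, l1).total
        doubled = loss_total(rec, ag, ad, con, 2 * g1, l1).total
        assert doubled - base == pytest.approx(g1 * (ag + ad), rel=1e-9)

    def test_report_invariant(self):
        rep = LossReport(rec=1.0, con=2.0, adv_g=3.0, adv_d=4.0,
                         gamma=0.7, lambda_con=0.2)
        assert rep.total == pytest.approx(1.0 + 0.7 * 7.0 + 0.2 * 2.0,
                                          rel=1e-6)

    def test_negative_weights_rejected(self):
        with pytest.raises(ValueError):
            loss_total(1.0, 1.0, 1.0, 1.0, -0.1, 0.1)


class TestCheckpoint:
    def test_save_load_bit_exact(self, tmp_path, rng):
        model = small_model(cell_types=("a", "b"), seed=11)
        x = rng.random((3, 12))
        m = OmicsMatrix(values=x, modality=ATAC, cell_ids=list("abc"),
                        feature_ids=[f"p{j}" for j in range(12)])
        z_before = encode(model, m).values
        path = tmp_path / "model.npz"
        save_model(model, path)
        loaded = load_model(path)
        for pa, pb in zip(model.generator_params + model.discriminator_params,
                          loaded.generator_params
                          + loaded.discriminator_params):
            assert np.array_equal(pa.data, pb.data)
        assert np.array_equal(encode(loaded, m).values, z_before)
        assert loaded.cell_types == model.cell_types
        assert loaded.chrom_layout == model.chrom_layout
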