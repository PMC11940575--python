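"""Decoder network, clamped-L1 MAP objective and joint training."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from beakmorph import autodecoder as ad
from beakmorph import sdf
from beakmorph.core import InvalidParameterError


def toy_samples(n_shapes=3, n_rows=150, seed=0):
    """Tiny per-shape SDF tables of analytic spheres of varying radius."""
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n_shapes):
        pts = rng.normal(size=(n_rows, 3))
        pts /= np.linalg.norm(pts, axis=1, keepdims=True)
        pts *= rng.random((n_rows, 1)) ** (1 / 3)
        r = 0.3 + 0.1 * i
        out.append(
            sdf.SDFSampleSet(
                shape_id=f"sphere{i}",
                points=pts,
                distances=np.linalg.norm(pts, axis=1) - r,
                near_surface_flag=np.zeros(n_rows, bool),
                seed=i,
            )
        )
    return out


class TestClamp:
    @pytest.mark.parametrize(
        "value,delta,expected",
        [(0.5, 0.1, 0.1), (-0.3, 0.1, -0.1), (0.05, 0.1, 0.05)],
    )
    def test_closed_forms(self, value, delta, expected):
        assert ad.clamp(value, delta) == pytest.approx(expected)

    @given(st.floats(-10, 10), st.floats(0.01, 1.0))
    def test_output_in_band(self, value, delta):
        out = ad.clamp(value, delta)
        assert -delta <= out <= delta
        if abs(value) < delta:
            assert out == value

    def test_invalid_delta(self):
        with pytest.raises(InvalidParameterError):
            ad.clamp(0.5, 0.0)


class TestDecoder:
    def test_batch_of_seven_gives_seven_outputs(self):
        params = ad.build_decoder(latent_dim=4, hidden_size=16, seed=0)
        out = ad.decoder_forward(
            params, np.zeros((7, 4)), np.random.default_rng(0).normal(size=(7, 3))
        )
        assert out.shape == (7,)

    def test_same_seed_identical_weights(self):
        a = ad.build_decoder(8, 32, seed=3)
        b = ad.build_decoder(8, 32, seed=3)
        for wa, wb in zip(a.params, b.params):
            assert np.array_equal(wa, wb)

    def test_skip_connection_widths(self):
        params = ad.build_decoder(latent_dim=8, hidden_size=32, seed=0)
        assert params.module1.layers[0].W.shape[0] == 8 + 3
        assert params.module2.layers[0].W.shape[0] == 32 + 8 + 3
        assert params.module2.layers[-1].W.shape[1] == 1

    def test_code_gradient_matches_finite_differences(self):
        params = ad.build_decoder(latent_dim=6, hidden_size=32, seed=0)
        rng = np.random.default_rng(1)
        z = rng.normal(size=(5, 6))
        x = rng.normal(size=(5, 3)) * 0.3
        s_obs = rng.normal(size=5) * 0.05
        delta = 0.1

        def loss_at(zz):
            return ad.clamped_l1(s_obs, ad.decoder_forward(params, zz, x), delta)

        pred, cache = ad.decoder_forward(params, z, x, want_cache=True)
        grad_pred = np.sign(ad.clamp(pred, delta) - ad.clamp(s_obs, delta)) * (
            np.abs(pred) < delta
        )
        g_z, _ = ad.decoder_backward(params, cache, grad_pred)
        eps = 1e-6
        for (i, j) in [(2, 3), (0, 0), (4, 5)]:
            z2 = z.copy()
            z2[i, j] += eps
            fd = (loss_at(z2) - loss_at(z)) / eps
            assert abs(fd - g_z[i, j]) <= 1e-4 * max(abs(fd), 1.0)


class TestMapLoss:
    def test_one_row_closed_form(self):
        # s = 0.5 and prediction -0.5 both clamp to +-0.1: loss 0.2
        assert ad.clamped_l1([0.5], [-0.5], 0.1) == pytest.approx(0.2)

    def test_zero_when_predictions_match(self):
        assert ad.clamped_l1([0.03, -0.2], [0.03, -0.2], 0.1) == 0.0

    def test_lambda_decomposition_identity(self):
        samples = toy_samples()
        params = ad.build_decoder(4, 16, seed=0)
        rng = np.random.default_rng(0)
        codes = rng.normal(size=(3, 4))
        pts = np.vstack([s.points[:20] for s in samples])
        dst = np.concatenate([s.distances[:20] for s in samples])
        idx = np.repeat(np.arange(3), 20)
        lam = 0.37
        l0 = ad.map_loss(pts, dst, idx, codes, params, ad.TrainConfig(4, 16, lam=0.0))
        l1 = ad.map_loss(pts, dst, idx, codes, params, ad.TrainConfig(4, 16, lam=lam))
        assert l1 == pytest.approx(l0 + lam * (codes**2).sum(), abs=1e-9)

    def test_zero_codes_zero_penalty(self):
        samples = toy_samples()
        params = ad.build_decoder(4, 16, seed=0)
        codes = np.zeros((3, 4))
        pts = samples[0].points[:10]
        dst = samples[0].distances[:10]
        idx = np.zeros(10, dtype=int)
        l0 = ad.map_loss(pts, dst, idx, codes, params, ad.TrainConfig(4, 16, lam=0.0))
        l1 = ad.map_loss(pts, dst, idx, codes, params, ad.TrainConfig(4, 16, lam=5.0))
        assert l0 == l1


class TestTrain:
    def config(self, lam=1e-4, epochs=15, seed=0):
        return ad.TrainConfig(
            latent_dim=4,
            hidden_size=32,
            lam=lam,
            epochs=epochs,
            steps_per_epoch=10,
            batch_size=64,
            learning_rate_theta=1e-3,
            learning_rate_z=1e-2,
            seed=seed,
        )

    def test_same_seed_identical_final_loss(self):
        a = ad.train(toy_samples(), self.config())
        b = ad.train(toy_samples(), self.config())
        assert a.history == b.history
        assert np.array_equal(a.codes.codes, b.codes.codes)

    def test_stronger_prior_shrinks_codes(self):
        weak = ad.train(toy_samples(), self.config(lam=1e-4))
        strong = ad.train(toy_samples(), self.config(lam=1.0))
        assert (
            np.linalg.norm(strong.codes.codes, axis=1).mean()
            < np.linalg.norm(weak.codes.codes, axis=1).mean()
        )

    def test_history_recorded_per_epoch(self):
        res = ad.train(toy_samples(), self.config(epochs=7))
        assert len(res.history) == 7
        assert np.isfinite(res.history).all()

    def test_too_few_shapes_rejected(self):
        with pytest.raises(InvalidParameterError):
            ad.train(toy_samples(n_shapes=1), self.config())

    def test_checkpoint_round_trip(self, tmp_path):
        path = tmp_path / "ckpt.npz"
        res = ad.train(toy_samples(), self.config(), checkpoint_path=path)
        params, codes, config = ad.load_checkpoint(path)
        x = np.random.default_rng(0).normal(size=(5, 3)) * 0.3
        orig = ad.decoder_forward(res.params, codes.codes[:1], x[:1])
        loaded = ad.decoder_forward(params, codes.codes[:1], x[:1])
        assert np.allclose(orig, loaded, atol=1e-12)
        assert codes.shape_ids == res.codes.shape_ids

    def test_embed_zero_steps_returns_initialization(self):
        res = ad.train(toy_samples(), self.config())
        cfg = self.config(seed=5)
        code, err = ad.embed_new_shape(
            res.params, toy_samples()[0], cfg, n_steps=0
        )
        rng = np.random.default_rng(5)
        expected = rng.normal(0.0, cfg.code_init_sd, size=(1, 4))
        assert np.array_equal(code, expected[0])


class TestDeskScaleModel:
    """Properties of the session-scoped 10-shape memorization run."""

    def test_smoothed_loss_non_increasing(self, overfit_model):
        h = np.asarray(overfit_model.result.history)
        win = 10
        smooth = np.convolve(h, np.ones(win) / win, mode="valid")
        # stochastic minibatch resampling allows small local bumps; the
        # smoothed trend must never rise by more than 10% of its level
        assert (np.diff(smooth) <= 0.1 * smooth[:-1]).all()

    def test_reembedding_recovers_trained_code(self, overfit_model):
        model = overfit_model
        sid = model.codes.shape_ids[0]
        fresh = sdf.sample_sdf(
            model.dataset.meshes[sid], n_uniform=1500, seed=999, shape_id="fresh"
        )
        cfg = ad.TrainConfig(
            latent_dim=8, hidden_size=128, seed=3,
            learning_rate_z=1e-2, batch_size=512,
        )
        code, err = ad.embed_new_shape(model.params, fresh, cfg, n_steps=600)
        trained = model.codes[sid]
        cos = code @ trained / (np.linalg.norm(code) * np.linalg.norm(trained))
        assert cos > 0.95

    def test_held_out_shape_embeds_with_comparable_error(self, overfit_model):
        from beakmorph import meshprep, synthetic

        model = overfit_model
        p = synthetic.ShapeParams("held", 3.7, 1.1, 0.9, curvature=0.1, hook=0.2)
        mesh, _ = meshprep.preprocess(synthetic.make_beak_mesh(p, resolution=32))
        sample = sdf.sample_sdf(mesh, n_uniform=1500, seed=555, shape_id="held")
        cfg = ad.TrainConfig(
            latent_dim=8, hidden_size=128, seed=4,
            learning_rate_z=1e-2, batch_size=512,
        )
        _, err = ad.embed_new_shape(model.params, sample, cfg, n_steps=600)
        train_err = ad.mean_clamped_error(
            model.params, model.codes, model.dataset.samples
        )
        assert err < 3 * max(train_err, 1e-3)

    def test_latent_interpolation_decodes_everywhere(self, overfit_model):
        from beakmorph import reconstruct

        model = overfit_model
        a = model.codes.codes[0]
        b = model.codes.codes[5]
        for t in np.linspace(0, 1, 5):
            grid = reconstruct.predict_sdf_grid(
                model.params, (1 - t) * a + t * b, resolution=32
            )
            mesh = reconstruct.extract_mesh(grid)
            assert len(mesh.faces) > 0
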