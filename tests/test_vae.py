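"""VAE: shapes, determinism, closed-form loss terms, training progress."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from flvae import nn
from flvae.phantom import PhantomSpec, make_phantom_cohort
from flvae.reslice import apply_mask_and_center
from flvae.types import SliceLabel
from flvae.vae import (VAEConfig, decode, elbo_loss, encode, encode_batch,
                       init_model, kl_divergence, latent_grid_panel,
                       load_checkpoint, reparameterize, save_checkpoint, train,
                       _loss_and_grads)

TINY = VAEConfig(conv_channels=(4, 8), hidden_units=8, epochs=2, seed=7)


@pytest.fixture(scope="module")
def toy_cohort():
    spec = PhantomSpec()
    slices, table = make_phantom_cohort(
        spec, {SliceLabel.NO_FL: 24, SliceLabel.THROMBOSED_FL: 24}, seed=42)
    return [apply_mask_and_center(s) for s in slices], table


@pytest.fixture(scope="module")
def toy_params(toy_cohort):
    images, _ = toy_cohort
    return train(images, VAEConfig(conv_channels=(4, 8), hidden_units=8,
                                   epochs=60, batch_size=16, seed=7))


class TestModelContracts:
    def test_encode_emits_two_2vectors(self, rng):
        p = init_model(TINY)
        lp = encode(p, rng.random((64, 64)))
        assert lp.mu.shape == (2,) and lp.logvar.shape == (2,)

    def test_same_seed_identical_weights(self):
        a, b = init_model(TINY), init_model(TINY)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_decode_range_and_shape(self):
        p = init_model(TINY)
        img = decode(p, (0.0, 0.0))
        assert img.shape == (64, 64)
        assert img.min() >= 0.0 and img.max() <= 1.0

    def test_encode_deterministic(self, rng):
        p = init_model(TINY)
        x = rng.random((64, 64))
        a, b = encode(p, x), encode(p, x)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.logvar, b.logvar)

    def test_batch_equals_single(self, rng):
        p = init_model(TINY)
        xs = rng.random((5, 64, 64))
        mu_b, lv_b = encode_batch(p, xs)
        for i in range(5):
            lp = encode(p, xs[i])
            np.testing.assert_allclose(mu_b[i], lp.mu, atol=1e-6)
            np.testing.assert_allclose(lv_b[i], lp.logvar, atol=1e-6)

    def test_wrong_shape_rejected(self, rng):
        p = init_model(TINY)
        with pytest.raises(ValueError):
            encode(p, rng.random((32, 32)))

    def test_collapsing_architecture_rejected(self):
        with pytest.raises(ValueError):
            init_model(VAEConfig(stride=16))


class TestReparameterize:
    def test_zero_noise_returns_mu(self):
        np.testing.assert_array_equal(
            reparameterize([1.5, -2.0], [0.3, 0.7], [0.0, 0.0]), [1.5, -2.0])

    def test_unit_variance_shift(self):
        np.testing.assert_allclose(
            reparameterize([0.0, 0.0], [0.0, 0.0], [1.0, 1.0]), [1.0, 1.0])

    def test_logvar_scales_noise(self):
        # logvar = 2 ln 2 -> sd 2, so unit noise moves z by 2
        z = reparameterize([0.0, 0.0], [2.0 * np.log(2.0), 0.0], [1.0, 0.0])
        np.testing.assert_allclose(z, [2.0, 0.0], rtol=1e-12)


class TestLoss:
    def test_kl_zero_at_prior(self):
        assert kl_divergence([0.0, 0.0], [0.0, 0.0]) == 0.0

    def test_kl_unit_mean_shift(self):
        assert kl_divergence([1.0, 0.0], [0.0, 0.0]) == pytest.approx(0.5)

    def test_kl_log2_variance(self):
        expected = 0.5 * (1.0 - np.log(2.0))
        assert kl_divergence([0.0, 0.0], [np.log(2.0), 0.0]) == pytest.approx(expected)

    @settings(deadline=None, max_examples=200)
    @given(st.lists(st.floats(-5, 5), min_size=2, max_size=2),
           st.lists(st.floats(-4, 4), min_size=2, max_size=2))
    def test_kl_nonnegative_and_zero_only_at_prior(self, mu, logvar):
        kl = kl_divergence(mu, logvar)
        assert kl >= 0.0
        if not np.allclose(mu, 0) or not np.allclose(logvar, 0):
            if max(abs(v) for v in mu + logvar) > 1e-3:
                assert kl > 0.0

    def test_elbo_total_is_sum_of_terms(self, rng):
        x = rng.random((64, 64))
        r = np.clip(x + rng.normal(0, 0.05, x.shape), 0, 1)
        total, recon, kl = elbo_loss(x, r, [0.3, -0.2], [0.1, 0.0])
        assert total == pytest.approx(recon + kl)
        assert recon > 0 and kl > 0

    def test_elbo_gaussian_is_sse(self, rng):
        x = rng.random((64, 64))
        r = np.clip(x + 0.1, 0, 1)
        total, recon, kl = elbo_loss(x, r, [0.0, 0.0], [0.0, 0.0],
                                     recon_loss="gaussian")
        assert recon == pytest.approx(np.square(r - x).sum())
        assert kl == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            elbo_loss(np.full((2, 2), np.nan), np.zeros((2, 2)), [0, 0], [0, 0])


class TestBackprop:
    def test_gradients_match_finite_differences(self, rng):
        """Analytic gradients of the full ELBO vs central differences, with
        biases shifted off the ReLU kinks so differencing is valid."""
        cfg = VAEConfig(conv_channels=(3, 5), hidden_units=7, epochs=1, seed=3)
        w = {k: v.astype(np.float64) + (0.2 if k.endswith("_b") else 0.0)
             for k, v in init_model(cfg).weights.items()}
        x = rng.random((2, 1, 64, 64))
        eps = rng.standard_normal((2, 2))
        r0, k0, grads = _loss_and_grads(w, x, eps, cfg)
        h = 1e-6
        for name in ("enc_c1_w", "enc_c2_w", "enc_d_w", "enc_mu_w", "enc_lv_w",
                     "dec_d1_w", "dec_d2_w", "dec_t1_w", "dec_t2_w", "dec_t1_b"):
            flat = w[name].ravel()
            for i in rng.choice(flat.size, size=3, replace=False):
                old = flat[i]
                flat[i] = old + h
                r1, k1, _ = _loss_and_grads(w, x, eps, cfg)
                flat[i] = old - h
                r2, k2, _ = _loss_and_grads(w, x, eps, cfg)
                flat[i] = old
                num = ((r1 + k1) - (r2 + k2)) / (2 * h)
                ana = grads[name].ravel()[i]
                assert abs(num - ana) <= 1e-4 * max(1.0, abs(num)), name

    def test_conv_transpose_is_adjoint_of_conv(self, rng):
        """<conv(x), y> == <x, convT(y)> for shared weights (exact linear
        algebra identity of the two operators)."""
        x = rng.random((2, 3, 16, 16))
        y = rng.random((2, 5, 8, 8))
        w = rng.random((5, 3, 3, 3))
        lhs = np.sum(nn.conv2d(x, w, np.zeros(5), 2, 1) * y)
        rhs = np.sum(x * nn.conv_transpose2d(y, w, np.zeros(3), 2, 1, 16))
        assert lhs == pytest.approx(rhs, rel=1e-12)


class TestTraining:
    def test_loss_history_length_matches_epochs(self, toy_params):
        assert toy_params.loss_history.shape == (toy_params.config.epochs, 3)
        assert toy_params.config.epochs == 60

    def test_default_epochs_is_100(self):
        assert VAEConfig().epochs == 100

    def test_training_reduces_loss(self, toy_params):
        assert toy_params.loss_history[-1, 0] < toy_params.loss_history[0, 0]

    def test_training_deterministic(self, toy_cohort):
        images, _ = toy_cohort
        cfg = VAEConfig(conv_channels=(4, 8), hidden_units=8, epochs=3, seed=9)
        a = train(images[:16], cfg)
        b = train(images[:16], cfg)
        np.testing.assert_array_equal(a.loss_history, b.loss_history)
        for k in a.weights:
            np.testing.assert_array_equal(a.weights[k], b.weights[k])

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            train([], TINY)

    def test_trained_reconstruction_beats_untrained(self, toy_cohort, toy_params):
        """Reconstruction through the trained posterior mean must at least
        halve the untrained model's mean absolute error on held-out-ish
        phantom slices."""
        images, _ = toy_cohort
        untrained = init_model(toy_params.config)

        def mae(params):
            errs = []
            for im in images[::6]:
                rec = decode(params, encode(params, im).mu)
                errs.append(np.abs(rec - im.pixels).mean())
            return np.mean(errs)

        assert mae(toy_params) < 0.5 * mae(untrained)

    def test_latent_cloud_stays_in_prior_support(self):
        """The KL term anchors the pooled posterior-mean cloud to the
        standard-normal prior: per-axis mean and spread stay within the
        prior's 3-sigma support at study-scale cohort sizes (empirical band
        for this architecture; see the methods note for measured centering).
        """
        spec = PhantomSpec()
        slices, _ = make_phantom_cohort(
            spec, {SliceLabel.NO_FL: 100, SliceLabel.THROMBOSED_FL: 60,
                   SliceLabel.PARTIAL_FL: 40}, seed=21)
        images = [apply_mask_and_center(s) for s in slices]
        params = train(images, VAEConfig(epochs=100, seed=7))
        mu, _ = encode_batch(params, images)
        assert np.all(np.abs(mu.mean(axis=0)) < 3.0)
        assert np.all(mu.std(axis=0) < 3.0)


class TestLatentGrid:
    def test_tile_count_and_shape(self):
        p = init_model(TINY)
        panel = latent_grid_panel(p, -3, 3, n=4)
        assert panel.shape == (4 * 64, 4 * 64)

    def test_corner_tiles_decode_grid_corners(self):
        p = init_model(TINY)
        panel = latent_grid_panel(p, -3, 3, n=3)
        np.testing.assert_allclose(panel[:64, :64], decode(p, (-3.0, -3.0)),
                                   atol=1e-12)
        np.testing.assert_allclose(panel[-64:, -64:], decode(p, (3.0, 3.0)),
                                   atol=1e-12)
        np.testing.assert_allclose(panel[:64, -64:], decode(p, (3.0, -3.0)),
                                   atol=1e-12)

    def test_degenerate_span_tiles_nearly_identical(self):
        p = init_model(TINY)
        panel = latent_grid_panel(p, 0.0, 1e-9, n=2)
        np.testing.assert_allclose(panel[:64, :64], panel[64:, 64:], atol=1e-6)

    def test_invalid_grid_rejected(self):
        p = init_model(TINY)
        with pytest.raises(ValueError):
            latent_grid_panel(p, 1.0, -1.0, n=4)


class TestCheckpoint:
    def test_roundtrip(self, toy_params, tmp_path):
        path = tmp_path / "ckpt.npz"
        save_checkpoint(toy_params, path)
        loaded = load_checkpoint(path)
        assert loaded.fingerprint == toy_params.fingerprint
        assert loaded.config == toy_params.config
        np.testing.assert_array_equal(loaded.loss_history, toy_params.loss_history)
        for k in toy_params.weights:
            np.testing.assert_array_equal(loaded.weights[k], toy_params.weights[k])
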