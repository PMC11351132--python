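"""VAE components: posterior, reparameterization, ELBO, training, sampling."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fermaug.preprocess import Normalizer, SeriesTensor
from fermaug.vae import (
    EncoderPosterior,
    VAEConfig,
    VAEModel,
    elbo_loss,
    encode,
    generate_synthetic,
    kl_divergence,
    reparameterize,
    train_vae,
)


@pytest.fixture(scope="module")
def tiny_config():
    """Full architecture on a short 50-point grid (keeps dense layers small)."""
    return VAEConfig(n_points=50, epochs=3, seed=1)


@pytest.fixture(scope="module")
def tiny_model(tiny_config):
    return VAEModel(tiny_config)


@pytest.fixture(scope="module")
def tiny_tensor(rng_module):
    data = rng_module.random((6, 50, 7))
    return SeriesTensor(data)


@pytest.fixture(scope="module")
def rng_module():
    return np.random.default_rng(77)


class TestConfig:
    def test_flat_dimension_on_default_grid(self):
        assert VAEConfig().flat_dim == 32_000

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"conv_filters": (32, 32, 48, 64)},          # not five layers
            {"conv_filters": (32, 32, 48, 64, 32)},      # last layer not 64
            {"dense_units": (256, 64)},
            {"epochs": 0},
            {"stride": 2},
            {"dropout_rate": 1.0},
        ],
    )
    def test_architecture_invariants_enforced(self, kwargs):
        with pytest.raises(ValueError):
            VAEConfig(**kwargs)


class TestEncode:
    def test_posterior_vectors_have_latent_size(self, tiny_model, rng):
        x = rng.random((50, 7))
        post = encode(x, tiny_model)
        assert post.mu.shape == (10,)
        assert post.logvar.shape == (10,)

    def test_encoding_is_deterministic(self, tiny_model, rng):
        x = rng.random((50, 7))
        a, b = encode(x, tiny_model), encode(x, tiny_model)
        np.testing.assert_array_equal(a.mu, b.mu)
        np.testing.assert_array_equal(a.logvar, b.logvar)

    def test_zero_initialized_heads_give_standard_prior(self, rng):
        model = VAEModel(VAEConfig(n_points=50, zero_init_heads=True))
        post = encode(rng.random((50, 7)), model)
        np.testing.assert_array_equal(post.mu, np.zeros(10))
        np.testing.assert_array_equal(post.logvar, np.zeros(10))

    def test_shape_mismatch_rejected(self, tiny_model, rng):
        with pytest.raises(ValueError, match="expected shape"):
            encode(rng.random((60, 7)), tiny_model)

    def test_nonfinite_input_rejected(self, tiny_model, rng):
        x = rng.random((50, 7))
        x[0, 0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            encode(x, tiny_model)


class TestReparameterize:
    def test_vanishing_variance_returns_mean(self):
        post = EncoderPosterior(mu=np.arange(10.0), logvar=np.full(10, -700.0))
        sample = reparameterize(post, seed=0)
        np.testing.assert_allclose(sample.z, np.arange(10.0), atol=1e-12)

    def test_monte_carlo_mean_matches_mu(self):
        post = EncoderPosterior(mu=np.zeros(10), logvar=np.zeros(10))
        draws = np.stack(
            [reparameterize(post, seed=s).z for s in range(10_000)]
        )
        assert np.all(np.abs(draws.mean(axis=0)) < 4 / np.sqrt(10_000))

    def test_fixed_seed_reproducible(self):
        post = EncoderPosterior(mu=np.ones(10), logvar=np.zeros(10))
        np.testing.assert_array_equal(
            reparameterize(post, seed=5).z, reparameterize(post, seed=5).z
        )


def _kl_monte_carlo(post, n=10_000, seed=0):
    """Independent KL oracle: E_q[log q(z) - log p(z)] by antithetic sampling."""
    rng = np.random.default_rng(seed)
    sd = np.exp(0.5 * post.logvar)
    eps = rng.standard_normal((n // 2, post.mu.size))
    z = np.vstack([post.mu + sd * eps, post.mu - sd * eps])
    log_q = -0.5 * (((z - post.mu) / sd) ** 2 + post.logvar + np.log(2 * np.pi)).sum(axis=1)
    log_p = -0.5 * (z**2 + np.log(2 * np.pi)).sum(axis=1)
    return float(np.mean(log_q - log_p))


class TestKLDivergence:
    def test_zero_when_posterior_equals_prior(self):
        assert kl_divergence(EncoderPosterior(np.zeros(10), np.zeros(10))) == 0.0

    def test_unit_mean_shift_gives_half(self):
        mu = np.zeros(10)
        mu[0] = 1.0
        post = EncoderPosterior(mu, np.zeros(10))
        assert kl_divergence(post) == pytest.approx(0.5, rel=1e-12)
        assert kl_divergence(post) == pytest.approx(_kl_monte_carlo(post), rel=0.01)

    def test_inflated_variance_coordinate(self):
        logvar = np.zeros(10)
        logvar[3] = np.log(4.0)
        post = EncoderPosterior(np.zeros(10), logvar)
        expected = 0.5 * (4.0 - np.log(4.0) - 1.0)
        assert kl_divergence(post) == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.8069, abs=1e-4)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        mu=st.lists(st.floats(-3, 3), min_size=10, max_size=10),
        logvar=st.lists(st.floats(-2, 2), min_size=10, max_size=10),
    )
    def test_nonnegative_for_all_posteriors(self, mu, logvar):
        assert kl_divergence(EncoderPosterior(np.array(mu), np.array(logvar))) >= 0.0

    def test_nonfinite_posterior_rejected(self):
        with pytest.raises(ValueError):
            EncoderPosterior(np.full(10, np.nan), np.zeros(10))


class TestElboLoss:
    def test_perfect_reconstruction_at_prior_is_zero(self, rng):
        x = rng.random((50, 7))
        post = EncoderPosterior(np.zeros(10), np.zeros(10))
        record = elbo_loss(x, x, post)
        assert record.total == 0.0

    def test_kl_component_matches_kl_divergence(self, rng):
        x = rng.random((50, 7))
        post = EncoderPosterior(rng.normal(size=10), rng.normal(size=10))
        record = elbo_loss(x, x + 0.1, post)
        assert record.kl == kl_divergence(post)

    def test_reconstruction_is_hand_summed_squared_error(self):
        x = np.array([[1.0], [3.0]])
        x_hat = np.array([[2.0], [1.0]])
        record = elbo_loss(x, x_hat, EncoderPosterior(np.zeros(2), np.zeros(2)))
        assert record.reconstruction == pytest.approx(1.0 + 4.0, rel=1e-15)

    def test_total_decomposes_exactly(self, rng):
        x = rng.random((50, 7))
        post = EncoderPosterior(rng.normal(size=10), rng.normal(size=10))
        record = elbo_loss(x, x + 0.3, post)
        assert record.total == record.reconstruction + record.kl

    def test_shape_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            elbo_loss(rng.random((5, 7)), rng.random((6, 7)),
                      EncoderPosterior(np.zeros(2), np.zeros(2)))


class TestTraining:
    def test_loss_declines_and_decoder_shape(self, tiny_tensor, tiny_config):
        cfg = VAEConfig(**{**tiny_config.__dict__, "epochs": 20})
        model, history = train_vae(tiny_tensor, cfg)
        assert len(history) == 20
        assert history[0].total > history[-1].total
        decoded = model.decode_batch(np.zeros((1, 10)))
        assert decoded.shape == (1, 50, 7)
        assert np.all((decoded >= 0) & (decoded <= 1))

    def test_unnormalized_input_warns(self, tiny_config, rng):
        data = rng.normal(loc=50.0, scale=10.0, size=(3, 50, 7))
        with pytest.warns(UserWarning, match="normalizer"):
            train_vae(SeriesTensor(data), tiny_config)

    def test_loss_records_decompose(self, tiny_tensor, tiny_config):
        _, history = train_vae(tiny_tensor, tiny_config)
        for rec in history:
            assert rec.total == rec.reconstruction + rec.kl
            assert rec.kl >= 0


class TestGeneration:
    def _normalizer(self):
        return Normalizer(scheme="minmax", shift=np.zeros(7), scale=np.ones(7))

    def test_sample_count_and_shape(self, tiny_tensor, tiny_config):
        model, _ = train_vae(tiny_tensor, tiny_config)
        pool = generate_synthetic(model, 5, self._normalizer(), seed=0)
        assert len(pool) == 5
        assert all(s.values.shape == (50, 7) for s in pool)
        assert all(s.provenance == "synthetic" for s in pool)

    def test_generated_values_respect_decoder_bounds(self, tiny_tensor, tiny_config):
        model, _ = train_vae(tiny_tensor, tiny_config)
        pool = generate_synthetic(model, 4, self._normalizer(), seed=1)
        stacked = pool.stacked_values()
        assert stacked.min() >= 0.0 and stacked.max() <= 1.0

    def test_zero_samples_rejected(self, tiny_tensor, tiny_config):
        model, _ = train_vae(tiny_tensor, tiny_config)
        with pytest.raises(ValueError):
            generate_synthetic(model, 0, self._normalizer(), seed=0)

    def test_fixed_seed_reproducible(self, tiny_tensor, tiny_config):
        model, _ = train_vae(tiny_tensor, tiny_config)
        a = generate_synthetic(model, 3, self._normalizer(), seed=9)
        b = generate_synthetic(model, 3, self._normalizer(), seed=9)
        np.testing.assert_array_equal(a.stacked_values(), b.stacked_values())


class TestPersistence:
    def test_save_load_roundtrip(self, tiny_tensor, tiny_config, tmp_path):
        model, _ = train_vae(tiny_tensor, tiny_config)
        model.time_grid = np.linspace(0, 10, 50)
        path = tmp_path / "model.npz"
        model.save(path)
        loaded = VAEModel.load(path)
        z = np.random.default_rng(3).standard_normal((2, 10))
        np.testing.assert_array_equal(model.decode_batch(z), loaded.decode_batch(z))
        np.testing.assert_array_equal(model.time_grid, loaded.time_grid)
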