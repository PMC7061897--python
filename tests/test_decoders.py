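import itertools

import numpy as np
import pytest

from eegfactors import (
    ConfigError,
    GRBMModel,
    Recording,
    ValidationError,
    encode,
    fit_ae,
    fit_grbm,
    fit_ica,
    fit_pca,
    fit_vae,
    gaussian_kl,
    grbm_unroll_finetune,
    ica_match_channels,
    reconstruct,
    reparameterize,
)
from eegfactors.decoders import AEModel, load_model, save_model
from eegfactors.evaluation import pearson_r


def _mean_channel_r(original, reconstructed):
    return np.mean(
        [pearson_r(original[i], reconstructed[i]) for i in range(original.shape[0])]
    )


# ---------------------------------------------------------------------------
# Autoencoder
# ---------------------------------------------------------------------------


class TestAutoencoder:
    def test_full_width_linear_ae_reconstructs_near_perfectly(self, laplace_mixture):
        _, _, rec = laplace_mixture
        X = (rec.data.T - rec.data.T.mean(0)) / rec.data.T.std(0)
        ae = fit_ae(X, m=8, epochs=40, batch=250, hidden_activation="linear",
                    lr_decay=0.9, seed=0)
        r = _mean_channel_r(X.T, ae.reconstruct_samples(ae.encode_samples(X)).T)
        assert r >= 0.999

    def test_linear_bottleneck_matches_principal_subspace(self, laplace_mixture):
        """A rank-3 linear AE trained to convergence on noiseless 3-source
        mixtures must match the rank-3 orthogonal projection computed
        directly by eigendecomposition of the covariance."""
        _, _, rec = laplace_mixture
        X = rec.data.T - rec.data.T.mean(0)
        ae = fit_ae(X, m=3, epochs=60, batch=250, hidden_activation="linear",
                    lr_decay=0.92, seed=1)
        recon_ae = ae.reconstruct_samples(ae.encode_samples(X))
        w, V = np.linalg.eigh(np.cov(X.T))
        P = V[:, -3:] @ V[:, -3:].T
        recon_proj = X @ P
        r_ae = _mean_channel_r(X.T, recon_ae.T)
        r_proj = _mean_channel_r(X.T, recon_proj.T)
        assert abs(r_ae - r_proj) <= 0.02

    def test_loss_plateaus_within_twenty_epochs(self, pooled_samples):
        X, _ = pooled_samples
        ae = fit_ae(X, m=3, epochs=20, batch=500, seed=0)
        h = ae.loss_history
        assert len(h) == 20
        assert (h[-4] - h[-1]) / h[-4] < 0.01  # relative change over final 3

    def test_loss_nonincreasing_over_five_epoch_windows(self, pooled_samples):
        X, _ = pooled_samples
        ae = fit_ae(X, m=4, epochs=20, batch=500, seed=2)
        h = ae.loss_history
        for k in range(len(h) - 5):
            assert h[k + 5] <= h[k] * 1.05

    def test_overcomplete_latent_warns(self, rng):
        X = rng.standard_normal((600, 4))
        with pytest.warns(UserWarning, match="over-complete"):
            fit_ae(X, m=6, epochs=1, batch=500, seed=0)

    def test_training_is_deterministic(self, rng):
        X = rng.standard_normal((600, 4))
        a = fit_ae(X, m=2, epochs=3, batch=200, seed=5)
        b = fit_ae(X, m=2, epochs=3, batch=200, seed=5)
        np.testing.assert_array_equal(a.W1, b.W1)
        np.testing.assert_array_equal(a.W2, b.W2)


# ---------------------------------------------------------------------------
# Gaussian RBM
# ---------------------------------------------------------------------------


class TestGaussianRBM:
    def test_zero_weights_give_uninformative_hidden_conditional(self, rng):
        model = GRBMModel(W=np.zeros((3, 2)), a=np.zeros(3), b=np.zeros(2),
                          sigma=np.ones(3))
        X = rng.standard_normal((10, 3))
        np.testing.assert_allclose(model.p_hidden(X), 0.5)

    @pytest.mark.parametrize("n_vis,n_hid", [(2, 2), (1, 3), (3, 1)])
    def test_hidden_conditional_matches_exhaustive_enumeration(self, n_vis, n_hid, rng):
        """P(h_j=1|x) from the logistic formula must equal the conditional
        computed by enumerating every hidden state under the Boltzmann
        distribution of the Gaussian-visible energy."""
        rng = np.random.default_rng(3)
        model = GRBMModel(
            W=0.5 * rng.standard_normal((n_vis, n_hid)),
            a=0.3 * rng.standard_normal(n_vis),
            b=0.2 * rng.standard_normal(n_hid),
            sigma=np.ones(n_vis),
        )
        x = rng.standard_normal(n_vis)
        weights = {}
        for h in itertools.product([0, 1], repeat=n_hid):
            weights[h] = np.exp(-model.energy(x, np.array(h, float)))
        Z = sum(weights.values())
        for j in range(n_hid):
            p_enum = sum(w for h, w in weights.items() if h[j] == 1) / Z
            p_formula = model.p_hidden(x[None, :])[0, j]
            assert abs(p_enum - p_formula) < 1e-10

    def test_visible_conditional_is_gaussian_with_stated_mean(self, rng):
        sigma = np.array([1.0, 2.0])
        model = GRBMModel(W=rng.standard_normal((2, 2)), a=np.array([0.1, -0.2]),
                          b=np.zeros(2), sigma=sigma)
        h = np.array([[1.0, 0.0]])
        expected = sigma * (h @ model.W.T)[0] + model.a
        np.testing.assert_allclose(model.visible_mean(h)[0], expected)

    def test_cd1_reduces_reconstruction_error_across_seeds(self, pooled_samples):
        X, _ = pooled_samples
        improved = 0
        for seed in range(10):
            model = fit_grbm(X, m=4, cd_k=1, epochs=10, batch=500, seed=seed)
            if model.recon_errors[9] <= model.recon_errors[0]:
                improved += 1
        assert improved >= 9

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ConfigError, match="sigma"):
            GRBMModel(W=np.zeros((2, 2)), a=np.zeros(2), b=np.zeros(2),
                      sigma=np.array([1.0, 0.0]))

    def test_unrolling_without_training_reproduces_mean_field(self, pooled_samples):
        X, _ = pooled_samples
        grbm = fit_grbm(X, m=3, epochs=3, batch=500, seed=0)
        ae = grbm_unroll_finetune(grbm, X, epochs=0)
        np.testing.assert_allclose(
            ae.reconstruct_samples(ae.encode_samples(X)),
            grbm.mean_field_reconstruction(X),
            atol=1e-12,
        )
        assert ae.W1.shape == (3, X.shape[1])
        assert ae.W2.shape == (X.shape[1], 3)

    def test_finetuning_improves_reconstruction_across_seeds(self, pooled_samples):
        X, _ = pooled_samples
        improved = 0
        for seed in range(10):
            grbm = fit_grbm(X, m=3, epochs=3, batch=500, seed=seed)
            before = np.mean(
                np.sum((X - grbm.mean_field_reconstruction(X)) ** 2, axis=1)
            )
            ae = grbm_unroll_finetune(grbm, X, epochs=10, batch=500, seed=seed)
            after = np.mean(
                np.sum((X - ae.reconstruct_samples(ae.encode_samples(X))) ** 2, axis=1)
            )
            if after < before:
                improved += 1
        assert improved >= 8


# ---------------------------------------------------------------------------
# Variational autoencoder
# ---------------------------------------------------------------------------


class TestVAE:
    def test_kl_vanishes_at_the_prior(self):
        assert gaussian_kl(np.zeros(4), np.zeros(4)) == 0.0

    def test_kl_closed_form_worked_example(self):
        # mu=[1,0], sigma=[1,1]: -0.5 * sum(1 + log s^2 - mu^2 - s^2) = 0.5
        assert abs(gaussian_kl([1.0, 0.0], [0.0, 0.0]) - 0.5) < 1e-12

    def test_kl_is_nonnegative(self, rng):
        for _ in range(50):
            mu = rng.standard_normal(3)
            logvar = rng.uniform(-2, 2, 3)
            assert gaussian_kl(mu, logvar) >= 0

    def test_reparameterized_draw_moments(self):
        rng = np.random.default_rng(0)
        z = reparameterize(np.full(10**5, 2.0), np.full(10**5, 3.0), rng)
        assert abs(z.mean() - 2.0) / 2.0 < 0.01
        assert abs(z.std() - 3.0) / 3.0 < 0.01

    def test_loss_decomposes_into_finite_reconstruction_and_kl(self, pooled_samples):
        X, _ = pooled_samples
        vae = fit_vae(X, m=3, epochs=5, batch=500, seed=0)
        for total, rec, kl in zip(vae.loss_history, vae.recon_history, vae.kl_history):
            assert np.isfinite(total) and np.isfinite(rec) and np.isfinite(kl)
            assert kl >= 0
            assert abs(total - (rec + kl)) < 1e-9

    def test_invalid_monte_carlo_count_rejected(self, rng):
        with pytest.raises(ConfigError, match="L"):
            fit_vae(rng.standard_normal((600, 4)), m=2, epochs=1, L=0)

    def test_encoding_is_deterministic(self, pooled_samples, tiny_dataset):
        X, normed = pooled_samples
        vae = fit_vae(X, m=3, epochs=3, batch=500, seed=1)
        a = encode(vae, normed[0])
        b = encode(vae, normed[0])
        np.testing.assert_array_equal(a.factors, b.factors)


# ---------------------------------------------------------------------------
# Shared encode / reconstruct contract
# ---------------------------------------------------------------------------


class TestEncodeReconstruct:
    def test_identity_encoder_returns_channels(self, small_recording):
        n = small_recording.n_channels
        ae = AEModel(W1=np.eye(n), b1=np.zeros(n), W2=np.eye(n), b2=np.zeros(n),
                     hidden_activation="linear")
        seq = encode(ae, small_recording)
        np.testing.assert_allclose(seq.factors, small_recording.data)

    def test_encode_shape_contract(self, pooled_samples, tiny_dataset):
        X, normed = pooled_samples
        vae = fit_vae(X, m=3, epochs=2, batch=500, seed=0)
        rec = normed[0]
        seq = encode(vae, rec)
        assert seq.factors.shape == (3, rec.n_samples)

    def test_channel_count_mismatch_rejected(self, pooled_samples, rng):
        X, _ = pooled_samples
        vae = fit_vae(X, m=3, epochs=1, batch=500, seed=0)
        bad = Recording("s", None, ["a", "b"], 128.0, rng.standard_normal((2, 64)))
        with pytest.raises(ValidationError, match="channels"):
            encode(vae, bad)

    def test_reconstruct_dimension_mismatch_rejected(self, pooled_samples, tiny_dataset):
        X, normed = pooled_samples
        vae = fit_vae(X, m=3, epochs=1, batch=500, seed=0)
        seq = encode(vae, normed[0])
        seq.factors = seq.factors[:2]
        with pytest.raises(ValidationError, match="m="):
            reconstruct(vae, seq)

    def test_model_checkpoint_roundtrip(self, tmp_path, pooled_samples, tiny_dataset):
        X, normed = pooled_samples
        for fitted in (fit_vae(X, 3, epochs=1, seed=0), fit_pca(X, 3),
                       fit_ae(X, 3, epochs=1, seed=0)):
            save_model(fitted, tmp_path / "ckpt.npz")
            back = load_model(tmp_path / "ckpt.npz")
            a = encode(fitted, normed[0]).factors
            b = encode(back, normed[0]).factors
            np.testing.assert_array_equal(a, b)


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def test_full_rank_reconstruction_is_exact(self, laplace_mixture, tiny_dataset):
        _, _, rec = laplace_mixture
        X = rec.data.T
        pca = fit_pca(X, m=8)
        recon = pca.reconstruct_samples(pca.encode_samples(X))
        assert _mean_channel_r(X.T, recon.T) >= 1 - 1e-10

    def test_explained_variance_matches_eigendecomposition(self, laplace_mixture):
        _, _, rec = laplace_mixture
        X = rec.data.T
        pca = fit_pca(X, m=5)
        w = np.sort(np.linalg.eigvalsh(np.cov(X.T, ddof=1)))[::-1]
        np.testing.assert_allclose(
            pca.explained_variance_ratio, w[:5] / w.sum(), atol=1e-8
        )

    def test_reconstruction_equals_projection_oracle(self, laplace_mixture):
        _, _, rec = laplace_mixture
        X = rec.data.T
        pca = fit_pca(X, m=3)
        mu = X.mean(0)
        w, V = np.linalg.eigh(np.cov(X.T))
        P = V[:, -3:] @ V[:, -3:].T
        oracle = mu + (X - mu) @ P
        recon = pca.reconstruct_samples(pca.encode_samples(X))
        np.testing.assert_allclose(recon, oracle, atol=1e-8)

    def test_components_are_orthonormal(self, laplace_mixture):
        _, _, rec = laplace_mixture
        pca = fit_pca(rec.data.T, m=4)
        np.testing.assert_allclose(pca.unmix @ pca.unmix.T, np.eye(4), atol=1e-8)

    def test_excess_components_rejected(self, rng):
        with pytest.raises(ConfigError):
            fit_pca(rng.standard_normal((100, 3)), m=4)


# ---------------------------------------------------------------------------
# FastICA + counterpart matching
# ---------------------------------------------------------------------------


class TestICA:
    def test_recovers_independent_sources(self, laplace_mixture):
        model, S, rec = laplace_mixture
        ica = fit_ica(rec.data.T, m=3, seed=0, n_runs=1)
        est = ica.encode_samples(rec.data.T).T
        for j in range(3):
            best = max(abs(pearson_r(S[j], est[k])) for k in range(3))
            assert best >= 0.95

    def test_sign_flip_leaves_recovery_unchanged(self, laplace_mixture):
        model, S, rec = laplace_mixture
        ica = fit_ica(rec.data.T, m=3, seed=0, n_runs=1)
        est = ica.encode_samples(rec.data.T).T
        flipped = -est
        for j in range(3):
            a = max(abs(pearson_r(S[j], est[k])) for k in range(3))
            b = max(abs(pearson_r(S[j], flipped[k])) for k in range(3))
            assert abs(a - b) < 1e-12

    def test_same_seed_reproduces_unmixing(self, laplace_mixture):
        _, _, rec = laplace_mixture
        a = fit_ica(rec.data.T, m=3, seed=4, n_runs=2)
        b = fit_ica(rec.data.T, m=3, seed=4, n_runs=2)
        np.testing.assert_array_equal(a.unmix, b.unmix)

    def test_self_match_is_identity(self, small_recording):
        match = ica_match_channels(small_recording, small_recording)
        np.testing.assert_array_equal(match.mapping, np.arange(8))
        np.testing.assert_allclose(match.matched_r, 1.0)

    def test_known_permutation_recovered(self, small_recording):
        perm = np.array([3, 0, 7, 1, 5, 2, 6, 4])
        permuted = small_recording.copy_with(data=small_recording.data[perm])
        match = ica_match_channels(small_recording, permuted)
        # original channel i now lives at the row where perm == i
        expected = np.array([int(np.where(perm == i)[0][0]) for i in range(8)])
        np.testing.assert_array_equal(match.mapping, expected)
        np.testing.assert_allclose(match.matched_r, 1.0)

    def test_noisy_permutation_recovered_in_most_seeds(self, small_recording):
        perm = np.array([3, 0, 7, 1, 5, 2, 6, 4])
        expected = np.array([int(np.where(perm == i)[0][0]) for i in range(8)])
        sig_power = np.mean(small_recording.data**2)
        noise_sd = np.sqrt(sig_power / 10)  # 10 dB SNR
        hits = 0
        for seed in range(10):
            noise = np.random.default_rng(seed).normal(
                0, noise_sd, small_recording.data.shape
            )
            noisy = small_recording.copy_with(data=small_recording.data[perm] + noise)
            match = ica_match_channels(small_recording, noisy)
            if np.array_equal(match.mapping, expected):
                hits += 1
        assert hits >= 9

    def test_shape_mismatch_rejected(self, small_recording):
        other = small_recording.copy_with(data=small_recording.data[:, :100].copy())
        with pytest.raises(ValidationError, match="mismatch"):
            ica_match_channels(small_recording, other)


# ---------------------------------------------------------------------------
# Cross-family invariants
# ---------------------------------------------------------------------------


def test_linear_ae_matches_pca_reconstruction_error(laplace_mixture):
    """With linear activations the converged AE spans the principal subspace,
    so its reconstruction error must be within 2% of PCA's at the same m."""
    _, _, rec = laplace_mixture
    X = rec.data.T - rec.data.T.mean(0)
    pca = fit_pca(X, m=3)
    err_pca = np.mean(
        np.sum((X - pca.reconstruct_samples(pca.encode_samples(X))) ** 2, axis=1)
    )
    ae = fit_ae(X, m=3, epochs=60, batch=250, hidden_activation="linear",
                lr_decay=0.92, seed=3)
    err_ae = np.mean(
        np.sum((X - ae.reconstruct_samples(ae.encode_samples(X))) ** 2, axis=1)
    )
    total = np.mean(np.sum(X**2, axis=1))
    assert (err_ae - err_pca) / total <= 0.02
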