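"""Autoencoder math fixtures, training behavior, latent classifier."""

import numpy as np
import pytest

from laryngofuse.autoencoder import (
    AEHyperparams,
    AEParams,
    AutoencoderClassifier,
    decode,
    encode,
    reconstruction_loss,
    train_autoencoder,
)


def _scalar_params(we, be, wd, bd, act="relu", out_act="relu"):
    return AEParams(
        W_e=np.array([[we]]), b_e=np.array([be]),
        W_d=np.array([[wd]]), b_d=np.array([bd]),
        activation=act, output_activation=out_act,
    )


class TestEncodeDecode:
    def test_zero_map(self):
        p = _scalar_params(0.0, 0.0, 0.0, 0.0)
        assert encode(np.array([5.0]), p) == 0.0
        assert decode(np.array([5.0]), p) == 0.0

    def test_hand_evaluated_chain(self):
        # encoder: relu(2*3 + 1) = 7; decoder: relu(1*7 + 0) = 7
        p = _scalar_params(2.0, 1.0, 1.0, 0.0)
        z = encode(np.array([3.0]), p)
        np.testing.assert_allclose(z, [7.0])
        np.testing.assert_allclose(decode(z, p), [7.0])

    def test_sigmoid_range(self):
        rng = np.random.default_rng(0)
        p = AEParams(
            W_e=rng.normal(size=(3, 6)), b_e=rng.normal(size=3),
            W_d=rng.normal(size=(6, 3)), b_d=rng.normal(size=6),
            activation="sigmoid",
        )
        z = encode(rng.normal(size=(10, 6)), p)
        assert np.all((z > 0) & (z < 1))

    def test_shape_mismatches_raise(self):
        p = _scalar_params(1.0, 0.0, 1.0, 0.0)
        with pytest.raises(ValueError, match="input length"):
            encode(np.zeros(3), p)
        with pytest.raises(ValueError, match="latent length"):
            decode(np.zeros(3), p)
        with pytest.raises(ValueError, match="inconsistent shapes"):
            AEParams(W_e=np.zeros((2, 4)), b_e=np.zeros(3),
                     W_d=np.zeros((4, 2)), b_d=np.zeros(4))


class TestReconstructionLoss:
    def test_zero_iff_equal(self):
        x = np.array([1.0, 2.0, 3.0])
        assert reconstruction_loss(x, x) == 0.0
        assert reconstruction_loss(x, x + 1e-3) > 0.0

    def test_hand_fixture(self):
        assert reconstruction_loss([1.0, 2.0], [0.0, 0.0]) == pytest.approx(2.5)

    def test_quadratic_homogeneity(self):
        x = np.array([1.0, -2.0, 0.5])
        xh = np.zeros(3)
        assert reconstruction_loss(2 * x, xh) == pytest.approx(4 * reconstruction_loss(x, xh))

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="shape mismatch"):
            reconstruction_loss([1.0], [1.0, 2.0])


class TestTraining:
    def linear_manifold(self, seed=0, n=200, d=20, k=3):
        rng = np.random.default_rng(seed)
        return rng.normal(size=(n, k)) @ rng.normal(size=(k, d))

    def test_linear_manifold_reaches_under_ten_percent(self):
        X = self.linear_manifold()
        h = AEHyperparams(latent_dim=3, learning_rate=1e-2, batch_size=32, epochs=200)
        _, hist = train_autoencoder(X, h, seed=0)
        assert hist[-1] < 0.1 * hist[0]

    def test_manifold_residual_near_linear_projection_oracle(self):
        """The trained bottleneck should approach the optimum of a full-rank
        linear projection (exactly 0 for rank-3 data and a 3-d latent)."""
        X = self.linear_manifold(seed=1)
        h = AEHyperparams(latent_dim=3, learning_rate=1e-2, batch_size=32, epochs=300)
        _, hist = train_autoencoder(X, h, seed=1, activation="linear")
        # PCA oracle: best rank-3 linear reconstruction error
        Xc = X - X.mean(axis=0)
        svals = np.linalg.svd(Xc, compute_uv=False)
        oracle = (svals[3:] ** 2).sum() / X.size  # 0 up to rounding
        assert hist[-1] < oracle + 0.05 * hist[0]

    def test_full_latent_linear_identity_recoverable(self):
        X = self.linear_manifold(seed=2, d=10, k=10)
        h = AEHyperparams(latent_dim=10, learning_rate=1e-2, batch_size=32, epochs=300)
        _, hist = train_autoencoder(X, h, seed=2, activation="linear")
        assert hist[-1] < 0.02 * hist[0]

    def test_history_deterministic_in_seed(self):
        X = self.linear_manifold(seed=3)
        h = AEHyperparams(latent_dim=3, epochs=20)
        _, h1 = train_autoencoder(X, h, seed=5)
        _, h2 = train_autoencoder(X, h, seed=5)
        assert h1 == h2

    def test_median_improvement_over_seeds(self):
        X = self.linear_manifold(seed=4)
        h = AEHyperparams(latent_dim=3, epochs=30)
        inits, finals = [], []
        for seed in range(5):
            _, hist = train_autoencoder(X, h, seed=seed)
            inits.append(hist[0])
            finals.append(hist[-1])
        assert np.median(finals) < np.median(inits)

    def test_invalid_hyperparams(self):
        with pytest.raises(ValueError, match="learning_rate"):
            AEHyperparams(learning_rate=0.0).validate()
        with pytest.raises(ValueError, match="dropout"):
            AEHyperparams(dropout=1.0).validate()


class TestClassifier:
    def blobs(self, seed=0, n_per=40, d=16):
        rng = np.random.default_rng(seed)
        centers = rng.normal(size=(4, d)) * 10  # spacing far above sigma=0.5
        X = np.concatenate([c + 0.5 * rng.normal(size=(n_per, d)) for c in centers])
        y = np.repeat(np.arange(4), n_per)
        order = rng.permutation(len(y))
        return X[order], y[order]

    def test_separable_blobs_held_out_accuracy(self):
        X, y = self.blobs()
        clf = AutoencoderClassifier(AEHyperparams(latent_dim=8, learning_rate=3e-3, epochs=60))
        clf.fit(X[:120], y[:120], seed=0)
        assert (clf.predict(X[120:]) == y[120:]).mean() > 0.9

    def test_posteriors_normalized(self):
        X, y = self.blobs(seed=1)
        clf = AutoencoderClassifier(AEHyperparams(latent_dim=4, epochs=20)).fit(X, y, seed=0)
        post = clf.predict_proba(X[:10])
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-6)
        assert post.shape == (10, 4)
        single = clf.classify(X[0])
        np.testing.assert_allclose(single, post[0])

    def test_checkpoint_callback_fires_at_requested_epochs(self):
        X, y = self.blobs(seed=4)
        seen = []
        clf = AutoencoderClassifier(AEHyperparams(latent_dim=4, epochs=12))
        clf.fit(X, y, seed=0, checkpoints=(4, 8),
                checkpoint_callback=lambda e, m: seen.append((e, m.predict(X[:1]).shape)))
        assert [e for e, _ in seen] == [4, 8]

    def test_untrained_model_rejected(self):
        with pytest.raises(RuntimeError, match="not been trained"):
            AutoencoderClassifier().predict(np.zeros((1, 8)))

    def test_latent_must_compress(self):
        X, y = self.blobs(seed=2, d=4)
        with pytest.raises(ValueError, match="latent_dim"):
            AutoencoderClassifier(AEHyperparams(latent_dim=8, epochs=5)).fit(X, y)

    def test_consistent_feature_permutation_invariance(self):
        """Permuting input coordinates together with the encoder columns is a
        pure relabeling: the latent code and posteriors are unchanged."""
        rng = np.random.default_rng(3)
        p = AEParams(W_e=rng.normal(size=(3, 8)), b_e=rng.normal(size=3),
                     W_d=rng.normal(size=(8, 3)), b_d=rng.normal(size=8))
        x = rng.normal(size=8)
        perm = rng.permutation(8)
        p_perm = AEParams(W_e=p.W_e[:, perm], b_e=p.b_e, W_d=p.W_d[perm], b_d=p.b_d[perm])
        np.testing.assert_allclose(encode(x[perm], p_perm), encode(x, p), atol=1e-12)
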