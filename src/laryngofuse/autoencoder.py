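"""Autoencoder over fused features plus a latent-space softmax classifier.

The autoencoder is a single affine + activation per side: the encoder maps
the input to a lower-dimensional latent code ``Z = sigma(W_e X + b_e)`` and
the decoder reconstructs ``X_hat = sigma(W_d Z + b_d)``; training minimizes
the mean squared reconstruction error ``L = (1/n) sum (X_i - X_hat_i)^2``.

Classification attaches a softmax head to the latent code and proceeds in
two phases: unsupervised reconstruction pretraining of the autoencoder, then
supervised fine-tuning of encoder + head with cross-entropy.  Features are
standardized (train-split mean/std) before the autoencoder, and the decoder
output activation defaults to linear so standardized (negative) values are
reachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .labels import N_CLASSES
from .nn.train import Adam, softmax, softmax_cross_entropy

_ACTIVATIONS = ("relu", "sigmoid", "linear")


def _act(name: str, x: np.ndarray) -> np.ndarray:
    if name == "relu":
        return np.maximum(x, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(x, -60, 60)))
    return x


def _act_grad(name: str, pre: np.ndarray, post: np.ndarray) -> np.ndarray:
    if name == "relu":
        return (pre > 0).astype(pre.dtype)
    if name == "sigmoid":
        return post * (1.0 - post)
    return np.ones_like(pre)


@dataclass
class AEParams:
    """Encoder/decoder weights with shape invariants enforced."""

    W_e: np.ndarray  # (latent_dim, input_dim)
    b_e: np.ndarray  # (latent_dim,)
    W_d: np.ndarray  # (input_dim, latent_dim)
    b_d: np.ndarray  # (input_dim,)
    activation: str = "relu"
    output_activation: str = "linear"

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS or self.output_activation not in _ACTIVATIONS:
            raise ValueError(f"activation must be one of {_ACTIVATIONS}")
        latent, inp = self.W_e.shape
        if self.b_e.shape != (latent,) or self.W_d.shape != (inp, latent) or self.b_d.shape != (inp,):
            raise ValueError(
                f"inconsistent shapes: W_e {self.W_e.shape}, b_e {self.b_e.shape}, "
                f"W_d {self.W_d.shape}, b_d {self.b_d.shape}"
            )

    @property
    def latent_dim(self) -> int:
        return self.W_e.shape[0]

    @property
    def input_dim(self) -> int:
        return self.W_e.shape[1]


@dataclass
class AEHyperparams:
    """Hyperparameters of the autoencoder classifier; the osprey optimizer
    searches over these."""

    latent_dim: int = 32
    learning_rate: float = 1e-3
    batch_size: int = 32
    dropout: float = 0.0
    epochs: int = 100

    def validate(self) -> None:
        if self.latent_dim < 1 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("latent_dim, batch_size and epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ValueError(f"learning_rate must be positive, got {self.learning_rate}")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0, 1), got {self.dropout}")


def encode(X: np.ndarray, p: AEParams) -> np.ndarray:
    """Latent code ``Z = sigma(W_e X + b_e)``; accepts a vector or a batch."""
    X = np.asarray(X, dtype=float)
    if X.shape[-1] != p.input_dim:
        raise ValueError(f"input length {X.shape[-1]} != input_dim {p.input_dim}")
    return _act(p.activation, X @ p.W_e.T + p.b_e)


def decode(Z: np.ndarray, p: AEParams) -> np.ndarray:
    """Reconstruction ``X_hat = sigma(W_d Z + b_d)``."""
    Z = np.asarray(Z, dtype=float)
    if Z.shape[-1] != p.latent_dim:
        raise ValueError(f"latent length {Z.shape[-1]} != latent_dim {p.latent_dim}")
    return _act(p.output_activation, Z @ p.W_d.T + p.b_d)


def reconstruction_loss(X: np.ndarray, X_hat: np.ndarray) -> float:
    """Mean squared reconstruction error over all components."""
    X = np.asarray(X, dtype=float)
    X_hat = np.asarray(X_hat, dtype=float)
    if X.shape != X_hat.shape:
        raise ValueError(f"shape mismatch: {X.shape} vs {X_hat.shape}")
    if X.size == 0:
        raise ValueError("reconstruction loss undefined for empty input")
    return float(np.mean((X - X_hat) ** 2))


def _init_params(input_dim: int, latent_dim: int, rng: np.random.Generator,
                 activation: str, output_activation: str) -> AEParams:
    se = np.sqrt(2.0 / input_dim)
    sd = np.sqrt(2.0 / latent_dim)
    return AEParams(
        W_e=rng.standard_normal((latent_dim, input_dim)) * se,
        b_e=np.zeros(latent_dim),
        W_d=rng.standard_normal((input_dim, latent_dim)) * sd,
        b_d=np.zeros(input_dim),
        activation=activation,
        output_activation=output_activation,
    )


def train_autoencoder(
    features: np.ndarray,
    h: AEHyperparams,
    seed: int = 0,
    activation: str = "relu",
    output_activation: str = "linear",
) -> tuple[AEParams, list[float]]:
    """Minimize the reconstruction error with Adam; returns params + history.

    The history holds the full-dataset loss at initialization followed by
    the loss after each epoch, so ``history[-1] <= history[0]`` certifies
    improvement.  Deterministic in ``seed``.
    """
    h.validate()
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError(f"features must be 2-D (n, input_dim), got shape {X.shape}")
    rng = np.random.default_rng(seed)
    p = _init_params(X.shape[1], h.latent_dim, rng, activation, output_activation)
    params = [p.W_e, p.b_e, p.W_d, p.b_d]
    grads = [np.zeros_like(a) for a in params]
    opt = Adam(params, grads, lr=h.learning_rate)
    n = X.shape[0]
    best = None
    history = [reconstruction_loss(X, decode(encode(X, p), p))]
    for _ in range(h.epochs):
        order = rng.permutation(n)
        for start in range(0, n, h.batch_size):
            xb = X[order[start : start + h.batch_size]]
            pre_z = xb @ p.W_e.T + p.b_e
            z = _act(p.activation, pre_z)
            pre_x = z @ p.W_d.T + p.b_d
            xh = _act(p.output_activation, pre_x)
            m = xb.size
            gxh = 2.0 * (xh - xb) / m
            gpre_x = gxh * _act_grad(p.output_activation, pre_x, xh)
            grads[2][...] = gpre_x.T @ z
            grads[3][...] = gpre_x.sum(axis=0)
            gz = gpre_x @ p.W_d
            gpre_z = gz * _act_grad(p.activation, pre_z, z)
            grads[0][...] = gpre_z.T @ xb
            grads[1][...] = gpre_z.sum(axis=0)
            opt.step()
        loss = reconstruction_loss(X, decode(encode(X, p), p))
        if not np.isfinite(loss):
            raise FloatingPointError("autoencoder training diverged: non-finite loss")
        history.append(loss)
        if best is None or loss < best[0]:
            best = (loss, [a.copy() for a in params])
    # keep the best epoch's weights (plain SGD-style loops can end on an uptick)
    if best is not None:
        for a, saved in zip(params, best[1]):
            a[...] = saved
    return p, history


class AutoencoderClassifier:
    """Two-phase autoencoder classifier over fused (or any) feature vectors.

    Phase 1 pretrains the autoencoder on reconstruction; phase 2 fine-tunes
    the encoder and a latent softmax head with cross-entropy.  Standardizes
    features with train-split statistics.
    """

    def __init__(self, h: AEHyperparams | None = None, n_classes: int = N_CLASSES) -> None:
        self.h = h or AEHyperparams()
        self.n_classes = n_classes
        self.params: AEParams | None = None
        self.W_c: np.ndarray | None = None
        self.b_c: np.ndarray | None = None
        self._mean: np.ndarray | None = None
        self._std: np.ndarray | None = None
        self.recon_history: list[float] = []
        self.finetune_history: list[float] = []

    def _standardize(self, X: np.ndarray) -> np.ndarray:
        return (X - self._mean) / self._std

    def fit(self, X: np.ndarray, y: np.ndarray, *, seed: int = 0,
            recon_epochs: int | None = None, finetune_epochs: int | None = None,
            checkpoint_callback=None, checkpoints: tuple[int, ...] = ()) -> "AutoencoderClassifier":
        self.h.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError(f"feature/label shape mismatch: {X.shape} vs {y.shape}")
        if self.h.latent_dim >= X.shape[1]:
            raise ValueError(
                f"latent_dim {self.h.latent_dim} must be below input_dim {X.shape[1]}"
            )
        self._mean = X.mean(axis=0)
        self._std = np.maximum(X.std(axis=0), 1e-8)
        Xs = self._standardize(X)

        recon_epochs = recon_epochs if recon_epochs is not None else self.h.epochs
        finetune_epochs = finetune_epochs if finetune_epochs is not None else self.h.epochs
        self.params, self.recon_history = train_autoencoder(
            Xs, AEHyperparams(self.h.latent_dim, self.h.learning_rate, self.h.batch_size,
                              self.h.dropout, recon_epochs),
            seed=seed,
        )

        p = self.params
        rng = np.random.default_rng([seed, 1])
        self.W_c = rng.standard_normal((p.latent_dim, self.n_classes)) * np.sqrt(2.0 / p.latent_dim)
        self.b_c = np.zeros(self.n_classes)
        params = [p.W_e, p.b_e, self.W_c, self.b_c]
        grads = [np.zeros_like(a) for a in params]
        opt = Adam(params, grads, lr=self.h.learning_rate)
        n = Xs.shape[0]
        self.finetune_history = []
        for _ in range(finetune_epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.h.batch_size):
                idx = order[start : start + self.h.batch_size]
                xb, yb = Xs[idx], y[idx]
                pre_z = xb @ p.W_e.T + p.b_e
                z = _act(p.activation, pre_z)
                if self.h.dropout > 0:
                    mask = (rng.random(z.shape) >= self.h.dropout) / (1.0 - self.h.dropout)
                    zd = z * mask
                else:
                    mask = None
                    zd = z
                logits = zd @ self.W_c + self.b_c
                loss, gl = softmax_cross_entropy(logits, yb)
                if not np.isfinite(loss):
                    raise FloatingPointError("fine-tuning diverged: non-finite loss")
                grads[2][...] = zd.T @ gl
                grads[3][...] = gl.sum(axis=0)
                gz = gl @ self.W_c.T
                if mask is not None:
                    gz = gz * mask
                gpre = gz * _act_grad(p.activation, pre_z, z)
                grads[0][...] = gpre.T @ xb
                grads[1][...] = gpre.sum(axis=0)
                opt.step()
                losses.append(loss)
            self.finetune_history.append(float(np.mean(losses)))
            epoch_no = len(self.finetune_history)
            if checkpoint_callback is not None and epoch_no in checkpoints:
                checkpoint_callback(epoch_no, self)
        return self

    def _check_trained(self) -> None:
        if self.params is None or self.W_c is None:
            raise RuntimeError("classifier has not been trained; call fit() first")

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Class posteriors over the four labels (rows sum to 1)."""
        self._check_trained()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        z = encode(self._standardize(X), self.params)
        return softmax(z @ self.W_c + self.b_c)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return np.argmax(self.predict_proba(X), axis=-1)

    def classify(self, x: np.ndarray) -> np.ndarray:
        """Posterior vector for a single feature vector."""
        return self.predict_proba(np.atleast_2d(x))[0]

    def save(self, path) -> None:
        self._check_trained()
        import json
        from pathlib import Path

        path = Path(path)
        np.savez(path.with_suffix(".npz"),
                 W_e=self.params.W_e, b_e=self.params.b_e,
                 W_d=self.params.W_d, b_d=self.params.b_d,
                 W_c=self.W_c, b_c=self.b_c, mean=self._mean, std=self._std)
        meta = {
            "latent_dim": self.params.latent_dim,
            "input_dim": self.params.input_dim,
            "n_classes": self.n_classes,
            "hyperparams": vars(self.h),
            "activation": self.params.activation,
            "output_activation": self.params.output_activation,
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
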