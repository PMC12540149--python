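"""Adam optimizer and cross-entropy training loop for the numpy layers."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, params: list[np.ndarray], grads: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8) -> None:
        if lr <= 0:
            raise ValueError(f"learning rate must be positive, got {lr}")
        self.params, self.grads = params, grads
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, self.grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1c) / (np.sqrt(v / b2c) + self.eps)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: np.ndarray, y: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean categorical cross-entropy and its gradient w.r.t. the logits.

    ``y`` holds integer class indices.  The combined softmax + cross-entropy
    gradient is ``(p - onehot(y)) / batch``.
    """
    p = softmax(logits)
    n = logits.shape[0]
    loss = float(-np.mean(np.log(np.maximum(p[np.arange(n), y], 1e-12))))
    grad = p.copy()
    grad[np.arange(n), y] -= 1.0
    return loss, (grad / n).astype(np.float32)


def fit_classifier(model, head, images: np.ndarray, labels: np.ndarray, *,
                   epochs: int, batch_size: int, lr: float, seed: int) -> list[float]:
    """Train body+head with Adam on categorical cross-entropy.

    ``model`` maps images to embeddings, ``head`` maps embeddings to logits.
    Returns the per-epoch mean training loss.  Deterministic in ``seed``
    (shuffling and dropout masks come from one generator).
    """
    rng = np.random.default_rng(seed)
    params = model.params + head.params
    grads = model.grads + head.grads
    opt = Adam(params, grads, lr=lr)
    n = images.shape[0]
    history: list[float] = []
    for _ in range(epochs):
        order = rng.permutation(n)
        losses = []
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            emb = model.forward(images[idx], train=True, rng=rng)
            logits = head.forward(emb, train=True, rng=rng)
            loss, gl = softmax_cross_entropy(logits, labels[idx])
            if not np.isfinite(loss):
                raise FloatingPointError("training diverged: non-finite loss")
            model.backward(head.backward(gl))
            opt.step()
            losses.append(loss)
        history.append(float(np.mean(losses)))
    return history
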