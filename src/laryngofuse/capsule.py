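"""Capsule-network primitives: squashing, routing softmax, dynamic routing.

A capsule's output is a vector whose norm encodes the probability that a
feature is present and whose direction encodes its pose.  The squashing
nonlinearity maps an aggregated input ``s`` to the same direction with norm
``|s|^2 / (1 + |s|^2) < 1``.  Dynamic routing iteratively reallocates
coupling coefficients between child and parent capsules toward parents whose
outputs agree with the child's predictions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def squash(s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Squashing nonlinearity ``(|s|^2 / (1 + |s|^2)) * s / |s|``.

    Applied along ``axis``; the zero vector maps to the zero vector (the
    continuous limit).  Output norm is ``n^2/(1+n^2)``, strictly below 1 and
    strictly increasing in the input norm ``n``.
    """
    s = np.asarray(s, dtype=float)
    if not np.all(np.isfinite(s)):
        raise ValueError("squash input must be finite")
    sq_norm = np.sum(s * s, axis=axis, keepdims=True)
    norm = np.sqrt(sq_norm)
    # s * n / (1 + n^2) == (n^2/(1+n^2)) * s/n, safe at n = 0
    return s * (norm / (1.0 + sq_norm + np.finfo(float).tiny * (norm == 0)))


def squash_jacobian_apply(grad_v: np.ndarray, s: np.ndarray, axis: int = -1) -> np.ndarray:
    """Pull an upstream gradient on ``v = squash(s)`` back to ``s``.

    With ``h(n) = n / (1 + n^2)`` and ``v = h(n) s``,
    ``dv/ds = h I + (h'(n)/n) s s^T``; the Jacobian vanishes at ``s = 0``.
    """
    s = np.asarray(s, dtype=float)
    sq = np.sum(s * s, axis=axis, keepdims=True)
    n = np.sqrt(sq)
    h = n / (1.0 + sq)
    hp = (1.0 - sq) / (1.0 + sq) ** 2  # h'(n)
    dot = np.sum(s * grad_v, axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        coef = np.where(n > 0, hp / np.maximum(n, np.finfo(float).tiny), 0.0)
    return h * grad_v + coef * dot * s


def routing_softmax(b: np.ndarray, axis: int = -1) -> np.ndarray:
    """Softmax of routing logits over the parent-capsule axis.

    Numerically stabilized by a max shift, so the result is invariant to
    adding a constant to all logits of one child.
    """
    b = np.asarray(b, dtype=float)
    if not np.all(np.isfinite(b)):
        raise ValueError("routing logits must be finite")
    shifted = b - np.max(b, axis=axis, keepdims=True)
    e = np.exp(shifted)
    return e / np.sum(e, axis=axis, keepdims=True)


@dataclass
class RoutingState:
    """State of the dynamic-routing recursion.

    ``b``: logits per (child i, parent j); ``c``: coupling coefficients used
    in the final iteration (rows over parents sum to 1); ``s``: aggregated
    parent inputs; ``v``: squashed parent outputs with ``|v_j| < 1``.
    """

    b: np.ndarray
    c: np.ndarray
    s: np.ndarray
    v: np.ndarray


def dynamic_routing(U: np.ndarray, iterations: int = 3) -> RoutingState:
    """Routing-by-agreement over prediction vectors.

    ``U`` has shape ``(..., n_children, n_parents, dim)``.  Each iteration
    computes couplings ``c = softmax(b)`` over parents, aggregates
    ``s_j = sum_i c_ij U_ij``, squashes ``v_j = squash(s_j)`` and reinforces
    logits by the agreement ``b_ij += U_ij . v_j``.  Returns the final state.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim < 3:
        raise ValueError(f"U must have shape (..., children, parents, dim), got {U.shape}")
    if iterations < 1:
        raise ValueError(f"routing iterations must be >= 1, got {iterations}")
    b = np.zeros(U.shape[:-1], dtype=float)
    for _ in range(iterations):
        c = routing_softmax(b, axis=-1)
        s = np.sum(c[..., None] * U, axis=-3)
        v = squash(s, axis=-1)
        b = b + np.sum(U * v[..., None, :, :], axis=-1)
    return RoutingState(b=b, c=c, s=s, v=v)


@dataclass
class CapsuleLayerParams:
    """Configuration of a fully connected routed capsule layer."""

    num_input_capsules: int
    input_dim: int = 8
    num_output_capsules: int = 16
    output_dim: int = 8
    routing_iterations: int = 3
    W: np.ndarray | None = field(default=None, repr=False)

    def validate(self) -> None:
        if min(self.num_input_capsules, self.input_dim, self.num_output_capsules, self.output_dim) < 1:
            raise ValueError("capsule counts and dimensions must be >= 1")
        if self.routing_iterations < 1:
            raise ValueError(f"routing_iterations must be >= 1, got {self.routing_iterations}")
        expected = (self.num_input_capsules, self.num_output_capsules, self.input_dim, self.output_dim)
        if self.W is not None and self.W.shape != expected:
            raise ValueError(f"W shape {self.W.shape} inconsistent with capsule config {expected}")
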