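"""Layer implementations with explicit forward/backward passes.

All activations are float32, images are NHWC.  Convolutions are stride-1
with 'same' zero padding and use an im2col + matmul formulation; the
backward pass scatters column gradients back with a small loop over kernel
offsets (k^2 iterations, fully vectorized over the batch).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from ..capsule import dynamic_routing, squash, squash_jacobian_apply


class Layer:
    """Base layer: trainable params/grads plus forward/backward."""

    def __init__(self) -> None:
        self.params: list[np.ndarray] = []
        self.grads: list[np.ndarray] = []

    def forward(self, x: np.ndarray, *, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, g: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, in_dim: int, units: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.in_dim, self.units = in_dim, units
        self.W = rng.standard_normal((in_dim, units), dtype=np.float32)
        self.W *= np.float32(np.sqrt(2.0 / in_dim))
        self.b = np.zeros(units, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.gW, self.gb]

    def forward(self, x, *, train=False, rng=None):
        self._x = x
        return x @ self.W + self.b

    def backward(self, g):
        self.gW[...] = self._x.T @ g
        self.gb[...] = g.sum(axis=0)
        return g @ self.W.T


class Conv2D(Layer):
    """Stride-1 'same' convolution, NHWC."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int, rng: np.random.Generator) -> None:
        super().__init__()
        if kernel % 2 == 0:
            raise ValueError("kernel must be odd for 'same' padding")
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        fan_in = kernel * kernel * in_channels
        self.W = rng.standard_normal((fan_in, out_channels), dtype=np.float32)
        self.W *= np.float32(np.sqrt(2.0 / fan_in))
        self.b = np.zeros(out_channels, dtype=np.float32)
        self.gW = np.zeros_like(self.W)
        self.gb = np.zeros_like(self.b)
        self.params = [self.W, self.b]
        self.grads = [self.gW, self.gb]

    def forward(self, x, *, train=False, rng=None):
        k = self.kernel
        p = k // 2
        B, H, Wd, C = x.shape
        xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0)))
        win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (B, H, W, C, k, k)
        cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(B * H * Wd, k * k * C)
        self._cols = cols
        self._shape = (B, H, Wd, C)
        out = cols @ self.W + self.b
        return out.reshape(B, H, Wd, self.out_channels)

    def backward(self, g):
        B, H, Wd, C = self._shape
        k = self.kernel
        p = k // 2
        g2 = g.reshape(B * H * Wd, self.out_channels)
        self.gW[...] = self._cols.T @ g2
        self.gb[...] = g2.sum(axis=0)
        gcols = (g2 @ self.W.T).reshape(B, H, Wd, k, k, C)
        dxp = np.zeros((B, H + 2 * p, Wd + 2 * p, C), dtype=gcols.dtype)
        for a in range(k):
            for b in range(k):
                dxp[:, a : a + H, b : b + Wd, :] += gcols[:, :, :, a, b, :]
        return dxp[:, p : p + H, p : p + Wd, :]


class MaxPool2(Layer):
    """2x2 max pooling with stride 2; gradient is split evenly among ties."""

    def forward(self, x, *, train=False, rng=None):
        B, H, Wd, C = x.shape
        if H % 2 or Wd % 2:
            raise ValueError(f"spatial dims must be even for 2x2 pooling, got {(H, Wd)}")
        xr = x.reshape(B, H // 2, 2, Wd // 2, 2, C)
        out = xr.max(axis=(2, 4))
        mask = xr == out[:, :, None, :, None, :]
        self._mask = (mask / np.maximum(mask.sum(axis=(2, 4), keepdims=True), 1)).astype(x.dtype)
        self._shape = x.shape
        return out

    def backward(self, g):
        B, H, Wd, C = self._shape
        gx = self._mask * g[:, :, None, :, None, :]
        return gx.reshape(B, H, Wd, C)


class ReLU(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._mask = x > 0
        return x * self._mask

    def backward(self, g):
        return g * self._mask


class Dropout(Layer):
    def __init__(self, rate: float) -> None:
        super().__init__()
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate

    def forward(self, x, *, train=False, rng=None):
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("training-mode dropout requires an RNG")
        self._mask = (rng.random(x.shape) >= self.rate).astype(x.dtype) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, g):
        return g if self._mask is None else g * self._mask


class Flatten(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, g):
        return g.reshape(self._shape)


class GlobalAvgPool(Layer):
    def forward(self, x, *, train=False, rng=None):
        self._shape = x.shape
        return x.mean(axis=(1, 2))

    def backward(self, g):
        B, H, Wd, C = self._shape
        return np.broadcast_to(g[:, None, None, :] / (H * Wd), self._shape).astype(g.dtype)


class FireModule(Layer):
    """SqueezeNet fire block: 1x1 squeeze -> parallel 1x1 and 3x3 expands.

    Output channels = expand1x1 + expand3x3 (channel concatenation).
    """

    def __init__(self, in_channels: int, squeeze: int, expand1: int, expand3: int, rng: np.random.Generator) -> None:
        super().__init__()
        self.squeeze_conv = Conv2D(in_channels, squeeze, 1, rng)
        self.expand1_conv = Conv2D(squeeze, expand1, 1, rng)
        self.expand3_conv = Conv2D(squeeze, expand3, 3, rng)
        self.out_channels = expand1 + expand3
        self._subs = [self.squeeze_conv, self.expand1_conv, self.expand3_conv]
        self.params = [p for l in self._subs for p in l.params]
        self.grads = [g for l in self._subs for g in l.grads]

    def forward(self, x, *, train=False, rng=None):
        z = self.squeeze_conv.forward(x)
        self._zmask = z > 0
        z = z * self._zmask
        a = self.expand1_conv.forward(z)
        b = self.expand3_conv.forward(z)
        out = np.concatenate([a, b], axis=-1)
        self._omask = out > 0
        self._split = a.shape[-1]
        return out * self._omask

    def backward(self, g):
        g = g * self._omask
        ga, gb = g[..., : self._split], g[..., self._split :]
        gz = self.expand1_conv.backward(np.ascontiguousarray(ga))
        gz = gz + self.expand3_conv.backward(np.ascontiguousarray(gb))
        gz = gz * self._zmask
        return self.squeeze_conv.backward(gz)


class CapsuleHead(Layer):
    """Primary capsules + one routed capsule layer over a conv feature map.

    The incoming NHWC map is reshaped into ``num_input_capsules`` vectors of
    ``input_dim`` components, squashed, transformed by the per-pair weight
    tensor ``W`` into prediction vectors, and routed for a fixed number of
    agreement iterations.  The output is the concatenation of the parent
    capsule vectors (length ``num_output_capsules * output_dim``).

    Backpropagation treats the final coupling coefficients as constants
    (gradients flow through the transform and both squashes, not through the
    routing recursion itself).
    """

    def __init__(self, caps, rng: np.random.Generator) -> None:
        super().__init__()
        caps.validate()
        self.caps = caps
        if caps.W is None:
            caps.W = rng.standard_normal(
                (caps.num_input_capsules, caps.num_output_capsules, caps.input_dim, caps.output_dim),
                dtype=np.float32,
            )
            caps.W *= np.float32(0.1)
        self.W = caps.W.astype(np.float32)
        self.gW = np.zeros_like(self.W)
        self.params = [self.W]
        self.grads = [self.gW]
        self.out_dim = caps.num_output_capsules * caps.output_dim

    def forward(self, x, *, train=False, rng=None):
        B = x.shape[0]
        c = self.caps
        expected = c.num_input_capsules * c.input_dim
        if int(np.prod(x.shape[1:])) != expected:
            raise ValueError(
                f"feature map of size {tuple(x.shape[1:])} cannot form "
                f"{c.num_input_capsules} capsules of dim {c.input_dim}"
            )
        self._xshape = x.shape
        u_raw = x.reshape(B, c.num_input_capsules, c.input_dim).astype(np.float64)
        u = squash(u_raw, axis=-1)
        U = np.einsum("bnd,node->bnoe", u, self.W.astype(np.float64), optimize=True)
        state = dynamic_routing(U, iterations=c.routing_iterations)
        self._u_raw, self._u, self._U, self._state = u_raw, u, U, state
        self._in_dtype = x.dtype
        return state.v.reshape(B, self.out_dim).astype(x.dtype)

    def backward(self, g):
        B = g.shape[0]
        c = self.caps
        gv = g.reshape(B, c.num_output_capsules, c.output_dim).astype(np.float64)
        gs = squash_jacobian_apply(gv, self._state.s, axis=-1)
        # s_j = sum_i c_ij U_ij with c treated as constant
        gU = self._state.c[..., None] * gs[:, None, :, :]
        self.gW[...] = np.einsum("bnd,bnoe->node", self._u, gU, optimize=True)
        gu = np.einsum("node,bnoe->bnd", self.W.astype(np.float64), gU, optimize=True)
        gx = squash_jacobian_apply(gu, self._u_raw, axis=-1)
        return gx.reshape(self._xshape).astype(self._in_dtype)


class Sequential:
    """Ordered layer container with whole-network forward/backward."""

    def __init__(self, layers: list[Layer]) -> None:
        self.layers = layers

    def forward(self, x: np.ndarray, *, train: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train, rng=rng)
        return x

    def backward(self, g: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g

    @property
    def params(self) -> list[np.ndarray]:
        return [p for l in self.layers for p in l.params]

    @property
    def grads(self) -> list[np.ndarray]:
        return [g for l in self.layers for g in l.grads]

    def find(self, cls: type) -> list[Layer]:
        out = []
        for l in self.layers:
            if isinstance(l, cls):
                out.append(l)
            for sub in getattr(l, "_subs", []):
                if isinstance(sub, cls):
                    out.append(sub)
        return out
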