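"""Minimal NumPy neural-network layers with manual backpropagation.

Only what the sequence-to-sequence WGAN needs: dense, 1-D convolution,
1-D transposed convolution (with symmetric output cropping so stride-1 stacks
preserve length), leaky-ReLU, reshape, and an RMSprop optimizer.  Everything
is deterministic given the initialisation RNG, and all parameters live in
plain ``{name: ndarray}`` dicts so weight clipping and checkpointing are
trivial.

Array convention: convolutional tensors are ``(batch, channels, length)``.
"""

from __future__ import annotations

import numpy as np

_INIT_SCALE = 0.02  # DCGAN-style N(0, 0.02) weight init


class Layer:
    """Base layer: ``forward(x)`` caches what ``backward(dy)`` needs."""

    def params(self) -> dict[str, np.ndarray]:
        return {}

    def grads(self) -> dict[str, np.ndarray]:
        return {}

    def forward(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = rng.normal(0.0, _INIT_SCALE, size=(n_out, n_in))
        self.b = np.zeros(n_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        self._x = x
        return x @ self.W.T + self.b

    def backward(self, dy):
        self.dW = dy.T @ self._x
        self.db = dy.sum(axis=0)
        return dy @ self.W


class Conv1d(Layer):
    """Valid (no-padding) strided 1-D convolution via im2col."""

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator):
        self.k, self.stride = k, stride
        self.W = rng.normal(0.0, _INIT_SCALE, size=(c_out, c_in, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def out_length(self, l_in: int) -> int:
        return (l_in - self.k) // self.stride + 1

    def forward(self, x):
        b, c_in, l_in = x.shape
        l_out = self.out_length(l_in)
        idx = self.stride * np.arange(l_out)[:, None] + np.arange(self.k)[None, :]
        cols = x[:, :, idx]                      # (B, C_in, L_out, K)
        cols = cols.transpose(0, 2, 1, 3).reshape(b, l_out, -1)  # (B, L_out, C_in*K)
        self._x_shape, self._cols = x.shape, cols
        w_mat = self.W.reshape(self.W.shape[0], -1)              # (C_out, C_in*K)
        y = cols @ w_mat.T + self.b              # (B, L_out, C_out)
        return y.transpose(0, 2, 1)

    def backward(self, dy):
        b, c_out, l_out = dy.shape
        dy_t = dy.transpose(0, 2, 1)                             # (B, L_out, C_out)
        w_mat = self.W.reshape(c_out, -1)
        self.dW = np.einsum("blo,blk->ok", dy_t, self._cols).reshape(self.W.shape)
        self.db = dy_t.sum(axis=(0, 1))
        dcols = dy_t @ w_mat                                     # (B, L_out, C_in*K)
        c_in = self._x_shape[1]
        dcols = dcols.reshape(b, l_out, c_in, self.k)
        dx = np.zeros(self._x_shape)
        pos = self.stride * np.arange(l_out)
        for kk in range(self.k):
            dx[:, :, pos + kk] += dcols[:, :, :, kk].transpose(0, 2, 1)
        return dx


class ConvTranspose1d(Layer):
    """1-D transposed convolution with optional symmetric output cropping.

    Output length before cropping is ``(L_in - 1) * stride + k``; with
    ``crop=(c, c)`` and stride 1, ``k = 2c + 1`` preserves the input length.
    """

    def __init__(self, c_in: int, c_out: int, k: int, stride: int,
                 rng: np.random.Generator, crop: tuple[int, int] = (0, 0)):
        self.k, self.stride, self.crop = k, stride, crop
        self.W = rng.normal(0.0, _INIT_SCALE, size=(c_in, c_out, k))
        self.b = np.zeros(c_out)
        self.dW = np.zeros_like(self.W)
        self.db = np.zeros_like(self.b)

    def params(self):
        return {"W": self.W, "b": self.b}

    def grads(self):
        return {"W": self.dW, "b": self.db}

    def forward(self, x):
        b, c_in, l_in = x.shape
        l_full = (l_in - 1) * self.stride + self.k
        t = np.einsum("bcl,cok->bolk", x, self.W)  # (B, C_out, L_in, K)
        y = np.zeros((b, self.W.shape[1], l_full))
        pos = self.stride * np.arange(l_in)
        for kk in range(self.k):
            y[:, :, pos + kk] += t[:, :, :, kk]
        cl, cr = self.crop
        self._x, self._l_full = x, l_full
        y = y[:, :, cl : l_full - cr] + self.b[None, :, None]
        return y

    def backward(self, dy):
        cl, cr = self.crop
        b = dy.shape[0]
        dy_full = np.zeros((b, self.W.shape[1], self._l_full))
        dy_full[:, :, cl : self._l_full - cr] = dy
        self.db = dy.sum(axis=(0, 2))
        pos = self.stride * np.arange(self._x.shape[2])
        # gather dy at each kernel offset: (B, C_out, L_in, K)
        g = np.stack([dy_full[:, :, pos + kk] for kk in range(self.k)], axis=-1)
        self.dW = np.einsum("bcl,bolk->cok", self._x, g)
        dx = np.einsum("bolk,cok->bcl", g, self.W)
        return dx


class LeakyReLU(Layer):
    def __init__(self, alpha: float = 0.2):
        self.alpha = alpha

    def forward(self, x):
        self._mask = x >= 0
        return np.where(self._mask, x, self.alpha * x)

    def backward(self, dy):
        return np.where(self._mask, dy, self.alpha * dy)


class Reshape(Layer):
    def __init__(self, shape: tuple[int, ...]):
        self.shape = shape  # per-sample shape

    def forward(self, x):
        self._in_shape = x.shape
        return x.reshape((x.shape[0],) + self.shape)

    def backward(self, dy):
        return dy.reshape(self._in_shape)


class Sequential:
    """A plain feed-forward stack of layers."""

    def __init__(self, layers: list[Layer]):
        self.layers = layers

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, dy):
        for layer in reversed(self.layers):
            dy = layer.backward(dy)
        return dy

    def parameters(self) -> list[tuple[Layer, str, np.ndarray]]:
        return [
            (layer, name, arr)
            for layer in self.layers
            for name, arr in layer.params().items()
        ]

    def clip_(self, c: float) -> None:
        """In-place clip of every parameter to [-c, c]."""
        if c <= 0:
            raise ValueError("clip constant must be positive")
        for _, _, arr in self.parameters():
            np.clip(arr, -c, c, out=arr)

    def state_arrays(self) -> dict[str, np.ndarray]:
        return {
            f"{i}.{name}": arr
            for i, layer in enumerate(self.layers)
            for name, arr in layer.params().items()
        }

    def load_state_arrays(self, state: dict[str, np.ndarray]) -> None:
        for i, layer in enumerate(self.layers):
            for name, arr in layer.params().items():
                arr[...] = state[f"{i}.{name}"]


class RMSprop:
    """RMSprop with the classic WGAN defaults (lr 5e-5)."""

    def __init__(self, net: Sequential, lr: float = 5e-5, rho: float = 0.9,
                 eps: float = 1e-8):
        self.net, self.lr, self.rho, self.eps = net, lr, rho, eps
        self.cache = {
            f"{i}.{name}": np.zeros_like(arr)
            for i, layer in enumerate(net.layers)
            for name, arr in layer.params().items()
        }

    def step(self) -> None:
        for i, layer in enumerate(self.net.layers):
            params, grads = layer.params(), layer.grads()
            for name in params:
                key = f"{i}.{name}"
                g = grads[name]
                c = self.cache[key]
                c *= self.rho
                c += (1.0 - self.rho) * g * g
                params[name] -= self.lr * g / (np.sqrt(c) + self.eps)
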