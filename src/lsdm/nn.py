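"""Locally connected 3-D linear networks with per-location batch normalization.

This is the numerical core of the layered searchlight: a stack of
"convolution-like" layers in which every output location owns its own filter
weights (no weight sharing), applied with stride 1 and valid padding, with
batch normalization per (location, channel) between layers.  By default no
nonlinear activation is used, so each searchlight patch computes an affine map
of its receptive field at evaluation time.

The forward/backward passes are written directly in NumPy as batched GEMMs
(``np.matmul`` over a leading location axis).  Activations are kept in
location-major layout ``(X, Y, Z, batch, channels)`` so that window extraction
and the backward scatter are nearly copy-free; the public model API converts
to the conventional ``(batch, channels, X, Y, Z)`` at its boundary.  Gradients
are exercised against finite differences in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["LocallyConnectedLayer", "BatchNorm", "LocallyConnectedNet", "Adam"]

_DTYPE = np.float32


def _out_shape(in_shape: tuple[int, int, int], k: int) -> tuple[int, int, int]:
    out = tuple(s - k + 1 for s in in_shape)
    if any(s < 1 for s in out):
        raise ValueError(f"input grid {in_shape} smaller than kernel {k}")
    return out


class LocallyConnectedLayer:
    """One layer of per-location linear filters (kernel ``k``, stride 1, valid).

    Weights: ``W[n_loc, c_in*k^3, c_out]``, bias ``b[n_loc, c_out]``.  Filters
    are initialized from a zero-mean Gaussian with variance ``1/fan_in``.
    Activations flow in location-major layout ``(X, Y, Z, B, C)``.
    """

    def __init__(self, in_shape, k, c_in, c_out, rng: np.random.Generator):
        self.in_shape = tuple(in_shape)
        self.k = int(k)
        self.c_in = int(c_in)
        self.c_out = int(c_out)
        self.out_shape = _out_shape(self.in_shape, self.k)
        self.n_loc = int(np.prod(self.out_shape))
        fan_in = c_in * k**3
        self.W = rng.normal(0.0, 1.0 / np.sqrt(fan_in), (self.n_loc, fan_in, c_out)).astype(_DTYPE)
        self.b = np.zeros((self.n_loc, c_out), dtype=_DTYPE)
        self._patches = None

    @property
    def n_params(self) -> int:
        return self.W.size + self.b.size

    def params(self):
        return [self.W, self.b]

    def _extract_patches(self, x: np.ndarray) -> np.ndarray:
        # x: (X, Y, Z, B, c_in) -> (n_loc, B, c_in * k^3)
        k = self.k
        b = x.shape[3]
        win = sliding_window_view(x, (k, k, k), axis=(0, 1, 2))
        # (X', Y', Z', B, c_in, k, k, k): merge channel+window axes (adjacent)
        p = win.reshape(self.n_loc, b, self.c_in * k**3)
        return p

    def forward(self, x: np.ndarray, keep_cache: bool = False) -> np.ndarray:
        p = self._extract_patches(x)
        self._patches = p if keep_cache else None
        out = np.matmul(p, self.W)  # (n_loc, B, c_out)
        out += self.b[:, None, :]
        return out.reshape(*self.out_shape, x.shape[3], self.c_out)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """``dout``: (X', Y', Z', B, c_out) -> (dx, dW, db)."""
        b = dout.shape[3]
        d = dout.reshape(self.n_loc, b, self.c_out)
        p = self._patches
        dW = np.matmul(p.transpose(0, 2, 1), d)
        db = d.sum(axis=1)
        dp = np.matmul(d, self.W.transpose(0, 2, 1))  # (n_loc, B, F)
        dx = self._fold_patches(dp, b)
        return dx, dW.astype(_DTYPE), db.astype(_DTYPE)

    def _fold_patches(self, dp: np.ndarray, batch: int) -> np.ndarray:
        k = self.k
        ox, oy, oz = self.out_shape
        dp = dp.reshape(ox, oy, oz, batch, self.c_in, k, k, k)
        dx = np.zeros((*self.in_shape, batch, self.c_in), dtype=_DTYPE)
        for i in range(k):
            for j in range(k):
                for l in range(k):
                    dx[i : i + ox, j : j + oy, l : l + oz] += dp[..., i, j, l]
        return dx


class BatchNorm:
    """Batch normalization with independent statistics per (location, channel).

    Training uses batch statistics and updates running estimates with the given
    momentum; evaluation uses the running estimates.  Parameters are stored as
    ``(X, Y, Z, 1, C)`` to broadcast over the batch axis of location-major
    activations.
    """

    def __init__(self, feature_shape, momentum: float = 0.1, eps: float = 1e-5):
        self.feature_shape = tuple(feature_shape)  # (X, Y, Z, 1, C)
        self.momentum = float(momentum)
        self.eps = float(eps)
        self.gamma = np.ones(self.feature_shape, dtype=_DTYPE)
        self.beta = np.zeros(self.feature_shape, dtype=_DTYPE)
        self.running_mean = np.zeros(self.feature_shape, dtype=_DTYPE)
        self.running_var = np.ones(self.feature_shape, dtype=_DTYPE)
        self._cache = None

    @property
    def n_params(self) -> int:
        return self.gamma.size + self.beta.size

    def params(self):
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, train: bool, keep_cache: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=3, keepdims=True)
            centered = x - mean
            var = np.einsum(
                "xyzbc,xyzbc->xyzc", centered, centered, optimize=True
            )[:, :, :, None, :] / x.shape[3]
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(_DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(_DTYPE)
        else:
            mean, var = self.running_mean, self.running_var
            centered = x - mean
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = centered * inv_std
        if keep_cache:
            self._cache = (xhat, inv_std)
        return (self.gamma * xhat + self.beta).astype(_DTYPE)

    def backward(self, dout: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        xhat, inv_std = self._cache
        b = dout.shape[3]
        dgamma = (dout * xhat).sum(axis=3, keepdims=True)
        dbeta = dout.sum(axis=3, keepdims=True)
        dxhat = dout * self.gamma
        dx = (
            inv_std
            / b
            * (
                b * dxhat
                - dxhat.sum(axis=3, keepdims=True)
                - xhat * (dxhat * xhat).sum(axis=3, keepdims=True)
            )
        )
        return dx.astype(_DTYPE), dgamma.astype(_DTYPE), dbeta.astype(_DTYPE)


class Adam:
    """Adam optimizer over a flat list of parameter arrays (updated in place)."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1 - b1**self.t
        corr2 = 1 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


@dataclass
class _NetSpec:
    in_shape: tuple[int, int, int]
    c_in: int
    k: int
    n_layers: int
    ch: int
    n_classes: int


def to_location_major(x: np.ndarray) -> np.ndarray:
    """(B, C, X, Y, Z) -> contiguous (X, Y, Z, B, C)."""
    return np.ascontiguousarray(np.moveaxis(np.asarray(x, dtype=_DTYPE), (0, 1), (3, 4)))


def to_batch_major(x: np.ndarray) -> np.ndarray:
    """(X, Y, Z, B, C) -> contiguous (B, C, X, Y, Z)."""
    return np.ascontiguousarray(np.moveaxis(x, (3, 4), (0, 1)))


class LocallyConnectedNet:
    """Stack of L locally connected layers with batch norm between layers.

    Channel plan: ``c_in -> ch -> ... -> ch -> n_classes``.  Batch norm (and the
    optional activation/dropout) is applied after each hidden layer, i.e.
    between layers; the final layer is a linear readout per location.  The
    "latent" representation is the input to the final layer in evaluation mode.

    ``forward`` accepts and returns batch-major arrays ``(B, C, X, Y, Z)``;
    internally everything is location-major.
    """

    def __init__(
        self,
        in_shape,
        c_in: int,
        k: int,
        n_layers: int,
        ch: int,
        n_classes: int,
        seed: int = 0,
        bn_momentum: float = 0.1,
        bn_eps: float = 1e-5,
        activation: str | None = None,
        dropout: float = 0.0,
    ):
        if k < 1 or n_layers < 1 or ch < 1:
            raise ValueError("k, n_layers and ch must all be >= 1")
        rf = n_layers * k - n_layers + 1
        if any(s < rf for s in in_shape):
            raise ValueError(
                f"grid {tuple(in_shape)} smaller than the receptive field {rf}"
            )
        self.spec = _NetSpec(tuple(in_shape), c_in, k, n_layers, ch, n_classes)
        self.activation = activation
        self.dropout = float(dropout)
        rng = np.random.default_rng(seed)
        channels = [c_in] + [ch] * (n_layers - 1) + [n_classes]
        self.layers: list[LocallyConnectedLayer] = []
        self.bns: list[BatchNorm] = []
        shape = tuple(in_shape)
        for a in range(n_layers):
            layer = LocallyConnectedLayer(shape, k, channels[a], channels[a + 1], rng)
            self.layers.append(layer)
            shape = layer.out_shape
            if a < n_layers - 1:
                self.bns.append(BatchNorm((*shape, 1, channels[a + 1]), bn_momentum, bn_eps))
        self.out_shape = shape
        self._drop_rng = np.random.default_rng(seed + 1)
        self._cache_masks: list = []

    @property
    def receptive_field(self) -> int:
        s = self.spec
        return s.n_layers * s.k - s.n_layers + 1

    @property
    def n_params(self) -> int:
        return sum(l.n_params for l in self.layers) + sum(b.n_params for b in self.bns)

    def params(self):
        out = []
        for a, layer in enumerate(self.layers):
            out.extend(layer.params())
            if a < len(self.bns):
                out.extend(self.bns[a].params())
        return out

    def forward_loc(
        self, x_loc: np.ndarray, train: bool = False, keep_cache: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Location-major forward: (X, Y, Z, B, C) in, (scores, latent) out."""
        h = x_loc
        self._cache_masks = []
        for a, layer in enumerate(self.layers[:-1]):
            h = layer.forward(h, keep_cache=keep_cache)
            h = self.bns[a].forward(h, train=train, keep_cache=keep_cache)
            if self.activation == "relu":
                mask = h > 0
                h = h * mask
            else:
                mask = None
            if train and self.dropout > 0:
                drop = (self._drop_rng.random(h.shape) >= self.dropout).astype(_DTYPE)
                h = h * drop / (1.0 - self.dropout)
            else:
                drop = None
            if keep_cache:
                self._cache_masks.append((mask, drop))
        latent = h
        scores = self.layers[-1].forward(h, keep_cache=keep_cache)
        return scores, latent

    def forward(
        self, x: np.ndarray, train: bool = False, keep_cache: bool = False
    ) -> tuple[np.ndarray, np.ndarray]:
        """Batch-major forward: returns ``(scores, latent)``.

        ``scores``: (B, n_classes, *out_shape); ``latent``: the input to the
        final layer, (B, ch, *penultimate_shape) — for a single-layer net the
        latent is the raw input.
        """
        scores, latent = self.forward_loc(to_location_major(x), train, keep_cache)
        return to_batch_major(scores), to_batch_major(latent)

    def backward_loc(self, dscores_loc: np.ndarray) -> list[np.ndarray]:
        """Gradients (params order) from a location-major score gradient."""
        grads_rev: list[np.ndarray] = []
        dx, dW, db = self.layers[-1].backward(dscores_loc)
        grads_rev.extend([db, dW])
        for a in range(len(self.layers) - 2, -1, -1):
            mask, drop = self._cache_masks[a]
            if drop is not None:
                dx = dx * drop / (1.0 - self.dropout)
            if mask is not None:
                dx = dx * mask
            dx, dgamma, dbeta = self.bns[a].backward(dx)
            grads_rev.extend([dbeta, dgamma])
            dx, dW, db = self.layers[a].backward(dx)
            grads_rev.extend([db, dW])
        return grads_rev[::-1]

    def backward(self, dscores: np.ndarray) -> list[np.ndarray]:
        """Gradients for all params from a batch-major score gradient."""
        return self.backward_loc(to_location_major(dscores))

    def clear_caches(self):
        for layer in self.layers:
            layer._patches = None
        for bn in self.bns:
            bn._cache = None
        self._cache_masks = []

    # -- serialization ------------------------------------------------------
    def state_arrays(self) -> dict[str, np.ndarray]:
        out = {}
        for a, layer in enumerate(self.layers):
            out[f"layer{a}_W"] = layer.W
            out[f"layer{a}_b"] = layer.b
        for a, bn in enumerate(self.bns):
            out[f"bn{a}_gamma"] = bn.gamma
            out[f"bn{a}_beta"] = bn.beta
            out[f"bn{a}_mean"] = bn.running_mean
            out[f"bn{a}_var"] = bn.running_var
        return out

    def load_state_arrays(self, arrays: dict[str, np.ndarray]) -> None:
        for a, layer in enumerate(self.layers):
            layer.W = np.asarray(arrays[f"layer{a}_W"], dtype=_DTYPE)
            layer.b = np.asarray(arrays[f"layer{a}_b"], dtype=_DTYPE)
        for a, bn in enumerate(self.bns):
            bn.gamma = np.asarray(arrays[f"bn{a}_gamma"], dtype=_DTYPE)
            bn.beta = np.asarray(arrays[f"bn{a}_beta"], dtype=_DTYPE)
            bn.running_mean = np.asarray(arrays[f"bn{a}_mean"], dtype=_DTYPE)
            bn.running_var = np.asarray(arrays[f"bn{a}_var"], dtype=_DTYPE)
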