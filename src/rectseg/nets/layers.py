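"""Differentiable layers for the N-dimensional conv-net engine.

Every layer stores parameters in ``self.params`` and gradients in
``self.grads`` (same keys), caches what it needs on ``forward`` and
returns the input gradient from ``backward``.  Tensors are laid out as
``(N, C, *spatial)`` float32; the same code path serves 2D and 3D.

Convolutions are evaluated via im2col + BLAS matmul; the column matrix is
rebuilt in ``backward`` rather than cached, trading a little compute for
a much smaller memory footprint on volumetric inputs.
"""

from __future__ import annotations

from itertools import product

import numpy as np

__all__ = [
    "Layer",
    "Conv",
    "ConvTranspose",
    "ReLU",
    "MaxPool",
    "GlobalAvgPool",
    "Linear",
]


def kaiming_uniform(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    bound = np.sqrt(6.0 / fan_in)
    return rng.uniform(-bound, bound, size=shape).astype(np.float32)


class Layer:
    def __init__(self) -> None:
        self.params: dict[str, np.ndarray] = {}
        self.grads: dict[str, np.ndarray] = {}

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def backward(self, gy: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def n_params(self) -> int:
        return sum(int(p.size) for p in self.params.values())


def _im2col(x: np.ndarray, ksize: int) -> np.ndarray:
    """(N, C, *S) with same-padding -> (N * prod(S), C * ksize^d)."""
    d = x.ndim - 2
    pad = ksize // 2
    xp = np.pad(x, [(0, 0), (0, 0)] + [(pad, pad)] * d)
    win = np.lib.stride_tricks.sliding_window_view(
        xp, (ksize,) * d, axis=tuple(range(2, 2 + d))
    )  # (N, C, *S, *k)
    # -> (N, *S, C, *k) then flatten
    win = np.moveaxis(win, 1, 1 + d)
    n = x.shape[0]
    spatial = int(np.prod(x.shape[2:]))
    return np.ascontiguousarray(win).reshape(n * spatial, -1)


class Conv(Layer):
    """Same-padded convolution, kernel ``ksize`` per axis, stride 1."""

    def __init__(self, c_in: int, c_out: int, ndim: int, ksize: int = 3,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.ndim, self.ksize = c_in, c_out, ndim, ksize
        fan_in = c_in * ksize ** ndim
        self.params["w"] = kaiming_uniform(rng, (c_out, c_in) + (ksize,) * ndim, fan_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        if x.shape[1] != self.c_in:
            raise ValueError(f"channel count mismatch: got {x.shape[1]}, expected {self.c_in}")
        self._x = x if train else None
        cols = _im2col(x, self.ksize)
        w = self.params["w"].reshape(self.c_out, -1)
        y = cols @ w.T + self.params["b"]
        n, spatial = x.shape[0], x.shape[2:]
        y = y.reshape((n,) + spatial + (self.c_out,))
        return np.ascontiguousarray(np.moveaxis(y, -1, 1))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None, "backward before forward(train=True)"
        n, spatial = x.shape[0], x.shape[2:]
        d = len(spatial)
        gy2 = np.moveaxis(gy, 1, -1).reshape(-1, self.c_out)  # (N*S, Co)
        cols = _im2col(x, self.ksize)
        self.grads["w"] = (gy2.T @ cols).reshape(self.params["w"].shape)
        self.grads["b"] = gy2.sum(axis=0)
        w = self.params["w"].reshape(self.c_out, -1)
        dcols = gy2 @ w  # (N*S, C*k^d)
        dwin = dcols.reshape((n,) + spatial + (self.c_in,) + (self.ksize,) * d)
        dwin = np.moveaxis(dwin, 1 + d, 1)  # (N, C, *S, *k)
        pad = self.ksize // 2
        dxp = np.zeros((n, self.c_in) + tuple(s + 2 * pad for s in spatial),
                       dtype=np.float32)
        for off in product(range(self.ksize), repeat=d):
            sl = (slice(None), slice(None)) + tuple(
                slice(o, o + s) for o, s in zip(off, spatial)
            )
            dxp[sl] += dwin[(Ellipsis,) + off]
        core = (slice(None), slice(None)) + tuple(slice(pad, pad + s) for s in spatial)
        return dxp[core]


class ConvTranspose(Layer):
    """Stride-2, kernel-2 transposed convolution (doubles each spatial axis)."""

    def __init__(self, c_in: int, c_out: int, ndim: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.c_in, self.c_out, self.ndim = c_in, c_out, ndim
        fan_in = c_in * 2 ** ndim
        self.params["w"] = kaiming_uniform(rng, (c_in, c_out) + (2,) * ndim, fan_in)
        self.params["b"] = np.zeros(c_out, dtype=np.float32)
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x if train else None
        n, spatial = x.shape[0], x.shape[2:]
        d = len(spatial)
        xf = np.moveaxis(x, 1, -1).reshape(-1, self.c_in)  # (N*S, C)
        w = self.params["w"].reshape(self.c_in, -1)  # (C, Co*2^d)
        t = (xf @ w).reshape((n,) + spatial + (self.c_out,) + (2,) * d)
        # interleave (N, S1..Sd, Co, k1..kd) -> (N, Co, S1, k1, ..., Sd, kd)
        perm = [0, d + 1] + [ax for i in range(d) for ax in (1 + i, d + 2 + i)]
        t = t.transpose(perm)
        out_shape = (n, self.c_out) + tuple(2 * s for s in spatial)
        y = np.ascontiguousarray(t).reshape(out_shape)
        b = self.params["b"].reshape((1, self.c_out) + (1,) * d)
        return y + b

    def backward(self, gy: np.ndarray) -> np.ndarray:
        x = self._x
        assert x is not None
        n, spatial = x.shape[0], x.shape[2:]
        d = len(spatial)
        self.grads["b"] = gy.sum(axis=(0,) + tuple(range(2, 2 + d)))
        # de-interleave gy: (N, Co, S1, k1, ..., Sd, kd) -> (N, S1..Sd, Co, k1..kd)
        t = gy.reshape((n, self.c_out) + tuple(
            v for s in spatial for v in (s, 2)
        ))
        perm = [0] + [2 + 2 * i for i in range(d)] + [1] + [3 + 2 * i for i in range(d)]
        t = t.transpose(perm)
        tf = np.ascontiguousarray(t).reshape(-1, self.c_out * 2 ** d)  # (N*S, Co*2^d)
        xf = np.moveaxis(x, 1, -1).reshape(-1, self.c_in)
        self.grads["w"] = (xf.T @ tf).reshape(self.params["w"].shape)
        w = self.params["w"].reshape(self.c_in, -1)
        dxf = tf @ w.T  # (N*S, C)
        dx = dxf.reshape((n,) + spatial + (self.c_in,))
        return np.ascontiguousarray(np.moveaxis(dx, -1, 1))


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        return np.where(self._mask, gy, 0.0).astype(np.float32)


class MaxPool(Layer):
    """2^d max pooling with stride 2; spatial extents must be even."""

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, c = x.shape[:2]
        spatial = x.shape[2:]
        if any(s % 2 for s in spatial):
            raise ValueError(f"spatial extents must be even for 2x pooling, got {spatial}")
        d = len(spatial)
        t = x.reshape((n, c) + tuple(v for s in spatial for v in (s // 2, 2)))
        # (N, C, S1/2, k1, ..., Sd/2, kd) -> (N, C, S1/2..Sd/2, k1..kd)
        perm = [0, 1] + [2 + 2 * i for i in range(d)] + [3 + 2 * i for i in range(d)]
        t = t.transpose(perm)
        self._in_shape = x.shape
        windows = np.ascontiguousarray(t).reshape(
            (n, c) + tuple(s // 2 for s in spatial) + (2 ** d,)
        )
        self._argmax = windows.argmax(axis=-1)
        return windows.max(axis=-1)

    def backward(self, gy: np.ndarray) -> np.ndarray:
        n, c = gy.shape[:2]
        out_spatial = gy.shape[2:]
        d = len(out_spatial)
        windows = np.zeros(gy.shape + (2 ** d,), dtype=np.float32)
        np.put_along_axis(windows, self._argmax[..., None], gy[..., None], axis=-1)
        t = windows.reshape((n, c) + out_spatial + (2,) * d)
        # (N, C, S1/2..Sd/2, k1..kd) -> (N, C, S1/2, k1, ..., Sd/2, kd)
        perm = [0, 1] + [ax for i in range(d) for ax in (2 + i, 2 + d + i)]
        return np.ascontiguousarray(t.transpose(perm)).reshape(self._in_shape)


class GlobalAvgPool(Layer):
    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._in_shape = x.shape
        return x.mean(axis=tuple(range(2, x.ndim)))

    def backward(self, gy: np.ndarray) -> np.ndarray:
        spatial = self._in_shape[2:]
        scale = 1.0 / float(np.prod(spatial))
        return np.broadcast_to(
            gy.reshape(gy.shape + (1,) * len(spatial)) * scale, self._in_shape
        ).astype(np.float32)


class Linear(Layer):
    def __init__(self, n_in: int, n_out: int,
                 rng: np.random.Generator | None = None) -> None:
        super().__init__()
        rng = rng or np.random.default_rng()
        self.params["w"] = kaiming_uniform(rng, (n_out, n_in), n_in)
        self.params["b"] = np.zeros(n_out, dtype=np.float32)

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        self._x = x
        return x @ self.params["w"].T + self.params["b"]

    def backward(self, gy: np.ndarray) -> np.ndarray:
        self.grads["w"] = gy.T @ self._x
        self.grads["b"] = gy.sum(axis=0)
        return gy @ self.params["w"]
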