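"""Minimal NumPy layer stack for 2D encoder-decoder networks.

Convolutions are evaluated as im2col + BLAS matrix products in
float32. All layers operate on channels-last (N, H, W, C) arrays:
with channels last an im2col patch row is a run of k contiguous
k*C-element chunks, so the patch matrix is assembled by large memcpys
and the GEMM output is already in layout — on one CPU core this is
what keeps a scaled-down U-Net trainable in minutes. No autodiff:
backward passes are written out explicitly, layer by layer, and each
layer exposes ``params()`` as (weight, gradient) pairs consumed by the
Adam optimizer.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = [
    "Conv2D",
    "ReLU",
    "MaxPool2",
    "UpConv2",
    "Adam",
    "softmax",
    "masked_cross_entropy",
]


try:  # optional JIT for the patch-gather inner loop
    import numba as _numba

    @_numba.njit(fastmath=True)
    def _im2col_kernel(xp, k, out):  # pragma: no cover - exercised via _im2col
        n, hp, wp, c = xp.shape
        ho, wo = hp - k + 1, wp - k + 1
        for ni in range(n):
            for i in range(ho):
                for j in range(wo):
                    row = (ni * ho + i) * wo + j
                    idx = 0
                    for p in range(k):
                        for q in range(k):
                            for cc in range(c):
                                out[row, idx] = xp[ni, i + p, j + q, cc]
                                idx += 1

except ImportError:  # pragma: no cover
    _im2col_kernel = None


def _im2col(xp: np.ndarray, k: int) -> np.ndarray:
    """(N, Hp, Wp, C) padded input -> (N*Ho*Wo, k*k*C) patch matrix.

    The JIT kernel and the stride-trick fallback produce bit-identical
    matrices; only the gather speed differs.
    """
    n, hp, wp, c = xp.shape
    ho, wo = hp - k + 1, wp - k + 1
    if _im2col_kernel is not None:
        out = np.empty((n * ho * wo, k * k * c), dtype=xp.dtype)
        _im2col_kernel(xp, k, out)
        return out
    win = sliding_window_view(xp, (k, k), axis=(1, 2))  # (N, Ho, Wo, C, k, k)
    # reorder window dims to (kh, kw, C): rows become chunked memcpys
    return np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        n * ho * wo, k * k * c
    )


class Conv2D:
    """k x k convolution; ``pad`` in {0, k//2} (valid / same).

    Weights are stored as (k, k, C_in, C_out), matching the im2col
    patch order.
    """

    def __init__(self, cin: int, cout: int, rng: np.random.Generator,
                 ksize: int = 3, pad: int | None = None):
        self.cin, self.cout, self.k = cin, cout, ksize
        self.pad = ksize // 2 if pad is None else pad
        fan_in = cin * ksize * ksize
        self.w = (rng.standard_normal((ksize, ksize, cin, cout))
                  * np.sqrt(2.0 / fan_in)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        p, k = self.pad, self.k
        if k == 1:
            cols = x.reshape(-1, c)
        else:
            xp = np.pad(x, ((0, 0), (p, p), (p, p), (0, 0))) if p else x
            cols = _im2col(xp, k)
        y = cols @ self.w.reshape(-1, self.cout) + self.b
        ho, wo = h + 2 * p - k + 1, w + 2 * p - k + 1
        if train:
            self._cache = (cols, (n, h, w))
        return y.reshape(n, ho, wo, self.cout)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        cols, (n, h, w) = self._cache
        self._cache = None
        k, p = self.k, self.pad
        dyf = dy.reshape(-1, self.cout)
        self.dw = (cols.T @ dyf).reshape(self.w.shape)
        self.db = dyf.sum(axis=0)
        if k == 1:
            return (dyf @ self.w.reshape(self.cin, self.cout).T).reshape(n, h, w, self.cin)
        # dx = full correlation of dy with flipped, channel-swapped weights
        q = k - 1 - p
        dyp = np.pad(dy, ((0, 0), (q, q), (q, q), (0, 0))) if q else dy
        dcols = _im2col(dyp, k)
        wt = self.w[::-1, ::-1].transpose(0, 1, 3, 2)  # (k, k, cout, cin)
        dx = dcols @ wt.reshape(-1, self.cin)
        return dx.reshape(n, h, w, self.cin)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class ReLU:
    def __init__(self):
        self._mask = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        y = np.maximum(x, 0.0)
        if train:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dx = dy * self._mask
        self._mask = None
        return dx

    def params(self):
        return []


class MaxPool2:
    """2x2 max pooling, stride 2; ties route their gradient to the
    first maximal element of the window."""

    def __init__(self):
        self._cache = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        if h % 2 or w % 2:
            raise ValueError(f"MaxPool2 needs even spatial dims, got {h}x{w}")
        xw = np.stack(
            [x[:, 0::2, 0::2], x[:, 0::2, 1::2], x[:, 1::2, 0::2], x[:, 1::2, 1::2]],
            axis=-1,
        )  # (n, h/2, w/2, c, 4)
        idx = xw.argmax(axis=-1)
        y = np.take_along_axis(xw, idx[..., None], axis=-1)[..., 0]
        if train:
            self._cache = (idx, (n, h, w, c))
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        idx, (n, h, w, c) = self._cache
        self._cache = None
        dxw = np.zeros((n, h // 2, w // 2, c, 4), dtype=dy.dtype)
        np.put_along_axis(dxw, idx[..., None], dy[..., None], axis=-1)
        dx = np.empty((n, h, w, c), dtype=dy.dtype)
        dx[:, 0::2, 0::2] = dxw[..., 0]
        dx[:, 0::2, 1::2] = dxw[..., 1]
        dx[:, 1::2, 0::2] = dxw[..., 2]
        dx[:, 1::2, 1::2] = dxw[..., 3]
        return dx

    def params(self):
        return []


class UpConv2:
    """2x2 transposed convolution with stride 2 (learned upsampling)."""

    def __init__(self, cin: int, cout: int, rng: np.random.Generator):
        self.cin, self.cout = cin, cout
        self.w = (rng.standard_normal((cin, cout, 2, 2))
                  * np.sqrt(2.0 / cin)).astype(np.float32)
        self.b = np.zeros(cout, dtype=np.float32)
        self.dw = np.zeros_like(self.w)
        self.db = np.zeros_like(self.b)
        self._x = None

    def forward(self, x: np.ndarray, train: bool = True) -> np.ndarray:
        n, h, w, c = x.shape
        y = np.tensordot(x, self.w, axes=([3], [0]))  # (n, h, w, cout, 2, 2)
        y = np.ascontiguousarray(y.transpose(0, 1, 4, 2, 5, 3)).reshape(
            n, 2 * h, 2 * w, self.cout
        )
        y += self.b
        if train:
            self._x = x
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        self._x = None
        n, h, w, c = x.shape
        dy4 = np.ascontiguousarray(
            dy.reshape(n, h, 2, w, 2, self.cout).transpose(0, 1, 3, 5, 2, 4)
        )  # (n, h, w, cout, 2, 2)
        self.dw = np.tensordot(x, dy4, axes=([0, 1, 2], [0, 1, 2]))
        self.db = dy.sum(axis=(0, 1, 2))
        dx = np.tensordot(dy4, self.w, axes=([3, 4, 5], [1, 2, 3]))  # (n, h, w, cin)
        return np.ascontiguousarray(dx)

    def params(self):
        return [(self.w, self.dw), (self.b, self.db)]


class Adam:
    """Adam with the canonical defaults (lr 1e-3, betas 0.9/0.999)."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.params = params  # list of layers exposing .params()
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(w) for layer in params for (w, _) in layer.params()]
        self.v = [np.zeros_like(w) for layer in params for (w, _) in layer.params()]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        i = 0
        for layer in self.params:
            for (w, g) in layer.params():
                m, v = self.m[i], self.v[i]
                m *= self.b1
                m += (1 - self.b1) * g
                v *= self.b2
                v += (1 - self.b2) * (g * g)
                w -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
                i += 1


def softmax(logits: np.ndarray, axis: int = -1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z, dtype=np.float32)
    return e / e.sum(axis=axis, keepdims=True)


def masked_cross_entropy(
    logits: np.ndarray, labels: np.ndarray, mask: np.ndarray
) -> tuple[float, np.ndarray]:
    """Categorical cross-entropy over non-excluded voxels only.

    ``logits``: (N, H, W, K); ``labels``: (N, H, W) integer class index
    in 0..K-1 (arbitrary where mask is False); ``mask``: (N, H, W)
    boolean. Excluded voxels contribute zero loss and zero gradient.
    Returns (mean loss per included voxel, dlogits).
    """
    k = logits.shape[-1]
    total = int(mask.sum())
    if total == 0:
        return 0.0, np.zeros_like(logits)
    p = softmax(logits, axis=-1)
    flatp = p.reshape(-1, k)
    flat_lab = labels.reshape(-1)
    flat_mask = mask.reshape(-1)
    picked = flatp[np.arange(flatp.shape[0]), flat_lab]
    loss = float(-np.log(np.maximum(picked[flat_mask], 1e-12)).sum() / total)
    grad = flatp
    grad[np.arange(grad.shape[0]), flat_lab] -= 1.0
    grad *= (flat_mask / total)[:, None]
    return loss, grad.reshape(logits.shape).astype(np.float32)
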