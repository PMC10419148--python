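"""A compact numpy convolutional network for phase-image classification.

Architecture: three stages of [3x3 conv (pad 1) -> ReLU -> 2x2 average pool]
with 16/32/64 channels, global average pooling, and a single-logit linear
head, trained with Adam on the binary cross-entropy loss. Convolutions are
implemented with im2col so the heavy lifting is BLAS matmul; the whole model
is a pure function of its seed, so training is bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SimpleCNN"]


def _im2col(x: np.ndarray, k: int = 3, pad: int = 1) -> np.ndarray:
    """(N, C, H, W) -> (N, C*k*k, H*W) patch matrix (stride 1)."""
    n, c, h, w = x.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    s = xp.strides
    view = np.lib.stride_tricks.as_strided(
        xp, shape=(n, c, k, k, h, w), strides=(s[0], s[1], s[2], s[3], s[2], s[3])
    )
    return view.reshape(n, c * k * k, h * w)


def _col2im(dcols: np.ndarray, xshape: tuple, k: int = 3, pad: int = 1) -> np.ndarray:
    n, c, h, w = xshape
    dx = np.zeros((n, c, h + 2 * pad, w + 2 * pad), dtype=dcols.dtype)
    d = dcols.reshape(n, c, k, k, h, w)
    for i in range(k):
        for j in range(k):
            dx[:, :, i : i + h, j : j + w] += d[:, :, i, j]
    return dx[:, :, pad : pad + h, pad : pad + w]


class SimpleCNN:
    """Binary classifier over single-channel square images."""

    def __init__(self, input_side: int = 32, channels: tuple[int, ...] = (16, 32, 64),
                 seed: int = 0):
        if input_side % (2 ** len(channels)) != 0:
            raise ValueError("input_side must be divisible by 2^len(channels)")
        self.input_side = input_side
        self.channels = tuple(channels)
        rng = np.random.default_rng(seed)
        self.params: dict[str, np.ndarray] = {}
        c_in = 1
        for li, c_out in enumerate(self.channels):
            fan_in = c_in * 9
            self.params[f"W{li}"] = rng.normal(
                0.0, np.sqrt(2.0 / fan_in), (c_out, c_in * 9)
            ).astype(np.float32)
            self.params[f"b{li}"] = np.zeros(c_out, dtype=np.float32)
            c_in = c_out
        self.params["Wd"] = rng.normal(0.0, np.sqrt(2.0 / c_in), (c_in,)).astype(np.float32)
        self.params["bd"] = np.zeros(1, dtype=np.float32)

    # -- forward / backward -------------------------------------------------
    def _forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        for li in range(len(self.channels)):
            w, b = self.params[f"W{li}"], self.params[f"b{li}"]
            cols = _im2col(x)
            n, _, hw = cols.shape
            h = int(np.sqrt(hw))
            z = np.einsum("fk,nkp->nfp", w, cols) + b[None, :, None]
            z = z.reshape(n, -1, h, h)
            relu_mask = z > 0
            a = z * relu_mask
            pooled = a.reshape(n, a.shape[1], h // 2, 2, h // 2, 2).mean(axis=(3, 5))
            if cache is not None:
                cache.append((x.shape, cols, relu_mask, h))
            x = pooled
        gap = x.mean(axis=(2, 3))
        if cache is not None:
            cache.append((x.shape, gap))
        return gap @ self.params["Wd"] + self.params["bd"][0]

    def _backward(self, dlogit: np.ndarray, cache: list) -> dict[str, np.ndarray]:
        grads: dict[str, np.ndarray] = {}
        pshape, gap = cache[-1]
        grads["Wd"] = gap.T @ dlogit
        grads["bd"] = np.array([dlogit.sum()])
        dgap = np.outer(dlogit, self.params["Wd"])
        n, c, hp, wp = pshape
        dx = np.broadcast_to((dgap / (hp * wp))[:, :, None, None],
                             (n, c, hp, wp)).astype(np.float32)
        for li in range(len(self.channels) - 1, -1, -1):
            xshape, cols, relu_mask, h = cache[li]
            # un-pool: gradient of a 2x2 mean spreads evenly
            da = np.repeat(np.repeat(dx, 2, axis=2), 2, axis=3) / 4.0
            dz = da * relu_mask
            dzf = dz.reshape(dz.shape[0], dz.shape[1], -1)
            grads[f"W{li}"] = np.einsum("nfp,nkp->fk", dzf, cols)
            grads[f"b{li}"] = dzf.sum(axis=(0, 2))
            dcols = np.einsum("fk,nfp->nkp", self.params[f"W{li}"], dzf)
            dx = _col2im(dcols, xshape)
        return grads

    # -- training -----------------------------------------------------------
    def fit(
        self,
        x: np.ndarray,
        y: np.ndarray,
        epochs: int = 6,
        batch_size: int = 64,
        lr: float = 1e-3,
        seed: int = 0,
    ) -> "SimpleCNN":
        """Train with Adam on binary cross-entropy. ``x``: (N, side, side) in
        [0, 1]; ``y``: (N,) in {0, 1}."""
        x = np.asarray(x, dtype=np.float32)[:, None, :, :]
        y = np.asarray(y, dtype=np.float32)
        rng = np.random.default_rng(seed)
        m = {k: np.zeros_like(v) for k, v in self.params.items()}
        v = {k: np.zeros_like(p) for k, p in self.params.items()}
        b1, b2, eps = 0.9, 0.999, 1e-8
        t = 0
        n = x.shape[0]
        for _ in range(epochs):
            order = rng.permutation(n)
            for start in range(0, n, batch_size):
                idx = order[start : start + batch_size]
                cache: list = []
                logits = self._forward(x[idx], cache)
                p = 1.0 / (1.0 + np.exp(-logits))
                dlogit = (p - y[idx]) / len(idx)
                grads = self._backward(dlogit.astype(np.float32), cache)
                t += 1
                for key, g in grads.items():
                    m[key] = b1 * m[key] + (1 - b1) * g
                    v[key] = b2 * v[key] + (1 - b2) * g * g
                    mhat = m[key] / (1 - b1**t)
                    vhat = v[key] / (1 - b2**t)
                    self.params[key] -= lr * mhat / (np.sqrt(vhat) + eps)
        return self

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Per-image probability of the positive (SCD) class."""
        x = np.asarray(x, dtype=np.float32)[:, None, :, :]
        out = np.empty(x.shape[0])
        for start in range(0, x.shape[0], batch_size):
            logits = self._forward(x[start : start + batch_size])
            out[start : start + batch_size] = 1.0 / (1.0 + np.exp(-logits))
        return out
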