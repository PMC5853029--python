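"""Minimal NumPy neural-network engine for the focus classifier.

Implements exactly the layers the ordinal defocus classifier needs —
valid (unpadded) 2-D convolution, 2 x 2 max pooling, fully connected
layers, ReLU, inverted dropout and softmax — with explicit backward passes
and an Adam optimizer.  Convolutions are lowered to BLAS matrix products via
im2col, which keeps desk-scale training (thousands of steps on one CPU)
practical in float32.

Gradient correctness is pinned by a finite-difference check in the test
suite rather than trusted by construction.
"""

from __future__ import annotations

import numpy as np

try:  # single-pass fused update; keeps Adam off the memory-bandwidth floor
    from numba import njit

    @njit(cache=True, fastmath=True)
    def _adam_update(p, g, m, v, b1, b2, lr_t, eps):  # pragma: no cover
        for i in range(p.size):
            gi = g[i]
            m[i] = b1 * m[i] + (1.0 - b1) * gi
            v[i] = b2 * v[i] + (1.0 - b2) * gi * gi
            p[i] -= lr_t * m[i] / (np.sqrt(v[i]) + eps)

except ImportError:  # pragma: no cover
    _adam_update = None

__all__ = ["FocusNet", "Adam"]


def _im2col(x: np.ndarray, k: int) -> tuple[np.ndarray, tuple[int, int, int]]:
    """(B,C,H,W) -> (B*OH*OW, C*k*k) patch matrix for valid correlation."""
    b = x.shape[0]
    win = np.lib.stride_tricks.sliding_window_view(x, (k, k), axis=(2, 3))
    # (B, C, OH, OW, k, k) -> (B, OH, OW, C, k, k)
    win = win.transpose(0, 2, 3, 1, 4, 5)
    oh, ow = win.shape[1], win.shape[2]
    return np.ascontiguousarray(win).reshape(b * oh * ow, -1), (b, oh, ow)


def _conv_forward(x, w, bias):
    """Valid correlation. x (B,C,H,W), w (F,C,k,k) -> y (B,F,OH,OW).

    Lowered to one BLAS matmul via im2col; the patch matrix is cached for
    the weight gradient.
    """
    f, c, k, _ = w.shape
    col, (b, oh, ow) = _im2col(x, k)
    y = col @ w.reshape(f, c * k * k).T + bias
    y = np.ascontiguousarray(y.reshape(b, oh, ow, f).transpose(0, 3, 1, 2))
    return y, (col, x.shape, w)


def _conv_backward(dy, cache, need_dx=True):
    """Gradients of a valid correlation.

    dW reuses the cached im2col matrix (one matmul).  dX is accumulated as
    k*k shifted tensordots, which avoids building the much larger im2col
    matrix of the padded upstream gradient.
    """
    col, x_shape, w = cache
    f, c, k, _ = w.shape
    oh, ow = dy.shape[2], dy.shape[3]
    dyt = np.ascontiguousarray(dy.transpose(0, 2, 3, 1))  # (B, OH, OW, F)
    dyf = dyt.reshape(-1, f)
    dw = (dyf.T @ col).reshape(f, c, k, k)
    db = dyf.sum(axis=0)
    dx = None
    if need_dx:
        dx = np.zeros(x_shape, dtype=dy.dtype)
        for u in range(k):
            for v in range(k):
                dx[:, :, u:u + oh, v:v + ow] += np.tensordot(
                    dyt, w[:, :, u, v], axes=([3], [0])).transpose(0, 3, 1, 2)
    return dx, dw, db


def _pool_forward(x):
    """2x2 max pool, stride 2; input spatial dims must be even."""
    s = (x[:, :, 0::2, 0::2], x[:, :, 0::2, 1::2],
         x[:, :, 1::2, 0::2], x[:, :, 1::2, 1::2])
    y = np.maximum(np.maximum(s[0], s[1]), np.maximum(s[2], s[3]))
    return y, (s, y, x.shape)


def _pool_backward(dy, cache):
    """Route each upstream gradient to the first position attaining the max
    in its 2x2 window (deterministic tie-break)."""
    s, y, x_shape = cache
    dx = np.zeros(x_shape, dtype=dy.dtype)
    taken = np.zeros(dy.shape, dtype=bool)
    views = (dx[:, :, 0::2, 0::2], dx[:, :, 0::2, 1::2],
             dx[:, :, 1::2, 0::2], dx[:, :, 1::2, 1::2])
    for sub, view in zip(s, views):
        hit = (sub == y) & ~taken
        view += dy * hit
        taken |= hit
    return dx


def _truncated_normal(rng, shape, std):
    """Normal(0, std) redrawn into +-2 std (simple rejection)."""
    out = rng.standard_normal(shape)
    bad = np.abs(out) > 2.0
    while bad.any():
        out[bad] = rng.standard_normal(int(bad.sum()))
        bad = np.abs(out) > 2.0
    return (out * std).astype(np.float32)


class FocusNet:
    """conv32-5x5 / pool / conv64-5x5 / pool / FC1024 / dropout / FC n_levels.

    Input is a (B, 1, 84, 84) float32 batch already scaled to [0, ~1];
    output is the softmax class distribution over the ordered defocus
    levels.  Valid convolutions: 84 -> 80 -> 40 -> 36 -> 18, giving an
    18*18*64 flattened feature vector.
    """

    INPUT_SIZE = 84

    def __init__(self, n_levels: int = 11, seed: int = 0,
                 conv_filters: tuple[int, int] = (32, 64),
                 kernel_size: int = 5, fc_units: int = 1024,
                 dropout: float = 0.5, input_size: int | None = None):
        self.n_levels = n_levels
        self.dropout = dropout
        self.kernel_size = kernel_size
        self.input_size = input_size or self.INPUT_SIZE
        rng = np.random.default_rng(seed)
        f1, f2 = conv_filters
        k = kernel_size
        s = self.input_size
        side = ((s - k + 1) // 2 - k + 1) // 2
        self.flat_dim = side * side * f2
        self.feature_side = side
        self.params = {
            "w1": _truncated_normal(rng, (f1, 1, k, k), np.sqrt(2.0 / (k * k))),
            "b1": np.zeros(f1, dtype=np.float32),
            "w2": _truncated_normal(rng, (f2, f1, k, k),
                                    np.sqrt(2.0 / (f1 * k * k))),
            "b2": np.zeros(f2, dtype=np.float32),
            "w3": _truncated_normal(rng, (self.flat_dim, fc_units),
                                    np.sqrt(2.0 / self.flat_dim)),
            "b3": np.zeros(fc_units, dtype=np.float32),
            "w4": _truncated_normal(rng, (fc_units, n_levels),
                                    np.sqrt(2.0 / fc_units)),
            "b4": np.zeros(n_levels, dtype=np.float32),
        }

    def forward(self, x: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (probs, cache).  Dropout is active only when training."""
        p = self.params
        a1, c1 = _conv_forward(x, p["w1"], p["b1"])
        r1 = np.maximum(a1, 0.0)
        p1, cp1 = _pool_forward(r1)
        a2, c2 = _conv_forward(p1, p["w2"], p["b2"])
        r2 = np.maximum(a2, 0.0)
        p2, cp2 = _pool_forward(r2)
        flat = p2.reshape(x.shape[0], -1)
        h = flat @ p["w3"] + p["b3"]
        rh = np.maximum(h, 0.0)
        if train and self.dropout > 0:
            if rng is None:
                raise ValueError("training forward pass needs an rng")
            keep = (rng.random(rh.shape) >= self.dropout).astype(np.float32)
            rd = rh * keep / (1.0 - self.dropout)
        else:
            keep = None
            rd = rh
        logits = rd @ p["w4"] + p["b4"]
        z = logits - logits.max(axis=1, keepdims=True)
        e = np.exp(z)
        probs = e / e.sum(axis=1, keepdims=True)
        cache = (c1, a1, cp1, c2, a2, cp2, flat, h, keep, rd)
        return probs, cache

    def backward(self, dlogits: np.ndarray, cache) -> dict[str, np.ndarray]:
        """Gradients of the loss w.r.t. every parameter.

        ``dlogits`` is dLoss/dlogits (softmax already folded in by the
        caller), float32, shape (B, n_levels).
        """
        p = self.params
        c1, a1, cp1, c2, a2, cp2, flat, h, keep, rd = cache
        grads = {}
        grads["w4"] = rd.T @ dlogits
        grads["b4"] = dlogits.sum(axis=0)
        drd = dlogits @ p["w4"].T
        if keep is not None:
            drd = drd * keep / (1.0 - self.dropout)
        dh = drd * (h > 0)
        grads["w3"] = flat.T @ dh
        grads["b3"] = dh.sum(axis=0)
        dflat = dh @ p["w3"].T
        b = dlogits.shape[0]
        side = self.feature_side
        dp2 = dflat.reshape(b, p["w2"].shape[0], side, side)
        dr2 = _pool_backward(dp2, cp2)
        da2 = dr2 * (a2 > 0)
        dp1, grads["w2"], grads["b2"] = _conv_backward(da2, c2)
        dr1 = _pool_backward(dp1, cp1)
        da1 = dr1 * (a1 > 0)
        # first layer: the gradient w.r.t. the input image is never used
        _, grads["w1"], grads["b1"] = _conv_backward(da1, c1, need_dx=False)
        return grads

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for k in self.params:
            self.params[k] = np.asarray(state[k], dtype=np.float32)


class Adam:
    """Adaptive-moment optimizer (the standard bias-corrected form)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        # in-place scratch: the FC1 moments are ~21M floats, so avoiding
        # fresh temporaries per update matters
        self._s = {k: np.empty_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray],
             grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        # fused bias correction: lr_t = lr * sqrt(1-b2^t) / (1-b1^t)
        lr_t = self.lr * np.sqrt(1.0 - b2 ** self.t) / (1.0 - b1 ** self.t)
        for k, g in grads.items():
            if _adam_update is not None:
                _adam_update(params[k].ravel(), g.ravel(),
                             self.m[k].ravel(), self.v[k].ravel(),
                             np.float32(b1), np.float32(b2),
                             np.float32(lr_t), np.float32(self.eps))
                continue
            m, v, s = self.m[k], self.v[k], self._s[k]
            np.multiply(g, 1.0 - b1, out=s)
            m *= b1
            m += s
            np.multiply(g, g, out=s)
            s *= (1.0 - b2)
            v *= b2
            v += s
            np.sqrt(v, out=s)
            s += self.eps
            np.divide(m, s, out=s)
            s *= lr_t
            params[k] -= s
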