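"""Minimal 1D convolutional network with Adam, dropout and early stopping.

Pure NumPy implementation of the small architecture used by the FOG
detector:

    conv1d(16 filters, kernel 17, same padding, ReLU) -> dropout(0.5)
    conv1d(16 filters, kernel 17, same padding, ReLU) -> dropout(0.5)
    max-pool(2) -> flatten -> dense(10, ReLU) -> dense(1, sigmoid)

The loss is weighted binary cross-entropy (computed on logits for
stability).  Convolutions are im2col + matmul; gradients use the
transposed-kernel convolution, so everything is dense linear algebra.
All randomness (init, dropout, batch shuffling) flows from one
``numpy.random.Generator``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["ConvNet1D", "Adam", "train_network", "weighted_bce_from_logits"]

_F32 = np.float32


def _im2col(x: np.ndarray, kernel: int) -> np.ndarray:
    """(N, T, C) -> (N, T - kernel + 1, kernel * C) sliding-window view."""
    v = np.lib.stride_tricks.sliding_window_view(x, kernel, axis=1)
    # v: (N, T-K+1, C, K) -> (N, T-K+1, K, C)
    return np.ascontiguousarray(v.transpose(0, 1, 3, 2)).reshape(
        x.shape[0], x.shape[1] - kernel + 1, kernel * x.shape[2]
    )


class _Conv1DSame:
    """Same-padded 1D convolution over (N, T, C_in) -> (N, T, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator):
        self.kernel = kernel
        self.pad = kernel // 2
        scale = np.sqrt(2.0 / (kernel * c_in))  # He init for ReLU stacks
        self.w = (rng.standard_normal((kernel, c_in, c_out)) * scale).astype(_F32)
        self.b = np.zeros(c_out, dtype=_F32)
        self._x_cols: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        k, c_in, c_out = self.w.shape
        xp = np.pad(x, ((0, 0), (self.pad, self.pad), (0, 0)))
        cols = _im2col(xp, k)
        self._x_cols = cols if keep_cache else None
        return cols @ self.w.reshape(k * c_in, c_out) + self.b

    def backward(self, grad_out: np.ndarray):
        k, c_in, c_out = self.w.shape
        n, t, _ = grad_out.shape
        cols = self._x_cols
        g2 = grad_out.reshape(n * t, c_out)
        dw = (cols.reshape(n * t, k * c_in).T @ g2).reshape(k, c_in, c_out)
        db = g2.sum(axis=0)
        # dX: correlate grad_out with the kernel flipped along its length
        gp = np.pad(grad_out, ((0, 0), (k - 1, k - 1), (0, 0)))
        gcols = _im2col(gp, k)
        w_flip = self.w[::-1].transpose(0, 2, 1).reshape(k * c_out, c_in)
        dxp = gcols @ w_flip
        # dxp is the gradient w.r.t. the padded input; crop the padding
        dx = dxp[:, self.pad : self.pad + t, :]
        self._x_cols = None
        return dx, [dw.astype(_F32), db.astype(_F32)]


class _Dense:
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, relu: bool):
        scale = np.sqrt((2.0 if relu else 1.0) / n_in)
        self.w = (rng.standard_normal((n_in, n_out)) * scale).astype(_F32)
        self.b = np.zeros(n_out, dtype=_F32)
        self._x: np.ndarray | None = None

    @property
    def params(self):
        return [self.w, self.b]

    def forward(self, x: np.ndarray, keep_cache: bool) -> np.ndarray:
        self._x = x if keep_cache else None
        return x @ self.w + self.b

    def backward(self, grad_out: np.ndarray):
        dw = self._x.T @ grad_out
        db = grad_out.sum(axis=0)
        dx = grad_out @ self.w.T
        self._x = None
        return dx, [dw.astype(_F32), db.astype(_F32)]


class ConvNet1D:
    """The two-conv-layer FOG window classifier.

    Input windows are ``(n_channels, n_samples)`` (channels first, as
    produced by the windowing stage); internally time-major.  ``predict``
    returns sigmoid probabilities, ``logits`` the pre-sigmoid scores.
    """

    def __init__(
        self,
        n_channels: int,
        n_samples: int,
        rng: np.random.Generator,
        n_filters: int = 16,
        kernel_len: int = 17,
        pool_len: int = 2,
        dense_units: int = 10,
        dropout_rate: float = 0.5,
    ):
        if n_samples <= kernel_len:
            raise ValueError(
                f"window length {n_samples} must exceed kernel length {kernel_len}"
            )
        if not 0.0 <= dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        self.n_channels = n_channels
        self.n_samples = n_samples
        self.pool_len = pool_len
        self.dropout_rate = dropout_rate
        self.conv1 = _Conv1DSame(n_channels, n_filters, kernel_len, rng)
        self.conv2 = _Conv1DSame(n_filters, n_filters, kernel_len, rng)
        pooled = n_samples // pool_len
        self.dense1 = _Dense(pooled * n_filters, dense_units, rng, relu=True)
        self.dense2 = _Dense(dense_units, 1, rng, relu=False)
        self._cache: dict | None = None

    # -- parameter flattening (for Adam and best-weights restore) ------
    @property
    def layers(self):
        return [self.conv1, self.conv2, self.dense1, self.dense2]

    def get_params(self) -> list[np.ndarray]:
        return [p for layer in self.layers for p in layer.params]

    def set_params(self, values: list[np.ndarray]) -> None:
        for p, v in zip(self.get_params(), values):
            p[...] = v

    # -- forward / backward --------------------------------------------
    def _check_input(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        if x.ndim == 2:
            x = x[None]
        if x.shape[1:] != (self.n_channels, self.n_samples):
            raise ValueError(
                f"input shape {x.shape[1:]} does not match expected "
                f"({self.n_channels}, {self.n_samples})"
            )
        return x.transpose(0, 2, 1)  # (N, T, C)

    def forward_logits(
        self,
        x: np.ndarray,
        training: bool = False,
        rng: np.random.Generator | None = None,
    ) -> np.ndarray:
        xt = self._check_input(x)
        cache: dict = {}

        z1 = self.conv1.forward(xt, training)
        a1 = np.maximum(z1, 0)
        if training:
            m1 = (rng.uniform(size=a1.shape) >= self.dropout_rate).astype(_F32) / (
                1 - self.dropout_rate
            )
            a1 = a1 * m1
            cache.update(z1=z1, m1=m1)
        z2 = self.conv2.forward(a1, training)
        a2 = np.maximum(z2, 0)
        if training:
            m2 = (rng.uniform(size=a2.shape) >= self.dropout_rate).astype(_F32) / (
                1 - self.dropout_rate
            )
            a2 = a2 * m2
            cache.update(z2=z2, m2=m2)

        n, t, f = a2.shape
        tp = (t // self.pool_len) * self.pool_len
        pooled_in = a2[:, :tp].reshape(n, tp // self.pool_len, self.pool_len, f)
        pooled = pooled_in.max(axis=2)
        flat = pooled.reshape(n, -1)

        z3 = self.dense1.forward(flat, training)
        a3 = np.maximum(z3, 0)
        logits = self.dense2.forward(a3, training)[:, 0]
        if training:
            cache.update(
                pooled_in=pooled_in, pooled=pooled, z3=z3, a2_shape=a2.shape
            )
            self._cache = cache
        return logits

    def backward(self, grad_logits: np.ndarray) -> list[np.ndarray]:
        c = self._cache
        grads: list[np.ndarray] = []
        g, g_d2 = self.dense2.backward(grad_logits[:, None])
        g = g * (c["z3"] > 0)
        g, g_d1 = self.dense1.backward(g)

        n, tpool, f = c["pooled"].shape
        g_pool = g.reshape(n, tpool, f)
        # route gradient to the argmax within each pool pair
        is_max = c["pooled_in"] == c["pooled"][:, :, None, :]
        # break ties toward the first element, as argmax would
        first = np.cumsum(is_max, axis=2) == 1
        route = (is_max & first).astype(_F32)
        g_a2 = (route * g_pool[:, :, None, :]).reshape(n, tpool * self.pool_len, f)
        t_full = c["a2_shape"][1]
        if t_full != g_a2.shape[1]:
            g_a2 = np.pad(g_a2, ((0, 0), (0, t_full - g_a2.shape[1]), (0, 0)))

        g_a2 = g_a2 * c["m2"] * (c["z2"] > 0)
        g, g_c2 = self.conv2.backward(g_a2)
        g = g * c["m1"] * (c["z1"] > 0)
        _, g_c1 = self.conv1.backward(g)
        self._cache = None
        return g_c1 + g_c2 + g_d1 + g_d2

    def predict_proba(self, x: np.ndarray, batch_size: int = 4096) -> np.ndarray:
        x = np.asarray(x, dtype=_F32)
        single = x.ndim == 2
        if single:
            x = x[None]
        out = np.concatenate(
            [
                1.0 / (1.0 + np.exp(-self.forward_logits(x[i : i + batch_size])))
                for i in range(0, len(x), batch_size)
            ]
        )
        return float(out[0]) if single else out


def weighted_bce_from_logits(
    logits: np.ndarray, y: np.ndarray, w: np.ndarray | None = None
) -> float:
    """Weighted binary cross-entropy, numerically stable on logits.

    softplus(z) - y*z  ==  -[y log p + (1-y) log(1-p)] for p = sigmoid(z).
    Weighted mean (sum(w * loss) / sum(w)); unweighted if w is None.
    """
    z = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    per = np.logaddexp(0.0, z) - y * z
    if w is None:
        return float(per.mean())
    w = np.asarray(w, dtype=float)
    return float(np.sum(w * per) / np.sum(w))


class Adam:
    """Standard Adam over a flat parameter list."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-7):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def train_network(
    net: ConvNet1D,
    x_train_fn: Callable[[int], tuple[np.ndarray, np.ndarray, np.ndarray]],
    x_val: np.ndarray,
    y_val: np.ndarray,
    rng: np.random.Generator,
    lr: float = 1e-3,
    batch_size: int = 512,
    max_epochs: int = 100,
    patience: int = 10,
) -> dict:
    """Mini-batch Adam training with early stopping on validation loss.

    ``x_train_fn(epoch)`` returns this epoch's ``(x, y, w)`` arrays —
    the hook through which fresh rotation augmentation is injected each
    epoch.  Training stops when the validation loss fails to improve for
    *patience* consecutive epochs (or at *max_epochs*); the parameters
    from the best-validation-loss epoch are restored.  Returns history
    with per-epoch ``train_loss``/``val_loss``, ``stopped_epoch`` and
    ``best_epoch``.
    """
    opt = Adam(net.get_params(), lr=lr)
    history: dict = {"train_loss": [], "val_loss": []}
    best_loss = np.inf
    best_params: list[np.ndarray] | None = None
    best_epoch = -1
    bad_epochs = 0

    for epoch in range(max_epochs):
        x, y, w = x_train_fn(epoch)
        order = rng.permutation(len(x))
        tot_loss = 0.0
        tot_w = 0.0
        for i in range(0, len(order), batch_size):
            idx = order[i : i + batch_size]
            xb = np.asarray(x[idx], dtype=_F32)
            yb = y[idx].astype(_F32)
            wb = w[idx].astype(_F32)
            logits = net.forward_logits(xb, training=True, rng=rng)
            per = np.logaddexp(0.0, logits) - yb * logits
            wsum = float(wb.sum())
            tot_loss += float(np.sum(wb * per))
            tot_w += wsum
            p = 1.0 / (1.0 + np.exp(-logits.astype(float)))
            grad = (wb * (p - yb) / max(wsum, 1e-12)).astype(_F32)
            grads = net.backward(grad)
            opt.step(grads)
        history["train_loss"].append(tot_loss / max(tot_w, 1e-12))

        val_logits = np.concatenate(
            [
                net.forward_logits(np.asarray(x_val[i : i + 4096], dtype=_F32))
                for i in range(0, len(x_val), 4096)
            ]
        )
        val_loss = weighted_bce_from_logits(val_logits, y_val)
        history["val_loss"].append(val_loss)

        if val_loss < best_loss - 1e-12:
            best_loss = val_loss
            best_params = [p.copy() for p in net.get_params()]
            best_epoch = epoch
            bad_epochs = 0
        else:
            bad_epochs += 1
            if bad_epochs >= patience:
                break

    if best_params is not None:
        net.set_params(best_params)
    history["best_epoch"] = best_epoch
    history["stopped_epoch"] = len(history["val_loss"]) - 1
    return history
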