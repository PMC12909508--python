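"""Minimal reverse-mode automatic differentiation on numpy arrays.

A deliberately small tensor engine — just the operations the backbone
(convolutions, batch norm, pooling, ConvLSTM) and the Wave-GRU (dense
gates, sigmoid/sine activations) need, plus an Adam optimizer with
decoupled weight decay.  Convolutions are im2col-based so both the
forward and backward passes reduce to matrix multiplications.

Arrays are float32 throughout; image tensors use NCHW layout.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "relu",
    "sigmoid",
    "tanh",
    "sin",
    "add",
    "mul",
    "matmul",
    "concat",
    "conv2d",
    "maxpool2d",
    "global_avg_pool",
    "batchnorm2d",
    "dropout",
    "flatten",
    "softmax_cross_entropy",
    "softmax",
    "mse_loss",
    "Adam",
]


class Tensor:
    """A node in the computation graph wrapping an ``np.ndarray``."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad=False, _prev=(), name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.data.shape}, name={self.name!r})"


def _as_tensor(x):
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(out_prev):
    return any(p.requires_grad or p._prev for p in out_prev)


def _unbroadcast(grad, shape):
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, s in enumerate(shape):
        if s == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


def _binary(a, b, fwd, bwd_a, bwd_b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(fwd(a.data, b.data), _prev=(a, b))

    def _backward(g):
        a._accumulate(_unbroadcast(bwd_a(g, a.data, b.data), a.data.shape))
        b._accumulate(_unbroadcast(bwd_b(g, a.data, b.data), b.data.shape))

    out._backward = _backward
    return out


def add(a, b):
    return _binary(a, b, lambda x, y: x + y, lambda g, x, y: g, lambda g, x, y: g)


def sub(a, b):
    return _binary(a, b, lambda x, y: x - y, lambda g, x, y: g, lambda g, x, y: -g)


def mul(a, b):
    return _binary(a, b, lambda x, y: x * y, lambda g, x, y: g * y, lambda g, x, y: g * x)


def matmul(a, b):
    a, b = _as_tensor(a), _as_tensor(b)
    out = Tensor(a.data @ b.data, _prev=(a, b))

    def _backward(g):
        a._accumulate(g @ b.data.T)
        b._accumulate(a.data.T @ g)

    out._backward = _backward
    return out


def _unary(a, fwd, bwd):
    a = _as_tensor(a)
    y = fwd(a.data)
    out = Tensor(y, _prev=(a,))

    def _backward(g):
        a._accumulate(bwd(g, a.data, y))

    out._backward = _backward
    return out


def relu(a):
    return _unary(a, lambda x: np.maximum(x, 0.0), lambda g, x, y: g * (x > 0))


def _stable_sigmoid(x):
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def sigmoid(a):
    return _unary(a, _stable_sigmoid, lambda g, x, y: g * y * (1.0 - y))


def tanh(a):
    return _unary(a, np.tanh, lambda g, x, y: g * (1.0 - y * y))


def sin(a):
    """The wave activation: elementwise sine, range [-1, 1]."""
    return _unary(a, np.sin, lambda g, x, y: g * np.cos(x))


def neg(a):
    return _unary(a, lambda x: -x, lambda g, x, y: -g)


def scale(a, c):
    c = float(c)
    return _unary(a, lambda x: x * c, lambda g, x, y: g * c)


def concat(tensors, axis=1):
    tensors = [_as_tensor(t) for t in tensors]
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]

    def _backward(g):
        start = 0
        for t, s in zip(tensors, sizes):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(start, start + s)
            t._accumulate(g[tuple(sl)])
            start += s

    out._backward = _backward
    return out


def flatten(a):
    a = _as_tensor(a)
    n = a.data.shape[0]
    out = Tensor(a.data.reshape(n, -1), _prev=(a,))

    def _backward(g):
        a._accumulate(g.reshape(a.data.shape))

    out._backward = _backward
    return out


# ---------------------------------------------------------------------------
# Convolution machinery (im2col / col2im, NCHW)
# ---------------------------------------------------------------------------

def _im2col(x, kh, kw, stride, pad):
    n, c, h, w = x.shape
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    ho = (x.shape[2] - kh) // stride + 1
    wo = (x.shape[3] - kw) // stride + 1
    s0, s1, s2, s3 = x.strides
    cols = np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride),
    )
    # (n, ho, wo, c*kh*kw)
    return np.ascontiguousarray(cols.transpose(0, 4, 5, 1, 2, 3)).reshape(n * ho * wo, -1), ho, wo


def _col2im(cols, x_shape, kh, kw, stride, pad):
    n, c, h, w = x_shape
    hp, wp = h + 2 * pad, w + 2 * pad
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    xg = np.zeros((n, c, hp, wp), dtype=np.float32)
    cols = cols.reshape(n, ho, wo, c, kh, kw).transpose(0, 3, 4, 5, 1, 2)
    for i in range(kh):
        for j in range(kw):
            xg[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += cols[:, :, i, j]
    if pad:
        xg = xg[:, :, pad : pad + h, pad : pad + w]
    return xg


def conv2d(x, w, b=None, stride=1, pad=None):
    """2-D convolution (cross-correlation), NCHW; `pad=None` means 'same' for stride 1."""
    x, w = _as_tensor(x), _as_tensor(w)
    co, ci, kh, kw = w.data.shape
    if pad is None:
        pad = kh // 2
    cols, ho, wo = _im2col(x.data, kh, kw, stride, pad)
    wmat = w.data.reshape(co, -1)
    y = cols @ wmat.T
    if b is not None:
        b = _as_tensor(b)
        y = y + b.data.reshape(1, co)
    n = x.data.shape[0]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(y.reshape(n, ho, wo, co).transpose(0, 3, 1, 2), _prev=prev)

    def _backward(g):
        gmat = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(-1, co)
        w._accumulate((gmat.T @ cols).reshape(w.data.shape))
        x._accumulate(_col2im(gmat @ wmat, x.data.shape, kh, kw, stride, pad))
        if b is not None:
            b._accumulate(gmat.sum(axis=0).reshape(b.data.shape))

    out._backward = _backward
    return out


def maxpool2d(x, k=3, stride=2, pad=None):
    x = _as_tensor(x)
    if pad is None:
        pad = k // 2 if stride == 1 else 0
    n, c, h, w = x.data.shape
    xr = x.data.reshape(n * c, 1, h, w)
    if pad:
        xr = np.pad(xr, ((0, 0), (0, 0), (pad, pad), (pad, pad)), constant_values=-np.inf)
    cols, ho, wo = _im2col(xr, k, k, stride, 0)
    idx = cols.argmax(axis=1)
    y = cols[np.arange(cols.shape[0]), idx]
    out = Tensor(y.reshape(n * c, ho, wo).reshape(n, c, ho, wo), _prev=(x,))

    def _backward(g):
        gcols = np.zeros_like(cols)
        gcols[np.arange(cols.shape[0]), idx] = g.reshape(-1)
        xg = _col2im(gcols, (n * c, 1, h + 2 * pad, w + 2 * pad), k, k, stride, 0)
        if pad:
            xg = xg[:, :, pad : pad + h, pad : pad + w]
        x._accumulate(xg.reshape(n, c, h, w))

    out._backward = _backward
    return out


def global_avg_pool(x):
    x = _as_tensor(x)
    n, c, h, w = x.data.shape
    out = Tensor(x.data.mean(axis=(2, 3)), _prev=(x,))

    def _backward(g):
        x._accumulate(np.broadcast_to(g[:, :, None, None] / (h * w), x.data.shape).copy())

    out._backward = _backward
    return out


def batchnorm2d(x, gamma, beta, running, training, momentum=0.1, eps=1e-5):
    """Batch normalization over N,H,W per channel.

    `running` is a dict with 'mean' and 'var' arrays updated in place
    during training and used directly in eval mode.
    """
    x, gamma, beta = _as_tensor(x), _as_tensor(gamma), _as_tensor(beta)
    if training:
        mean = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running["mean"] = (1 - momentum) * running["mean"] + momentum * mean
        running["var"] = (1 - momentum) * running["var"] + momentum * var
    else:
        mean, var = running["mean"], running["var"]
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mean[None, :, None, None]) * inv[None, :, None, None]
    y = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]
    out = Tensor(y, _prev=(x, gamma, beta))
    m = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]

    def _backward(g):
        gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        beta._accumulate(g.sum(axis=(0, 2, 3)))
        gx_hat = g * gamma.data[None, :, None, None]
        if training:
            t1 = gx_hat.sum(axis=(0, 2, 3))
            t2 = (gx_hat * xhat).sum(axis=(0, 2, 3))
            gx = (inv[None, :, None, None] / m) * (
                m * gx_hat - t1[None, :, None, None] - xhat * t2[None, :, None, None]
            )
        else:
            gx = gx_hat * inv[None, :, None, None]
        x._accumulate(gx.astype(np.float32))

    out._backward = _backward
    return out


def dropout(x, rate, rng, training):
    x = _as_tensor(x)
    if not training or rate <= 0.0:
        return x
    mask = (rng.random(x.data.shape) >= rate).astype(np.float32) / (1.0 - rate)
    return mul(x, Tensor(mask))


def softmax(x):
    x = _as_tensor(x)
    z = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    out = Tensor(p, _prev=(x,))

    def _backward(g):
        dot = (g * p).sum(axis=1, keepdims=True)
        x._accumulate(p * (g - dot))

    out._backward = _backward
    return out


def softmax_cross_entropy(logits, labels):
    """Mean cross-entropy of integer `labels`; fused softmax backward."""
    logits = _as_tensor(logits)
    labels = np.asarray(labels)
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n = p.shape[0]
    loss = -np.log(np.maximum(p[np.arange(n), labels], 1e-12)).mean()
    out = Tensor(loss, _prev=(logits,))

    def _backward(g):
        gp = p.copy()
        gp[np.arange(n), labels] -= 1.0
        logits._accumulate(g * gp / n)

    out._backward = _backward
    return out


def mse_loss(pred, target):
    pred = _as_tensor(pred)
    target = np.asarray(target, dtype=np.float32)
    diff = pred.data - target
    out = Tensor(np.mean(diff**2), _prev=(pred,))

    def _backward(g):
        pred._accumulate(g * 2.0 * diff / diff.size)

    out._backward = _backward
    return out


class Adam:
    """Adam with decoupled weight decay."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * (mhat / (np.sqrt(vhat) + self.eps) + self.weight_decay * p.data)
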