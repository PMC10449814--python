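"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the segmentation architectures need:
2-D convolution (stride 1, 'same' padding, optional dilation), 2x2 max
pooling, nearest-neighbour upsampling, channel concatenation, ReLU,
elementwise add, global average pooling with spatial broadcast, and a fused
weighted softmax cross-entropy.  Tensors are NCHW float64 throughout.

The graph is a tape: each op returns a ``Tensor`` holding its parents and a
closure that routes the output gradient to them.  ``Tensor.backward`` runs a
topological sort and accumulates gradients; leaves created with
``requires_grad=True`` (model parameters) keep their ``grad`` for the
optimiser.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "maxpool2d",
    "upsample_nearest",
    "concat",
    "relu",
    "add",
    "global_avg_pool",
    "broadcast_spatial",
    "weighted_softmax_cross_entropy",
    "softmax",
]


class Tensor:
    """A node in the autodiff tape wrapping a float64 ndarray."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    def zero_grad(self):
        self.grad = None

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.ones_like(self.data)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = g.copy()
        else:
            self.grad += g


def _needs_graph(*tensors):
    return any(t.requires_grad or t._parents for t in tensors)


def conv2d(x: Tensor, w: Tensor, b: Tensor, dilation: int = 1) -> Tensor:
    """'Same' convolution, stride 1.  x: (N,C,H,W); w: (O,C,k,k); b: (O,)."""
    n, c, h, wd = x.data.shape
    o, c2, kh, kw = w.data.shape
    if c != c2:
        raise ValueError(f"channel mismatch: input {c}, kernel {c2}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("only odd kernel sizes are supported")
    d = int(dilation)
    ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    span_h, span_w = d * (kh - 1) + 1, d * (kw - 1) + 1
    win = np.lib.stride_tricks.sliding_window_view(xp, (span_h, span_w), axis=(2, 3))
    win = win[..., ::d, ::d]  # (N,C,H,W,kh,kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * wd, c * kh * kw)
    wmat = w.data.reshape(o, c * kh * kw)
    out = (cols @ wmat.T).reshape(n, h, wd, o).transpose(0, 3, 1, 2) + b.data[None, :, None, None]
    result = Tensor(out, parents=(x, w, b))

    def backward(g):
        gm = g.transpose(0, 2, 3, 1).reshape(n * h * wd, o)
        if w.requires_grad or w._parents:
            w._accumulate((gm.T @ cols).reshape(o, c, kh, kw))
        if b.requires_grad or b._parents:
            b._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._parents:
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    # grad: (N,O,H,W) x w[:, :, i, j]: (O,C) -> (N,C,H,W)
                    gxp[:, :, i * d:i * d + h, j * d:j * d + wd] += np.einsum(
                        "nohw,oc->nchw", g, w.data[:, :, i, j], optimize=True
                    )
            x._accumulate(gxp[:, :, ph:ph + h, pw:pw + wd] if (ph or pw) else gxp)

    result._backward = backward if _needs_graph(x, w, b) else None
    return result


def maxpool2d(x: Tensor) -> Tensor:
    """2x2 max pooling, stride 2.  Spatial dims must be even."""
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2d needs even spatial dims, got {h}x{w}")
    xr = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = xr.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]
    result = Tensor(out, parents=(x,))

    def backward(g):
        gf = np.zeros_like(flat)
        np.put_along_axis(gf, idx[..., None], g[..., None], axis=-1)
        gx = gf.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accumulate(gx)

    result._backward = backward if _needs_graph(x) else None
    return result


def upsample_nearest(x: Tensor, factor: int) -> Tensor:
    f = int(factor)
    out = x.data.repeat(f, axis=2).repeat(f, axis=3)
    result = Tensor(out, parents=(x,))

    def backward(g):
        n, c, h, w = x.data.shape
        x._accumulate(g.reshape(n, c, h, f, w, f).sum(axis=(3, 5)))

    result._backward = backward if _needs_graph(x) else None
    return result


def concat(tensors, axis: int = 1) -> Tensor:
    out = np.concatenate([t.data for t in tensors], axis=axis)
    result = Tensor(out, parents=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad or t._parents:
                t._accumulate(piece)

    result._backward = backward if _needs_graph(*tensors) else None
    return result


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    result = Tensor(x.data * mask, parents=(x,))

    def backward(g):
        x._accumulate(g * mask)

    result._backward = backward if _needs_graph(x) else None
    return result


def add(x: Tensor, y: Tensor) -> Tensor:
    if x.data.shape != y.data.shape:
        raise ValueError("add requires equal shapes")
    result = Tensor(x.data + y.data, parents=(x, y))

    def backward(g):
        if x.requires_grad or x._parents:
            x._accumulate(g)
        if y.requires_grad or y._parents:
            y._accumulate(g)

    result._backward = backward if _needs_graph(x, y) else None
    return result


def global_avg_pool(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    result = Tensor(x.data.mean(axis=(2, 3), keepdims=True), parents=(x,))

    def backward(g):
        x._accumulate(np.broadcast_to(g / (h * w), x.data.shape).copy())

    result._backward = backward if _needs_graph(x) else None
    return result


def broadcast_spatial(x: Tensor, h: int, w: int) -> Tensor:
    """Broadcast a (N,C,1,1) tensor to (N,C,h,w) — the ASPP image-pooling path."""
    n, c, h0, w0 = x.data.shape
    if (h0, w0) != (1, 1):
        raise ValueError("broadcast_spatial expects spatial dims (1,1)")
    result = Tensor(np.broadcast_to(x.data, (n, c, h, w)).copy(), parents=(x,))

    def backward(g):
        x._accumulate(g.sum(axis=(2, 3), keepdims=True))

    result._backward = backward if _needs_graph(x) else None
    return result


def softmax(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    """Numerically stable softmax on a plain array (no gradient)."""
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)


def weighted_softmax_cross_entropy(logits: Tensor, labels: np.ndarray,
                                   class_weights: np.ndarray,
                                   eps: float = 1e-7) -> Tensor:
    """Mean over pixels of w_c * (-log softmax(logits)_c), c the true class.

    ``labels``: int array (N,H,W); ``class_weights``: (K,).  Probabilities are
    clipped at ``eps`` before the log.
    """
    n, k, h, w = logits.data.shape
    labels = np.asarray(labels)
    if labels.shape != (n, h, w):
        raise ValueError(f"labels shape {labels.shape} != {(n, h, w)}")
    p = softmax(logits.data, axis=1)
    wpix = np.asarray(class_weights, dtype=np.float64)[labels]  # (N,H,W)
    ni, ri, ci = np.ogrid[:n, :h, :w]
    p_true = np.clip(p[ni, labels, ri, ci], eps, None)
    npix = n * h * w
    loss = float((wpix * -np.log(p_true)).sum() / npix)
    result = Tensor(loss, parents=(logits,))

    def backward(g):
        onehot = np.zeros_like(p)
        onehot[ni, labels, ri, ci] = 1.0
        glog = wpix[:, None, :, :] * (p - onehot) / npix
        logits._accumulate(g * glog)

    result._backward = backward if _needs_graph(logits) else None
    return result
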