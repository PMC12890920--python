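"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the restoration network needs:
2D convolution (stride 1 or 2, 'same' zero padding), 2x average pooling,
2x nearest-neighbour upsampling, channel concatenation, ReLU, elementwise
add, scalar scaling, and the two training losses (pixel MSE and the
Fourier-magnitude loss). Arrays are NHWC float32 throughout; gradients are
accumulated in float32 as well.

The engine is tape-based: every op appends its parents and a backward
closure to the produced :class:`Tensor`; ``Tensor.backward()`` runs the
tape in reverse topological order.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv2d",
    "relu",
    "add",
    "scale",
    "concat_channels",
    "avg_pool2",
    "upsample2",
    "add_const",
    "mse_loss",
    "ft_loss",
    "Adam",
]


class Tensor:
    """A numpy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward", "name")

    def __init__(self, data, requires_grad=False, name=""):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = ()
        self._backward = None
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def __add__(self, other):
        if isinstance(other, Tensor):
            return add(self, other)
        return add_const(self, other)

    __radd__ = __add__

    def __mul__(self, s):
        return scale(self, float(s))

    __rmul__ = __mul__

    def backward(self):
        """Backpropagate from this (scalar) tensor through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self):
        self.grad = None


def _accumulate(t: Tensor, g: np.ndarray) -> None:
    if not (t.requires_grad or t._backward is not None or t._parents):
        return
    if t.grad is None:
        t.grad = g.astype(np.float32, copy=True)
    else:
        t.grad += g


def _make(data, parents, backward) -> Tensor:
    out = Tensor(data)
    # the node participates in the tape iff any parent does
    if any(p.requires_grad or p._parents or p._backward is not None for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


# ---------------------------------------------------------------- conv2d

def conv2d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """'Same'-padded 2D convolution, NHWC input, (k, k, C, OC) kernel.

    For stride 2 the spatial extent halves (input extent must be even).
    """
    k = w.data.shape[0]
    pad = k // 2
    B, H, W, C = x.data.shape
    xp = np.pad(x.data, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(1, 2))
    win = win[:, ::stride, ::stride]  # (B, oh, ow, C, k, k)
    oh, ow = win.shape[1], win.shape[2]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(
        B * oh * ow, k * k * C
    )
    w2 = w.data.reshape(k * k * C, -1)
    y = cols @ w2 + b.data
    oc = w2.shape[1]
    out_data = y.reshape(B, oh, ow, oc)

    def backward(gout):
        g = gout.reshape(-1, oc)
        if w.requires_grad or w._parents:
            _accumulate(w, (cols.T @ g).reshape(w.data.shape))
        if b.requires_grad or b._parents:
            _accumulate(b, g.sum(axis=0))
        if x.requires_grad or x._parents:
            dcols = (g @ w2.T).reshape(B, oh, ow, k, k, C)
            dxp = np.zeros_like(xp)
            for ki in range(k):
                for kj in range(k):
                    dxp[
                        :,
                        ki : ki + stride * oh : stride,
                        kj : kj + stride * ow : stride,
                        :,
                    ] += dcols[:, :, :, ki, kj, :]
            _accumulate(x, dxp[:, pad : pad + H, pad : pad + W, :])

    return _make(out_data, (x, w, b), backward)


# ---------------------------------------------------------------- pointwise

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(gout):
        _accumulate(x, gout * mask)

    return _make(np.where(mask, x.data, 0.0), (x,), backward)


def add(a: Tensor, b: Tensor) -> Tensor:
    def backward(gout):
        _accumulate(a, gout)
        _accumulate(b, gout)

    return _make(a.data + b.data, (a, b), backward)


def add_const(a: Tensor, c) -> Tensor:
    def backward(gout):
        _accumulate(a, gout)

    return _make(a.data + np.asarray(c, dtype=np.float32), (a,), backward)


def scale(a: Tensor, s: float) -> Tensor:
    def backward(gout):
        _accumulate(a, gout * s)

    return _make(a.data * np.float32(s), (a,), backward)


def concat_channels(a: Tensor, b: Tensor) -> Tensor:
    ca = a.data.shape[-1]

    def backward(gout):
        _accumulate(a, gout[..., :ca])
        _accumulate(b, gout[..., ca:])

    return _make(np.concatenate([a.data, b.data], axis=-1), (a, b), backward)


# ---------------------------------------------------------------- resampling

def avg_pool2(x: Tensor) -> Tensor:
    """2x2 mean pooling; spatial dims must be even."""
    B, H, W, C = x.data.shape
    y = x.data.reshape(B, H // 2, 2, W // 2, 2, C).mean(axis=(2, 4))

    def backward(gout):
        g = np.repeat(np.repeat(gout, 2, axis=1), 2, axis=2) * np.float32(0.25)
        _accumulate(x, g)

    return _make(y, (x,), backward)


def upsample2(x: Tensor) -> Tensor:
    """Nearest-neighbour 2x upsampling."""
    y = np.repeat(np.repeat(x.data, 2, axis=1), 2, axis=2)

    def backward(gout):
        B, H2, W2, C = gout.shape
        g = gout.reshape(B, H2 // 2, 2, W2 // 2, 2, C).sum(axis=(2, 4))
        _accumulate(x, g)

    return _make(y, (x,), backward)


# ---------------------------------------------------------------- losses

def mse_loss(pred: Tensor, target: np.ndarray) -> Tensor:
    """Mean over all elements of the squared difference."""
    diff = pred.data.astype(np.float64) - np.asarray(target, dtype=np.float64)
    val = np.float32((diff * diff).mean())

    def backward(gout):
        g = (2.0 / diff.size) * diff * float(gout)
        _accumulate(pred, g.astype(np.float32))

    return _make(val, (pred,), backward)


def ft_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-12) -> Tensor:
    """Mean magnitude of the orthonormal-2D-DFT difference spectrum.

    For a batch (B, H, W[, 1]) the loss is
    ``mean_{b,k} |FFT2(pred_b - target_b)[k]|`` with the unitary ("ortho")
    transform convention. Because the DFT is unitary and linear, the
    gradient is the real part of the inverse transform of the unit-modulus
    phase field of the difference spectrum.
    """
    p = pred.data.astype(np.float64)
    t = np.asarray(target, dtype=np.float64)
    squeeze = p.ndim == 4
    if squeeze:
        p, t = p[..., 0], t[..., 0]
    D = np.fft.fft2(p - t, norm="ortho")
    mag = np.abs(D)
    val = np.float32(mag.mean())

    def backward(gout):
        phase = D / (mag + eps)
        g = np.real(np.fft.ifft2(phase, norm="ortho")) / D.size * float(gout)
        if squeeze:
            g = g[..., None]
        _accumulate(pred, g.astype(np.float32))

    return _make(val, (pred,), backward)


# ---------------------------------------------------------------- optimizer

class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8) over Tensors."""

    def __init__(self, params, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = b1 * self.m[i] + (1 - b1) * g
            self.v[i] = b2 * self.v[i] + (1 - b2) * (g * g)
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
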