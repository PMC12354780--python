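"""Minimal reverse-mode automatic differentiation on numpy arrays.

This is the training engine behind the segmentation network: a tape-based
:class:`Tensor` with the handful of differentiable operations a convolutional
encoder-decoder needs (convolution, batch normalization, pooling, nearest
upsampling, concatenation, the usual pointwise nonlinearities) plus an Adam
optimizer.  Data layout is NCHW throughout.  Everything is plain float64/
float32 numpy; no threads, so seeded runs are bit-reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "concat",
    "conv2d",
    "maxpool2x2",
    "upsample_nearest",
    "upsample_nearest2x",
    "avgpool",
    "Conv2d",
    "BatchNorm2d",
    "Dropout",
    "Adam",
    "he_uniform",
]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array with a gradient tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple = ()

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _wrap(other):
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float64))

    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            return _unbroadcast(g, self.data.shape), _unbroadcast(g, other.data.shape)

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data
        a, b = self, other

        def backward(g):
            return (_unbroadcast(g * b.data, a.data.shape),
                    _unbroadcast(g * a.data, b.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other.pow(-1.0)

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self.pow(-1.0)

    def pow(self, exponent: float):
        x = self
        out_data = np.power(x.data, exponent)

        def backward(g):
            return (g * exponent * np.power(x.data, exponent - 1.0),)

        return Tensor._make(out_data, (x,), backward)

    def matmul(self, other):
        other = Tensor._wrap(other)
        a, b = self, other
        out_data = a.data @ b.data

        def backward(g):
            return g @ b.data.T, a.data.T @ g

        return Tensor._make(out_data, (a, b), backward)

    # -- pointwise nonlinearities --------------------------------------------
    def relu(self):
        x = self
        out_data = np.maximum(x.data, 0.0)

        def backward(g):
            return (g * (x.data > 0.0),)

        return Tensor._make(out_data, (x,), backward)

    def sigmoid(self):
        x = self
        out_data = 1.0 / (1.0 + np.exp(-x.data))

        def backward(g, s=out_data):
            return (g * s * (1.0 - s),)

        return Tensor._make(out_data, (x,), backward)

    def tanh(self):
        x = self
        out_data = np.tanh(x.data)

        def backward(g, t=out_data):
            return (g * (1.0 - t * t),)

        return Tensor._make(out_data, (x,), backward)

    def log(self):
        x = self
        out_data = np.log(x.data)

        def backward(g):
            return (g / x.data,)

        return Tensor._make(out_data, (x,), backward)

    def exp(self):
        x = self
        out_data = np.exp(x.data)

        def backward(g, e=out_data):
            return (g * e,)

        return Tensor._make(out_data, (x,), backward)

    def clamp(self, lo: float, hi: float):
        """Clip values; gradient is passed only where un-clipped."""
        x = self
        out_data = np.clip(x.data, lo, hi)
        inside = (x.data > lo) & (x.data < hi)

        def backward(g):
            return (g * inside,)

        return Tensor._make(out_data, (x,), backward)

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        x = self
        out_data = x.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, x.data.shape).copy(),)

        return Tensor._make(out_data, (x,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))])
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        x = self
        out_data = x.data.reshape(*shape)

        def backward(g):
            return (g.reshape(x.data.shape),)

        return Tensor._make(out_data, (x,), backward)

    def transpose(self, axes):
        x = self
        out_data = x.data.transpose(axes)
        inv = np.argsort(axes)

        def backward(g):
            return (g.transpose(inv),)

        return Tensor._make(out_data, (x,), backward)

    # -- autodiff driver ------------------------------------------------------
    def backward(self):
        """Reverse-mode sweep from this (scalar) tensor."""
        topo = _toposort(self)
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = np.zeros_like(parent.data)
                parent.grad += g

    def zero_grad(self):
        self.grad = None


def _toposort(root: Tensor) -> list:
    order: list[Tensor] = []
    seen: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in seen:
            continue
        seen.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in seen:
                stack.append((p, False))
    return order


# -- structural ops -----------------------------------------------------------

def concat(tensors: list, axis: int = 1) -> Tensor:
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out_data, tuple(tensors), backward)


def _im2col(x: np.ndarray, kh: int, kw: int) -> np.ndarray:
    """(N,C,H+kh-1,W+kw-1) padded input -> (N*H*W, C*kh*kw) patch matrix."""
    n, c, hp, wp = x.shape
    h, w = hp - kh + 1, wp - kw + 1
    windows = np.lib.stride_tricks.sliding_window_view(x, (kh, kw), axis=(2, 3))
    # windows: (N, C, H, W, kh, kw) -> (N, H, W, C, kh, kw)
    cols = windows.transpose(0, 2, 3, 1, 4, 5).reshape(n * h * w, c * kh * kw)
    return np.ascontiguousarray(cols)


def _conv1x1(x: Tensor, weight: Tensor, bias: Tensor | None) -> Tensor:
    """Fast path: a 1x1 convolution is a channel-mixing matmul."""
    n, cin, h, w = x.data.shape
    cout = weight.data.shape[0]
    xmat = x.data.transpose(0, 2, 3, 1).reshape(-1, cin)      # (N*H*W, Cin)
    wmat = weight.data.reshape(cout, cin)
    out = xmat @ wmat.T
    out_data = out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data += bias.data.reshape(1, cout, 1, 1)
    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(-1, cout)
        dw = (gmat.T @ xmat).reshape(weight.data.shape)
        dx = (gmat @ wmat).reshape(n, h, w, cin).transpose(0, 3, 1, 2)
        if bias is None:
            return dx, dw
        return dx, dw, g.sum(axis=(0, 2, 3))

    return Tensor._make(out_data, parents, backward)


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None = None) -> Tensor:
    """'Same'-padded stride-1 2-D convolution (cross-correlation), odd kernels."""
    n, cin, h, w = x.data.shape
    cout, cin_w, kh, kw = weight.data.shape
    if cin != cin_w:
        raise ValueError(f"conv2d: input has {cin} channels, weight expects {cin_w}")
    if kh == 1 and kw == 1:
        return _conv1x1(x, weight, bias)
    ph, pw = (kh - 1) // 2, (kw - 1) // 2
    xpad = np.pad(x.data, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode="constant")
    cols = _im2col(xpad, kh, kw)                      # (N*H*W, Cin*kh*kw)
    wmat = weight.data.reshape(cout, -1)              # (Cout, Cin*kh*kw)
    out = cols @ wmat.T                               # (N*H*W, Cout)
    out_data = out.reshape(n, h, w, cout).transpose(0, 3, 1, 2)
    if bias is not None:
        out_data = out_data + bias.data.reshape(1, cout, 1, 1)

    parents = (x, weight) if bias is None else (x, weight, bias)

    def backward(g):
        gmat = g.transpose(0, 2, 3, 1).reshape(n * h * w, cout)
        dw = (gmat.T @ cols).reshape(weight.data.shape)
        # dX = full correlation of g with flipped weights
        gpad = np.pad(g, ((0, 0), (0, 0), (ph, ph), (pw, pw)), mode="constant")
        gcols = _im2col(gpad, kh, kw)                 # (N*H*W, Cout*kh*kw)
        wflip = weight.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3).reshape(cin, -1)
        dx = (gcols @ wflip.T).reshape(n, h, w, cin).transpose(0, 3, 1, 2)
        if bias is None:
            return dx, dw
        db = g.sum(axis=(0, 2, 3))
        return dx, dw, db

    return Tensor._make(out_data, parents, backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    if h % 2 or w % 2:
        raise ValueError(f"maxpool2x2 needs even spatial dims, got {h}x{w}")
    ho, wo = h // 2, w // 2
    blocks = x.data.reshape(n, c, ho, 2, wo, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, ho, wo, 4)
    idx = flat.argmax(axis=-1)
    out_data = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        gflat = np.zeros((n, c, ho, wo, 4))
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (gx,)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest(x: Tensor, s: int) -> Tensor:
    """Nearest-neighbor upsampling by integer factor `s`."""
    n, c, h, w = x.data.shape
    out_data = x.data.repeat(s, axis=2).repeat(s, axis=3)

    def backward(g):
        gx = g.reshape(n, c, h, s, w, s).sum(axis=(3, 5))
        return (gx,)

    return Tensor._make(out_data, (x,), backward)


def upsample_nearest2x(x: Tensor) -> Tensor:
    return upsample_nearest(x, 2)


def avgpool(x: Tensor, s: int) -> Tensor:
    """Non-overlapping s x s average pooling (spatial dims divisible by s)."""
    n, c, h, w = x.data.shape
    if h % s or w % s:
        raise ValueError(f"avgpool factor {s} does not divide {h}x{w}")
    out_data = x.data.reshape(n, c, h // s, s, w // s, s).mean(axis=(3, 5))

    def backward(g):
        gx = np.repeat(np.repeat(g, s, axis=2), s, axis=3) / (s * s)
        return (gx,)

    return Tensor._make(out_data, (x,), backward)


# -- layers -------------------------------------------------------------------

def he_uniform(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    limit = np.sqrt(6.0 / fan_in)
    return rng.uniform(-limit, limit, size=shape)


class Conv2d:
    """Stride-1 same-padded convolution layer with He-uniform init."""

    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator):
        fan_in = cin * k * k
        self.weight = Tensor(he_uniform(rng, (cout, cin, k, k), fan_in), requires_grad=True)
        self.bias = Tensor(np.zeros(cout), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)

    def parameters(self):
        return [self.weight, self.bias]

    def n_params(self) -> int:
        return self.weight.data.size + self.bias.data.size


class BatchNorm2d:
    """Per-channel batch normalization with running statistics."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        c = x.data.shape[1]
        if training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            xc = x - mu
            var = (xc * xc).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(c))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(c))
            xhat = xc * (var + self.eps).pow(-0.5)
        else:
            mu = self.running_mean.reshape(1, c, 1, 1)
            sd = np.sqrt(self.running_var + self.eps).reshape(1, c, 1, 1)
            xhat = (x - mu) * (1.0 / sd)
        return xhat * self.gamma.reshape(1, c, 1, 1) + self.beta.reshape(1, c, 1, 1)

    def parameters(self):
        return [self.gamma, self.beta]

    def n_params(self) -> int:
        return self.gamma.data.size + self.beta.data.size


class Dropout:
    """Inverted dropout; identity in eval mode."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"dropout rate must be in [0,1), got {rate}")
        self.rate = rate

    def __call__(self, x: Tensor, training: bool, rng: np.random.Generator) -> Tensor:
        if not training or self.rate == 0.0:
            return x
        keep = 1.0 - self.rate
        mask = (rng.random(x.data.shape) < keep) / keep
        return x * Tensor(mask)


class Adam:
    """Adaptive-moment optimizer."""

    def __init__(self, params: list, lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad ** 2
            mhat = self.m[i] / (1 - b1 ** self.t)
            vhat = self.v[i] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
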