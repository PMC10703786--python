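"""Minimal reverse-mode autodiff and neural-network layers on NumPy.

The engine is tape-based: every operation records its parents and a
closure that accumulates gradients into them. Convolutions are lowered
to k*k shifted channel-last GEMMs, and the weight/input gradients reuse
the same loop in transposed form, so both passes run through BLAS.
Parameters are float32; tensors built from float64 arrays stay float64,
which the numerical-equivalence tests rely on.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "Linear",
    "ConvBlock",
    "Adam",
    "concat",
    "stack",
    "softmax",
    "maxpool2x2",
    "upsample_bilinear",
    "channel_mean",
    "channel_max",
    "as_tensor",
]

_DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of NumPy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A NumPy array plus the bookkeeping needed for backpropagation."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False, parents=(), backward=None):
        data = np.asarray(data)
        if data.dtype != np.float64:  # float64 kept for high-precision use
            data = data.astype(_DTYPE, copy=False)
        self.data = data
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # ---- basic introspection -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # ---- graph walk ----------------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        order = _toposort(self)
        self.grad = np.asarray(grad, dtype=self.data.dtype)
        for node in order:
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(grad, dtype=self.data.dtype, copy=True)
        else:
            self.grad += grad

    # ---- operators -----------------------------------------------------------
    def __add__(self, other):
        return add(self, other)

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, other)

    __rmul__ = __mul__

    def __neg__(self):
        return mul(self, -1.0)

    def __sub__(self, other):
        return add(self, -as_tensor(other))

    def __rsub__(self, other):
        return add(as_tensor(other), -self)

    def __truediv__(self, other):
        other = as_tensor(other)
        return mul(self, power(other, -1.0))

    def __rtruediv__(self, other):
        return as_tensor(other) / self

    def __pow__(self, exponent):
        return power(self, exponent)

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis=axis, keepdims=keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis=axis, keepdims=keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _toposort(root: Tensor) -> list[Tensor]:
    order: list[Tensor] = []
    visited: set[int] = set()
    stack: list[tuple[Tensor, bool]] = [(root, False)]
    while stack:
        node, processed = stack.pop()
        if processed:
            order.append(node)
            continue
        if id(node) in visited:
            continue
        visited.add(id(node))
        stack.append((node, True))
        for p in node._parents:
            if id(p) not in visited:
                stack.append((p, False))
    order.reverse()
    return order


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _needs(*tensors: Tensor) -> bool:
    return any(t.requires_grad for t in tensors)


# ---- elementwise ops ---------------------------------------------------------

def add(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data + b.data
    if not _needs(a, b):
        return Tensor(out_data)

    def backward(grad):
        if a.requires_grad or a._backward:
            a.accumulate(_unbroadcast(grad, a.data.shape))
        if b.requires_grad or b._backward:
            b.accumulate(_unbroadcast(grad, b.data.shape))

    return Tensor(out_data, True, (a, b), backward)


def mul(a, b) -> Tensor:
    a, b = as_tensor(a), as_tensor(b)
    out_data = a.data * b.data
    if not _needs(a, b):
        return Tensor(out_data)

    def backward(grad):
        if a.requires_grad or a._backward:
            a.accumulate(_unbroadcast(grad * b.data, a.data.shape))
        if b.requires_grad or b._backward:
            b.accumulate(_unbroadcast(grad * a.data, b.data.shape))

    return Tensor(out_data, True, (a, b), backward)


def power(a, exponent: float) -> Tensor:
    a = as_tensor(a)
    out_data = np.power(a.data, exponent)
    if not _needs(a):
        return Tensor(out_data)

    def backward(grad):
        a.accumulate(_unbroadcast(grad * exponent * np.power(a.data, exponent - 1.0), a.data.shape))

    return Tensor(out_data, True, (a,), backward)


def log(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.log(a.data)
    if not _needs(a):
        return Tensor(out_data)

    def backward(grad):
        a.accumulate(grad / a.data)

    return Tensor(out_data, True, (a,), backward)


def exp(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.exp(a.data)
    if not _needs(a):
        return Tensor(out_data)

    def backward(grad):
        a.accumulate(grad * out_data)

    return Tensor(out_data, True, (a,), backward)


def relu(a) -> Tensor:
    a = as_tensor(a)
    out_data = np.maximum(a.data, 0)
    if not _needs(a):
        return Tensor(out_data)
    mask = a.data > 0

    def backward(grad):
        a.accumulate(grad * mask)

    return Tensor(out_data, True, (a,), backward)


def sigmoid(a) -> Tensor:
    a = as_tensor(a)
    # numerically stable logistic
    out_data = np.empty_like(a.data)
    pos = a.data >= 0
    out_data[pos] = 1.0 / (1.0 + np.exp(-a.data[pos]))
    ex = np.exp(a.data[~pos])
    out_data[~pos] = ex / (1.0 + ex)
    if not _needs(a):
        return Tensor(out_data)

    def backward(grad):
        a.accumulate(grad * out_data * (1.0 - out_data))

    return Tensor(out_data, True, (a,), backward)


def clip(a, lo: float, hi: float) -> Tensor:
    """Clamp values; gradient passes only through the un-clamped region."""
    a = as_tensor(a)
    out_data = np.clip(a.data, lo, hi)
    if not _needs(a):
        return Tensor(out_data)
    mask = (a.data > lo) & (a.data < hi)

    def backward(grad):
        a.accumulate(grad * mask)

    return Tensor(out_data, True, (a,), backward)


# ---- reductions / shaping ----------------------------------------------------

def tsum(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.sum(axis=axis, keepdims=keepdims)
    if not _needs(a):
        return Tensor(out_data)

    def backward(grad):
        g = grad
        if axis is not None and not keepdims:
            axes = axis if isinstance(axis, tuple) else (axis,)
            g = np.expand_dims(g, tuple(ax % a.data.ndim for ax in axes))
        a.accumulate(np.broadcast_to(g, a.data.shape).astype(a.data.dtype))

    return Tensor(out_data, True, (a,), backward)


def tmean(a, axis=None, keepdims=False) -> Tensor:
    a = as_tensor(a)
    if axis is None:
        n = a.data.size
    else:
        axes = axis if isinstance(axis, tuple) else (axis,)
        n = int(np.prod([a.data.shape[ax] for ax in axes]))
    return tsum(a, axis=axis, keepdims=keepdims) * (1.0 / n)


def reshape(a, shape) -> Tensor:
    a = as_tensor(a)
    out_data = a.data.reshape(shape)
    if not _needs(a):
        return Tensor(out_data)

    def backward(grad):
        a.accumulate(grad.reshape(a.data.shape))

    return Tensor(out_data, True, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(grad):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad or t._backward:
                idx = [slice(None)] * grad.ndim
                idx[axis] = slice(lo, hi)
                t.accumulate(grad[tuple(idx)])

    return Tensor(out_data, True, tuple(tensors), backward)


def stack(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.stack([t.data for t in tensors], axis=axis)
    if not any(t.requires_grad for t in tensors):
        return Tensor(out_data)

    def backward(grad):
        for i, t in enumerate(tensors):
            if t.requires_grad or t._backward:
                t.accumulate(np.take(grad, i, axis=axis))

    return Tensor(out_data, True, tuple(tensors), backward)


def softmax(a, axis: int) -> Tensor:
    """Softmax along `axis`; built from primitives, shift-invariance makes the
    detached max subtraction gradient-exact."""
    a = as_tensor(a)
    shift = Tensor(a.data.max(axis=axis, keepdims=True))
    e = exp(a - shift)
    return e / tsum(e, axis=axis, keepdims=True)


# ---- spatial ops -------------------------------------------------------------

def _conv2d_raw(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, pad: int) -> np.ndarray:
    """Stride-1 convolution as k*k shifted (C_in -> C_out) GEMMs.

    Channel-last layout keeps each shifted slice a BLAS-friendly matmul
    without materializing an im2col matrix.
    """
    n, c, h, wd = x.shape
    o, _, k, _ = w.shape
    xp = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x
    oh, ow = h + 2 * pad - k + 1, wd + 2 * pad - k + 1
    xr = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))  # N, Hp, Wp, C
    wr = w.transpose(2, 3, 1, 0)  # k, k, C, O
    acc = np.zeros((n, oh, ow, o), dtype=np.result_type(x, w))
    for dy in range(k):
        for dx in range(k):
            acc += xr[:, dy : dy + oh, dx : dx + ow, :] @ wr[dy, dx]
    if b is not None:
        acc += b
    return acc.transpose(0, 3, 1, 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int) -> Tensor:
    """Stride-1 2D convolution (cross-correlation), 'same' when pad=(k-1)/2."""
    out_data = _conv2d_raw(x.data, w.data, b.data if b is not None else None, pad)
    parents = (x, w) if b is None else (x, w, b)
    if not _needs(*parents):
        return Tensor(out_data)
    k = w.data.shape[2]

    def backward(grad):
        n, o, oh, ow = grad.shape
        _, c, h, wd = x.data.shape
        gr = np.ascontiguousarray(grad.transpose(0, 2, 3, 1)).reshape(-1, o)  # (N*OH*OW, O)
        if w.requires_grad or w._backward:
            xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
            xr = np.ascontiguousarray(xp.transpose(0, 2, 3, 1))
            gw = np.empty_like(w.data)
            for dy in range(k):
                for dx in range(k):
                    sl = np.ascontiguousarray(xr[:, dy : dy + oh, dx : dx + ow, :]).reshape(-1, c)
                    gw[:, :, dy, dx] = gr.T @ sl
            w.accumulate(gw)
        if b is not None and (b.requires_grad or b._backward):
            b.accumulate(grad.sum(axis=(0, 2, 3)))
        if x.requires_grad or x._backward:
            wr = w.data.transpose(2, 3, 1, 0)  # k, k, C, O
            gr4 = gr.reshape(n, oh, ow, o)
            gxp = np.zeros((n, h + 2 * pad, wd + 2 * pad, c), dtype=x.data.dtype)
            for dy in range(k):
                for dx in range(k):
                    gxp[:, dy : dy + oh, dx : dx + ow, :] += gr4 @ wr[dy, dx].T
            gx = gxp.transpose(0, 3, 1, 2)
            if pad:
                gx = gx[:, :, pad:-pad, pad:-pad]
            x.accumulate(np.ascontiguousarray(gx))

    return Tensor(out_data, True, parents, backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data
    if not _needs(a, b):
        return Tensor(out_data)

    def backward(grad):
        if a.requires_grad or a._backward:
            a.accumulate(grad @ b.data.T)
        if b.requires_grad or b._backward:
            b.accumulate(a.data.T @ grad)

    return Tensor(out_data, True, (a, b), backward)


def maxpool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    assert h % 2 == 0 and w % 2 == 0, "maxpool2x2 needs even spatial size"
    patches = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = patches.argmax(axis=-1)
    out_data = np.take_along_axis(patches, idx[..., None], axis=-1)[..., 0]
    if not _needs(x):
        return Tensor(out_data)

    def backward(grad):
        gpatches = np.zeros((n, c, h // 2, w // 2, 4), dtype=x.data.dtype)
        np.put_along_axis(gpatches, idx[..., None], grad[..., None], axis=-1)
        gx = gpatches.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x.accumulate(gx)

    return Tensor(out_data, True, (x,), backward)


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp_matrix(n_in: int, n_out: int) -> np.ndarray:
    """Row-stochastic 1-D bilinear interpolation matrix (half-pixel centers)."""
    key = (n_in, n_out)
    if key in _INTERP_CACHE:
        return _INTERP_CACHE[key]
    m = np.zeros((n_out, n_in), dtype=_DTYPE)
    src = (np.arange(n_out) + 0.5) * (n_in / n_out) - 0.5
    lo = np.clip(np.floor(src).astype(int), 0, n_in - 1)
    hi = np.clip(lo + 1, 0, n_in - 1)
    frac = np.clip(src - lo, 0.0, 1.0)
    m[np.arange(n_out), lo] += 1.0 - frac
    m[np.arange(n_out), hi] += frac
    _INTERP_CACHE[key] = m
    return m


def upsample_bilinear(x: Tensor, out_h: int, out_w: int) -> Tensor:
    """Bilinear resize expressed as two matrix products (exactly differentiable)."""
    n, c, h, w = x.data.shape
    if (h, w) == (out_h, out_w):
        return x
    mr = _interp_matrix(h, out_h)
    mc = _interp_matrix(w, out_w)
    out_data = np.einsum("oh,nchw,pw->ncop", mr, x.data, mc, optimize=True).astype(x.data.dtype)
    if not _needs(x):
        return Tensor(out_data)

    def backward(grad):
        gx = np.einsum("oh,ncop,pw->nchw", mr, grad, mc, optimize=True).astype(x.data.dtype)
        x.accumulate(gx)

    return Tensor(out_data, True, (x,), backward)


def channel_mean(x: Tensor) -> Tensor:
    """Mean over the channel axis, keepdims — used by spatial attention."""
    return tmean(x, axis=1, keepdims=True)


def channel_max(x: Tensor) -> Tensor:
    """Max over the channel axis, keepdims; gradient routed to the argmax."""
    x = as_tensor(x)
    idx = x.data.argmax(axis=1, keepdims=True)
    out_data = np.take_along_axis(x.data, idx, axis=1)
    if not _needs(x):
        return Tensor(out_data)

    def backward(grad):
        gx = np.zeros_like(x.data)
        np.put_along_axis(gx, idx, grad, axis=1)
        x.accumulate(gx)

    return Tensor(out_data, True, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    """(N,C,H,W) -> (N,C) global average pooling."""
    return tmean(x, axis=(2, 3))


# ---- modules -----------------------------------------------------------------

class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight parameter container with train/eval state."""

    def __init__(self):
        self.training = True

    @staticmethod
    def _walk(value, name):
        """Yield (name, Parameter|Module) pairs from arbitrarily nested containers."""
        if isinstance(value, (Parameter, Module)):
            yield name, value
        elif isinstance(value, (list, tuple)):
            for i, item in enumerate(value):
                yield from Module._walk(item, f"{name}.{i}")

    def modules(self):
        for name, value in self.__dict__.items():
            for _, item in Module._walk(value, name):
                if isinstance(item, Module):
                    yield item
                    yield from item.modules()

    def named_parameters(self, prefix: str = ""):
        for name, value in self.__dict__.items():
            for full, item in Module._walk(value, f"{prefix}{name}"):
                if isinstance(item, Parameter):
                    yield full, item
                else:
                    yield from item.named_parameters(f"{full}.")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def train(self):
        self.training = True
        for m in self.modules():
            m.training = True
        return self

    def eval(self):
        self.training = False
        for m in self.modules():
            m.training = False
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                state[f"__bn{i}.running_mean"] = m.running_mean.copy()
                state[f"__bn{i}.running_var"] = m.running_var.copy()
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=_DTYPE).reshape(p.data.shape)
        for i, m in enumerate(self.modules()):
            if isinstance(m, BatchNorm2d):
                m.running_mean = np.asarray(state[f"__bn{i}.running_mean"], dtype=_DTYPE)
                m.running_var = np.asarray(state[f"__bn{i}.running_var"], dtype=_DTYPE)
        return self


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator, pad: int | None = None):
        super().__init__()
        self.pad = (kernel - 1) // 2 if pad is None else pad
        fan_in = in_ch * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(out_ch, in_ch, kernel, kernel)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_ch, dtype=_DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.pad)


class Linear(Module):
    def __init__(self, in_f: int, out_f: int, rng: np.random.Generator):
        super().__init__()
        std = np.sqrt(2.0 / in_f)
        self.weight = Parameter(rng.normal(0.0, std, size=(in_f, out_f)).astype(_DTYPE))
        self.bias = Parameter(np.zeros(out_f, dtype=_DTYPE))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class BatchNorm2d(Module):
    def __init__(self, channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(channels, dtype=_DTYPE))
        self.beta = Parameter(np.zeros(channels, dtype=_DTYPE))
        self.running_mean = np.zeros(channels, dtype=_DTYPE)
        self.running_var = np.ones(channels, dtype=_DTYPE)

    def __call__(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mu = tmean(x, axis=(0, 2, 3), keepdims=True)
            var = tmean(power(x - mu, 2.0), axis=(0, 2, 3), keepdims=True)
            n = x.data.size / c
            self.running_mean = ((1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()).astype(_DTYPE)
            unbiased = var.data.ravel() * (n / max(n - 1, 1))
            self.running_var = ((1 - self.momentum) * self.running_var + self.momentum * unbiased).astype(_DTYPE)
        else:
            mu = Tensor(self.running_mean.reshape(shape))
            var = Tensor(self.running_var.reshape(shape))
        inv = power(var + self.eps, -0.5)
        return (x - mu) * inv * reshape(self.gamma, shape) + reshape(self.beta, shape)


class ConvBlock(Module):
    """Two (3x3 conv -> batch norm -> ReLU) units; spatial size preserved."""

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_ch, out_ch, 3, rng)
        self.bn1 = BatchNorm2d(out_ch)
        self.conv2 = Conv2d(out_ch, out_ch, 3, rng)
        self.bn2 = BatchNorm2d(out_ch)

    def __call__(self, x: Tensor) -> Tensor:
        x = relu(self.bn1(self.conv1(x)))
        return relu(self.bn2(self.conv2(x)))


class Adam:
    """Adam with the standard bias correction (beta1=0.9, beta2=0.999)."""

    def __init__(self, params: list[Parameter], lr: float = 3e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self):
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p.data -= (self.lr / bc1) * m / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None
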