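"""Minimal reverse-mode automatic differentiation on NumPy arrays.

This is the compute engine behind the segmentation generator and the domain
discriminators: a tape-based scalar-rooted autodiff over ``float32`` arrays
with exactly the operations the networks need (3x3/4x4 convolutions,
transposed convolution via zero-stuffing, 2x2 max pooling, batch/group
normalisation, pointwise nonlinearities and reductions), plus an Adam
optimiser whose ``step`` acts only on an explicitly named parameter subset so
the alternating training procedure can route updates to individual
sub-networks.

Convolutions are evaluated as im2col + BLAS matmul; the col2im scatter in the
backward pass loops over the (small, <=16) kernel taps with strided slice
adds, which keeps everything vectorised.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concat",
    "Conv2d",
    "ConvTranspose2d",
    "BatchNorm2d",
    "GroupNorm2d",
    "MaxPool2d",
    "Module",
    "Adam",
]


class Tensor:
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents
        self._backward = backward

    # -- introspection -----------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def numpy(self) -> np.ndarray:
        return self.data

    # -- backward ----------------------------------------------------------
    def backward(self):
        """Reverse-accumulate gradients from this (scalar) node."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(node):
            if id(node) in seen:
                return
            seen.add(id(node))
            for p in node._parents:
                visit(p)
            topo.append(node)

        visit(self)
        for node in topo:
            node.grad = None
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g):
        if self.grad is None:
            self.grad = g.copy() if isinstance(g, np.ndarray) else np.asarray(g)
        else:
            self.grad = self.grad + g

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other):
        return _binary(self, other, np.add, _add_back)

    __radd__ = __add__

    def __mul__(self, other):
        return _binary(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __sub__(self, other):
        return _binary(self, other, np.subtract, _sub_back)

    def __rsub__(self, other):
        return _binary(as_tensor(other), self, np.subtract, _sub_back)

    def __truediv__(self, other):
        return _binary(self, other, np.divide, _div_back)

    def __rtruediv__(self, other):
        return _binary(as_tensor(other), self, np.divide, _div_back)

    def __neg__(self):
        return self * (-1.0)

    def __pow__(self, p):
        if not np.isscalar(p):
            raise TypeError("only scalar exponents supported")
        out_data = self.data**p

        def back(g, a=self, p=p):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))

        return _node(out_data, (self,), back)

    # -- reductions / elementwise -----------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            gg = np.asarray(g)
            if axis is not None and not keepdims:
                gg = np.expand_dims(gg, axis)
            a._accum(np.broadcast_to(gg, a.data.shape))

        return _node(out_data, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def log(self):
        out_data = np.log(self.data)

        def back(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)

        return _node(out_data, (self,), back)

    def clip(self, lo, hi):
        out_data = np.clip(self.data, lo, hi)
        inside = (self.data > lo) & (self.data < hi)

        def back(g, a=self, inside=inside):
            if a.requires_grad:
                a._accum(g * inside)

        return _node(out_data, (self,), back)

    def relu(self):
        out_data = np.maximum(self.data, 0)

        def back(g, a=self, out_data=out_data):
            if a.requires_grad:
                a._accum(g * (out_data > 0))

        return _node(out_data, (self,), back)

    def leaky_relu(self, slope=0.2):
        pos = self.data > 0
        out_data = np.where(pos, self.data, slope * self.data)

        def back(g, a=self, pos=pos, slope=slope):
            if a.requires_grad:
                a._accum(g * np.where(pos, 1.0, slope).astype(g.dtype))

        return _node(out_data, (self,), back)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        p = x >= 0
        out_data[p] = 1.0 / (1.0 + np.exp(-x[p]))
        e = np.exp(x[~p])
        out_data[~p] = e / (1.0 + e)

        def back(g, a=self, y=out_data):
            if a.requires_grad:
                a._accum(g * y * (1.0 - y))

        return _node(out_data, (self,), back)

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def back(g, a=self):
            if a.requires_grad:
                a._accum(np.asarray(g).reshape(a.data.shape))

        return _node(out_data, (self,), back)


def _node(data, parents, back):
    req = any(p.requires_grad for p in parents)
    return Tensor(data, requires_grad=req, parents=tuple(p for p in parents), backward=back if req else None)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float64 if np.ndim(x) == 0 else None))


def _unbroadcast(g, shape):
    """Sum ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    g = np.asarray(g)
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binary(a, b, fn, back_fn):
    a, b = as_tensor(a), as_tensor(b)
    out_data = fn(a.data, b.data)

    def back(g):
        back_fn(g, a, b)

    return _node(out_data, (a, b), back)


def _add_back(g, a, b):
    if a.requires_grad:
        a._accum(_unbroadcast(g, a.data.shape))
    if b.requires_grad:
        b._accum(_unbroadcast(g, b.data.shape))


def _sub_back(g, a, b):
    if a.requires_grad:
        a._accum(_unbroadcast(g, a.data.shape))
    if b.requires_grad:
        b._accum(_unbroadcast(-g, b.data.shape))


def _mul_back(g, a, b):
    if a.requires_grad:
        a._accum(_unbroadcast(g * b.data, a.data.shape))
    if b.requires_grad:
        b._accum(_unbroadcast(g * a.data, b.data.shape))


def _div_back(g, a, b):
    if a.requires_grad:
        a._accum(_unbroadcast(g / b.data, a.data.shape))
    if b.requires_grad:
        b._accum(_unbroadcast(-g * a.data / (b.data**2), b.data.shape))


def concat(tensors, axis=1):
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        parts = np.split(np.asarray(g), splits, axis=axis)
        for t, p in zip(tensors, parts):
            if t.requires_grad:
                t._accum(p)

    return _node(out_data, tuple(tensors), back)


# ---------------------------------------------------------------------------
# convolution primitives
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, pad=1) -> Tensor:
    """2D cross-correlation. ``w``: (O, C, kh, kw); ``x``: (N, C, H, W).

    Evaluated as a sum over kernel taps of channel-mixing matmuls: each tap
    (i, j) contributes ``w[:, :, i, j] @ x_shifted`` via a batched GEMM.
    This keeps the data movement to cheap 2D reshapes.
    """
    n, c, h, wd = x.data.shape
    o, cw, kh, kw = w.data.shape
    if cw != c:
        raise ValueError(f"conv2d: input has {c} channels, weight expects {cw}")
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    hp, wp = xp.shape[2:]
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    if ho < 1 or wo < 1:
        raise ValueError(f"conv2d: input {h}x{wd} too small for kernel {kh}x{kw}")
    dtype = np.result_type(x.data, w.data)
    k2 = kh * kw
    cols = np.empty((n, c, k2, ho * wo), dtype=dtype)
    for i in range(kh):
        for j in range(kw):
            cols[:, :, i * kw + j, :] = xp[
                :, :, i : i + stride * ho : stride, j : j + stride * wo : stride
            ].reshape(n, c, ho * wo)
    cols = cols.reshape(n, c * k2, ho * wo)
    wmat = w.data.reshape(o, c * k2).astype(dtype, copy=False)
    out = np.matmul(wmat, cols)  # (n, o, ho*wo)
    if b is not None:
        out += b.data[None, :, None]
    out_data = out.reshape(n, o, ho, wo)

    def back(g):
        g3 = np.asarray(g).reshape(n, o, ho * wo)
        if b is not None and b.requires_grad:
            b._accum(g3.sum(axis=(0, 2)))
        if w.requires_grad:
            dW = np.matmul(g3, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dW.reshape(w.data.shape))
        if x.requires_grad:
            dcols = np.matmul(wmat.T, g3).reshape(n, c, k2, ho * wo)
            dxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i : i + stride * ho : stride, j : j + stride * wo : stride] += dcols[
                        :, :, i * kw + j, :
                    ].reshape(n, c, ho, wo)
            x._accum(dxp[:, :, pad : pad + h, pad : pad + wd] if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, back)


def dilate2d(x: Tensor, stride: int) -> Tensor:
    """Insert ``stride-1`` zeros between spatial elements (for transposed conv)."""
    if stride == 1:
        return x
    n, c, h, w = x.data.shape
    out_data = np.zeros((n, c, (h - 1) * stride + 1, (w - 1) * stride + 1), dtype=x.data.dtype)
    out_data[:, :, ::stride, ::stride] = x.data

    def back(g, a=x, stride=stride):
        if a.requires_grad:
            a._accum(np.asarray(g)[:, :, ::stride, ::stride])

    return _node(out_data, (x,), back)


def max_pool2d(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""
    n, c, h, w = x.data.shape
    v = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // 2, w // 2, 4)
    idx = v.argmax(axis=-1)
    out_data = np.take_along_axis(v, idx[..., None], axis=-1)[..., 0]

    def back(g, x=x, idx=idx, n=n, c=c, h=h, w=w):
        if not x.requires_grad:
            return
        gwin = np.zeros((n, c, h // 2, w // 2, 4), dtype=np.asarray(g).dtype)
        np.put_along_axis(gwin, idx[..., None], np.asarray(g)[..., None], axis=-1)
        dx = gwin.reshape(n, c, h // 2, w // 2, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        x._accum(dx)

    return _node(out_data, (x,), back)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


class Module:
    """Tiny module base: tracks parameters, sub-modules and train/eval mode."""

    def __init__(self):
        self.training = True

    def _children(self):
        for v in self.__dict__.values():
            if isinstance(v, Module):
                yield v
            elif isinstance(v, (list, tuple)):
                for u in v:
                    if isinstance(u, Module):
                        yield u

    def parameters(self) -> list[Tensor]:
        params = [v for v in self.__dict__.values() if isinstance(v, Tensor) and v.requires_grad]
        for child in self._children():
            params.extend(child.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        out = list(getattr(self, "_buffers", ()))
        for child in self._children():
            out.extend(child.buffers())
        return out

    def train(self, mode: bool = True):
        self.training = mode
        for child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None


def _init_conv_weight(rng: np.random.Generator, shape):
    # normal(0, 0.02): common adversarial-training initialisation
    return Tensor(rng.normal(0.0, 0.02, size=shape).astype(np.float32), requires_grad=True)


class Conv2d(Module):
    def __init__(self, in_ch, out_ch, kernel, stride=1, pad=0, rng=None, bias=True):
        super().__init__()
        self.stride, self.pad = stride, pad
        self.weight = _init_conv_weight(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x):
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class ConvTranspose2d(Module):
    """Transposed convolution as zero-stuffing followed by a stride-1 conv."""

    def __init__(self, in_ch, out_ch, kernel, stride, rng=None):
        super().__init__()
        self.kernel, self.stride = kernel, stride
        self.weight = _init_conv_weight(rng, (out_ch, in_ch, kernel, kernel))
        self.bias = Tensor(np.zeros(out_ch, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return conv2d(dilate2d(x, self.stride), self.weight, self.bias, stride=1, pad=self.kernel - 1)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        super().__init__()
        self.eps, self.momentum = eps, momentum
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self._buffers = (self.running_mean, self.running_var)

    def buffers(self):
        return [self.running_mean, self.running_var]

    def __call__(self, x: Tensor) -> Tensor:
        c = x.data.shape[1]
        if self.training:
            m = x.data.mean(axis=(0, 2, 3))
            v = x.data.var(axis=(0, 2, 3))
            self.running_mean += self.momentum * (m - self.running_mean)
            self.running_var += self.momentum * (v - self.running_var)
        else:
            m, v = self.running_mean, self.running_var
        invstd = 1.0 / np.sqrt(v + self.eps)
        xhat = (x.data - m[None, :, None, None]) * invstd[None, :, None, None]
        out_data = xhat * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
        training = self.training
        gamma, beta = self.gamma, self.beta

        def back(g, x=x, xhat=xhat, invstd=invstd):
            g = np.asarray(g)
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gi = gamma.data[None, :, None, None] * invstd[None, :, None, None]
                if training:
                    n = g.shape[0] * g.shape[2] * g.shape[3]
                    gsum = g.sum(axis=(0, 2, 3), keepdims=True)
                    gx = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
                    x._accum(gi * (g - gsum / n - xhat * gx / n))
                else:
                    x._accum(gi * g)

        return _node(out_data, (x, gamma, beta), back)


class GroupNorm2d(Module):
    """Per-sample group normalisation; batch-size-independent alternative to BN."""

    def __init__(self, channels, groups=None, eps=1e-5):
        super().__init__()
        if groups is None:
            groups = 4 if channels % 4 == 0 else 1
        if channels % groups:
            raise ValueError("channels must divide into groups")
        self.groups, self.eps = groups, eps
        self.gamma = Tensor(np.ones(channels, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=np.float32), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        n, c, h, w = x.data.shape
        gsz = c // self.groups
        xr = x.data.reshape(n, self.groups, gsz * h * w)
        m = xr.mean(axis=2, keepdims=True)
        v = xr.var(axis=2, keepdims=True)
        invstd = 1.0 / np.sqrt(v + self.eps)
        xhat = ((xr - m) * invstd).reshape(n, c, h, w)
        out_data = xhat * self.gamma.data[None, :, None, None] + self.beta.data[None, :, None, None]
        gamma, beta = self.gamma, self.beta

        def back(g, x=x, xhat=xhat, invstd=invstd):
            g = np.asarray(g)
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2, 3)))
            if beta.requires_grad:
                beta._accum(g.sum(axis=(0, 2, 3)))
            if x.requires_grad:
                gg = (g * gamma.data[None, :, None, None]).reshape(n, self.groups, gsz * h * w)
                xh = xhat.reshape(n, self.groups, gsz * h * w)
                m_ = gsz * h * w
                gsum = gg.sum(axis=2, keepdims=True)
                gx = (gg * xh).sum(axis=2, keepdims=True)
                dx = invstd * (gg - gsum / m_ - xh * gx / m_)
                x._accum(dx.reshape(n, c, h, w))

        return _node(out_data, (x, gamma, beta), back)


class MaxPool2d(Module):
    def __call__(self, x):
        return max_pool2d(x)


# ---------------------------------------------------------------------------
# optimiser
# ---------------------------------------------------------------------------


class Adam:
    """Adam with per-parameter state; ``step`` updates only the given subset.

    The alternating training procedure updates disjoint sub-networks in turn;
    restricting the update to the parameters named in each step guarantees
    that a parameter with no gradient (and no step call) never moves through
    stale momentum.
    """

    def __init__(self, params, lr, betas=(0.9, 0.999), eps=1e-8):
        self.lr, self.betas, self.eps = lr, betas, eps
        self._state: dict[int, tuple] = {}
        self._params = list(params)

    def step(self, params=None):
        b1, b2 = self.betas
        for p in self._params if params is None else params:
            if p.grad is None:
                continue
            g = p.grad.astype(p.data.dtype, copy=False)
            m, v, t = self._state.get(id(p), (np.zeros_like(p.data), np.zeros_like(p.data), 0))
            t += 1
            m = b1 * m + (1 - b1) * g
            v = b2 * v + (1 - b2) * g * g
            self._state[id(p)] = (m, v, t)
            mh = m / (1 - b1**t)
            vh = v / (1 - b2**t)
            p.data = p.data - self.lr * mh / (np.sqrt(vh) + self.eps)

    def zero_grad(self, params=None):
        for p in self._params if params is None else params:
            p.grad = None
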