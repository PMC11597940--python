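"""Minimal reverse-mode automatic differentiation over numpy arrays.

A :class:`Tensor` wraps an ``ndarray`` and records the operations that
produced it; :meth:`Tensor.backward` runs reverse-mode accumulation over
the recorded tape.  Only the operations needed by the segmentation
framework are provided (broadcast arithmetic, matmul, reductions,
activations, 2-D convolution, pooling, bilinear resize, batch
normalisation, channel softmax).  Everything is float32 by default and
fully deterministic.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "max_pool2d",
    "upsample_bilinear2d",
    "batch_norm2d",
    "softmax_channels",
]

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # ------------------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def __float__(self) -> float:
        return float(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    # ------------------------------------------------------------------
    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(DTYPE, copy=True)
        else:
            self.grad += grad

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss tensor")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
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

    # ------------------------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def __add__(self, other):
        other = self._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accumulate(
                    _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        out_data = self.data**exponent

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * exponent * self.data ** (exponent - 1))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                self._accumulate(g @ other.data.swapaxes(-1, -2))
            if other.requires_grad:
                other._accumulate(self.data.swapaxes(-1, -2) @ g)

        return self._make(out_data, (self, other), backward)

    # ------------------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accumulate(np.broadcast_to(g, self.data.shape))
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accumulate(np.broadcast_to(g, self.data.shape))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        out_data = self.data.reshape(shape)
        orig = self.data.shape

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.reshape(orig))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if not axes:
            axes = tuple(reversed(range(self.data.ndim)))
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------------
    def relu(self):
        mask = self.data > 0
        out_data = self.data * mask

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.2):
        factor = np.where(self.data > 0, 1.0, negative_slope).astype(DTYPE)
        out_data = self.data * factor

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * factor)

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        x = self.data
        out_data = np.empty_like(x)
        pos = x >= 0
        out_data[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
        ex = np.exp(x[~pos])
        out_data[~pos] = ex / (1.0 + ex)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g / self.data)

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * out_data)

        return self._make(out_data, (self,), backward)

    def clip(self, lo: float, hi: float):
        out_data = np.clip(self.data, lo, hi)
        mask = ((self.data > lo) & (self.data < hi)).astype(DTYPE)

        def backward(g):
            if self.requires_grad:
                self._accumulate(g * mask)

        return self._make(out_data, (self,), backward)


def as_tensor(x, requires_grad: bool = False) -> Tensor:
    if isinstance(x, Tensor):
        return x
    return Tensor(x, requires_grad=requires_grad)


def concatenate(tensors, axis: int = 0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            if t.requires_grad:
                t._accumulate(piece)

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out


# ----------------------------------------------------------------------
# Structured ops with hand-written backward passes (speed-critical path).
# ----------------------------------------------------------------------

def _sliding_windows(xp: np.ndarray, kh: int, kw: int, stride: int) -> np.ndarray:
    """View of padded input as (N, C, Ho, Wo, kh, kw)."""
    view = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    return view[:, :, ::stride, ::stride]


def conv2d(x: Tensor, weight: Tensor, bias: Tensor | None,
           stride: int = 1, padding: int = 0) -> Tensor:
    """2-D cross-correlation, NCHW layout, square stride/padding."""
    xd = x.data
    wd = weight.data
    n, c_in, h, w = xd.shape
    c_out, c_in_w, kh, kw = wd.shape
    if c_in != c_in_w:
        raise ValueError(f"conv2d channel mismatch: input {c_in}, weight {c_in_w}")
    if padding:
        xp = np.pad(xd, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    else:
        xp = xd
    view = _sliding_windows(xp, kh, kw, stride)
    ho, wo = view.shape[2], view.shape[3]
    # (N, Ho, Wo, C_out) <- (N,C,Ho,Wo,kh,kw) x (C_out,C,kh,kw)
    out = np.tensordot(view, wd, axes=([1, 4, 5], [1, 2, 3]))
    out = np.ascontiguousarray(out.transpose(0, 3, 1, 2))
    if bias is not None:
        out += bias.data[None, :, None, None]

    def backward(g):
        if weight.requires_grad:
            gw = np.tensordot(g, view, axes=([0, 2, 3], [0, 2, 3]))
            weight._accumulate(gw)
        if bias is not None and bias.requires_grad:
            bias._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gx_pad = np.zeros_like(xp)
            for dy in range(kh):
                for dx in range(kw):
                    # (N,Ho,Wo,C_in) contribution for this kernel offset
                    contrib = np.tensordot(g, wd[:, :, dy, dx], axes=([1], [0]))
                    gx_pad[:, :, dy:dy + ho * stride:stride,
                           dx:dx + wo * stride:stride] += contrib.transpose(0, 3, 1, 2)
            if padding:
                gx = gx_pad[:, :, padding:padding + h, padding:padding + w]
            else:
                gx = gx_pad
            x._accumulate(gx)

    out_t = Tensor(out)
    if x.requires_grad or weight.requires_grad or (bias is not None and bias.requires_grad):
        out_t.requires_grad = True
        out_t._parents = tuple(p for p in (x, weight, bias) if p is not None)
        out_t._backward = backward
    return out_t


def max_pool2d(x: Tensor, kernel: int = 2) -> Tensor:
    n, c, h, w = x.data.shape
    if h % kernel or w % kernel:
        raise ValueError("max_pool2d requires dimensions divisible by the kernel")
    ho, wo = h // kernel, w // kernel
    windows = x.data.reshape(n, c, ho, kernel, wo, kernel).transpose(0, 1, 2, 4, 3, 5)
    windows = windows.reshape(n, c, ho, wo, kernel * kernel)
    idx = windows.argmax(axis=-1)
    out = np.take_along_axis(windows, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        if not x.requires_grad:
            return
        gw = np.zeros((n, c, ho, wo, kernel * kernel), dtype=DTYPE)
        np.put_along_axis(gw, idx[..., None], g[..., None], axis=-1)
        gw = gw.reshape(n, c, ho, wo, kernel, kernel).transpose(0, 1, 2, 4, 3, 5)
        x._accumulate(gw.reshape(n, c, h, w))

    out_t = Tensor(out)
    if x.requires_grad:
        out_t.requires_grad = True
        out_t._parents = (x,)
        out_t._backward = backward
    return out_t


def _interp_matrix(n_out: int, n_in: int) -> np.ndarray:
    """Row-stochastic bilinear interpolation matrix (align_corners=False)."""
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    scale = n_in / n_out
    for i in range(n_out):
        src = (i + 0.5) * scale - 0.5
        src = min(max(src, 0.0), n_in - 1.0)
        lo = int(np.floor(src))
        hi = min(lo + 1, n_in - 1)
        frac = src - lo
        m[i, lo] += 1.0 - frac
        m[i, hi] += frac
    return m


_INTERP_CACHE: dict[tuple[int, int], np.ndarray] = {}


def _interp(n_out: int, n_in: int) -> np.ndarray:
    key = (n_out, n_in)
    if key not in _INTERP_CACHE:
        _INTERP_CACHE[key] = _interp_matrix(n_out, n_in)
    return _INTERP_CACHE[key]


def upsample_bilinear2d(x: Tensor, size: tuple[int, int]) -> Tensor:
    n, c, h, w = x.data.shape
    ho, wo = size
    a = _interp(ho, h)
    b = _interp(wo, w)
    # out[n,c,i,j] = sum_{h,w} A[i,h] x[n,c,h,w] B[j,w]
    out = np.einsum("ih,nchw,jw->ncij", a, x.data, b, optimize=True)

    def backward(g):
        if x.requires_grad:
            gx = np.einsum("ih,ncij,jw->nchw", a, g, b, optimize=True)
            x._accumulate(gx.astype(DTYPE))

    out_t = Tensor(out)
    if x.requires_grad:
        out_t.requires_grad = True
        out_t._parents = (x,)
        out_t._backward = backward
    return out_t


def batch_norm2d(x: Tensor, gamma: Tensor, beta: Tensor,
                 running_mean: np.ndarray, running_var: np.ndarray,
                 training: bool, momentum: float = 0.1,
                 eps: float = 1e-5) -> Tensor:
    xd = x.data
    n, c, h, w = xd.shape
    if training:
        mu = xd.mean(axis=(0, 2, 3))
        var = xd.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var
    else:
        mu = running_mean
        var = running_var
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def backward(g):
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            gscale = g * gamma.data[None, :, None, None]
            if training:
                m = n * h * w
                sum_g = gscale.sum(axis=(0, 2, 3))
                sum_gx = (gscale * xhat).sum(axis=(0, 2, 3))
                gx = (gscale - (sum_g[None, :, None, None]
                                + xhat * sum_gx[None, :, None, None]) / m)
                gx *= inv_std[None, :, None, None]
            else:
                gx = gscale * inv_std[None, :, None, None]
            x._accumulate(gx.astype(DTYPE))

    out_t = Tensor(out)
    if x.requires_grad or gamma.requires_grad or beta.requires_grad:
        out_t.requires_grad = True
        out_t._parents = (x, gamma, beta)
        out_t._backward = backward
    return out_t


def softmax_channels(x: Tensor) -> Tensor:
    """Softmax over axis 1 (channel axis) of an NCHW tensor."""
    shifted = x.data - x.data.max(axis=1, keepdims=True)
    e = np.exp(shifted)
    out = e / e.sum(axis=1, keepdims=True)

    def backward(g):
        if x.requires_grad:
            dot = (g * out).sum(axis=1, keepdims=True)
            x._accumulate(out * (g - dot))

    out_t = Tensor(out)
    if x.requires_grad:
        out_t.requires_grad = True
        out_t._parents = (x,)
        out_t._backward = backward
    return out_t
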