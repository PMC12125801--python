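"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operations needed by the segmentation models in
:mod:`msaunet.arch`: broadcast arithmetic, matmul, reductions, shape ops,
pointwise nonlinearities, stride-1 2-D convolution, pooling and bilinear
upsampling. All tensors are float32 unless constructed otherwise.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "concat",
    "conv2d",
    "avg_pool2d",
    "max_pool2d",
    "upsample_bilinear",
    "pad2d",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float32)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers ------------------------------------------------
    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(np.asarray(other, dtype=np.float32))

    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    # -- introspection -------------------------------------------------------
    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (_unbroadcast(g, self.shape), _unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __neg__(self):
        return self._make(-self.data, (self,), lambda g, out: (-g,))

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __mul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (
                _unbroadcast(g * other.data, self.shape),
                _unbroadcast(g * self.data, other.shape),
            )

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (
                _unbroadcast(g / other.data, self.shape),
                _unbroadcast(-g * self.data / (other.data ** 2), other.shape),
            )

        return self._make(self.data / other.data, (self, other), backward)

    def __rtruediv__(self, other):
        return self._wrap(other) / self

    def __pow__(self, exponent: float):
        e = float(exponent)

        def backward(g, out):
            return (g * e * self.data ** (e - 1),)

        return self._make(self.data ** e, (self,), backward)

    def __matmul__(self, other):
        other = self._wrap(other)

        def backward(g, out):
            return (g @ other.data.T, self.data.T @ g)

        return self._make(self.data @ other.data, (self, other), backward)

    # -- reductions ----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def backward(g, out):
            if axis is None:
                return (np.broadcast_to(g, self.shape).copy(),)
            gg = g
            if not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % self.ndim for a in ax)
                gg = np.expand_dims(g, ax)
            return (np.broadcast_to(gg, self.shape).copy(),)

        return self._make(self.data.sum(axis=axis, keepdims=keepdims), (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            ax = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.shape[a] for a in ax]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ---------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.shape

        def backward(g, out):
            return (g.reshape(old),)

        return self._make(self.data.reshape(shape), (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = tuple(np.argsort(axes))

        def backward(g, out):
            return (g.transpose(inv),)

        return self._make(self.data.transpose(axes), (self,), backward)

    # -- pointwise nonlinearities --------------------------------------------
    def relu(self):
        mask = self.data > 0

        def backward(g, out):
            return (g * mask,)

        return self._make(self.data * mask, (self,), backward)

    def sigmoid(self):
        d = self.data
        s = np.empty_like(d)
        pos = d >= 0
        s[pos] = 1.0 / (1.0 + np.exp(-d[pos]))
        e = np.exp(d[~pos])
        s[~pos] = e / (1.0 + e)
        # keep strictly inside (0,1): float saturation would break the
        # open-interval contract on attention weights and probabilities
        tiny = 1e-7 if self.data.dtype == np.float32 else 1e-12
        s = np.clip(s, tiny, 1.0 - tiny)

        def backward(g, out):
            return (g * s * (1.0 - s),)

        return self._make(s, (self,), backward)

    def exp(self):
        def backward(g, out):
            return (g * out.data,)

        return self._make(np.exp(self.data), (self,), backward)

    def log(self):
        def backward(g, out):
            return (g / self.data,)

        return self._make(np.log(self.data), (self,), backward)

    def sqrt(self):
        def backward(g, out):
            return (g * 0.5 / out.data,)

        return self._make(np.sqrt(self.data), (self,), backward)

    # -- autodiff driver -----------------------------------------------------
    def backward(self, grad: np.ndarray | None = None) -> None:
        if not self.requires_grad:
            raise RuntimeError("backward() on a tensor that does not require grad")
        if grad is None:
            if self.data.size != 1:
                raise RuntimeError("grad must be provided for non-scalar output")
            grad = np.ones_like(self.data)

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
                if p.requires_grad and id(p) not in seen:
                    stack.append((p, False))

        self.grad = grad.astype(self.data.dtype, copy=True)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad, node)
            for parent, g in zip(node._parents, grads):
                if not parent.requires_grad or g is None:
                    continue
                g = g.astype(parent.data.dtype, copy=False)
                if parent.grad is None:
                    parent.grad = g.copy()
                else:
                    parent.grad += g


class Parameter(Tensor):
    """A tensor registered as trainable by :class:`msaunet.nn.Module`."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------

def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g, out):
        return tuple(
            np.take(g, np.arange(offsets[i], offsets[i + 1]), axis=axis)
            for i in range(len(tensors))
        )

    return Tensor._make(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def pad2d(x: Tensor, pad_h: tuple[int, int], pad_w: tuple[int, int], value: float = 0.0) -> Tensor:
    (pt, pb), (pl, pr) = pad_h, pad_w
    H, W = x.shape[2], x.shape[3]

    def backward(g, out):
        return (g[:, :, pt:pt + H, pl:pl + W],)

    padded = np.pad(
        x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)), mode="constant", constant_values=value
    )
    return Tensor._make(padded, (x,), backward)


# ---------------------------------------------------------------------------
# convolution (stride 1)
# ---------------------------------------------------------------------------

def _conv_forward(x: np.ndarray, w: np.ndarray, b: np.ndarray | None, padding: int):
    """Shift-and-accumulate stride-1 cross-correlation.

    Returns (out, x_padded); the padded input is reused by the weight
    gradient. Much faster than im2col here: it avoids the large strided
    gather and leans on BLAS via tensordot per kernel offset.
    """
    cout, cin, kh, kw = w.shape
    if padding:
        x = np.pad(x, ((0, 0), (0, 0), (padding, padding), (padding, padding)))
    n, _, hp, wp = x.shape
    ho, wo = hp - kh + 1, wp - kw + 1
    out = np.zeros((n, cout, ho, wo), dtype=x.dtype)
    for i in range(kh):
        for j in range(kw):
            xs = x[:, :, i:i + ho, j:j + wo]
            out += np.tensordot(xs, w[:, :, i, j], axes=([1], [1])).transpose(0, 3, 1, 2)
    if b is not None:
        out += b[None, :, None, None]
    return out, x


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, padding: int = 0) -> Tensor:
    """2-D cross-correlation, stride 1, symmetric zero padding.

    x: (N, C_in, H, W); w: (C_out, C_in, kH, kW); b: (C_out,) or None.
    """
    cout, cin, kh, kw = w.shape
    out_data, xp = _conv_forward(x.data, w.data, None if b is None else b.data, padding)
    parents = (x, w) if b is None else (x, w, b)

    def backward(g, out):
        _, _, ho, wo = g.shape
        grad_w = np.empty_like(w.data)
        for i in range(kh):
            for j in range(kw):
                xs = xp[:, :, i:i + ho, j:j + wo]
                grad_w[:, :, i, j] = np.tensordot(g, xs, axes=([0, 2, 3], [0, 2, 3]))
        # grad wrt input: correlate g with spatially-flipped, channel-swapped kernel
        w_flip = np.ascontiguousarray(w.data[:, :, ::-1, ::-1].transpose(1, 0, 2, 3))
        grad_x, _ = _conv_forward(g, w_flip, None, kh - 1 - padding)
        if b is None:
            return (grad_x, grad_w)
        return (grad_x, grad_w, g.sum(axis=(0, 2, 3)))

    return Tensor._make(out_data, parents, backward)


# ---------------------------------------------------------------------------
# pooling / resampling
# ---------------------------------------------------------------------------

def avg_pool2d(x: Tensor, factor: int) -> Tensor:
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool factor {factor}")
    if factor > h or factor > w:
        raise ValueError(f"pool factor {factor} exceeds spatial dims {(h, w)}")
    view = x.data.reshape(n, c, h // factor, factor, w // factor, factor)
    out = view.mean(axis=(3, 5))

    def backward(g, out_t):
        gg = g[:, :, :, None, :, None] / (factor * factor)
        return (np.broadcast_to(gg, (n, c, h // factor, factor, w // factor, factor)).reshape(n, c, h, w).copy(),)

    return Tensor._make(out, (x,), backward)


def max_pool2d(x: Tensor, factor: int = 2) -> Tensor:
    n, c, h, w = x.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool factor {factor}")
    view = x.data.reshape(n, c, h // factor, factor, w // factor, factor)
    flat = view.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h // factor, w // factor, factor * factor)
    idx = flat.argmax(axis=-1)
    out = np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0]

    def backward(g, out_t):
        gflat = np.zeros_like(flat)
        np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
        gx = gflat.reshape(n, c, h // factor, w // factor, factor, factor)
        gx = gx.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, h, w)
        return (np.ascontiguousarray(gx),)

    return Tensor._make(out, (x,), backward)


def _linear_resample_indices(size_in: int, size_out: int):
    """align_corners=False source indices/weights for 1-D linear interpolation."""
    scale = size_in / size_out
    src = (np.arange(size_out) + 0.5) * scale - 0.5
    src = np.clip(src, 0, size_in - 1)
    lo = np.floor(src).astype(np.int64)
    hi = np.minimum(lo + 1, size_in - 1)
    frac = (src - lo).astype(np.float32)
    return lo, hi, frac


def upsample_bilinear(x: Tensor, size: tuple[int, int]) -> Tensor:
    n, c, h, w = x.shape
    ho, wo = size
    r0, r1, rf = _linear_resample_indices(h, ho)
    c0, c1, cf = _linear_resample_indices(w, wo)
    rf = rf[:, None]
    cf = cf[None, :]

    d = x.data
    top = d[:, :, r0][:, :, :, c0] * (1 - cf) + d[:, :, r0][:, :, :, c1] * cf
    bot = d[:, :, r1][:, :, :, c0] * (1 - cf) + d[:, :, r1][:, :, :, c1] * cf
    out = top * (1 - rf) + bot * rf

    def backward(g, out_t):
        gx = np.zeros((n, c, h, w), dtype=g.dtype)
        for rows, rw in ((r0, 1 - rf), (r1, rf)):
            for cols_, cw in ((c0, 1 - cf), (c1, cf)):
                contrib = g * rw * cw
                np.add.at(gx, (slice(None), slice(None), rows[:, None], cols_[None, :]), contrib)
        return (gx,)

    return Tensor._make(out.astype(d.dtype), (x,), backward)
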