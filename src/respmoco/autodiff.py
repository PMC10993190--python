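"""Minimal reverse-mode automatic differentiation over numpy arrays.

The end-to-end training of the motion-estimation and denoising networks
needs gradients through 3D convolutions, trilinear warping (with respect to
both the image and the displacement field), scaling-and-squaring, the
unitary FFT and an unrolled conjugate-gradient solve.  This module provides
a small tape: a :class:`Tensor` wraps a real-valued numpy array, operations
record a backward closure, and :meth:`Tensor.backward` accumulates
gradients in reverse topological order.

Complex images are represented as two real channels throughout, so every
node in the graph is real and the usual real-linear adjoint rules apply;
the FFT primitives move to the complex domain internally and come back.
The heavy primitives (convolution via im2col GEMM, warping, resampling)
have hand-written gradients; everything else is composed from elementwise
arithmetic and reductions.

Gradients follow the convention ``grad = dL/dx`` for a scalar loss ``L``.
"""

from __future__ import annotations

import numpy as np

from . import motion as _motion
from .phantom import fft3c as _fft3c, ifft3c as _ifft3c

__all__ = [
    "Tensor",
    "no_grad",
    "constant",
    "parameter",
    "concat",
    "stack",
    "leaky_relu",
    "sqrt",
    "conv3d",
    "avg_pool2",
    "upsample2",
    "warp",
    "fft3c_pair",
    "ifft3c_pair",
    "complex_mul",
    "sample_rows",
    "scatter_rows",
    "pair_to_complex",
    "complex_to_pair",
]

_GRAD_ENABLED = True


class no_grad:
    """Context manager disabling tape construction (inference mode)."""

    def __enter__(self):
        global _GRAD_ENABLED
        self._prev = _GRAD_ENABLED
        _GRAD_ENABLED = False

    def __exit__(self, *exc):
        global _GRAD_ENABLED
        _GRAD_ENABLED = self._prev
        return False


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad = None
        self.requires_grad = bool(requires_grad) and _GRAD_ENABLED
        self._backward = None
        self._parents = ()

    # -- graph plumbing ------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def dtype(self):
        return self.data.dtype

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accumulate(grad)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    def zero_grad(self):
        self.grad = None

    def item(self) -> float:
        return float(self.data)

    # -- arithmetic ----------------------------------------------------------

    def __add__(self, other):
        return _binary(self, other, lambda a, b: a + b,
                       lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return _binary(self, other, lambda a, b: a - b,
                       lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return _binary(self, other, lambda a, b: b - a,
                       lambda g, a, b: -g, lambda g, a, b: g)

    def __mul__(self, other):
        return _binary(self, other, lambda a, b: a * b,
                       lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return _binary(self, other, lambda a, b: a / b,
                       lambda g, a, b: g / b, lambda g, a, b: -g * a / (b * b))

    def __neg__(self):
        return self * (-1.0)

    def __getitem__(self, idx):
        out = _node(self.data[idx], (self,))
        if out.requires_grad:
            def bwd(g, idx=idx, self=self):
                full = np.zeros_like(self.data)
                np.add.at(full, idx, g)
                self._accumulate(full)
            out._backward = bwd
        return out

    def reshape(self, *shape):
        out = _node(self.data.reshape(*shape), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(g.reshape(self.data.shape))
        return out

    def sum(self):
        out = _node(np.asarray(self.data.sum()), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.broadcast_to(g, self.data.shape))
        return out

    def mean(self):
        n = self.data.size
        out = _node(np.asarray(self.data.mean()), (self,))
        if out.requires_grad:
            out._backward = lambda g: self._accumulate(np.broadcast_to(g / n, self.data.shape))
        return out


def _node(data, parents) -> Tensor:
    t = Tensor.__new__(Tensor)
    t.data = np.asarray(data)
    t.grad = None
    t._backward = None
    parents = tuple(p for p in parents if isinstance(p, Tensor))
    t.requires_grad = _GRAD_ENABLED and any(p.requires_grad for p in parents)
    t._parents = parents if t.requires_grad else ()
    return t


def _unbroadcast(g, shape):
    """Reduce a gradient to the shape it was broadcast from."""
    extra = g.ndim - len(shape)
    if extra > 0:
        g = g.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and g.shape[i] != 1)
    if axes:
        g = g.sum(axis=axes, keepdims=True)
    return g


def _binary(a, b, fwd, bwd_a, bwd_b):
    a_t = a if isinstance(a, Tensor) else None
    b_t = b if isinstance(b, Tensor) else None
    av = a.data if a_t is not None else np.asarray(a)
    bv = b.data if b_t is not None else np.asarray(b)
    out = _node(fwd(av, bv), (a_t, b_t))
    if out.requires_grad:
        def bwd(g):
            if a_t is not None and a_t.requires_grad:
                a_t._accumulate(_unbroadcast(np.asarray(bwd_a(g, av, bv)), av.shape))
            if b_t is not None and b_t.requires_grad:
                b_t._accumulate(_unbroadcast(np.asarray(bwd_b(g, av, bv)), bv.shape))
        out._backward = bwd
    return out


def constant(data) -> Tensor:
    return Tensor(np.asarray(data), requires_grad=False)


def parameter(data) -> Tensor:
    return Tensor(np.array(data, copy=True), requires_grad=True)


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else constant(x)


# ---------------------------------------------------------------------------
# structural ops
# ---------------------------------------------------------------------------


def concat(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        def bwd(g):
            ofs = 0
            for t, n in zip(tensors, sizes):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(ofs, ofs + n)
                    t._accumulate(g[tuple(sl)])
                ofs += n
        out._backward = bwd
    return out


def stack(tensors, axis=0) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.stack([t.data for t in tensors], axis=axis), tuple(tensors))
    if out.requires_grad:
        def bwd(g):
            for i, t in enumerate(tensors):
                if t.requires_grad:
                    t._accumulate(np.take(g, i, axis=axis))
        out._backward = bwd
    return out


def leaky_relu(x: Tensor, alpha: float = 0.1) -> Tensor:
    x = as_tensor(x)
    mask = x.data >= 0
    out = _node(np.where(mask, x.data, alpha * x.data), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(np.where(mask, g, alpha * g))
    return out


def sqrt(x: Tensor) -> Tensor:
    x = as_tensor(x)
    root = np.sqrt(x.data)
    out = _node(root, (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(g * 0.5 / root)
    return out


# ---------------------------------------------------------------------------
# convolution and resampling
# ---------------------------------------------------------------------------


def _im2col(x: np.ndarray, k: int = 3):
    """(C, X, Y, Z) -> (C*k^3, X*Y*Z) patch matrix with same-padding."""
    p = k // 2
    xp = np.pad(x, ((0, 0), (p, p), (p, p), (p, p)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (k, k, k), axis=(1, 2, 3))
    c, X, Y, Z = x.shape
    return win.transpose(0, 4, 5, 6, 1, 2, 3).reshape(c * k ** 3, X * Y * Z)


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padding stride-1 3D convolution (cross-correlation).

    ``x`` is (C_in, X, Y, Z), ``w`` is (C_out, C_in, k, k, k) with odd
    ``k``, ``b`` is (C_out,).
    """
    x, w = as_tensor(x), as_tensor(w)
    co, ci, k = w.data.shape[0], w.data.shape[1], w.data.shape[2]
    spatial = x.data.shape[1:]
    cols = _im2col(x.data, k)
    w2 = w.data.reshape(co, ci * k ** 3)
    out_v = (w2 @ cols).reshape(co, *spatial)
    if b is not None:
        b = as_tensor(b)
        out_v = out_v + b.data.reshape(co, 1, 1, 1)
    out = _node(out_v, (x, w, b))
    if out.requires_grad:
        def bwd(g):
            g2 = g.reshape(co, -1)
            if w.requires_grad:
                w._accumulate((g2 @ cols.T).reshape(w.data.shape))
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(1, 2, 3)))
            if x.requires_grad:
                # grad wrt input: convolution of g with spatially flipped
                # kernels, in/out channels swapped
                wt = w.data[:, :, ::-1, ::-1, ::-1].transpose(1, 0, 2, 3, 4)
                gcols = _im2col(g, k)
                x._accumulate(
                    (wt.reshape(ci, co * k ** 3) @ gcols).reshape(x.data.shape)
                )
        out._backward = bwd
    return out


def avg_pool2(x: Tensor) -> Tensor:
    """2x average pooling over the three trailing (even-sized) axes."""
    x = as_tensor(x)
    c, X, Y, Z = x.data.shape
    v = x.data.reshape(c, X // 2, 2, Y // 2, 2, Z // 2, 2).mean(axis=(2, 4, 6))
    out = _node(v, (x,))
    if out.requires_grad:
        def bwd(g):
            gg = np.repeat(np.repeat(np.repeat(g, 2, 1), 2, 2), 2, 3) / 8.0
            x._accumulate(gg)
        out._backward = bwd
    return out


def _upsample1(v: np.ndarray, axis: int) -> np.ndarray:
    """Cell-centered linear x2 upsampling along one axis (edge clamped)."""
    v = np.moveaxis(v, axis, -1)
    lo = np.concatenate([v[..., :1], v[..., :-1]], axis=-1)
    hi = np.concatenate([v[..., 1:], v[..., -1:]], axis=-1)
    even = 0.75 * v + 0.25 * lo
    odd = 0.75 * v + 0.25 * hi
    out = np.stack([even, odd], axis=-1).reshape(*v.shape[:-1], 2 * v.shape[-1])
    return np.moveaxis(out, -1, axis)


def _upsample1_adj(g: np.ndarray, axis: int) -> np.ndarray:
    g = np.moveaxis(g, axis, -1)
    even = g[..., 0::2]
    odd = g[..., 1::2]
    out = 0.75 * (even + odd)
    # lo-neighbour contributions of 'even', hi-neighbour of 'odd'
    out[..., 0] += 0.25 * even[..., 0]
    out[..., :-1] += 0.25 * even[..., 1:]
    out[..., -1] += 0.25 * odd[..., -1]
    out[..., 1:] += 0.25 * odd[..., :-1]
    return np.moveaxis(out, -1, axis)


def upsample2(x: Tensor) -> Tensor:
    """Trilinear 2x upsampling of (C, X, Y, Z) over the spatial axes."""
    x = as_tensor(x)
    v = x.data
    for ax in (1, 2, 3):
        v = _upsample1(v, ax)
    out = _node(v, (x,))
    if out.requires_grad:
        def bwd(g):
            for ax in (3, 2, 1):
                g = _upsample1_adj(g, ax)
            x._accumulate(g)
        out._backward = bwd
    return out


def warp(vol: Tensor, disp: Tensor) -> Tensor:
    """Trilinear warp ``out(x) = vol(x + disp(x))``, differentiable in both.

    ``vol`` is (C, X, Y, Z) real, ``disp`` is (3, X, Y, Z) in voxels.
    """
    vol, disp = as_tensor(vol), as_tensor(disp)
    out = _node(_motion.warp(vol.data, disp.data), (vol, disp))
    if out.requires_grad:
        def bwd(g):
            if vol.requires_grad:
                vol._accumulate(_motion.warp_adjoint(g, disp.data))
            if disp.requires_grad:
                disp._accumulate(_motion.warp_grad_disp(vol.data, disp.data, g))
        out._backward = bwd
    return out


# ---------------------------------------------------------------------------
# complex-pair primitives (channel 0 = real, channel 1 = imaginary)
# ---------------------------------------------------------------------------


def pair_to_complex(x: np.ndarray) -> np.ndarray:
    """(..., 2, X, Y, Z) real pair -> (..., X, Y, Z) complex."""
    re = np.take(x, 0, axis=-4)
    im = np.take(x, 1, axis=-4)
    return re + 1j * im


def complex_to_pair(z: np.ndarray, dtype=None) -> np.ndarray:
    out = np.stack([z.real, z.imag], axis=-4)
    return out.astype(dtype) if dtype is not None else out


def fft3c_pair(x: Tensor) -> Tensor:
    """Unitary centered 3D FFT of a (..., 2, X, Y, Z) real/imag pair.

    Unitary, so the real-linear adjoint (= backward pass) is the inverse
    transform.  Leading axes are batched.
    """
    x = as_tensor(x)
    out = _node(complex_to_pair(_fft3c(pair_to_complex(x.data)), x.dtype), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(
            complex_to_pair(_ifft3c(pair_to_complex(g)), x.dtype)
        )
    return out


def ifft3c_pair(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(complex_to_pair(_ifft3c(pair_to_complex(x.data)), x.dtype), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(
            complex_to_pair(_fft3c(pair_to_complex(g)), x.dtype)
        )
    return out


def _cmul_pair(x: np.ndarray, s: np.ndarray) -> np.ndarray:
    re = np.take(x, 0, axis=-4)
    im = np.take(x, 1, axis=-4)
    return np.stack([re * s.real - im * s.imag, re * s.imag + im * s.real], axis=-4)


def complex_mul(x: Tensor, s: np.ndarray) -> Tensor:
    """Multiply a complex pair by a constant complex array.

    ``x`` is (..., 2, X, Y, Z) and ``s`` broadcasts against the complex
    view (..., X, Y, Z); the result broadcasts the leading axes (e.g. a
    single volume times per-coil maps gives a per-coil batch).
    """
    x = as_tensor(x)
    out_v = _cmul_pair(x.data, s)
    out = _node(out_v, (x,))
    if out.requires_grad:
        def bwd(g):
            gx = _cmul_pair(g, np.conj(s))
            x._accumulate(_unbroadcast(gx, x.data.shape))
        out._backward = bwd
    return out


def sum_axis0(x: Tensor) -> Tensor:
    """Sum over the leading axis (e.g. coil combination)."""
    x = as_tensor(x)
    out = _node(x.data.sum(axis=0), (x,))
    if out.requires_grad:
        out._backward = lambda g: x._accumulate(
            np.broadcast_to(g[None], x.data.shape)
        )
    return out


def sample_rows(k_pair: Tensor, flat_loc: np.ndarray, weights: np.ndarray) -> Tensor:
    """U of the encoding operator on a (..., 2, X, Y, Z) k-space pair.

    Gathers the (ky, kz) locations ``flat_loc`` (flattened over the two
    trailing axes) for every ``k_x`` and multiplies by the soft-gating
    weights; output is (..., 2, X, R).
    """
    k_pair = as_tensor(k_pair)
    *lead, X, Y, Z = k_pair.data.shape
    flat = k_pair.data.reshape(*lead, X, Y * Z)
    out = _node(flat[..., flat_loc] * weights, (k_pair,))
    if out.requires_grad:
        def bwd(g):
            gw = np.moveaxis(g * weights, -1, 0)  # (R, ..., X)
            acc = np.zeros((Y * Z, *lead, X), dtype=g.dtype)
            np.add.at(acc, flat_loc, gw)
            k_pair._accumulate(np.moveaxis(acc, 0, -1).reshape(k_pair.data.shape))
        out._backward = bwd
    return out


def scatter_rows(samples: Tensor, flat_loc: np.ndarray, weights: np.ndarray,
                 spatial: tuple[int, int, int]) -> Tensor:
    """U^T: weighted scatter of (..., 2, X, R) samples to (..., 2, X, Y, Z)."""
    samples = as_tensor(samples)
    X, Y, Z = spatial
    lead = samples.data.shape[:-1]
    sw = np.moveaxis(samples.data * weights, -1, 0)  # (R, ..., X)
    acc = np.zeros((Y * Z, *lead), dtype=samples.data.dtype)
    np.add.at(acc, flat_loc, sw)
    out = _node(np.moveaxis(acc, 0, -1).reshape(*lead, Y, Z), (samples,))
    if out.requires_grad:
        def bwd(g):
            flat = g.reshape(*lead, Y * Z)
            samples._accumulate(flat[..., flat_loc] * weights)
        out._backward = bwd
    return out
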