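"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the registration networks need:
N-dimensional strided convolution and transposed convolution, batch
normalisation, ReLU/Tanh, concatenation, reshape, a differentiable
trilinear vector-field resampling step (the building block of
scaling-and-squaring integration), and a masked mean-squared-error loss,
plus an Adam optimiser.  Everything is float32 and fully deterministic
given seeded initialisation.

The design is the usual dynamic tape: each :class:`Tensor` records its
parents and a closure that maps the output gradient to parent gradients;
``Tensor.backward`` walks the tape in reverse topological order.
"""

from __future__ import annotations

import itertools
import math
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "relu",
    "tanh",
    "add",
    "scale",
    "concat",
    "reshape",
    "conv_nd",
    "conv_transpose_nd",
    "batch_norm",
    "squaring_step",
    "masked_mse_loss",
    "Module",
    "ConvNd",
    "ConvTransposeNd",
    "BatchNorm",
    "Adam",
]


class Tensor:
    """Array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: np.ndarray,
        parents: tuple["Tensor", ...] = (),
        backward: Callable[[np.ndarray], tuple[np.ndarray | None, ...]] | None = None,
        requires_grad: bool = False,
    ) -> None:
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self._parents = parents if self.requires_grad else ()
        self._backward = backward if self.requires_grad else None

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is None or node.grad is None:
                continue
            grads = node._backward(node.grad)
            for parent, g in zip(node._parents, grads):
                if g is None or not parent.requires_grad:
                    continue
                if parent.grad is None:
                    parent.grad = g.astype(np.float32, copy=True)
                else:
                    parent.grad += g


class Parameter(Tensor):
    """Trainable tensor."""

    def __init__(self, data: np.ndarray) -> None:
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# elementwise / shape ops

def relu(x: Tensor) -> Tensor:
    out = np.maximum(x.data, 0.0)
    mask = x.data > 0
    return Tensor(out, (x,), lambda g: (g * mask,))


def tanh(x: Tensor) -> Tensor:
    out = np.tanh(x.data)
    return Tensor(out, (x,), lambda g: (g * (1.0 - out * out),))


def add(a: Tensor, b: Tensor) -> Tensor:
    return Tensor(a.data + b.data, (a, b), lambda g: (g, g))


def scale(x: Tensor, s: float) -> Tensor:
    return Tensor(x.data * s, (x,), lambda g: (g * s,))


def concat(tensors: Sequence[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g: np.ndarray):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor(data, tuple(tensors), backward)


def reshape(x: Tensor, shape: tuple[int, ...]) -> Tensor:
    old = x.data.shape
    return Tensor(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def replicate_border(x: Tensor, width: int = 2) -> Tensor:
    """Overwrite the outermost spatial band with the adjacent interior slice.

    Used as a boundary condition on predicted velocity fields: output
    voxels within ~2 voxels of the border of a 4/2/1 transposed-convolution
    stack receive reduced kernel support and, under a masked loss, no
    supervision, so their values are replaced by replication before
    integration.
    """
    nd = x.data.ndim - 2
    data = x.data.copy()
    full = [slice(None)] * data.ndim
    for ax in range(2, 2 + nd):
        for p in range(width):
            lo, lo_src = full.copy(), full.copy()
            hi, hi_src = full.copy(), full.copy()
            lo[ax], lo_src[ax] = p, width
            hi[ax], hi_src[ax] = -1 - p, -1 - width
            data[tuple(lo)] = data[tuple(lo_src)]
            data[tuple(hi)] = data[tuple(hi_src)]

    def backward(g: np.ndarray):
        g = g.copy()
        for ax in reversed(range(2, 2 + nd)):
            for p in range(width):
                lo, lo_src = full.copy(), full.copy()
                hi, hi_src = full.copy(), full.copy()
                lo[ax], lo_src[ax] = p, width
                hi[ax], hi_src[ax] = -1 - p, -1 - width
                g[tuple(lo_src)] += g[tuple(lo)]
                g[tuple(lo)] = 0
                g[tuple(hi_src)] += g[tuple(hi)]
                g[tuple(hi)] = 0
        return (g,)

    return Tensor(data, (x,), backward)


# ---------------------------------------------------------------------------
# convolutions

def _pad_spatial(x: np.ndarray, pad: int, mode: str = "zeros") -> np.ndarray:
    if pad == 0:
        return x
    width = [(0, 0), (0, 0)] + [(pad, pad)] * (x.ndim - 2)
    return np.pad(x, width, mode="edge" if mode == "edge" else "constant")


def _fold_edge_grad(dxp: np.ndarray, pad: int, axes: tuple[int, ...]) -> np.ndarray:
    """Adjoint of edge-replicate padding: fold pad-ring gradients onto the
    nearest interior voxels, one axis at a time (handles corners)."""
    for ax in axes:
        sl_lo = [slice(None)] * dxp.ndim
        sl_lo_t = [slice(None)] * dxp.ndim
        sl_hi = [slice(None)] * dxp.ndim
        sl_hi_t = [slice(None)] * dxp.ndim
        for p in range(pad):
            sl_lo[ax], sl_lo_t[ax] = p, pad
            sl_hi[ax], sl_hi_t[ax] = dxp.shape[ax] - 1 - p, dxp.shape[ax] - 1 - pad
            dxp[tuple(sl_lo_t)] += dxp[tuple(sl_lo)]
            dxp[tuple(sl_hi_t)] += dxp[tuple(sl_hi)]
    inner = tuple(
        slice(pad, -pad) if ax in axes else slice(None) for ax in range(dxp.ndim)
    )
    return dxp[inner]


def _offset_slices(offset: tuple[int, ...], stride: int, out_shape: tuple[int, ...]):
    return tuple(slice(o, o + stride * n, stride) for o, n in zip(offset, out_shape))


try:  # jitted 3D im2col / col2im feeding one BLAS GEMM: the decoder hot path
    from numba import njit as _njit_conv

    @_njit_conv(cache=True, fastmath=True)
    def _im2col3d_kernel(xl, k, s, o0, o1, o2, cols):  # pragma: no cover - jitted
        B = xl.shape[0]
        C = xl.shape[4]
        for b in range(B):
            n = 0
            for x in range(o0):
                for y in range(o1):
                    for z in range(o2):
                        f = 0
                        for c in range(C):
                            for kx in range(k):
                                for ky in range(k):
                                    for kz in range(k):
                                        cols[b, n, f] = xl[b, x * s + kx, y * s + ky, z * s + kz, c]
                                        f += 1
                        n += 1

    @_njit_conv(cache=True, fastmath=True)
    def _col2im3d_kernel(cols, k, s, o0, o1, o2, xl):  # pragma: no cover - jitted
        B = xl.shape[0]
        C = xl.shape[4]
        for b in range(B):
            n = 0
            for x in range(o0):
                for y in range(o1):
                    for z in range(o2):
                        f = 0
                        for c in range(C):
                            for kx in range(k):
                                for ky in range(k):
                                    for kz in range(k):
                                        xl[b, x * s + kx, y * s + ky, z * s + kz, c] += cols[b, n, f]
                                        f += 1
                        n += 1

    @_njit_conv(cache=True, fastmath=True)
    def _conv3d_s1_fwd(xp, w, out):  # pragma: no cover - jitted
        # channels-first stride-1: xp (B,Ci,Xp,Yp,Zp) padded, w (Co,Ci,k,k,k),
        # out (B,Co,X,Y,Z); the z loop is contiguous and vectorises.
        B, Co, X, Y, Z = out.shape
        Ci = xp.shape[1]
        k = w.shape[2]
        for b in range(B):
            for co in range(Co):
                for x in range(X):
                    for y in range(Y):
                        for z in range(Z):
                            out[b, co, x, y, z] = 0.0
                        for ci in range(Ci):
                            for kx in range(k):
                                for ky in range(k):
                                    for kz in range(k):
                                        wv = w[co, ci, kx, ky, kz]
                                        for z in range(Z):
                                            out[b, co, x, y, z] += wv * xp[b, ci, x + kx, y + ky, z + kz]

    @_njit_conv(cache=True, fastmath=True)
    def _conv3d_s1_bwd(xp, w, g, dxp, dw):  # pragma: no cover - jitted
        # accumulates dxp (padded) and dw from g (B,Co,X,Y,Z)
        B, Co, X, Y, Z = g.shape
        Ci = xp.shape[1]
        k = w.shape[2]
        for b in range(B):
            for co in range(Co):
                for ci in range(Ci):
                    for kx in range(k):
                        for ky in range(k):
                            for kz in range(k):
                                wv = w[co, ci, kx, ky, kz]
                                acc = 0.0
                                for x in range(X):
                                    for y in range(Y):
                                        for z in range(Z):
                                            gv = g[b, co, x, y, z]
                                            dxp[b, ci, x + kx, y + ky, z + kz] += wv * gv
                                            acc += gv * xp[b, ci, x + kx, y + ky, z + kz]
                                dw[co, ci, kx, ky, kz] += acc

    _HAVE_NUMBA_CONV = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA_CONV = False


def _im2col(xl: np.ndarray, k: int, stride: int, nd: int) -> np.ndarray:
    """Channels-last im2col: (B, *Sp, C) -> (B, *out, C, *K) windowed view
    subsampled by ``stride`` (caller reshapes, which copies)."""
    swv = np.lib.stride_tricks.sliding_window_view(xl, (k,) * nd, axis=tuple(range(1, 1 + nd)))
    sub = swv[(slice(None),) + (slice(None, None, stride),) * nd]
    return sub


def _pad_last(xl: np.ndarray, pad: int, nd: int, mode: str = "zeros") -> np.ndarray:
    if pad == 0:
        return xl
    width = [(0, 0)] + [(pad, pad)] * nd + [(0, 0)]
    return np.pad(xl, width, mode="edge" if mode == "edge" else "constant")


def conv_nd(x: Tensor, w: Tensor, stride: int, pad: int, pad_mode: str = "zeros") -> Tensor:
    """N-d convolution (cross-correlation), channels-first, no bias.

    ``x``: (B, Cin, *S); ``w``: (Cout, Cin, *K).  Implemented as an
    im2col matrix product so the work lands in one BLAS call.
    ``pad_mode`` is ``"zeros"`` or ``"edge"`` (replicate).
    """
    nd = x.data.ndim - 2
    k = w.data.shape[2]
    cin = w.data.shape[1]
    cout = w.data.shape[0]
    B = x.data.shape[0]
    out_shape = tuple((s + 2 * pad - k) // stride + 1 for s in x.data.shape[2:])
    N = int(np.prod(out_shape))
    F = cin * k**nd
    if _HAVE_NUMBA_CONV and nd == 3 and stride == 1:
        xp = _pad_spatial(np.ascontiguousarray(x.data), pad, pad_mode)
        out = np.empty((B, cout) + out_shape, dtype=np.float32)
        _conv3d_s1_fwd(xp, w.data, out)

        def backward_s1(g: np.ndarray):
            dxp = np.zeros_like(xp)
            dw = np.zeros_like(w.data)
            _conv3d_s1_bwd(xp, w.data, np.ascontiguousarray(g), dxp, dw)
            if pad:
                if pad_mode == "edge":
                    dxp = _fold_edge_grad(dxp, pad, (2, 3, 4))
                else:
                    dxp = dxp[(slice(None), slice(None)) + (slice(pad, -pad),) * nd]
            return dxp, dw

        return Tensor(out, (x, w), backward_s1)

    xl = _pad_last(np.ascontiguousarray(np.moveaxis(x.data, 1, -1)), pad, nd, pad_mode)
    use_jit = _HAVE_NUMBA_CONV and nd == 3
    if use_jit:
        cols = np.empty((B, N, F), dtype=np.float32)
        _im2col3d_kernel(xl, k, stride, *out_shape, cols)
        wf = np.ascontiguousarray(w.data.transpose(*range(1, nd + 2), 0)).reshape(F, cout)
        out = np.moveaxis((cols @ wf).reshape((B,) + out_shape + (cout,)), -1, 1)

        def backward_jit(g: np.ndarray):
            gm = np.ascontiguousarray(np.moveaxis(g, 1, -1)).reshape(B, N, cout)
            dwf = cols.reshape(B * N, F).T @ gm.reshape(B * N, cout)
            dw = dwf.reshape((cin,) + (k,) * nd + (cout,)).transpose(nd + 1, 0, *range(1, nd + 1))
            dcols = np.ascontiguousarray(gm @ wf.T)
            dxl = np.zeros_like(xl)
            _col2im3d_kernel(dcols, k, stride, *out_shape, dxl)
            if pad:
                if pad_mode == "edge":
                    dxl = _fold_edge_grad(dxl, pad, tuple(range(1, nd + 1)))
                else:
                    dxl = dxl[(slice(None),) + (slice(pad, -pad),) * nd + (slice(None),)]
            return np.moveaxis(dxl, -1, 1), dw

        return Tensor(out, (x, w), backward_jit)

    cols = np.ascontiguousarray(_im2col(xl, k, stride, nd)).reshape(B, N, F)
    wf = np.ascontiguousarray(w.data.transpose(*range(1, nd + 2), 0)).reshape(F, cout)
    out_mat = cols @ wf
    out = np.moveaxis(out_mat.reshape((B,) + out_shape + (cout,)), -1, 1)
    offsets = list(itertools.product(range(k), repeat=nd))

    def backward(g: np.ndarray):
        gm = np.ascontiguousarray(np.moveaxis(g, 1, -1)).reshape(B, N, cout)
        dwf = cols.reshape(B * N, F).T @ gm.reshape(B * N, cout)
        dw = dwf.reshape((cin,) + (k,) * nd + (cout,)).transpose(nd + 1, 0, *range(1, nd + 1))
        dcols = (gm @ wf.T).reshape((B,) + out_shape + (cin,) + (k,) * nd)
        dxl = np.zeros_like(xl)
        for off in offsets:
            sls = _offset_slices(off, stride, out_shape)
            dxl[(slice(None),) + sls + (slice(None),)] += dcols[
                (slice(None),) + (slice(None),) * nd + (slice(None),) + off
            ]
        if pad:
            if pad_mode == "edge":
                dxl = _fold_edge_grad(dxl, pad, tuple(range(1, nd + 1)))
            else:
                dxl = dxl[(slice(None),) + (slice(pad, -pad),) * nd + (slice(None),)]
        return np.moveaxis(dxl, -1, 1), dw

    return Tensor(out, (x, w), backward)


def conv_transpose_nd(x: Tensor, w: Tensor, stride: int, pad: int) -> Tensor:
    """N-d transposed convolution, channels-first, no bias.

    ``x``: (B, Cin, *S); ``w``: (Cin, Cout, *K).  Output spatial size is
    ``(S - 1) * stride - 2 * pad + K`` (= 2S for the 4/2/1 geometry).
    """
    nd = x.data.ndim - 2
    k = w.data.shape[2]
    cin, cout = w.data.shape[0], w.data.shape[1]
    B = x.data.shape[0]
    in_shape = x.data.shape[2:]
    out_shape = tuple((s - 1) * stride - 2 * pad + k for s in in_shape)
    N = int(np.prod(in_shape))
    kvol = k**nd
    xl = np.ascontiguousarray(np.moveaxis(x.data, 1, -1))
    padded_shape = tuple(o + 2 * pad for o in out_shape)
    mat = xl.reshape(B * N, cin)
    wf = w.data.reshape(cin, cout * kvol)
    use_jit = _HAVE_NUMBA_CONV and nd == 3
    if use_jit:
        cols = np.ascontiguousarray(mat @ wf).reshape(B, N, cout * kvol)
        outp = np.zeros((B,) + padded_shape + (cout,), dtype=np.float32)
        _col2im3d_kernel(cols, k, stride, *in_shape, outp)
        if pad:
            outp = outp[(slice(None),) + (slice(pad, -pad),) * nd + (slice(None),)]
        out = np.moveaxis(outp, -1, 1)

        def backward_jit(g: np.ndarray):
            gl = _pad_last(np.ascontiguousarray(np.moveaxis(g, 1, -1)), pad, nd)
            gcols = np.empty((B, N, cout * kvol), dtype=np.float32)
            _im2col3d_kernel(gl, k, stride, *in_shape, gcols)
            gm = gcols.reshape(B * N, cout * kvol)
            dx = np.moveaxis((gm @ wf.T).reshape((B,) + in_shape + (cin,)), -1, 1)
            dw = (mat.T @ gm).reshape((cin, cout) + (k,) * nd)
            return dx, dw

        return Tensor(out, (x, w), backward_jit)

    cols = (mat @ wf).reshape((B,) + in_shape + (cout,) + (k,) * nd)
    outp = np.zeros((B,) + padded_shape + (cout,), dtype=np.float32)
    offsets = list(itertools.product(range(k), repeat=nd))
    for off in offsets:
        sls = _offset_slices(off, stride, in_shape)
        outp[(slice(None),) + sls + (slice(None),)] += cols[
            (slice(None),) + (slice(None),) * nd + (slice(None),) + off
        ]
    if pad:
        outp = outp[(slice(None),) + (slice(pad, -pad),) * nd + (slice(None),)]
    out = np.moveaxis(outp, -1, 1)

    def backward(g: np.ndarray):
        gl = _pad_last(np.ascontiguousarray(np.moveaxis(g, 1, -1)), pad, nd)
        gcols = np.ascontiguousarray(_im2col(gl, k, stride, nd)).reshape(B * N, cout * kvol)
        dx = np.moveaxis((gcols @ wf.T).reshape((B,) + in_shape + (cin,)), -1, 1)
        dw = (mat.T @ gcols).reshape((cin, cout) + (k,) * nd)
        return dx, dw

    return Tensor(out, (x, w), backward)


# ---------------------------------------------------------------------------
# batch normalisation

def batch_norm(
    x: Tensor,
    gamma: Tensor,
    beta: Tensor,
    running_mean: np.ndarray,
    running_var: np.ndarray,
    training: bool,
    momentum: float = 0.1,
    eps: float = 1e-5,
) -> Tensor:
    """Batch normalisation over batch + spatial axes, channels-first.

    In training mode batch statistics are used and the running estimates
    updated in place; in evaluation mode the running statistics are used.
    """
    axes = (0,) + tuple(range(2, x.data.ndim))
    cshape = (1, -1) + (1,) * (x.data.ndim - 2)
    if training:
        mean = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        m = x.data.size // x.data.shape[1]
        running_mean *= 1 - momentum
        running_mean += momentum * mean
        running_var *= 1 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))
        ivar = 1.0 / np.sqrt(var + eps)
        xhat = (x.data - mean.reshape(cshape)) * ivar.reshape(cshape)
        out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

        def backward(g: np.ndarray):
            dgamma = (g * xhat).sum(axis=axes)
            dbeta = g.sum(axis=axes)
            gxsum = dgamma.reshape(cshape)
            gsum = dbeta.reshape(cshape)
            dx = (gamma.data.reshape(cshape) * ivar.reshape(cshape) / m) * (
                m * g - gsum - xhat * gxsum
            )
            return dx, dgamma, dbeta

        return Tensor(out, (x, gamma, beta), backward)

    ivar = 1.0 / np.sqrt(running_var + eps)
    xhat = (x.data - running_mean.reshape(cshape)) * ivar.reshape(cshape)
    out = gamma.data.reshape(cshape) * xhat + beta.data.reshape(cshape)

    def backward_eval(g: np.ndarray):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dx = g * (gamma.data * ivar).reshape(cshape)
        return dx, dgamma, dbeta

    return Tensor(out, (x, gamma, beta), backward_eval)


# ---------------------------------------------------------------------------
# differentiable trilinear resampling / scaling-and-squaring

try:  # numba compiles the scatter-heavy kernels; numpy fallback below
    from numba import njit as _njit

    @_njit(cache=True, fastmath=True)
    def _sq_fwd_kernel(disp, sp, out, i0, fr, inb):  # pragma: no cover - jitted
        B, _, D, H, W = disp.shape
        for b in range(B):
            n = 0
            for d in range(D):
                for h in range(H):
                    for w in range(W):
                        dims = (D, H, W)
                        coords = (d, h, w)
                        for a in range(3):
                            p = coords[a] + disp[b, a, d, h, w] / sp[a]
                            na = dims[a]
                            inb[b, a, n] = 1 if (p > 0.0 and p < na - 1) else 0
                            if p < 0.0:
                                p = 0.0
                            elif p > na - 1:
                                p = na - 1.0
                            ia = int(p)
                            if ia > na - 2:
                                ia = na - 2
                            i0[b, a, n] = ia
                            fr[b, a, n] = p - ia
                        f0, f1, f2 = fr[b, 0, n], fr[b, 1, n], fr[b, 2, n]
                        j0, j1, j2 = i0[b, 0, n], i0[b, 1, n], i0[b, 2, n]
                        for c in range(3):
                            v = 0.0
                            for c0 in range(2):
                                w0 = f0 if c0 else 1.0 - f0
                                for c1 in range(2):
                                    w1 = f1 if c1 else 1.0 - f1
                                    for c2 in range(2):
                                        w2 = f2 if c2 else 1.0 - f2
                                        v += w0 * w1 * w2 * disp[b, c, j0 + c0, j1 + c1, j2 + c2]
                            out[b, c, d, h, w] = v + disp[b, c, d, h, w]
                        n += 1

    @_njit(cache=True, fastmath=True)
    def _sq_bwd_kernel(disp, sp, g, i0, fr, inb, dd):  # pragma: no cover - jitted
        B, _, D, H, W = disp.shape
        for b in range(B):
            n = 0
            for d in range(D):
                for h in range(H):
                    for w in range(W):
                        f0, f1, f2 = fr[b, 0, n], fr[b, 1, n], fr[b, 2, n]
                        j0, j1, j2 = i0[b, 0, n], i0[b, 1, n], i0[b, 2, n]
                        g0 = g[b, 0, d, h, w]
                        g1 = g[b, 1, d, h, w]
                        g2 = g[b, 2, d, h, w]
                        dp0 = 0.0
                        dp1 = 0.0
                        dp2 = 0.0
                        for c0 in range(2):
                            w0 = f0 if c0 else 1.0 - f0
                            s0 = 1.0 if c0 else -1.0
                            for c1 in range(2):
                                w1 = f1 if c1 else 1.0 - f1
                                s1 = 1.0 if c1 else -1.0
                                for c2 in range(2):
                                    w2 = f2 if c2 else 1.0 - f2
                                    s2 = 1.0 if c2 else -1.0
                                    wgt = w0 * w1 * w2
                                    # scatter into the sampled field's gradient
                                    dd[b, 0, j0 + c0, j1 + c1, j2 + c2] += wgt * g0
                                    dd[b, 1, j0 + c0, j1 + c1, j2 + c2] += wgt * g1
                                    dd[b, 2, j0 + c0, j1 + c1, j2 + c2] += wgt * g2
                                    gv = (
                                        g0 * disp[b, 0, j0 + c0, j1 + c1, j2 + c2]
                                        + g1 * disp[b, 1, j0 + c0, j1 + c1, j2 + c2]
                                        + g2 * disp[b, 2, j0 + c0, j1 + c1, j2 + c2]
                                    )
                                    dp0 += s0 * w1 * w2 * gv
                                    dp1 += w0 * s1 * w2 * gv
                                    dp2 += w0 * w1 * s2 * gv
                        if inb[b, 0, n]:
                            dd[b, 0, d, h, w] += dp0 / sp[0]
                        if inb[b, 1, n]:
                            dd[b, 1, d, h, w] += dp1 / sp[1]
                        if inb[b, 2, n]:
                            dd[b, 2, d, h, w] += dp2 / sp[2]
                        dd[b, 0, d, h, w] += g0
                        dd[b, 1, d, h, w] += g1
                        dd[b, 2, d, h, w] += g2
                        n += 1

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - exercised only without numba
    _HAVE_NUMBA = False


def _gather_corners(field_flat: np.ndarray, i0: list[np.ndarray], f: list[np.ndarray], dims: tuple[int, int, int]):
    """Gather the 8 corner values and trilinear weights.

    ``field_flat``: (B, C, N); ``i0``/``f``: per-axis floor indices and
    fractions, each (B, N).  Returns corner values (8, B, C, N), weights
    (8, B, N) and the flat corner indices (8, B, N).
    """
    D, H, W = dims
    vals, weights, idxs = [], [], []
    for corner in itertools.product((0, 1), repeat=3):
        idx = ((i0[0] + corner[0]) * H + (i0[1] + corner[1])) * W + (i0[2] + corner[2])
        wgt = np.ones_like(f[0])
        for a in range(3):
            wgt = wgt * (f[a] if corner[a] else (1.0 - f[a]))
        vals.append(np.take_along_axis(field_flat, idx[:, None, :], axis=2))
        weights.append(wgt)
        idxs.append(idx)
    return vals, weights, idxs


def squaring_step(disp: Tensor, spacing: tuple[float, float, float], base: np.ndarray) -> Tensor:
    """One squaring: ``d <- d(v + d(v)) + d(v)`` with trilinear sampling.

    ``disp``: (B, 3, D, H, W) displacement in mm.  ``base`` is the dense
    voxel-index grid (3, D, H, W) (precomputed by the caller).  Sampling
    positions are edge clamped; the positional gradient is zeroed where the
    clamp is active.
    """
    if _HAVE_NUMBA:
        return _squaring_step_numba(disp, spacing)
    B = disp.data.shape[0]
    dims = disp.data.shape[2:]
    D, H, W = dims
    N = D * H * W
    sp = np.asarray(spacing, dtype=np.float32)
    flat = disp.data.reshape(B, 3, N)
    i0, frac, inb = [], [], []
    for a, n in enumerate(dims):
        p = base[a].reshape(1, N) + flat[:, a] / sp[a]
        inb.append((p > 0.0) & (p < n - 1))
        p = np.clip(p, 0.0, n - 1)
        ia = np.minimum(p.astype(np.int64), n - 2)
        i0.append(ia)
        frac.append((p - ia).astype(np.float32))
    vals, weights, idxs = _gather_corners(flat, i0, frac, dims)
    sampled = np.zeros_like(flat)
    for v, wgt in zip(vals, weights):
        sampled += wgt[:, None, :] * v
    out = (sampled + flat).reshape(disp.data.shape)

    def backward(g: np.ndarray):
        gf = g.reshape(B, 3, N)
        # gradient into the sampled field values: scatter w * g at corner idx
        chan = (np.arange(B, dtype=np.int64)[:, None, None] * 3 + np.arange(3, dtype=np.int64)[None, :, None]) * N
        dfield = np.zeros(B * 3 * N, dtype=np.float64)
        for wgt, idx in zip(weights, idxs):
            gi = (chan + idx[:, None, :]).ravel()
            dfield += np.bincount(gi, weights=(wgt[:, None, :] * gf).ravel(), minlength=B * 3 * N)
        dfield = dfield.reshape(B, 3, N).astype(np.float32)
        # gradient through the sampling positions
        dpos = np.zeros((B, 3, N), dtype=np.float32)  # per position axis
        for corner, (v, idx) in enumerate(zip(vals, idxs)):
            bits = (corner >> 2 & 1, corner >> 1 & 1, corner & 1)
            gv = (gf * v).sum(axis=1)  # (B, N)
            for a in range(3):
                others = [b for b in range(3) if b != a]
                wo = np.ones_like(frac[0])
                for b in others:
                    wo = wo * (frac[b] if bits[b] else (1.0 - frac[b]))
                sign = 1.0 if bits[a] else -1.0
                dpos[:, a] += sign * wo * gv
        ddisp = np.zeros_like(gf)
        for a in range(3):
            ddisp[:, a] = dpos[:, a] * inb[a] / sp[a]
        return ((dfield + ddisp).reshape(g.shape) + g,)

    return Tensor(out, (disp,), backward)


def _squaring_step_numba(disp: Tensor, spacing: tuple[float, float, float]) -> Tensor:
    B, _, D, H, W = disp.data.shape
    N = D * H * W
    sp = np.asarray(spacing, dtype=np.float32)
    out = np.empty_like(disp.data)
    i0 = np.empty((B, 3, N), dtype=np.int32)
    fr = np.empty((B, 3, N), dtype=np.float32)
    inb = np.empty((B, 3, N), dtype=np.uint8)
    _sq_fwd_kernel(disp.data, sp, out, i0, fr, inb)

    def backward(g: np.ndarray):
        dd = np.zeros_like(disp.data)
        _sq_bwd_kernel(disp.data, sp, np.ascontiguousarray(g), i0, fr, inb, dd)
        return (dd,)

    return Tensor(out, (disp,), backward)


def integrate_displacement(velocity: Tensor, T: int, spacing: tuple[float, float, float]) -> Tensor:
    """Differentiable scaling-and-squaring of a velocity tensor (mm)."""
    dims = velocity.data.shape[2:]
    base = np.stack(np.meshgrid(*(np.arange(n, dtype=np.float32) for n in dims), indexing="ij"))
    disp = scale(velocity, float(2.0 ** -T))
    for _ in range(T):
        disp = squaring_step(disp, spacing, base)
    return disp


def gradient_penalty(vel: Tensor) -> Tensor:
    """Mean squared forward difference of a field over its spatial axes.

    A weak Sobolev smoothness measure in (units per voxel)^2; used as an
    optional prior keeping predicted velocities in the smooth regime where
    scaling-and-squaring guarantees a diffeomorphism.
    """
    nd = vel.data.ndim - 2
    total = 0.0
    diffs = []
    count = 0
    for ax in range(2, 2 + nd):
        d = np.diff(vel.data, axis=ax)
        diffs.append((ax, d))
        total += float((d.astype(np.float64) ** 2).sum())
        count += d.size
    val = total / count

    def backward(g: np.ndarray):
        out = np.zeros_like(vel.data)
        for ax, d in diffs:
            gd = (2.0 / count) * d * g
            lo = [slice(None)] * vel.data.ndim
            hi = [slice(None)] * vel.data.ndim
            lo[ax] = slice(None, -1)
            hi[ax] = slice(1, None)
            out[tuple(lo)] -= gd
            out[tuple(hi)] += gd
        return (out,)

    return Tensor(np.float32(val), (vel,), backward)


def masked_mse_loss(pred: Tensor, label: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean squared error over (masked voxels x 3 components x batch)."""
    m = np.asarray(mask, dtype=np.float32)
    if m.sum() == 0:
        raise ValueError("masked MSE requires a non-empty mask")
    mb = m[None, None]  # broadcast over batch and component
    diff = (pred.data - label) * mb
    denom = float(pred.data.shape[0] * 3 * m.sum())
    val = float((diff.astype(np.float64) ** 2).sum() / denom)

    def backward(g: np.ndarray):
        return ((2.0 / denom) * diff * g,)

    return Tensor(np.float32(val), (pred,), backward)


# ---------------------------------------------------------------------------
# modules

class Module:
    """Composable layer container with recursive parameter discovery."""

    training = True

    def parameters(self) -> list[Parameter]:
        out: list[Parameter] = []
        for v in vars(self).values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def modules(self) -> list["Module"]:
        out: list[Module] = [self]
        for v in vars(self).values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, flag: bool = True) -> "Module":
        for m in self.modules():
            m.training = flag
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def num_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def walk(mod: Module, prefix: str) -> None:
            for name, v in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    out[key] = v.data
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    out[key] = v
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def walk(mod: Module, prefix: str) -> None:
            for name, v in vars(mod).items():
                key = f"{prefix}{name}"
                if isinstance(v, Parameter):
                    v.data = np.asarray(state[key], dtype=np.float32)
                elif isinstance(v, np.ndarray) and name.startswith("running_"):
                    v[...] = state[key]
                elif isinstance(v, Module):
                    walk(v, key + ".")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            walk(item, f"{key}.{i}.")

        walk(self, "")


def _kaiming(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return (rng.standard_normal(shape) * math.sqrt(2.0 / fan_in)).astype(np.float32)


class ConvNd(Module):
    """Strided convolution without bias (batch norm supplies the shift)."""

    def __init__(
        self,
        nd: int,
        cin: int,
        cout: int,
        k: int,
        stride: int,
        pad: int,
        rng: np.random.Generator,
        pad_mode: str = "zeros",
    ):
        self.stride, self.pad, self.pad_mode = stride, pad, pad_mode
        self.weight = Parameter(_kaiming(rng, (cout, cin) + (k,) * nd, cin * k**nd))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_nd(x, self.weight, self.stride, self.pad, self.pad_mode)


class ConvBias(Module):
    """Convolution with bias, for layers not followed by batch norm."""

    def __init__(
        self,
        nd: int,
        cin: int,
        cout: int,
        k: int,
        stride: int,
        pad: int,
        rng: np.random.Generator,
        pad_mode: str = "zeros",
    ):
        self.conv = ConvNd(nd, cin, cout, k, stride, pad, rng, pad_mode)
        self.bias = Parameter(np.zeros(cout, dtype=np.float32))

    def __call__(self, x: Tensor) -> Tensor:
        out = self.conv(x)
        cshape = (1, -1) + (1,) * (out.data.ndim - 2)
        b = self.bias
        return Tensor(
            out.data + b.data.reshape(cshape),
            (out, b),
            lambda g: (g, g.sum(axis=(0,) + tuple(range(2, g.ndim)))),
        )


class ConvTransposeNd(Module):
    def __init__(self, nd: int, cin: int, cout: int, k: int, stride: int, pad: int, rng: np.random.Generator):
        self.stride, self.pad = stride, pad
        self.weight = Parameter(_kaiming(rng, (cin, cout) + (k,) * nd, cin * k**nd))

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose_nd(x, self.weight, self.stride, self.pad)


class BatchNorm(Module):
    def __init__(self, c: int):
        self.gamma = Parameter(np.ones(c, dtype=np.float32))
        self.beta = Parameter(np.zeros(c, dtype=np.float32))
        self.running_mean = np.zeros(c, dtype=np.float32)
        self.running_var = np.ones(c, dtype=np.float32)

    def __call__(self, x: Tensor) -> Tensor:
        return batch_norm(x, self.gamma, self.beta, self.running_mean, self.running_var, self.training)


class Adam:
    """Adam optimiser with the standard moment defaults."""

    def __init__(self, params: Sequence[Parameter], lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1 - self.beta1**self.t
        b2t = 1 - self.beta2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
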