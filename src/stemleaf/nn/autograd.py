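"""Minimal reverse-mode autodiff on numpy arrays.

Provides exactly the operator set needed by the segmentation network and
its losses: broadcasting arithmetic, reductions, two-operand einsum,
softmax, 2-D convolution (stride 1, arbitrary dilation), 2x2 max pooling
and 2x bilinear upsampling.  Gradients accumulate into ``Tensor.grad``
after calling :meth:`Tensor.backward` on a scalar.

Arrays keep their floating dtype (float32 for training, float64 for
finite-difference gradient checks).
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "as_tensor",
    "concatenate",
    "conv2d",
    "einsum2",
    "maxpool2x2",
    "relu",
    "softmax",
    "upsample_bilinear2x",
]


def _to_array(x) -> np.ndarray:
    a = np.asarray(x)
    if a.dtype.kind in "iub":
        a = a.astype(np.float32)
    return a


class Tensor:
    """Array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _to_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- construction helpers -------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def zero_grad(self) -> None:
        self.grad = None

    def _accumulate(self, g: np.ndarray) -> None:
        if not self.requires_grad:
            return
        if self.grad is None:
            # copy: g may alias an upstream gradient buffer
            self.grad = np.array(g, dtype=self.data.dtype, copy=True)
        else:
            self.grad += g

    # -- graph traversal ------------------------------------------------------
    def backward(self, grad=None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
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
                if id(p) not in seen:
                    stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
            if node._parents:
                node.grad = None  # free intermediate gradients eagerly

    # -- arithmetic -----------------------------------------------------------
    def __add__(self, other):
        return _binop(self, other, np.add, _add_back)

    __radd__ = __add__

    def __mul__(self, other):
        return _binop(self, other, np.multiply, _mul_back)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-as_tensor(other))

    def __rsub__(self, other):
        return as_tensor(other) + (-self)

    def __truediv__(self, other):
        return self * (as_tensor(other) ** -1.0)

    def __rtruediv__(self, other):
        return as_tensor(other) * (self**-1.0)

    def __pow__(self, exponent: float):
        x = self
        out = _node(np.power(x.data, exponent), (x,))

        def back(g):
            x._accumulate(g * exponent * np.power(x.data, exponent - 1.0))

        out._backward = back
        return out

    def __getitem__(self, key):
        x = self
        out = _node(x.data[key], (x,))

        def back(g):
            full = np.zeros_like(x.data)
            np.add.at(full, key, g)
            x._accumulate(full)

        out._backward = back
        return out

    # -- reductions / reshaping ----------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        x = self
        out = _node(x.data.sum(axis=axis, keepdims=keepdims), (x,))

        def back(g):
            if axis is None:
                x._accumulate(np.broadcast_to(g, x.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            x._accumulate(np.broadcast_to(g, x.shape).copy())

        out._backward = back
        return out

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        x = self
        out = _node(x.data.reshape(*shape), (x,))

        def back(g):
            x._accumulate(g.reshape(x.shape))

        out._backward = back
        return out

    def transpose(self, axes):
        x = self
        inv = np.argsort(axes)
        out = _node(x.data.transpose(axes), (x,))

        def back(g):
            x._accumulate(g.transpose(inv))

        out._backward = back
        return out

    def broadcast_to(self, shape):
        x = self
        out = _node(np.broadcast_to(x.data, shape).copy(), (x,))

        def back(g):
            x._accumulate(_unbroadcast(g, x.shape))

        out._backward = back
        return out

    def __repr__(self):  # pragma: no cover
        return f"Tensor(shape={self.shape}, grad={self.requires_grad})"


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _node(data: np.ndarray, parents: tuple[Tensor, ...]) -> Tensor:
    out = Tensor(data)
    out._parents = tuple(p for p in parents if isinstance(p, Tensor))
    out.requires_grad = any(p.requires_grad for p in out._parents)
    return out


def _unbroadcast(g: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g


def _binop(a, b, fwd, make_back):
    a, b = as_tensor(a), as_tensor(b)
    out = _node(fwd(a.data, b.data), (a, b))
    out._backward = make_back(a, b)
    return out


def _add_back(a: Tensor, b: Tensor):
    def back(g):
        a._accumulate(_unbroadcast(g, a.shape))
        b._accumulate(_unbroadcast(g, b.shape))

    return back


def _mul_back(a: Tensor, b: Tensor):
    def back(g):
        a._accumulate(_unbroadcast(g * b.data, a.shape))
        b._accumulate(_unbroadcast(g * a.data, b.shape))

    return back


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    x = as_tensor(x)
    out = _node(np.maximum(x.data, 0.0), (x,))

    def back(g):
        x._accumulate(g * (x.data > 0))

    out._backward = back
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    # clamp: exp(-80) ~ 2e-35 is zero for our purposes, and avoiding the
    # underflow range keeps numpy's exp on its vectorized fast path
    np.maximum(z, -80.0, out=z)
    e = np.exp(z)
    y = e / e.sum(axis=axis, keepdims=True)
    out = _node(y, (x,))

    def back(g):
        dot = (g * y).sum(axis=axis, keepdims=True)
        x._accumulate(y * (g - dot))

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# shape ops
# ---------------------------------------------------------------------------


def concatenate(tensors, axis: int = 1) -> Tensor:
    tensors = [as_tensor(t) for t in tensors]
    out = _node(np.concatenate([t.data for t in tensors], axis=axis), tuple(tensors))
    sizes = [t.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def back(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accumulate(g[tuple(idx)])

    out._backward = back
    return out


def einsum2(subscripts: str, a, b) -> Tensor:
    """einsum with exactly two operands and no repeated in-operand indices."""
    a, b = as_tensor(a), as_tensor(b)
    lhs, s_out = subscripts.split("->")
    s_a, s_b = lhs.split(",")
    out = _node(np.einsum(subscripts, a.data, b.data, optimize=True), (a, b))

    def back(g):
        a._accumulate(np.einsum(f"{s_out},{s_b}->{s_a}", g, b.data, optimize=True))
        b._accumulate(np.einsum(f"{s_out},{s_a}->{s_b}", g, a.data, optimize=True))

    out._backward = back
    return out


# ---------------------------------------------------------------------------
# spatial primitives (NCHW layout, stride 1)
# ---------------------------------------------------------------------------


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation).

    x: (B, Cin, H, W); w: (Cout, Cin, kh, kw) with odd kh == kw; padding is
    dilation * (k - 1) / 2 so the spatial size is preserved.
    """
    x, w = as_tensor(x), as_tensor(w)
    B, Cin, H, W = x.shape
    Cout, Cin2, kh, kw = w.shape
    if Cin != Cin2:
        raise ValueError(f"channel mismatch: input {Cin}, weight {Cin2}")
    if kh % 2 == 0 or kw % 2 == 0:
        raise ValueError("kernel size must be odd")
    d = int(dilation)
    ph, pw = d * (kh - 1) // 2, d * (kw - 1) // 2
    # im2col in channels-last layout: one big BLAS matmul per conv
    xcl = np.ascontiguousarray(x.data.transpose(0, 2, 3, 1))  # (B,H,W,Cin)
    xp = np.pad(xcl, ((0, 0), (ph, ph), (pw, pw), (0, 0)))
    taps = kh * kw

    def im2col() -> np.ndarray:
        cols = np.empty((B, H, W, taps, Cin), dtype=x.dtype)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, :, i * kw + j, :] = xp[
                    :, i * d : i * d + H, j * d : j * d + W, :
                ]
        return cols.reshape(B * H * W, taps * Cin)

    wmat = w.data.transpose(2, 3, 1, 0).reshape(taps * Cin, Cout)
    out_cl = im2col() @ wmat  # (BHW, Cout); columns freed right after
    parents = (x, w) if b is None else (x, w, as_tensor(b))
    if b is not None:
        out_cl += parents[2].data
    out = _node(
        np.ascontiguousarray(out_cl.reshape(B, H, W, Cout).transpose(0, 3, 1, 2)),
        parents,
    )
    del out_cl

    def back(g):
        gcl = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(B * H * W, Cout)
        if w.requires_grad:
            gw = (im2col().T @ gcl).reshape(taps, Cin, Cout).transpose(2, 1, 0)
            w._accumulate(np.ascontiguousarray(gw.reshape(Cout, Cin, kh, kw)))
        if x.requires_grad:
            gcols = (gcl @ wmat.T).reshape(B, H, W, taps, Cin)
            gxp = np.zeros_like(xp)
            for i in range(kh):
                for j in range(kw):
                    gxp[:, i * d : i * d + H, j * d : j * d + W, :] += gcols[
                        :, :, :, i * kw + j, :
                    ]
            del gcols
            gx = gxp[:, ph : ph + H, pw : pw + W, :].transpose(0, 3, 1, 2)
            x._accumulate(np.ascontiguousarray(gx))
        if b is not None and parents[2].requires_grad:
            parents[2]._accumulate(gcl.sum(axis=0))

    out._backward = back
    return out


def maxpool2x2(x: Tensor) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    if H % 2 or W % 2:
        raise ValueError("maxpool2x2 requires even spatial dims")
    h, w = H // 2, W // 2
    win = x.data.reshape(B, C, h, 2, w, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
        B, C, h, w, 4
    )
    idx = win.argmax(axis=-1)
    out = _node(np.take_along_axis(win, idx[..., None], axis=-1)[..., 0], (x,))

    def back(g):
        gwin = np.zeros((B, C, h, w, 4), dtype=g.dtype)
        np.put_along_axis(gwin, idx[..., None], g[..., None], axis=-1)
        gx = gwin.reshape(B, C, h, w, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(
            B, C, H, W
        )
        x._accumulate(gx)

    out._backward = back
    return out


def _criss_cross_core(qd: np.ndarray, kd: np.ndarray, vd: np.ndarray, mask: float):
    """Shared forward math for criss-cross attention (numpy, channels-last).

    Returns (y, ar, ac, row_views, col_views) where ``ar`` (B,H,W,W) and
    ``ac`` (B,W,H,H) are the jointly-normalized attention weights over each
    position's row and column; the position's duplicate appearance in the
    column branch is suppressed by adding ``mask`` to the diagonal.
    """
    qr = np.ascontiguousarray(qd.transpose(0, 2, 3, 1))  # B,H,W,Cq
    kr = np.ascontiguousarray(kd.transpose(0, 2, 3, 1))
    vr = np.ascontiguousarray(vd.transpose(0, 2, 3, 1))  # B,H,W,C
    qc = np.ascontiguousarray(qd.transpose(0, 3, 2, 1))  # B,W,H,Cq
    kc = np.ascontiguousarray(kd.transpose(0, 3, 2, 1))
    vc = np.ascontiguousarray(vd.transpose(0, 3, 2, 1))
    h = qd.shape[2]
    e_row = qr @ kr.swapaxes(2, 3)  # (B,H,W,W): affinity along own row
    e_col = qc @ kc.swapaxes(2, 3)  # (B,W,H,H): affinity along own column
    e_col[:, :, np.arange(h), np.arange(h)] += mask
    m = np.maximum(e_row.max(-1), e_col.max(-1).transpose(0, 2, 1))  # B,H,W
    np.exp(np.maximum(e_row - m[..., None], -80.0), out=e_row)
    np.exp(np.maximum(e_col - m.transpose(0, 2, 1)[..., None], -80.0), out=e_col)
    z = e_row.sum(-1) + e_col.sum(-1).transpose(0, 2, 1)  # B,H,W
    ar = e_row
    ar /= z[..., None]
    ac = e_col
    ac /= z.transpose(0, 2, 1)[..., None]
    y = ar @ vr + (ac @ vc).transpose(0, 2, 1, 3)  # B,H,W,C
    return y, ar, ac, (qr, kr, vr), (qc, kc, vc)


def cca_attention(q: Tensor, k: Tensor, v: Tensor, mask: float = -30.0) -> Tensor:
    """Criss-cross attention aggregation as one fused autograd op.

    Each position (h, w) attends over the W positions of its row and the H
    positions of its column under a joint softmax (its duplicate column
    entry masked down); the attended values are summed.  Inputs are NCHW:
    q, k with the reduced channel count, v with the full one.
    """
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    y, ar, ac, (qr, kr, vr), (qc, kc, vc) = _criss_cross_core(
        q.data, k.data, v.data, mask
    )
    out = _node(np.ascontiguousarray(y.transpose(0, 3, 1, 2)), (q, k, v))
    del y

    def back(g):
        gr = np.ascontiguousarray(g.transpose(0, 2, 3, 1))  # B,H,W,C
        gc = np.ascontiguousarray(g.transpose(0, 3, 2, 1))  # B,W,H,C
        dar = gr @ vr.swapaxes(2, 3)  # B,H,W,W
        dac = gc @ vc.swapaxes(2, 3)  # B,W,H,H
        if v.requires_grad:
            dv = (ar.swapaxes(2, 3) @ gr) + (ac.swapaxes(2, 3) @ gc).transpose(
                0, 2, 1, 3
            )
            v._accumulate(np.ascontiguousarray(dv.transpose(0, 3, 1, 2)))
        # joint softmax backward over the row+column support
        s = (dar * ar).sum(-1) + (dac * ac).sum(-1).transpose(0, 2, 1)  # B,H,W
        dar -= s[..., None]
        dar *= ar
        dac -= s.transpose(0, 2, 1)[..., None]
        dac *= ac
        if q.requires_grad:
            dq = (dar @ kr) + (dac @ kc).transpose(0, 2, 1, 3)
            q._accumulate(np.ascontiguousarray(dq.transpose(0, 3, 1, 2)))
        if k.requires_grad:
            dk = (dar.swapaxes(2, 3) @ qr) + (
                dac.swapaxes(2, 3) @ qc
            ).transpose(0, 2, 1, 3)
            k._accumulate(np.ascontiguousarray(dk.transpose(0, 3, 1, 2)))

    out._backward = back
    return out


_BILINEAR_CACHE: dict[int, np.ndarray] = {}


def _bilinear_matrix(n: int) -> np.ndarray:
    """(2n, n) interpolation matrix for x2 upsampling, align_corners=False."""
    m = _BILINEAR_CACHE.get(n)
    if m is None:
        src = np.clip((np.arange(2 * n) + 0.5) / 2.0 - 0.5, 0.0, n - 1.0)
        i0 = np.floor(src).astype(int)
        i1 = np.minimum(i0 + 1, n - 1)
        frac = src - i0
        m = np.zeros((2 * n, n))
        m[np.arange(2 * n), i0] += 1.0 - frac
        m[np.arange(2 * n), i1] += frac
        _BILINEAR_CACHE[n] = m
    return m


def upsample_bilinear2x(x: Tensor) -> Tensor:
    x = as_tensor(x)
    B, C, H, W = x.shape
    lh = _bilinear_matrix(H).astype(x.dtype)
    lw = _bilinear_matrix(W).astype(x.dtype)
    y = np.einsum("ij,bcjk,lk->bcil", lh, x.data, lw, optimize=True)
    out = _node(y, (x,))

    def back(g):
        x._accumulate(np.einsum("ij,bcik,kl->bcjl", lh, g, lw, optimize=True))

    out._backward = back
    return out
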