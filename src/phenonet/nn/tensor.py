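"""Minimal reverse-mode autodiff on numpy arrays.

Supports exactly the operator set the phenotyping network needs: broadcasted
arithmetic, matmul, activations, reductions, reshaping/slicing/concat, 2-D
convolution (with stride/padding/groups), transposed convolution, and ROI
align.  All tensors are float32.  The graph is a tape of closures; call
:meth:`Tensor.backward` on a scalar loss.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Parameter", "concat", "stack"]

_DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(_DTYPE, copy=False)
    return np.asarray(x, dtype=_DTYPE)


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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = _as_array(data)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents: tuple = ()
        self._backward = None

    # -- construction helpers -------------------------------------------------
    @staticmethod
    def _make(data, parents, backward) -> "Tensor":
        req = any(p.requires_grad for p in parents)
        out = Tensor(data, requires_grad=req)
        if req:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    @property
    def size(self):
        return self.data.size

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def numpy(self) -> np.ndarray:
        return self.data

    def item(self) -> float:
        return float(self.data)

    # -- autograd driver ------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
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
        grads = {id(self): _as_array(grad)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t._backward is None:  # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if pg is None or not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg

    # -- arithmetic -----------------------------------------------------------
    def _coerce(self, other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def __add__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data + o.data, (self, o),
            lambda g: (_unbroadcast(g, self.data.shape), _unbroadcast(g, o.data.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        o = self._coerce(other)
        return Tensor._make(
            self.data * o.data, (self, o),
            lambda g: (_unbroadcast(g * o.data, self.data.shape),
                       _unbroadcast(g * self.data, o.data.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        o = self._coerce(other)
        return self * o ** -1.0

    def __rtruediv__(self, other):
        return self._coerce(other) * self ** -1.0

    def __pow__(self, p: float):
        d = self.data

        def back(g):
            return (g * p * np.power(d, p - 1.0),)

        return Tensor._make(np.power(d, p), (self,), back)

    def __matmul__(self, other):
        o = self._coerce(other)
        a, b = self.data, o.data

        def back(g):
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))

        return Tensor._make(a @ b, (self, o), back)

    # -- activations ----------------------------------------------------------
    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,), lambda g: (g / self.data,))

    def sqrt(self):
        out = np.sqrt(self.data)
        return Tensor._make(out, (self,), lambda g: (g * 0.5 / out,))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1.0 - out),))

    def silu(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = self.data * s
        return Tensor._make(out, (self,), lambda g: (g * (s + out * (1.0 - s)),))

    def relu(self):
        mask = self.data > 0

        def back(g):
            return (g * mask,)

        return Tensor._make(self.data * mask, (self,), back)

    def softplus(self):
        # numerically stable log(1 + e^x)
        out = np.maximum(self.data, 0) + np.log1p(np.exp(-np.abs(self.data)))
        s = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * s,))

    def abs(self):
        sign = np.sign(self.data)
        return Tensor._make(np.abs(self.data), (self,), lambda g: (g * sign,))

    # -- reductions -----------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        out = self.data.sum(axis=axis, keepdims=keepdims)
        shape = self.data.shape

        def back(g):
            if axis is None:
                return (np.broadcast_to(g, shape).astype(_DTYPE),)
            g2 = g
            if not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % len(shape) for a in axes):
                    g2 = np.expand_dims(g2, ax)
            return (np.broadcast_to(g2, shape).astype(_DTYPE),)

        return Tensor._make(out, (self,), back)

    def mean(self, axis=None, keepdims: bool = False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def max(self, axis=None, keepdims: bool = False):
        out = self.data.max(axis=axis, keepdims=keepdims)
        out_k = self.data.max(axis=axis, keepdims=True)
        mask = (self.data == out_k)
        mask = mask / mask.sum(axis=axis, keepdims=True)  # split ties
        shape = self.data.shape

        def back(g):
            g2 = g
            if axis is not None and not keepdims:
                axes = axis if isinstance(axis, tuple) else (axis,)
                for ax in sorted(a % len(shape) for a in axes):
                    g2 = np.expand_dims(g2, ax)
            elif axis is None:
                g2 = np.reshape(g, (1,) * len(shape))
            return ((mask * g2).astype(_DTYPE),)

        return Tensor._make(out, (self,), back)

    # -- shape ops ------------------------------------------------------------
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        return Tensor._make(self.data.reshape(shape), (self,),
                            lambda g: (g.reshape(old),))

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        return Tensor._make(self.data.transpose(axes), (self,),
                            lambda g: (g.transpose(inv),))

    def __getitem__(self, idx):
        shape = self.data.shape

        def back(g):
            out = np.zeros(shape, dtype=_DTYPE)
            np.add.at(out, idx, g)
            return (out,)

        return Tensor._make(self.data[idx], (self,), back)

    def pad2d(self, pad: int):
        """Zero-pad the last two axes by `pad` on each side."""
        if pad == 0:
            return self
        p = [(0, 0)] * (self.data.ndim - 2) + [(pad, pad), (pad, pad)]
        sl = (Ellipsis, slice(pad, self.data.shape[-2] + pad),
              slice(pad, self.data.shape[-1] + pad))
        return Tensor._make(np.pad(self.data, p), (self,), lambda g: (g[sl],))

    # -- convolution ----------------------------------------------------------
    def conv2d(self, weight: "Tensor", bias: "Tensor" = None,
               stride: int = 1, padding: int = 0, groups: int = 1):
        """NCHW convolution. weight: (O, C/groups, kh, kw)."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        O, Cg, kh, kw = w.shape
        if C != Cg * groups:
            raise ValueError(f"channel mismatch: x has {C}, weight expects {Cg * groups}")
        s, p = stride, padding
        Ho = (H + 2 * p - kh) // s + 1
        Wo = (W + 2 * p - kw) // s + 1
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        cols = np.empty((N, C, kh, kw, Ho, Wo), dtype=_DTYPE)
        for i in range(kh):
            for j in range(kw):
                cols[:, :, i, j] = xp[:, :, i:i + s * Ho:s, j:j + s * Wo:s]
        out = np.empty((N, O, Ho, Wo), dtype=_DTYPE)
        Og = O // groups
        col2 = cols.reshape(N, groups, Cg * kh * kw, Ho * Wo)
        w2 = w.reshape(groups, Og, Cg * kh * kw)
        for gidx in range(groups):
            out[:, gidx * Og:(gidx + 1) * Og] = (
                w2[gidx] @ col2[:, gidx]).reshape(N, Og, Ho, Wo)
        if bias is not None:
            out += bias.data.reshape(1, O, 1, 1)

        def back(g):
            g2 = g.reshape(N, groups, Og, Ho * Wo)
            dw = np.empty_like(w2)
            dcol = np.empty_like(col2)
            for gi in range(groups):
                dw[gi] = np.einsum("nor,ncr->oc", g2[:, gi], col2[:, gi])
                dcol[:, gi] = np.einsum("oc,nor->ncr", w2[gi], g2[:, gi])
            dcols = dcol.reshape(N, C, kh, kw, Ho, Wo)
            dxp = np.zeros((N, C, H + 2 * p, W + 2 * p), dtype=_DTYPE)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + s * Ho:s, j:j + s * Wo:s] += dcols[:, :, i, j]
            dx = dxp[:, :, p:p + H, p:p + W] if p else dxp
            db = g.sum(axis=(0, 2, 3)) if bias is not None else None
            grads = [dx, dw.reshape(w.shape)]
            if bias is not None:
                grads.append(db)
            return tuple(grads)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, back)

    def conv_transpose2d(self, weight: "Tensor", bias: "Tensor" = None,
                         stride: int = 2, padding: int = 0):
        """Transposed NCHW convolution. weight: (C, O, kh, kw)."""
        x, w = self.data, weight.data
        N, C, H, W = x.shape
        Cw, O, kh, kw = w.shape
        if C != Cw:
            raise ValueError(f"channel mismatch: x has {C}, weight expects {Cw}")
        s, p = stride, padding
        Hf = (H - 1) * s + kh
        Wf = (W - 1) * s + kw
        # full (unpadded) output, then crop
        tmp = np.einsum("nchw,cokl->noklhw", x, w)
        outp = np.zeros((N, O, Hf, Wf), dtype=_DTYPE)
        for i in range(kh):
            for j in range(kw):
                outp[:, :, i:i + s * H:s, j:j + s * W:s] += tmp[:, :, i, j]
        out = outp[:, :, p:Hf - p, p:Wf - p] if p else outp
        if bias is not None:
            out = out + bias.data.reshape(1, O, 1, 1)

        def back(g):
            gp = np.pad(g, ((0, 0), (0, 0), (p, p), (p, p))) if p else g
            gwin = np.empty((N, O, kh, kw, H, W), dtype=_DTYPE)
            for i in range(kh):
                for j in range(kw):
                    gwin[:, :, i, j] = gp[:, :, i:i + s * H:s, j:j + s * W:s]
            dx = np.einsum("noklhw,cokl->nchw", gwin, w)
            dw = np.einsum("nchw,noklhw->cokl", x, gwin)
            db = g.sum(axis=(0, 2, 3)) if bias is not None else None
            grads = [dx, dw]
            if bias is not None:
                grads.append(db)
            return tuple(grads)

        parents = (self, weight) if bias is None else (self, weight, bias)
        return Tensor._make(out, parents, back)

    # -- ROI align ------------------------------------------------------------
    def roi_align(self, rois: np.ndarray, out_size: int, sampling: int = 2):
        """ROI align with bilinear sampling.

        rois: (R, 5) float array [batch_idx, x0, y0, x1, y1] in feature-map
        coordinates (continuous, half-open).  Returns (R, C, out, out).
        """
        x = self.data
        N, C, H, W = x.shape
        rois = np.asarray(rois, dtype=np.float64)
        R = rois.shape[0]
        os, sr = out_size, sampling
        # sample positions per roi: (R, os*sr) in y and x
        bidx = rois[:, 0].astype(int)
        ys, xs = [], []
        for r in range(R):
            _, x0, y0, x1, y1 = rois[r]
            bh = max(y1 - y0, 1e-6) / os
            bw = max(x1 - x0, 1e-6) / os
            gy = y0 + bh * (np.add.outer(np.arange(os), (np.arange(sr) + 0.5) / sr)).ravel()
            gx = x0 + bw * (np.add.outer(np.arange(os), (np.arange(sr) + 0.5) / sr)).ravel()
            ys.append(gy)
            xs.append(gx)
        ys = np.clip(np.stack(ys), 0, H - 1)   # (R, os*sr)
        xs = np.clip(np.stack(xs), 0, W - 1)
        y0i = np.floor(ys).astype(int)
        x0i = np.floor(xs).astype(int)
        y1i = np.minimum(y0i + 1, H - 1)
        x1i = np.minimum(x0i + 1, W - 1)
        wy1 = (ys - y0i).astype(_DTYPE)
        wx1 = (xs - x0i).astype(_DTYPE)
        wy0, wx0 = 1 - wy1, 1 - wx1

        out = np.zeros((R, C, os, os), dtype=_DTYPE)
        corners = []
        for r in range(R):
            b = bidx[r]
            f = x[b]  # (C, H, W)
            # (C, P, Q) where P=os*sr rows, Q=os*sr cols
            v = (f[:, y0i[r]][:, :, x0i[r]] * np.outer(wy0[r], wx0[r])
                 + f[:, y0i[r]][:, :, x1i[r]] * np.outer(wy0[r], wx1[r])
                 + f[:, y1i[r]][:, :, x0i[r]] * np.outer(wy1[r], wx0[r])
                 + f[:, y1i[r]][:, :, x1i[r]] * np.outer(wy1[r], wx1[r]))
            out[r] = v.reshape(C, os, sr, os, sr).mean(axis=(2, 4))
            corners.append((b,))

        def back(g):
            dx = np.zeros_like(x)
            scale = 1.0 / (sr * sr)
            for r in range(R):
                b = bidx[r]
                gr = np.repeat(np.repeat(g[r], sr, axis=1), sr, axis=2) * scale  # C,P,Q
                for yi, wy in ((y0i[r], wy0[r]), (y1i[r], wy1[r])):
                    for xi, wx in ((x0i[r], wx0[r]), (x1i[r], wx1[r])):
                        contrib = gr * np.outer(wy, wx)  # C,P,Q
                        np.add.at(dx[b], (slice(None), yi[:, None], xi[None, :]), contrib)
            return (dx,)

        return Tensor._make(out, (self,), back)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


def concat(tensors, axis: int = 0) -> Tensor:
    datas = [t.data for t in tensors]
    out = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(out, tuple(tensors), back)


def stack(tensors, axis: int = 0) -> Tensor:
    out = np.stack([t.data for t in tensors], axis=axis)

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(out, tuple(tensors), back)
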