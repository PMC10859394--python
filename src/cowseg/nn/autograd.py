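"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operator set the segmentation network needs:
broadcast-aware elementwise arithmetic, matmul, 2-D (dilated/strided)
convolution via im2col, pooling, nearest/zero upsampling, reductions,
concatenation and a fused softmax cross-entropy.  Tensors record a
backward closure and the graph is traversed in reverse topological
order.  All computation is float32.
"""

from __future__ import annotations

import numpy as np

DTYPE = np.float32


def _as_array(x) -> np.ndarray:
    if isinstance(x, np.ndarray):
        return x.astype(DTYPE, copy=False)
    return np.asarray(x, dtype=DTYPE)


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (reverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndim_extra = grad.ndim - len(shape)
    if ndim_extra > 0:
        grad = grad.sum(axis=tuple(range(ndim_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev", "name")

    def __init__(self, data, requires_grad: bool = False, _prev=(), name: str = ""):
        self.data = _as_array(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev
        self.name = name

    # -- infrastructure ------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accumulate(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: deep graphs overflow recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = _as_array(grad).reshape(self.data.shape)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data + other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out = Tensor(self.data * other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad or other._prev:
                other._accumulate(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    def __neg__(self):
        return self * Tensor(np.array(-1.0, dtype=DTYPE))

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (-other)

    def __truediv__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self * other ** -1.0

    __radd__ = __add__
    __rmul__ = __mul__

    def __pow__(self, p: float):
        out = Tensor(self.data ** p, _prev=(self,))

        def bw(g):
            self._accumulate(g * p * self.data ** (p - 1.0))

        out._backward = bw
        return out

    def exp(self):
        out = Tensor(np.exp(self.data), _prev=(self,))

        def bw(g):
            self._accumulate(g * out.data)

        out._backward = bw
        return out

    def relu(self):
        out = Tensor(np.maximum(self.data, 0.0), _prev=(self,))
        mask = self.data > 0

        def bw(g):
            self._accumulate(g * mask)

        out._backward = bw
        return out

    def sigmoid(self):
        out = Tensor(1.0 / (1.0 + np.exp(-self.data)), _prev=(self,))

        def bw(g):
            self._accumulate(g * out.data * (1.0 - out.data))

        out._backward = bw
        return out

    def tanh(self):
        out = Tensor(np.tanh(self.data), _prev=(self,))

        def bw(g):
            self._accumulate(g * (1.0 - out.data ** 2))

        out._backward = bw
        return out

    # -- shape ops -----------------------------------------------------
    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape), _prev=(self,))

        def bw(g):
            self._accumulate(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def __getitem__(self, idx):
        out = Tensor(self.data[idx], _prev=(self,))

        def bw(g):
            full = np.zeros_like(self.data)
            full[idx] = g
            self._accumulate(full)

        out._backward = bw
        return out

    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), _prev=(self,))
        shape = self.data.shape

        def bw(g):
            if axis is None:
                self._accumulate(np.full(shape, g, dtype=DTYPE))
                return
            axes = axis if isinstance(axis, tuple) else (axis,)
            if not keepdims:
                g = np.expand_dims(g, axes)
            self._accumulate(np.broadcast_to(g, shape).astype(DTYPE))

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * Tensor(np.array(1.0 / n, dtype=DTYPE))

    def max(self, axis: int, keepdims: bool = False):
        idx = np.argmax(self.data, axis=axis)
        out_data = np.take_along_axis(self.data, np.expand_dims(idx, axis), axis=axis)
        if not keepdims:
            out_data = out_data.squeeze(axis)
        out = Tensor(out_data, _prev=(self,))

        def bw(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            full = np.zeros_like(self.data)
            np.put_along_axis(full, np.expand_dims(idx, axis), g, axis=axis)
            self._accumulate(full)

        out._backward = bw
        return out

    def matmul(self, other: "Tensor"):
        out = Tensor(self.data @ other.data, _prev=(self, other))

        def bw(g):
            if self.requires_grad or self._prev:
                self._accumulate(g @ other.data.T)
            if other.requires_grad or other._prev:
                other._accumulate(self.data.T @ g)

        out._backward = bw
        return out

    def __matmul__(self, other):
        return self.matmul(other)


class Parameter(Tensor):
    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)


# ---------------------------------------------------------------------
# im2col convolution
# ---------------------------------------------------------------------

def _conv_out_size(size, k, stride, pad, dil):
    return (size + 2 * pad - dil * (k - 1) - 1) // stride + 1


def _pad_pair(pad):
    return (pad, pad) if isinstance(pad, int) else tuple(pad)


def _im2col(x: np.ndarray, kh, kw, stride, pad, dil):
    n, c, h, w = x.shape
    ph, pw = _pad_pair(pad)
    oh = _conv_out_size(h, kh, stride, ph, dil)
    ow = _conv_out_size(w, kw, stride, pw, dil)
    if ph or pw:
        x = np.pad(x, ((0, 0), (0, 0), (ph, ph), (pw, pw)))
    col = np.empty((n, c, kh, kw, oh, ow), dtype=DTYPE)
    for i in range(kh):
        i0 = i * dil
        for j in range(kw):
            j0 = j * dil
            col[:, :, i, j] = x[:, :, i0:i0 + stride * oh:stride, j0:j0 + stride * ow:stride]
    return col.reshape(n, c * kh * kw, oh * ow), oh, ow


def _col2im(col: np.ndarray, x_shape, kh, kw, stride, pad, dil, oh, ow):
    n, c, h, w = x_shape
    ph, pw = _pad_pair(pad)
    xp = np.zeros((n, c, h + 2 * ph, w + 2 * pw), dtype=DTYPE)
    col = col.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        i0 = i * dil
        for j in range(kw):
            j0 = j * dil
            xp[:, :, i0:i0 + stride * oh:stride, j0:j0 + stride * ow:stride] += col[:, :, i, j]
    return xp[:, :, ph:h + ph, pw:w + pw]


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, stride=1, padding=0, dilation=1) -> Tensor:
    """x (N,C,H,W), w (F,C,kh,kw), b (F,) -> (N,F,OH,OW)."""
    f, c, kh, kw = w.data.shape
    col, oh, ow = _im2col(x.data, kh, kw, stride, padding, dilation)
    w2 = w.data.reshape(f, -1)
    out_data = np.matmul(w2, col)  # (N, F, OH*OW)
    if b is not None:
        out_data += b.data[None, :, None]
    n = x.data.shape[0]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor(out_data.reshape(n, f, oh, ow), _prev=prev)

    def bw(g):
        g2 = g.reshape(n, f, oh * ow)
        if w.requires_grad or w._prev:
            dw = np.einsum("nfl,nkl->fk", g2, col, optimize=True)
            w._accumulate(dw.reshape(w.data.shape))
        if b is not None and (b.requires_grad or b._prev):
            b._accumulate(g2.sum(axis=(0, 2)))
        if x.requires_grad or x._prev:
            dcol = np.matmul(w2.T, g2)  # (N, K, L)
            x._accumulate(_col2im(dcol, x.data.shape, kh, kw, stride, padding, dilation, oh, ow))

    out._backward = bw
    return out


def max_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    v = x.data[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
    v = v.transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho, wo, 4)
    idx = v.argmax(axis=-1)
    out = Tensor(np.take_along_axis(v, idx[..., None], axis=-1)[..., 0], _prev=(x,))

    def bw(g):
        dv = np.zeros((n, c, ho, wo, 4), dtype=DTYPE)
        np.put_along_axis(dv, idx[..., None], g[..., None], axis=-1)
        dv = dv.reshape(n, c, ho, wo, 2, 2).transpose(0, 1, 2, 4, 3, 5).reshape(n, c, ho * 2, wo * 2)
        full = np.zeros_like(x.data)
        full[:, :, : ho * 2, : wo * 2] = dv
        x._accumulate(full)

    out._backward = bw
    return out


def avg_pool2x2(x: Tensor) -> Tensor:
    n, c, h, w = x.data.shape
    ho, wo = h // 2, w // 2
    v = x.data[:, :, : ho * 2, : wo * 2].reshape(n, c, ho, 2, wo, 2)
    out = Tensor(v.mean(axis=(3, 5)), _prev=(x,))

    def bw(g):
        full = np.zeros_like(x.data)
        full[:, :, : ho * 2, : wo * 2] = np.repeat(np.repeat(g, 2, axis=2), 2, axis=3) * 0.25
        x._accumulate(full)

    out._backward = bw
    return out


def upsample_nearest(x: Tensor, scale: int) -> Tensor:
    out = Tensor(np.repeat(np.repeat(x.data, scale, axis=2), scale, axis=3), _prev=(x,))
    n, c, h, w = x.data.shape

    def bw(g):
        x._accumulate(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    out._backward = bw
    return out


def upsample_zero(x: Tensor, scale: int) -> Tensor:
    """Zero-stuffed upsampling: input values at every `scale`-th position.

    Followed by a convolution this realizes a learnable transposed
    (deconvolution) upsampling with exact output size (scale*H, scale*W).
    """
    n, c, h, w = x.data.shape
    data = np.zeros((n, c, h * scale, w * scale), dtype=DTYPE)
    data[:, :, ::scale, ::scale] = x.data
    out = Tensor(data, _prev=(x,))

    def bw(g):
        x._accumulate(g[:, :, ::scale, ::scale])

    out._backward = bw
    return out


def broadcast_hw(x: Tensor, h: int, w: int) -> Tensor:
    """Broadcast a (N,C,1,1) map to (N,C,h,w)."""
    out = Tensor(np.broadcast_to(x.data, x.data.shape[:2] + (h, w)).copy(), _prev=(x,))

    def bw(g):
        x._accumulate(g.sum(axis=(2, 3), keepdims=True))

    out._backward = bw
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis), _prev=tuple(tensors))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bw(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            sl = [slice(None)] * g.ndim
            sl[axis] = slice(a, b)
            t._accumulate(g[tuple(sl)])

    out._backward = bw
    return out


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean pixel-wise cross-entropy. logits (N,K,H,W), labels int (N,H,W)."""
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    e = np.exp(z)
    p = e / e.sum(axis=1, keepdims=True)
    n, k, h, w = p.shape
    flat = p.transpose(0, 2, 3, 1).reshape(-1, k)
    lab = labels.reshape(-1).astype(np.int64)
    npix = lab.size
    loss = -np.log(np.clip(flat[np.arange(npix), lab], 1e-12, None)).mean()
    out = Tensor(np.array(loss, dtype=DTYPE), _prev=(logits,))

    def bw(g):
        d = flat.copy()
        d[np.arange(npix), lab] -= 1.0
        d = d.reshape(n, h, w, k).transpose(0, 3, 1, 2) * (float(g) / npix)
        logits._accumulate(d.astype(DTYPE))

    out._backward = bw
    return out


def softmax_np(logits: np.ndarray, axis: int = 1) -> np.ndarray:
    z = logits - logits.max(axis=axis, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=axis, keepdims=True)
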