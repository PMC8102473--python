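"""Minimal reverse-mode automatic differentiation on numpy arrays.

Provides exactly the operations the segmentation networks need: broadcasted
arithmetic, reductions, activations, strided N-d convolution, 2x max pooling,
2x nearest-neighbour upsampling and channel concatenation.  Gradients are
accumulated into ``Tensor.grad`` by :meth:`Tensor.backward`, which runs a
topological sort of the recorded graph.

All data is kept in float32; the graph is rebuilt on every forward pass
(define-by-run), so control flow in the model code just works.
"""

from __future__ import annotations

from numpy.lib.stride_tricks import sliding_window_view

import numpy as np

__all__ = ["Tensor", "concat"]


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
    """A numpy array with an optional gradient tape entry."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- graph bookkeeping -------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def _make(self, data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(np.float32, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar output")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep nets overflow the recursion limit
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
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def __add__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.shape))

        return self._make(self.data + other.data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._lift(other))

    def __rsub__(self, other):
        return self._lift(other) + (-self)

    def __truediv__(self, other):
        return self * self._lift(other) ** (-1.0)

    def __rtruediv__(self, other):
        return self._lift(other) * self ** (-1.0)

    def __pow__(self, p: float):
        out_data = self.data**p

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** (p - 1.0))

        return self._make(out_data, (self,), backward)

    # -- reductions and shaping -------------------------------------------

    def sum(self, axis=None, keepdims: bool = False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def reshape(self, *shape):
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(self.shape))

        return self._make(out_data, (self,), backward)

    # -- activations -------------------------------------------------------

    def relu(self):
        mask = self.data > 0

        def backward(g):
            if self.requires_grad:
                self._accum(g * mask)

        return self._make(self.data * mask, (self,), backward)

    def leaky_relu(self, negative_slope: float = 0.01):
        pos = self.data > 0
        scale = np.where(pos, 1.0, negative_slope).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accum(g * scale)

        return self._make(self.data * scale, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    # -- convolution -------------------------------------------------------

    def conv(self, weight: "Tensor", bias: "Tensor | None" = None,
             stride: int = 1, padding: int = 0):
        """N-d cross-correlation over the trailing spatial axes.

        ``self``: (N, C, *spatial); ``weight``: (Co, C, *kernel); isotropic
        stride and zero padding.  Works for 2-D and 3-D alike.
        """
        x, w = self.data, weight.data
        nsp = x.ndim - 2
        if w.ndim - 2 != nsp:
            raise ValueError("kernel dimensionality does not match input")
        k = w.shape[2:]
        pad = ((0, 0), (0, 0)) + tuple((padding, padding) for _ in range(nsp))
        xp = np.pad(x, pad)
        spatial_axes = tuple(range(2, 2 + nsp))
        win = sliding_window_view(xp, k, axis=spatial_axes)
        if stride > 1:
            sl = (slice(None), slice(None)) + tuple(
                slice(None, None, stride) for _ in range(nsp)
            ) + (slice(None),) * nsp
            win = win[sl]
        # win: (N, C, *out, *k);  contract C and kernel axes against weight
        out_sp = win.shape[2:2 + nsp]
        n = x.shape[0]
        cin = x.shape[1]
        ksz = int(np.prod(k))
        # move C next to the kernel axes then flatten to a matmul
        win2 = np.moveaxis(win, 1, 1 + nsp)  # (N, *out, C, *k)
        cols = win2.reshape(n, int(np.prod(out_sp)), cin * ksz)
        wmat = w.reshape(w.shape[0], cin * ksz)
        out = cols @ wmat.T  # (N, prod(out), Co)
        out = np.moveaxis(out, -1, 1).reshape((n, w.shape[0]) + tuple(out_sp))
        if bias is not None:
            out += bias.data.reshape((1, -1) + (1,) * nsp)

        parents = (self, weight) if bias is None else (self, weight, bias)

        def backward(g):
            gmat = np.moveaxis(g.reshape(n, g.shape[1], -1), 1, 2)  # (N, prod(out), Co)
            if weight.requires_grad:
                dw = np.einsum("npo,npk->ok", gmat, cols)
                weight._accum(dw.reshape(w.shape))
            if bias is not None and bias.requires_grad:
                bias._accum(g.sum(axis=(0,) + spatial_axes))
            if self.requires_grad:
                dcols = gmat @ wmat  # (N, prod(out), C*ksz)
                dxp = np.zeros_like(xp)
                dcols = dcols.reshape((n,) + tuple(out_sp) + (cin,) + tuple(k))
                dcols = np.moveaxis(dcols, 1 + nsp, 1)  # (N, C, *out, *k)
                # scatter each kernel offset back onto the padded grid
                for idx in np.ndindex(*k):
                    sl = (slice(None), slice(None)) + tuple(
                        slice(i, i + o * stride, stride)
                        for i, o in zip(idx, out_sp)
                    )
                    dxp[sl] += dcols[(slice(None), slice(None)) +
                                     (slice(None),) * nsp + idx]
                crop = (slice(None), slice(None)) + tuple(
                    slice(padding, padding + s) for s in x.shape[2:]
                )
                self._accum(dxp[crop])

        return self._make(out, parents, backward)

    # -- pooling / resampling ---------------------------------------------

    def max_pool(self, factor: int = 2):
        """Non-overlapping max pooling by ``factor`` over all spatial axes."""
        x = self.data
        nsp = x.ndim - 2
        for s in x.shape[2:]:
            if s % factor:
                raise ValueError(f"spatial size {s} not divisible by pool factor {factor}")
        shape = x.shape[:2]
        for s in x.shape[2:]:
            shape = shape + (s // factor, factor)
        xr = x.reshape(shape)
        # gather the per-block window axes at the end
        win_axes = tuple(3 + 2 * i for i in range(nsp))
        xr = np.moveaxis(xr, win_axes, tuple(range(-nsp, 0)))
        blocks = xr.reshape(xr.shape[: 2 + nsp] + (factor**nsp,))
        idx = blocks.argmax(axis=-1)
        out = np.take_along_axis(blocks, idx[..., None], axis=-1)[..., 0]

        def backward(g):
            if not self.requires_grad:
                return
            dblocks = np.zeros_like(blocks)
            np.put_along_axis(dblocks, idx[..., None], g[..., None], axis=-1)
            d = dblocks.reshape(xr.shape)
            d = np.moveaxis(d, tuple(range(-nsp, 0)), win_axes)
            self._accum(d.reshape(x.shape))

        return self._make(out, (self,), backward)

    def upsample_nearest(self, factor: int = 2):
        """Nearest-neighbour upsampling by ``factor`` over all spatial axes."""
        x = self.data
        nsp = x.ndim - 2
        out = x
        for ax in range(2, 2 + nsp):
            out = np.repeat(out, factor, axis=ax)

        def backward(g):
            if not self.requires_grad:
                return
            shape = x.shape[:2]
            for s in x.shape[2:]:
                shape = shape + (s, factor)
            sum_axes = tuple(3 + 2 * i for i in range(nsp))
            self._accum(g.reshape(shape).sum(axis=sum_axes))

        return self._make(out, (self,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    """Concatenate along ``axis`` (channel axis by default)."""
    datas = [t.data for t in tensors]
    out_data = np.concatenate(datas, axis=axis)
    sizes = [d.shape[axis] for d in datas]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(lo, hi)
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._parents = tuple(tensors)
        out._backward = backward
    return out
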