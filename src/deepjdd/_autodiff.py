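"""Minimal reverse-mode automatic differentiation over numpy arrays.

A deliberately small tape-based engine: each op builds a node holding its
inputs and a closure that accumulates gradients into them.  It supports the
exact set of primitives the network and the kernel losses need (broadcasted
arithmetic, matmul, reshape/transpose/concat, exp/log/softplus/relu,
reductions, fused batch normalisation, same-padded 2-D convolution via
im2col/col2im, non-overlapping max pooling) and nothing more.  Gradients are
checked against central finite differences in the test suite.

Memory discipline matters more than raw speed here: gradients are only
computed for nodes on a path from a ``requires_grad`` leaf, and the tape is
released node-by-node as backpropagation consumes it.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "concat", "conv2d", "maxpool2d", "batchnorm"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` undoing numpy broadcasting."""
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
    """An array node on the autodiff tape."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        arr = np.asarray(data)
        if arr.dtype not in (np.float32, np.float64):
            arr = arr.astype(np.float64)
        self.data = arr
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev: tuple[Tensor, ...] = ()

    # ---- plumbing -------------------------------------------------------

    @property
    def shape(self):
        return self.data.shape

    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _accum(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += grad

    @staticmethod
    def _node(data, prev: tuple["Tensor", ...]) -> "Tensor":
        out = Tensor(data)
        out._prev = tuple(p for p in prev if p.requires_grad)
        out.requires_grad = bool(out._prev)
        return out

    def backward(self) -> None:
        """Backpropagate from this node, freeing the tape as it goes."""
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, done = stack.pop()
            if done:
                order.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None:
                node._backward()
            if node._prev:  # interior node: its grad and closure are spent
                node.grad = None
                node._backward = None
                node._prev = ()

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # ---- arithmetic -----------------------------------------------------

    def _binary(self, other, fwd, bwd_self, bwd_other) -> "Tensor":
        if isinstance(other, (int, float)):
            # keep python scalars scalar so float32 graphs stay float32
            out = Tensor._node(fwd(self.data, other), (self,))
            if not out.requires_grad:
                return out
            a, b = self.data, other

            def _backward_scalar():
                self._accum(_unbroadcast(bwd_self(out.grad, a, b), a.shape))

            out._backward = _backward_scalar
            return out
        other = Tensor._lift(other)
        out = Tensor._node(fwd(self.data, other.data), (self, other))
        if not out.requires_grad:
            return out
        a, b = self.data, other.data

        def _backward():
            g = out.grad
            if self.requires_grad:
                self._accum(_unbroadcast(bwd_self(g, a, b), a.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(bwd_other(g, a, b), b.shape))

        out._backward = _backward
        return out

    def __add__(self, other):
        return self._binary(other, lambda a, b: a + b,
                            lambda g, a, b: g, lambda g, a, b: g)

    __radd__ = __add__

    def __sub__(self, other):
        return self._binary(other, lambda a, b: a - b,
                            lambda g, a, b: g, lambda g, a, b: -g)

    def __rsub__(self, other):
        return Tensor._lift(other).__sub__(self)

    def __mul__(self, other):
        return self._binary(other, lambda a, b: a * b,
                            lambda g, a, b: g * b, lambda g, a, b: g * a)

    __rmul__ = __mul__

    def __truediv__(self, other):
        return self._binary(other, lambda a, b: a / b,
                            lambda g, a, b: g / b,
                            lambda g, a, b: -g * a / (b * b))

    def __rtruediv__(self, other):
        return Tensor._lift(other).__truediv__(self)

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = Tensor._lift(other)
        out = Tensor._node(self.data @ other.data, (self, other))
        if not out.requires_grad:
            return out
        a, b = self.data, other.data

        def _backward():
            g = out.grad
            if self.requires_grad:
                self._accum(g @ b.T)
            if other.requires_grad:
                other._accum(a.T @ g)

        out._backward = _backward
        return out

    def pow_const(self, p: float) -> "Tensor":
        out = Tensor._node(self.data ** p, (self,))
        if not out.requires_grad:
            return out
        x = self.data

        def _backward():
            self._accum(out.grad * p * x ** (p - 1.0))

        out._backward = _backward
        return out

    # ---- shape ops ------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        out = Tensor._node(self.data.reshape(*shape), (self,))
        if not out.requires_grad:
            return out
        orig = self.data.shape

        def _backward():
            self._accum(out.grad.reshape(orig))

        out._backward = _backward
        return out

    def transpose(self, axes) -> "Tensor":
        out = Tensor._node(np.transpose(self.data, axes), (self,))
        if not out.requires_grad:
            return out
        inv = np.argsort(axes)

        def _backward():
            self._accum(np.transpose(out.grad, inv))

        out._backward = _backward
        return out

    @property
    def T(self) -> "Tensor":
        return self.transpose(tuple(range(self.data.ndim))[::-1])

    # ---- elementwise nonlinearities -------------------------------------

    def exp(self) -> "Tensor":
        out = Tensor._node(np.exp(self.data), (self,))
        if not out.requires_grad:
            return out
        val = out.data

        def _backward():
            self._accum(out.grad * val)

        out._backward = _backward
        return out

    def log(self) -> "Tensor":
        out = Tensor._node(np.log(self.data), (self,))
        if not out.requires_grad:
            return out
        x = self.data

        def _backward():
            self._accum(out.grad / x)

        out._backward = _backward
        return out

    def relu(self) -> "Tensor":
        out = Tensor._node(np.maximum(self.data, 0.0), (self,))
        if not out.requires_grad:
            return out
        x = self.data

        def _backward():
            self._accum(out.grad * (x > 0.0))

        out._backward = _backward
        return out

    def softplus(self) -> "Tensor":
        # ln(1+e^x) computed stably; derivative is the logistic sigmoid
        x = self.data
        out = Tensor._node(np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x))),
                           (self,))
        if not out.requires_grad:
            return out

        def _backward():
            sig = 1.0 / (1.0 + np.exp(-np.clip(x, -500, 500)))
            self._accum(out.grad * sig)

        out._backward = _backward
        return out

    def sqrt(self) -> "Tensor":
        return self.pow_const(0.5)

    # ---- reductions -----------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor._node(self.data.sum(axis=axis, keepdims=keepdims),
                           (self,))
        if not out.requires_grad:
            return out
        shape = self.data.shape

        def _backward():
            g = out.grad
            if axis is not None and not keepdims:
                ax = axis if isinstance(axis, tuple) else (axis,)
                ax = tuple(a % len(shape) for a in ax)
                g = np.expand_dims(g, ax)
            self._accum(np.broadcast_to(g, shape))

        out._backward = _backward
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else int(
            np.prod([self.data.shape[a] for a in
                     (axis if isinstance(axis, tuple) else (axis,))]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))


def concat(tensors: list[Tensor], axis: int = 0) -> Tensor:
    """Concatenate along ``axis`` with gradient splitting."""
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    out._prev = tuple(t for t in tensors if t.requires_grad)
    out.requires_grad = bool(out._prev)
    if not out.requires_grad:
        return out
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)
    ndim = out.data.ndim

    def _backward():
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if not t.requires_grad:
                continue
            idx = [slice(None)] * ndim
            idx[axis] = slice(int(a), int(b))
            t._accum(out.grad[tuple(idx)])

    out._backward = _backward
    return out


def _same_pad(kh: int, kw: int) -> tuple[tuple[int, int], tuple[int, int]]:
    # asymmetric 'same' padding for even kernels (extra sample at the end)
    return ((kh - 1) // 2, kh - 1 - (kh - 1) // 2), \
           ((kw - 1) // 2, kw - 1 - (kw - 1) // 2)


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation).

    x: (batch, c_in, H, W); w: (c_out, c_in, kh, kw); b: (c_out,) or None.
    Output: (batch, c_out, H, W).  The weight gradient reuses the stored
    im2col matrix; the input gradient is a vectorised col2im scatter, one
    shifted add per kernel tap.
    """
    nb, cin, H, W = x.data.shape
    cout, cin_w, kh, kw = w.data.shape
    if cin != cin_w:
        raise ValueError("conv2d channel mismatch")
    (pt, pb), (pl, pr) = _same_pad(kh, kw)
    xp = np.pad(x.data, ((0, 0), (0, 0), (pt, pb), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (kh, kw), axis=(2, 3))
    # win: (nb, cin, H, W, kh, kw) -> cols (nb*H*W, cin*kh*kw)
    cols = win.transpose(0, 2, 3, 1, 4, 5).reshape(nb * H * W,
                                                    cin * kh * kw)
    wmat = w.data.reshape(cout, cin * kh * kw)
    out_data = (cols @ wmat.T).reshape(nb, H, W, cout).transpose(0, 3, 1, 2)
    if b is not None:
        out_data = out_data + b.data[None, :, None, None]
    prev = (x, w) if b is None else (x, w, b)
    out = Tensor._node(out_data, prev)
    if not out.requires_grad:
        return out

    def _backward():
        g = out.grad  # (nb, cout, H, W)
        gmat = g.transpose(0, 2, 3, 1).reshape(nb * H * W, cout)
        if w.requires_grad:
            w._accum((gmat.T @ cols).reshape(cout, cin, kh, kw))
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if x.requires_grad:
            dcols = (gmat @ wmat).reshape(nb, H, W, cin, kh, kw)
            dxp = np.zeros((nb, cin, H + kh - 1, W + kw - 1),
                           dtype=x.data.dtype)
            for i in range(kh):
                for j in range(kw):
                    dxp[:, :, i:i + H, j:j + W] += \
                        dcols[:, :, :, :, i, j].transpose(0, 3, 1, 2)
            x._accum(dxp[:, :, pt:pt + H, pl:pl + W])

    out._backward = _backward
    return out


def maxpool2d(x: Tensor, pool: tuple[int, int]) -> Tensor:
    """Non-overlapping max pooling with floor division on ragged edges."""
    ph, pw = pool
    nb, c, H, W = x.data.shape
    Ho, Wo = H // ph, W // pw
    if Ho < 1 or Wo < 1:
        raise ValueError(f"input {H}x{W} too small for pool {pool}")
    crop = x.data[:, :, :Ho * ph, :Wo * pw]
    blocks = crop.reshape(nb, c, Ho, ph, Wo, pw)
    flat = blocks.transpose(0, 1, 2, 4, 3, 5).reshape(nb, c, Ho, Wo,
                                                       ph * pw)
    arg = flat.argmax(axis=-1)
    out = Tensor._node(np.take_along_axis(flat, arg[..., None],
                                          axis=-1)[..., 0], (x,))
    if not out.requires_grad:
        return out

    def _backward():
        gflat = np.zeros((nb, c, Ho, Wo, ph * pw), dtype=x.data.dtype)
        np.put_along_axis(gflat, arg[..., None], out.grad[..., None], axis=-1)
        gblocks = gflat.reshape(nb, c, Ho, Wo, ph, pw) \
            .transpose(0, 1, 2, 4, 3, 5)
        gx = np.zeros_like(x.data)
        gx[:, :, :Ho * ph, :Wo * pw] = gblocks.reshape(nb, c, Ho * ph,
                                                       Wo * pw)
        x._accum(gx)

    out._backward = _backward
    return out


def batchnorm(x: Tensor, gamma: Tensor, beta: Tensor, axes: tuple[int, ...],
              eps: float = 1e-5) -> tuple[Tensor, np.ndarray, np.ndarray]:
    """Fused batch normalisation over ``axes`` with per-map affine.

    ``gamma``/``beta`` are 1-D over the non-reduced (map) axis.  Returns
    ``(out, batch_mean, batch_var)`` with the statistics as plain arrays
    (for running-average bookkeeping).  Fusing keeps the tape at one stored
    intermediate (x_hat) instead of the half-dozen a composed version needs.
    """
    xd = x.data
    mu = xd.mean(axis=axes, keepdims=True)
    var = xd.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (xd - mu) * inv_std
    bshape = [1] * xd.ndim
    map_axis = next(i for i in range(xd.ndim) if i not in axes)
    bshape[map_axis] = -1
    gm = gamma.data.reshape(bshape)
    out = Tensor._node(gm * xhat + beta.data.reshape(bshape),
                       (x, gamma, beta))
    if not out.requires_grad:
        return out, mu.reshape(-1), var.reshape(-1)
    m = float(np.prod([xd.shape[a] for a in axes]))

    def _backward():
        g = out.grad
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes).reshape(gamma.data.shape))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes).reshape(beta.data.shape))
        if x.requires_grad:
            dxhat = g * gm
            t1 = dxhat.mean(axis=axes, keepdims=True)
            t2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accum(inv_std * (dxhat - t1 - xhat * t2))

    out._backward = _backward
    return out, mu.reshape(-1), var.reshape(-1)
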