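"""A small reverse-mode automatic-differentiation engine on numpy arrays.

Just enough machinery to train the S4D sequence classifier: broadcasting
elementwise ops, reductions, channel-wise linear maps, FFT convolution with
a custom adjoint, and a fused softmax cross-entropy. Tensors hold float64
ndarrays; ``backward()`` runs a topological sweep accumulating ``.grad``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (the reverse of numpy broadcasting)."""
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
    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=float)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._parents: tuple[Tensor, ...] = ()
        self._backward = None

    # -- construction helpers ---------------------------------------------
    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    @staticmethod
    def _result(data, parents, backward) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad:
            out._parents = tuple(parents)
            out._backward = backward
        return out

    @property
    def shape(self):
        return self.data.shape

    # -- elementwise arithmetic ---------------------------------------------
    def __add__(self, other):
        other = Tensor._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g, b.data.shape))
        return Tensor._result(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __neg__(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g)
        return Tensor._result(-self.data, (self,), bwd)

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __mul__(self, other):
        other = Tensor._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g * b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(g * a.data, b.data.shape))
        return Tensor._result(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        def bwd(g, a=self, b=other):
            if a.requires_grad:
                a._accum(_unbroadcast(g / b.data, a.data.shape))
            if b.requires_grad:
                b._accum(_unbroadcast(-g * a.data / b.data**2, b.data.shape))
        return Tensor._result(self.data / other.data, (self, other), bwd)

    def pow_const(self, p: float):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * p * a.data ** (p - 1))
        return Tensor._result(self.data ** p, (self,), bwd)

    def exp(self):
        out_data = np.exp(self.data)
        def bwd(g, a=self, o=out_data):
            if a.requires_grad:
                a._accum(g * o)
        return Tensor._result(out_data, (self,), bwd)

    def log(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g / a.data)
        return Tensor._result(np.log(self.data), (self,), bwd)

    def sin(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(g * np.cos(a.data))
        return Tensor._result(np.sin(self.data), (self,), bwd)

    def cos(self):
        def bwd(g, a=self):
            if a.requires_grad:
                a._accum(-g * np.sin(a.data))
        return Tensor._result(np.cos(self.data), (self,), bwd)

    def sigmoid(self):
        s = 1.0 / (1.0 + np.exp(-self.data))
        def bwd(g, a=self, s=s):
            if a.requires_grad:
                a._accum(g * s * (1 - s))
        return Tensor._result(s, (self,), bwd)

    def gelu(self):
        """Exact GELU: x * Phi(x)."""
        from scipy.special import erf
        x = self.data
        phi = 0.5 * (1.0 + erf(x / np.sqrt(2.0)))
        pdf = np.exp(-0.5 * x**2) / np.sqrt(2 * np.pi)
        def bwd(g, a=self, phi=phi, pdf=pdf):
            if a.requires_grad:
                a._accum(g * (phi + a.data * pdf))
        return Tensor._result(x * phi, (self,), bwd)

    # -- shape ops -----------------------------------------------------------
    def reshape(self, *shape):
        orig = self.data.shape
        def bwd(g, a=self, orig=orig):
            if a.requires_grad:
                a._accum(g.reshape(orig))
        return Tensor._result(self.data.reshape(*shape), (self,), bwd)

    def sum(self, axis=None, keepdims: bool = False):
        def bwd(g, a=self, axis=axis, keepdims=keepdims):
            if not a.requires_grad:
                return
            if axis is None:
                a._accum(np.broadcast_to(g, a.data.shape).copy())
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                a._accum(np.broadcast_to(gg, a.data.shape).copy())
        return Tensor._result(self.data.sum(axis=axis, keepdims=keepdims),
                              (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else (
            np.prod([self.data.shape[a] for a in np.atleast_1d(axis)]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def narrow(self, axis: int, start: int, length: int):
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(start, start + length)
        sl = tuple(sl)
        def bwd(g, a=self, sl=sl):
            if a.requires_grad:
                full = np.zeros_like(a.data)
                full[sl] = g
                a._accum(full)
        return Tensor._result(self.data[sl], (self,), bwd)

    def flip(self, axis: int):
        def bwd(g, a=self, axis=axis):
            if a.requires_grad:
                a._accum(np.flip(g, axis=axis))
        return Tensor._result(np.flip(self.data, axis=axis), (self,), bwd)

    @staticmethod
    def concat(tensors: list["Tensor"], axis: int):
        sizes = [t.data.shape[axis] for t in tensors]
        offsets = np.cumsum([0] + sizes)
        def bwd(g, ts=tuple(tensors), axis=axis, offsets=offsets):
            for i, t in enumerate(ts):
                if t.requires_grad:
                    sl = [slice(None)] * g.ndim
                    sl[axis] = slice(offsets[i], offsets[i + 1])
                    t._accum(g[tuple(sl)])
        return Tensor._result(np.concatenate([t.data for t in tensors], axis=axis),
                              tensors, bwd)

    # -- linear maps ----------------------------------------------------------
    def channel_linear(self, w: "Tensor", b: "Tensor | None" = None):
        """(B, C, T) x (O, C) -> (B, O, T), optional bias (O,)."""
        x = self
        y = np.einsum("oc,bct->bot", w.data, x.data)
        if b is not None:
            y = y + b.data[None, :, None]
        parents = (x, w) if b is None else (x, w, b)
        def bwd(g, x=x, w=w, b=b):
            if x.requires_grad:
                x._accum(np.einsum("oc,bot->bct", w.data, g))
            if w.requires_grad:
                w._accum(np.einsum("bot,bct->oc", g, x.data))
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=(0, 2)))
        return Tensor._result(y, parents, bwd)

    def linear(self, w: "Tensor", b: "Tensor | None" = None):
        """(B, C) x (O, C) -> (B, O), optional bias (O,)."""
        x = self
        y = x.data @ w.data.T
        if b is not None:
            y = y + b.data[None, :]
        parents = (x, w) if b is None else (x, w, b)
        def bwd(g, x=x, w=w, b=b):
            if x.requires_grad:
                x._accum(g @ w.data)
            if w.requires_grad:
                w._accum(g.T @ x.data)
            if b is not None and b.requires_grad:
                b._accum(g.sum(axis=0))
        return Tensor._result(y, parents, bwd)

    def fftconv(self, k: "Tensor"):
        """Causal linear convolution along time: (B, H, T) * (H, L) -> (B, H, T).

        FFT length T + L (zero-padded), truncated back to T.
        """
        u = self
        T = u.data.shape[-1]
        L = k.data.shape[-1]
        n = T + L
        U = np.fft.rfft(u.data, n=n, axis=-1)
        K = np.fft.rfft(k.data, n=n, axis=-1)
        y = np.fft.irfft(U * K[None, :, :], n=n, axis=-1)[..., :T]
        def bwd(g, u=u, k=k, U=U, K=K, T=T, L=L, n=n):
            G = np.fft.rfft(g, n=n, axis=-1)
            if u.requires_grad:
                du = np.fft.irfft(G * np.conj(K)[None, :, :], n=n, axis=-1)[..., :T]
                u._accum(du)
            if k.requires_grad:
                dk = np.fft.irfft((G * np.conj(U)).sum(axis=0), n=n,
                                  axis=-1)[..., :L]
                k._accum(dk)
        return Tensor._result(y, (u, k), bwd)

    def softmax_cross_entropy(self, targets: np.ndarray):
        """Mean cross-entropy of (B, K) logits against integer targets."""
        z = self.data - self.data.max(axis=1, keepdims=True)
        ez = np.exp(z)
        p = ez / ez.sum(axis=1, keepdims=True)
        B = z.shape[0]
        loss = -np.mean(np.log(p[np.arange(B), targets] + 1e-300))
        def bwd(g, a=self, p=p, targets=targets, B=B):
            if a.requires_grad:
                d = p.copy()
                d[np.arange(B), targets] -= 1.0
                a._accum(g * d / B)
        return Tensor._result(loss, (self,), bwd)

    # -- autodiff driver ------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.array(g, dtype=float, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.array(1.0)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_graph(self) -> None:
        self._parents = ()
        self._backward = None


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    ez = np.exp(z)
    return ez / ez.sum(axis=-1, keepdims=True)


class Adam:
    """Adam with per-group learning rates (plain, no weight decay)."""

    def __init__(self, groups: list[dict]):
        # groups: [{"params": [Tensor, ...], "lr": float}, ...]
        self.groups = groups
        self.state: dict[int, tuple[np.ndarray, np.ndarray]] = {}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for g in self.groups:
            lr = g["lr"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                m, v = self.state.get(id(p), (np.zeros_like(p.data),
                                              np.zeros_like(p.data)))
                m = b1 * m + (1 - b1) * p.grad
                v = b2 * v + (1 - b2) * p.grad**2
                self.state[id(p)] = (m, v)
                mhat = m / (1 - b1**self.t)
                vhat = v / (1 - b2**self.t)
                p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)
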