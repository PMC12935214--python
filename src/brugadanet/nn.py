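"""Minimal reverse-mode automatic differentiation over numpy arrays.

Implements exactly the operations the 1D DenseNet backbone, the contrastive
losses and the gradient-based attributions require: broadcast add/mul, matmul,
same-padded 1D convolution (via an unfold/fold pair), batch normalisation,
average pooling, ReLU, channel concatenation, row L2-normalisation and fused
stable cross-entropy losses.  All tensors are float32; gradients accumulate
with ``+=`` so shared subgraphs (e.g. a similarity matrix built from one
embedding matrix and its transpose) differentiate correctly.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Conv1d",
    "Linear",
    "BatchNorm1d",
    "Adam",
    "relu",
    "concat",
    "avg_pool1d",
    "global_avg_pool",
    "normalize_rows",
    "matmul",
    "transpose",
    "softmax_cross_entropy",
    "sigmoid_bce_with_logits",
    "sigmoid",
    "softmax",
]

DTYPE = np.float32


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    @property
    def shape(self):
        return self.data.shape

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    # -- graph construction helpers ------------------------------------
    @staticmethod
    def _make(data, parents, backward):
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._parents = tuple(parents)
            out._backward = backward
        return out

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    # -- arithmetic ----------------------------------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    def __mul__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return Tensor._make(out_data, (self, other), backward)

    __radd__ = __add__
    __rmul__ = __mul__

    def __sub__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(other)
        return self + (other * -1.0)

    def mean(self) -> "Tensor":
        n = self.data.size

        def backward(g):
            if self.requires_grad:
                self._accum(np.full_like(self.data, g / n))

        return Tensor._make(self.data.mean(), (self,), backward)

    # -- backprop ------------------------------------------------------
    def backward(self) -> None:
        if self.data.ndim != 0:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()

        def visit(t: Tensor):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            order.append(t)

        visit(self)
        grads: dict[int, np.ndarray] = {id(self): np.asarray(1.0, dtype=DTYPE)}
        self.grad = grads[id(self)]
        for t in reversed(order):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)


class Parameter(Tensor):
    __slots__ = ("name", "block")

    def __init__(self, data, name: str = "", block: str = ""):
        super().__init__(data, requires_grad=True)
        self.name = name
        self.block = block  # freeze-group label, e.g. "block3" or "head"


# -- elementwise / structural ops --------------------------------------

def relu(x: Tensor) -> Tensor:
    mask = x.data > 0

    def backward(g):
        if x.requires_grad:
            x._accum(g * mask)

    return Tensor._make(x.data * mask, (x,), backward)


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(a, b)
                t._accum(g[tuple(sl)])

    return Tensor._make(data, tuple(tensors), backward)


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        if a.requires_grad:
            a._accum(g @ b.data.T)
        if b.requires_grad:
            b._accum(a.data.T @ g)

    return Tensor._make(out_data, (a, b), backward)


def transpose(x: Tensor) -> Tensor:
    def backward(g):
        if x.requires_grad:
            x._accum(g.T)

    return Tensor._make(x.data.T, (x,), backward)


def normalize_rows(x: Tensor, eps: float = 1e-8) -> Tensor:
    """L2-normalise each row; raises on a zero-norm row (degenerate embedding)."""
    norms = np.linalg.norm(x.data, axis=1, keepdims=True)
    if np.any(norms < eps):
        raise ValueError("zero-norm row cannot be L2-normalised")
    z = x.data / norms

    def backward(g):
        if x.requires_grad:
            # d(e/|e|) = (g - z (z.g)) / |e|
            dot = (z * g).sum(axis=1, keepdims=True)
            x._accum((g - z * dot) / norms)

    return Tensor._make(z, (x,), backward)


def avg_pool1d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping average pooling over the last axis (trailing remainder dropped)."""
    B, C, L = x.data.shape
    Lo = L // k
    view = x.data[:, :, : Lo * k].reshape(B, C, Lo, k)
    out_data = view.mean(axis=3)

    def backward(g):
        if x.requires_grad:
            gi = np.zeros_like(x.data)
            gi[:, :, : Lo * k] = np.repeat(g, k, axis=2) / k
            x._accum(gi)

    return Tensor._make(out_data, (x,), backward)


def global_avg_pool(x: Tensor) -> Tensor:
    B, C, L = x.data.shape
    out_data = x.data.mean(axis=2)

    def backward(g):
        if x.requires_grad:
            x._accum(np.repeat(g[:, :, None], L, axis=2) / L)

    return Tensor._make(out_data, (x,), backward)


# -- convolution -------------------------------------------------------

def _unfold(data: np.ndarray, k: int) -> np.ndarray:
    """(B, C, L) -> (B, L, C*k) patches with symmetric zero padding (same length)."""
    pl = (k - 1) // 2
    pr = k - 1 - pl
    padded = np.pad(data, ((0, 0), (0, 0), (pl, pr)))
    win = np.lib.stride_tricks.sliding_window_view(padded, k, axis=2)
    B, C, L, _ = win.shape
    return np.ascontiguousarray(win.transpose(0, 2, 1, 3)).reshape(B, L, C * k)


def conv1d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Same-padded 1D convolution; w has shape (C_out, C_in, k)."""
    Cout, Cin, k = w.data.shape
    B, C, L = x.data.shape
    cols = _unfold(x.data, k)  # (B, L, Cin*k)
    wmat = w.data.reshape(Cout, Cin * k)
    out_data = (cols @ wmat.T).transpose(0, 2, 1) + b.data[None, :, None]

    def backward(g):
        gmat = g.transpose(0, 2, 1)  # (B, L, Cout)
        if b.requires_grad:
            b._accum(g.sum(axis=(0, 2)))
        if w.requires_grad:
            gw = gmat.reshape(-1, Cout).T @ cols.reshape(-1, Cin * k)
            w._accum(gw.reshape(Cout, Cin, k))
        if x.requires_grad:
            gcols = gmat @ wmat  # (B, L, Cin*k)
            gcols = gcols.reshape(B, L, Cin, k)
            pl = (k - 1) // 2
            gpad = np.zeros((B, Cin, L + k - 1), dtype=DTYPE)
            for j in range(k):
                gpad[:, :, j : j + L] += gcols[:, :, :, j].transpose(0, 2, 1)
            x._accum(gpad[:, :, pl : pl + L])

    return Tensor._make(out_data, (x, w, b), backward)


# -- fused losses ------------------------------------------------------

def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer targets; stable log-softmax; fused backward."""
    z = logits.data.astype(np.float64)
    zmax = z.max(axis=1, keepdims=True)
    ez = np.exp(z - zmax)
    p = ez / ez.sum(axis=1, keepdims=True)
    n = z.shape[0]
    idx = (np.arange(n), np.asarray(targets))
    loss = -np.mean(np.log(p[idx] + 1e-300))

    def backward(g):
        if logits.requires_grad:
            gz = p.copy()
            gz[idx] -= 1.0
            logits._accum(g * gz / n)

    return Tensor._make(loss, (logits,), backward)


def sigmoid_bce_with_logits(logits: Tensor, y: np.ndarray) -> Tensor:
    """Mean binary cross-entropy on logits (1 column or flat); stable form."""
    z = logits.data.reshape(-1)
    yv = np.asarray(y, dtype=DTYPE).reshape(-1)
    # log(1+e^z) computed stably
    loss = np.mean(np.maximum(z, 0) - z * yv + np.log1p(np.exp(-np.abs(z))))
    s = 1.0 / (1.0 + np.exp(-z))
    n = z.size

    def backward(g):
        if logits.requires_grad:
            logits._accum((g * (s - yv) / n).reshape(logits.data.shape))

    return Tensor._make(loss, (logits,), backward)


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.asarray(z, dtype=np.float64)))


def softmax(z: np.ndarray) -> np.ndarray:
    z = np.asarray(z, dtype=np.float64)
    ez = np.exp(z - z.max(axis=-1, keepdims=True))
    return ez / ez.sum(axis=-1, keepdims=True)


# -- layers ------------------------------------------------------------

class Module:
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


class Conv1d(Module):
    def __init__(self, cin: int, cout: int, k: int, rng: np.random.Generator,
                 block: str = ""):
        scale = np.sqrt(2.0 / (cin * k))  # He initialisation
        self.w = Parameter(rng.normal(0.0, scale, size=(cout, cin, k)),
                           name="conv.w", block=block)
        self.b = Parameter(np.zeros(cout), name="conv.b", block=block)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.w, self.b)


class Linear(Module):
    def __init__(self, nin: int, nout: int, rng: np.random.Generator,
                 block: str = ""):
        scale = np.sqrt(2.0 / nin)
        self.w = Parameter(rng.normal(0.0, scale, size=(nin, nout)),
                           name="linear.w", block=block)
        self.b = Parameter(np.zeros(nout), name="linear.b", block=block)

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.w) + self.b


class BatchNorm1d(Module):
    """Per-channel batch normalisation over (batch, time) for (B, C, L) inputs.

    Running statistics (momentum 0.9) are used in eval mode so single-sample
    attribution passes are well defined.
    """

    def __init__(self, c: int, block: str = "", eps: float = 1e-5):
        self.gamma = Parameter(np.ones(c), name="bn.gamma", block=block)
        self.beta = Parameter(np.zeros(c), name="bn.beta", block=block)
        self.eps = eps
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.data.mean(axis=(0, 2))
            var = x.data.var(axis=(0, 2))
            self.running_mean = 0.9 * self.running_mean + 0.1 * mu.astype(DTYPE)
            self.running_var = 0.9 * self.running_var + 0.1 * var.astype(DTYPE)
        else:
            mu, var = self.running_mean, self.running_var
        std = np.sqrt(var + self.eps)
        xhat = (x.data - mu[None, :, None]) / std[None, :, None]
        out_data = xhat * self.gamma.data[None, :, None] + self.beta.data[None, :, None]
        n = x.data.shape[0] * x.data.shape[2]
        training = self.training
        gamma = self.gamma

        def backward(g):
            if gamma.requires_grad:
                gamma._accum((g * xhat).sum(axis=(0, 2)))
            if self.beta.requires_grad:
                self.beta._accum(g.sum(axis=(0, 2)))
            if x.requires_grad:
                gx_hat = g * gamma.data[None, :, None]
                if training:
                    # full batch-norm backward (mean and var depend on x)
                    t1 = gx_hat - gx_hat.mean(axis=(0, 2), keepdims=True)
                    t2 = xhat * (gx_hat * xhat).mean(axis=(0, 2), keepdims=True)
                    x._accum((t1 - t2) / std[None, :, None])
                else:
                    x._accum(gx_hat / std[None, :, None])

        return Tensor._make(out_data, (x, self.gamma, self.beta), backward)


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
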