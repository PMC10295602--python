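"""Minimal reverse-mode autodiff and CNN layers on numpy.

The segmentation network is small enough to train on a single CPU, so
the whole stack — tensors, convolution (im2col + GEMM), batch
normalisation, pooling, bilinear resizing, losses and Adam — lives here
in a few hundred lines. Gradients flow through an explicit tape: every
op returns a :class:`Tensor` holding a closure that scatters the
upstream gradient into its parents. Correctness is pinned by
finite-difference checks in the test suite.

All data is float32 NCHW. Everything is deterministic given the RNG
used at initialisation; no op consumes randomness.
"""

from __future__ import annotations

from functools import lru_cache
from typing import Callable, Iterable, Optional

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

DTYPE = np.float32


class Tensor:
    """A node in the computation graph: value, gradient slot, backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data,
        parents: tuple["Tensor", ...] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
        requires_grad: bool = False,
    ):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: Optional[np.ndarray] = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    def backward(self) -> None:
        """Backpropagate from a scalar loss through the tape."""
        if self.data.size != 1:
            raise ValueError("backward() must start from a scalar")
        topo: list[Tensor] = []
        visited: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; deep graphs overflow Python recursion
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if p.requires_grad:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def zero_grad(self) -> None:
        self.grad = None


def _accum(t: Tensor, g: np.ndarray) -> None:
    if not t.requires_grad:
        return
    if t.grad is None:
        t.grad = g.astype(DTYPE, copy=True)
    else:
        t.grad += g


def parameter(data, rng: Optional[np.random.Generator] = None) -> Tensor:
    return Tensor(data, requires_grad=True)


# ---------------------------------------------------------------------------
# ops
# ---------------------------------------------------------------------------

def conv2d(x: Tensor, weight: Tensor, bias: Tensor) -> Tensor:
    """Same-padded stride-1 2-D convolution (cross-correlation) via im2col."""
    n, c, h, w = x.data.shape
    o, c2, k, _ = weight.data.shape
    if c2 != c:
        raise ValueError(f"weight expects {c2} input channels, got {c}")
    p = k // 2
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p))) if p else x.data
    win = sliding_window_view(xp, (k, k), axis=(2, 3))  # n,c,h,w,k,k
    cols = np.ascontiguousarray(win.transpose(0, 2, 3, 1, 4, 5)).reshape(n * h * w, c * k * k)
    wmat = weight.data.reshape(o, c * k * k)
    out = cols @ wmat.T + bias.data
    out = np.ascontiguousarray(out.reshape(n, h, w, o).transpose(0, 3, 1, 2))

    def bwd(g: np.ndarray) -> None:
        gm = np.ascontiguousarray(g.transpose(0, 2, 3, 1)).reshape(n * h * w, o)
        _accum(bias, gm.sum(axis=0))
        _accum(weight, (gm.T @ cols).reshape(o, c, k, k))
        if x.requires_grad:
            dcols = (gm @ wmat).reshape(n, h, w, c, k, k).transpose(0, 3, 1, 2, 4, 5)
            dxp = np.zeros_like(xp)
            for i in range(k):
                for j in range(k):
                    dxp[:, :, i : i + h, j : j + w] += dcols[:, :, :, :, i, j]
            _accum(x, dxp[:, :, p : p + h, p : p + w] if p else dxp)

    return Tensor(out, parents=(x, weight, bias), backward=bwd)


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    out = x.data * mask

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * mask)

    return Tensor(out, parents=(x,), backward=bwd)


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data.astype(np.float64)))
    # keep probabilities strictly inside (0, 1) in float32
    s = np.clip(s, 1e-6, 1.0 - 1e-6).astype(DTYPE)

    def bwd(g: np.ndarray) -> None:
        _accum(x, g * s * (1.0 - s))

    return Tensor(s, parents=(x,), backward=bwd)


def add(a: Tensor, b: Tensor) -> Tensor:
    if a.data.shape != b.data.shape:
        raise ValueError(f"add shape mismatch: {a.data.shape} vs {b.data.shape}")
    out = a.data + b.data

    def bwd(g: np.ndarray) -> None:
        _accum(a, g)
        _accum(b, g)

    return Tensor(out, parents=(a, b), backward=bwd)


def concat(tensors: list[Tensor]) -> Tensor:
    """Concatenate along the channel axis."""
    out = np.concatenate([t.data for t in tensors], axis=1)
    splits = np.cumsum([t.data.shape[1] for t in tensors])[:-1]

    def bwd(g: np.ndarray) -> None:
        for t, piece in zip(tensors, np.split(g, splits, axis=1)):
            _accum(t, piece)

    return Tensor(out, parents=tuple(tensors), backward=bwd)


def max_pool2d(x: Tensor, factor: int) -> Tensor:
    """Non-overlapping max pooling with kernel = stride = factor."""
    n, c, h, w = x.data.shape
    if h % factor or w % factor:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool factor {factor}")
    ho, wo = h // factor, w // factor
    xr = x.data.reshape(n, c, ho, factor, wo, factor)
    out = xr.max(axis=(3, 5))

    def bwd(g: np.ndarray) -> None:
        if not x.requires_grad:
            return
        winners = xr == out[:, :, :, None, :, None]
        counts = winners.sum(axis=(3, 5), keepdims=True)  # split gradient over ties
        dxr = winners * (g[:, :, :, None, :, None] / counts)
        _accum(x, dxr.reshape(n, c, h, w))

    return Tensor(out, parents=(x,), backward=bwd)


@lru_cache(maxsize=None)
def _interp_matrix(n_in: int, factor: int) -> np.ndarray:
    """Dense 1-D bilinear interpolation matrix (n_in*factor, n_in),
    half-pixel-centre (align_corners=False) convention, edge-clamped."""
    n_out = n_in * factor
    s = (np.arange(n_out) + 0.5) / factor - 0.5
    i0 = np.floor(s).astype(int)
    frac = s - i0
    i0c = np.clip(i0, 0, n_in - 1)
    i1c = np.clip(i0 + 1, 0, n_in - 1)
    m = np.zeros((n_out, n_in), dtype=DTYPE)
    rows = np.arange(n_out)
    np.add.at(m, (rows, i0c), (1.0 - frac).astype(DTYPE))
    np.add.at(m, (rows, i1c), frac.astype(DTYPE))
    return m


def upsample_bilinear(x: Tensor, factor: int) -> Tensor:
    """Bilinear upsampling by an integer factor (separable dense matrices)."""
    n, c, h, w = x.data.shape
    mr = _interp_matrix(h, factor)
    mc = _interp_matrix(w, factor)
    out = np.matmul(np.matmul(mr, x.data), mc.T)

    def bwd(g: np.ndarray) -> None:
        if x.requires_grad:
            _accum(x, np.matmul(np.matmul(mr.T, g), mc))

    return Tensor(out, parents=(x,), backward=bwd)


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
    """Per-channel batch normalisation; running stats updated in place."""
    n, c, h, w = x.data.shape
    m = n * h * w
    if training:
        mu = x.data.mean(axis=(0, 2, 3))
        var = x.data.var(axis=(0, 2, 3))
        running_mean *= 1.0 - momentum
        running_mean += momentum * mu
        running_var *= 1.0 - momentum
        running_var += momentum * var * (m / max(m - 1, 1))  # unbiased for inference
    else:
        mu = running_mean
        var = running_var
    inv_std = (1.0 / np.sqrt(var + eps)).astype(DTYPE)
    xhat = (x.data - mu[None, :, None, None]) * inv_std[None, :, None, None]
    out = gamma.data[None, :, None, None] * xhat + beta.data[None, :, None, None]

    def bwd(g: np.ndarray) -> None:
        _accum(beta, g.sum(axis=(0, 2, 3)))
        _accum(gamma, (g * xhat).sum(axis=(0, 2, 3)))
        if not x.requires_grad:
            return
        gs = gamma.data[None, :, None, None] * inv_std[None, :, None, None]
        if training:
            sum_g = g.sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            sum_gx = (g * xhat).sum(axis=(0, 2, 3)).reshape(1, c, 1, 1)
            dx = gs * (g - sum_g / m - xhat * sum_gx / m)
        else:
            dx = gs * g
        _accum(x, dx)

    return Tensor(out, parents=(x, gamma, beta), backward=bwd)


def bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean binary cross-entropy computed stably from logits."""
    z = logits.data.astype(np.float64)
    y = np.asarray(targets, dtype=np.float64)
    loss = np.mean(np.maximum(z, 0.0) - z * y + np.log1p(np.exp(-np.abs(z))))
    p = 1.0 / (1.0 + np.exp(-z))

    def bwd(g: np.ndarray) -> None:
        _accum(logits, (float(g) * (p - y) / z.size).astype(DTYPE))

    return Tensor(np.float64(loss).astype(DTYPE), parents=(logits,), backward=bwd)


def soft_dice_loss(probs: Tensor, targets: np.ndarray, smooth: float = 1.0) -> Tensor:
    """1 - soft Dice overlap; complements BCE under heavy class imbalance."""
    p = probs.data.astype(np.float64)
    y = np.asarray(targets, dtype=np.float64)
    inter = float((p * y).sum())
    union = float(p.sum() + y.sum())
    loss = 1.0 - (2.0 * inter + smooth) / (union + smooth)

    def bwd(g: np.ndarray) -> None:
        d = -(2.0 * y * (union + smooth) - (2.0 * inter + smooth)) / (union + smooth) ** 2
        _accum(probs, (float(g) * d).astype(DTYPE))

    return Tensor(np.float64(loss).astype(DTYPE), parents=(probs,), backward=bwd)


def scalar_add(a: Tensor, b: Tensor, wa: float = 1.0, wb: float = 1.0) -> Tensor:
    out = wa * a.data + wb * b.data

    def bwd(g: np.ndarray) -> None:
        _accum(a, wa * g)
        _accum(b, wb * g)

    return Tensor(out, parents=(a, b), backward=bwd)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------

class Module:
    """Base class: parameter collection, train/eval mode, state (de)serialisation."""

    def __init__(self) -> None:
        self.training = True

    def _children(self) -> Iterable[tuple[str, "Module"]]:
        for name, value in vars(self).items():
            if isinstance(value, Module):
                yield name, value
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Tensor]:
        params = [v for v in vars(self).values() if isinstance(v, Tensor) and v.requires_grad]
        for _, child in self._children():
            params.extend(child.parameters())
        return params

    def num_params(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def train(self, flag: bool = True) -> "Module":
        self.training = flag
        for _, child in self._children():
            child.train(flag)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor) and value.requires_grad:
                state[prefix + name] = value.data.copy()
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                state[prefix + name] = value.copy()
        for name, child in self._children():
            state.update(child.state_dict(prefix + name + "/"))
        return state

    def load_state_dict(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for name, value in vars(self).items():
            key = prefix + name
            if isinstance(value, Tensor) and value.requires_grad:
                value.data = state[key].astype(DTYPE).reshape(value.data.shape)
            elif isinstance(value, np.ndarray) and name.startswith("running_"):
                value[...] = state[key]
        for name, child in self._children():
            child.load_state_dict(state, prefix + name + "/")

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


class Conv2d(Module):
    """Same-padded stride-1 convolution with He (fan-in) initialisation."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        self.weight = parameter(
            rng.normal(0.0, std, size=(out_channels, in_channels, kernel_size, kernel_size))
        )
        self.bias = parameter(np.zeros(out_channels))
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        super().__init__()
        self.gamma = parameter(np.ones(channels))
        self.beta = parameter(np.zeros(channels))
        self.running_mean = np.zeros(channels, dtype=np.float64)
        self.running_var = np.ones(channels, dtype=np.float64)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm(
            x, self.gamma, self.beta, self.running_mean, self.running_var,
            self.training, self.momentum, self.eps,
        )


class ConvBNReLU(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int, rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(in_channels, out_channels, kernel_size, rng)
        self.bn = BatchNorm2d(out_channels)

    def forward(self, x: Tensor) -> Tensor:
        return relu(self.bn(self.conv(x)))


class Adam:
    """Adam with the standard bias-corrected moment estimates."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1 ** self.t)
            vhat = v / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(DTYPE)
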