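"""Minimal 1-D neural-network layers with manual backprop.

Sequence tensors are ``(n, L, C)`` — batch, positions, channels; dense
tensors are ``(n, F)``.  Every layer caches what its backward pass needs,
exposes its parameters as ``Param`` records, and is trained with Adam on
a softmax cross-entropy loss.  Weight initialization is He-style and
fully determined by the generator passed to the constructor, so identical
seeds give identical parameter trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Param",
    "Layer",
    "DilatedConv1D",
    "PointwiseConv1D",
    "BatchNorm1D",
    "ReLU",
    "MaxPool1D",
    "AttentionPool",
    "LastPosition",
    "Dense",
    "Sequential",
    "ASPPModule",
    "TCNResidualBlock",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


@dataclass
class Param:
    value: np.ndarray
    grad: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.grad = np.zeros_like(self.value)


class Layer:
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dout: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def params(self) -> list[Param]:
        return []

    def children(self) -> list["Layer"]:
        return []

    def walk(self) -> list["Layer"]:
        out: list[Layer] = [self]
        for child in self.children():
            out.extend(child.walk())
        return out


def _he_init(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / max(fan_in, 1)), size=shape)


class DilatedConv1D(Layer):
    """Dilated 1-D convolution over ``(n, L, C)``.

    ``padding`` is one of ``"causal"`` (left zero-pad, length preserved),
    ``"same"`` (symmetric zero-pad, length preserved) or ``"valid"``
    (no pad, output length ``L - (k-1)*dilation``).  ``depthwise=True``
    convolves each input channel independently (weight ``(k, C)``).
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        dilation: int = 1,
        padding: str = "causal",
        depthwise: bool = False,
        rng: np.random.Generator | None = None,
    ):
        if kernel < 1 or dilation < 1:
            raise ValueError("kernel and dilation must be >= 1")
        if padding not in ("causal", "same", "valid"):
            raise ValueError(f"unknown padding {padding!r}")
        if depthwise and c_in != c_out:
            raise ValueError("depthwise conv requires c_in == c_out")
        rng = rng or np.random.default_rng(0)
        self.kernel, self.dilation, self.padding = kernel, dilation, padding
        self.depthwise = depthwise
        fan_in = kernel * (1 if depthwise else c_in)
        shape = (kernel, c_in) if depthwise else (kernel, c_in, c_out)
        self.w = Param(_he_init(rng, shape, fan_in))
        self.b = Param(np.zeros(c_out))

    def _pads(self) -> tuple[int, int]:
        span = (self.kernel - 1) * self.dilation
        if self.padding == "causal":
            return span, 0
        if self.padding == "same":
            return span // 2, span - span // 2
        return 0, 0

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        left, right = self._pads()
        xp = np.pad(x, ((0, 0), (left, right), (0, 0)))
        L_out = xp.shape[1] - (self.kernel - 1) * self.dilation
        if L_out < 1:
            raise ValueError("sequence too short for this kernel/dilation in valid mode")
        cols = np.stack(
            [xp[:, e * self.dilation : e * self.dilation + L_out, :] for e in range(self.kernel)],
            axis=2,
        )  # (n, L_out, k, C_in)
        self._cache = (cols, x.shape[1], left)
        if self.depthwise:
            y = np.einsum("nlec,ec->nlc", cols, self.w.value) + self.b.value
        else:
            y = np.einsum("nlec,eco->nlo", cols, self.w.value) + self.b.value
        return y

    def backward(self, dout: np.ndarray) -> np.ndarray:
        cols, L_in, left = self._cache
        n, L_out, k, c_in = cols.shape
        if self.depthwise:
            self.w.grad += np.einsum("nlec,nlc->ec", cols, dout)
            dcols = np.einsum("nlc,ec->nlec", dout, self.w.value)
        else:
            self.w.grad += np.einsum("nlec,nlo->eco", cols, dout)
            dcols = np.einsum("nlo,eco->nlec", dout, self.w.value)
        self.b.grad += dout.sum(axis=(0, 1))
        lpad, rpad = self._pads()
        dxp = np.zeros((n, L_in + lpad + rpad, c_in))
        for e in range(k):
            dxp[:, e * self.dilation : e * self.dilation + L_out, :] += dcols[:, :, e, :]
        return dxp[:, lpad : lpad + L_in, :]

    def params(self) -> list[Param]:
        return [self.w, self.b]


class PointwiseConv1D(Layer):
    """1x1 convolution (per-position linear map across channels)."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (c_in, c_out), c_in))
        self.b = Param(np.zeros(c_out))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += np.einsum("nlc,nlo->co", self._x, dout)
        self.b.grad += dout.sum(axis=(0, 1))
        return dout @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class BatchNorm1D(Layer):
    """Per-channel normalization over batch and position axes."""

    def __init__(self, channels: int, momentum: float = 0.9, eps: float = 1e-5):
        self.gamma = Param(np.ones(channels))
        self.beta = Param(np.zeros(channels))
        self.momentum, self.eps = momentum, eps
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if train:
            mean = x.mean(axis=(0, 1))
            var = x.var(axis=(0, 1))
            self.running_mean = self.momentum * self.running_mean + (1 - self.momentum) * mean
            self.running_var = self.momentum * self.running_var + (1 - self.momentum) * var
        else:
            mean, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        x_hat = (x - mean) * inv_std
        self._cache = (x_hat, inv_std, x.shape[0] * x.shape[1], train)
        return self.gamma.value * x_hat + self.beta.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x_hat, inv_std, m, trained = self._cache
        self.gamma.grad += (dout * x_hat).sum(axis=(0, 1))
        self.beta.grad += dout.sum(axis=(0, 1))
        dxhat = dout * self.gamma.value
        if not trained:
            return dxhat * inv_std
        return (
            inv_std / m
            * (m * dxhat - dxhat.sum(axis=(0, 1)) - x_hat * (dxhat * x_hat).sum(axis=(0, 1)))
        )

    def params(self) -> list[Param]:
        return [self.gamma, self.beta]


class ReLU(Layer):
    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._mask = x > 0
        return x * self._mask

    def backward(self, dout: np.ndarray) -> np.ndarray:
        return dout * self._mask


class MaxPool1D(Layer):
    """Non-overlapping max pooling along positions (stride == pool)."""

    def __init__(self, pool: int = 2):
        if pool < 1:
            raise ValueError("pool must be >= 1")
        self.pool = pool

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        n, L, c = x.shape
        if L < self.pool:
            raise ValueError(f"sequence length {L} shorter than pool kernel {self.pool}")
        L_out = L // self.pool
        xt = x[:, : L_out * self.pool, :].reshape(n, L_out, self.pool, c)
        self._argmax = xt.argmax(axis=2)
        self._shape = x.shape
        return xt.max(axis=2)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        n, L_out, c = dout.shape
        dx = np.zeros(self._shape)
        dxt = dx[:, : L_out * self.pool, :].reshape(n, L_out, self.pool, c)
        ni, li, ci = np.ogrid[:n, :L_out, :c]
        dxt[ni, li, self._argmax, ci] = dout
        return dx


class AttentionPool(Layer):
    """Softmax attention over positions.

    A learned projection scores each position; softmax over positions
    gives nonnegative weights summing to one, and the output is the
    weight-weighted sum of the position features: ``(n, L, C) -> (n, C)``.
    """

    def __init__(self, c_in: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (c_in,), c_in))
        self.b = Param(np.zeros(1))
        self.last_weights: np.ndarray | None = None

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        if x.shape[1] < 1:
            raise ValueError("empty sequence")
        scores = x @ self.w.value + self.b.value[0]        # (n, L)
        scores = scores - scores.max(axis=1, keepdims=True)
        e = np.exp(scores)
        a = e / e.sum(axis=1, keepdims=True)               # (n, L)
        self.last_weights = a
        self._cache = (x, a)
        return np.einsum("nl,nlc->nc", a, x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x, a = self._cache
        dx = a[:, :, None] * dout[:, None, :]
        ds = np.einsum("nlc,nc->nl", x, dout)
        da = a * (ds - np.einsum("nl,nl->n", a, ds)[:, None])   # softmax jacobian
        dx += da[:, :, None] * self.w.value[None, None, :]
        self.w.grad += np.einsum("nl,nlc->c", da, x)
        self.b.grad += np.array([da.sum()])
        return dx

    def params(self) -> list[Param]:
        return [self.w, self.b]


class LastPosition(Layer):
    """Take the final position's features: ``(n, L, C) -> (n, C)``."""

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x[:, -1, :]

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dx = np.zeros(self._shape)
        dx[:, -1, :] = dout
        return dx


class Dense(Layer):
    def __init__(self, f_in: int, f_out: int, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.w = Param(_he_init(rng, (f_in, f_out), f_in))
        self.b = Param(np.zeros(f_out))

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.w.value + self.b.value

    def backward(self, dout: np.ndarray) -> np.ndarray:
        self.w.grad += self._x.T @ dout
        self.b.grad += dout.sum(axis=0)
        return dout @ self.w.value.T

    def params(self) -> list[Param]:
        return [self.w, self.b]


class Sequential(Layer):
    def __init__(self, *layers: Layer):
        self.layers = list(layers)

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, train=train)
        return x

    def backward(self, dout: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            dout = layer.backward(dout)
        return dout

    def params(self) -> list[Param]:
        return [p for layer in self.layers for p in layer.params()]

    def children(self) -> list[Layer]:
        return self.layers


class ASPPModule(Layer):
    """Atrous spatial pyramid pooling over a 1-D sequence.

    One parallel branch per dilation rate, each a depthwise-separable
    dilated convolution (depthwise conv, then pointwise) followed by
    batch normalization and ReLU, all with same-padding so lengths
    align; branch outputs are concatenated along channels and fused by a
    pointwise convolution.
    """

    def __init__(
        self,
        c_in: int,
        rates: tuple[int, ...] = (1, 2, 4),
        branch_width: int = 4,
        fuse_width: int = 8,
        kernel: int = 3,
        rng: np.random.Generator | None = None,
        batch_norm: bool = True,
    ):
        if len(rates) == 0:
            raise ValueError("need at least one dilation rate")
        rng = rng or np.random.default_rng(0)
        self.rates = tuple(int(r) for r in rates)
        self.branches = []
        for rate in self.rates:
            stages: list[Layer] = [
                DilatedConv1D(c_in, c_in, kernel=kernel, dilation=rate,
                              padding="same", depthwise=True, rng=rng),
                PointwiseConv1D(c_in, branch_width, rng=rng),
            ]
            if batch_norm:
                stages.append(BatchNorm1D(branch_width))
            stages.append(ReLU())
            self.branches.append(Sequential(*stages))
        self.fuse = PointwiseConv1D(branch_width * len(self.rates), fuse_width, rng=rng)
        self.branch_width = branch_width
        self.fuse_width = fuse_width

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        outs = [br.forward(x, train=train) for br in self.branches]
        return self.fuse.forward(np.concatenate(outs, axis=2), train=train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dcat = self.fuse.backward(dout)
        w = self.branch_width
        dx = None
        for i, br in enumerate(self.branches):
            d = br.backward(dcat[:, :, i * w : (i + 1) * w])
            dx = d if dx is None else dx + d
        return dx

    def params(self) -> list[Param]:
        return [p for br in self.branches for p in br.params()] + self.fuse.params()

    def children(self) -> list[Layer]:
        return [*self.branches, self.fuse]


class TCNResidualBlock(Layer):
    """ReLU(x + F(x)) with F = causal dilated conv, ReLU, causal dilated conv.

    A pointwise projection matches channel counts when they differ.
    """

    def __init__(
        self,
        c_in: int,
        c_out: int,
        kernel: int = 3,
        dilation: int = 1,
        rng: np.random.Generator | None = None,
    ):
        rng = rng or np.random.default_rng(0)
        self.conv1 = DilatedConv1D(c_in, c_out, kernel, dilation, "causal", rng=rng)
        self.relu1 = ReLU()
        self.conv2 = DilatedConv1D(c_out, c_out, kernel, dilation, "causal", rng=rng)
        self.project = PointwiseConv1D(c_in, c_out, rng=rng) if c_in != c_out else None
        self.relu_out = ReLU()

    def forward(self, x: np.ndarray, train: bool = False) -> np.ndarray:
        fx = self.conv2.forward(self.relu1.forward(self.conv1.forward(x, train), train), train)
        skip = self.project.forward(x, train) if self.project is not None else x
        if fx.shape != skip.shape:
            raise RuntimeError("residual shape mismatch after projection")
        return self.relu_out.forward(skip + fx, train)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        dsum = self.relu_out.backward(dout)
        dx_f = self.conv1.backward(self.relu1.backward(self.conv2.backward(dsum)))
        dx_skip = self.project.backward(dsum) if self.project is not None else dsum
        return dx_f + dx_skip

    def params(self) -> list[Param]:
        ps = self.conv1.params() + self.conv2.params()
        if self.project is not None:
            ps += self.project.params()
        return ps

    def children(self) -> list[Layer]:
        kids: list[Layer] = [self.conv1, self.conv2]
        if self.project is not None:
            kids.append(self.project)
        return kids


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean cross-entropy and its gradient w.r.t. the logits."""
    probs = softmax(logits)
    n = logits.shape[0]
    eps = 1e-12
    loss = -float(np.mean(np.log(probs[np.arange(n), labels] + eps)))
    grad = probs.copy()
    grad[np.arange(n), labels] -= 1.0
    return loss, grad / n


class Adam:
    """Adam over a flat parameter list (decoupled from the metaheuristic's
    beta1/beta2, which belong to the egret-swarm update)."""

    def __init__(self, params: list[Param], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * p.grad
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * p.grad ** 2
            m_hat = self.m[i] / (1 - self.beta1 ** self.t)
            v_hat = self.v[i] / (1 - self.beta2 ** self.t)
            p.value -= self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
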