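"""Layers, losses, and the Adam optimizer used by the learned components.

Everything operates on :class:`wsimil._autodiff.Tensor`. Parameters are
initialized with He-style scaling from a caller-supplied generator so every
training run is reproducible from its seed.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor


class Dense:
    """Fully connected layer ``y = x W + b``."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / n_in)
        self.weight = Tensor(rng.normal(0.0, scale, size=(n_in, n_out)), requires_grad=True)
        self.bias = Tensor(np.zeros(n_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


class Conv2d:
    """Strided 2-D convolution (NCHW, VALID padding)."""

    def __init__(self, c_in: int, c_out: int, kernel: int, stride: int, rng: np.random.Generator):
        fan_in = c_in * kernel * kernel
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Tensor(
            rng.normal(0.0, scale, size=(c_out, c_in, kernel, kernel)), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride

    def __call__(self, x: Tensor) -> Tensor:
        return x.conv2d(self.weight, self.bias, stride=self.stride)

    def parameters(self) -> list[Tensor]:
        return [self.weight, self.bias]


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, H, W) -> (N, C) channel means."""
    return x.mean(axis=(2, 3))


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy of integer ``labels`` under softmax of ``logits``."""
    n = logits.shape[0]
    lse = logits.logsumexp(axis=1)
    picked = (logits * Tensor(np.eye(logits.shape[1])[labels])).sum(axis=1)
    return (lse - picked).sum() / float(n)


def bce_with_logits(logit: Tensor, target: float | np.ndarray) -> Tensor:
    """Bernoulli negative log-likelihood, numerically stable in the logit."""
    t = np.asarray(target, dtype=np.float64)
    # log(1 + e^x) = max(x, 0) + log(1 + e^-|x|)
    x = logit
    pos = x.relu()
    absx = x.relu() + (-x).relu()
    softplus = pos + ((-absx).exp() + 1.0).log()
    return (softplus - x * t).sum() / float(max(np.size(t), 1))


class Adam:
    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = b1 * self.m[i] + (1 - b1) * p.grad
            self.v[i] = b2 * self.v[i] + (1 - b2) * p.grad**2
            mhat = self.m[i] / (1 - b1**self.t)
            vhat = self.v[i] / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state(self) -> dict:
        return {"m": [m.copy() for m in self.m], "v": [v.copy() for v in self.v], "t": self.t}


def segment_sum(x: Tensor, seg_ids: np.ndarray, n_seg: int) -> Tensor:
    """Sum rows of ``x`` (N, d) by segment -> (n_seg, d)."""
    ind = np.zeros((n_seg, seg_ids.shape[0]))
    ind[seg_ids, np.arange(seg_ids.shape[0])] = 1.0
    return Tensor(ind) @ x


def segment_softmax(scores: Tensor, seg_ids: np.ndarray, n_seg: int) -> Tensor:
    """Softmax of (N, 1) ``scores`` within each segment."""
    shift = np.full(n_seg, -np.inf)
    np.maximum.at(shift, seg_ids, scores.data[:, 0])
    e = (scores - Tensor(shift[seg_ids, None])).exp()
    denom = segment_sum(e, seg_ids, n_seg)
    return e / denom.take(seg_ids, axis=0)


def snapshot(params: list[Tensor]) -> list[np.ndarray]:
    return [p.data.copy() for p in params]


def restore(params: list[Tensor], saved: list[np.ndarray]) -> None:
    for p, s in zip(params, saved):
        p.data[...] = s
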