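"""Neural-network building blocks on top of the autodiff core.

Layers hold their parameters as :class:`~stabsense._autograd.Tensor` objects;
``params()`` returns the flat list an optimizer updates in place. All layers
are deterministic given the ``numpy.random.Generator`` used at construction.
"""

from __future__ import annotations

import numpy as np

from ._autograd import Tensor, concat

__all__ = [
    "Dense",
    "BatchNorm1d",
    "GLUBlock",
    "MLP",
    "AdamW",
    "cosine_lr",
    "timestep_embedding",
]


class Dense:
    """Affine layer ``x @ W + b`` with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, bias: bool = True):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Tensor(rng.uniform(-limit, limit, size=(n_in, n_out)), requires_grad=True)
        self.b = Tensor(np.zeros(n_out), requires_grad=True) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out = x @ self.W
        return out + self.b if self.b is not None else out

    def params(self):
        return [self.W] + ([self.b] if self.b is not None else [])


class BatchNorm1d:
    """Batch normalization with running statistics for eval mode."""

    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n), requires_grad=True)
        self.beta = Tensor(np.zeros(n), requires_grad=True)
        self.running_mean = np.zeros(n)
        self.running_var = np.ones(n)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training and x.data.shape[0] > 1:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mu.data.ravel()
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var.data.ravel()
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            xhat = (x - self.running_mean) * (self.running_var + self.eps) ** -0.5
        return xhat * self.gamma + self.beta

    def params(self):
        return [self.gamma, self.beta]


class GLUBlock:
    """Dense -> BatchNorm -> gated linear unit, the feature-transformer cell."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.fc = Dense(n_in, 2 * n_out, rng)
        self.bn = BatchNorm1d(2 * n_out)
        self.n_out = n_out

    def __call__(self, x: Tensor) -> Tensor:
        h = self.bn(self.fc(x))
        a = h[:, : self.n_out]
        g = h[:, self.n_out :]
        return a * g.sigmoid()

    def params(self):
        return self.fc.params() + self.bn.params()

    def set_training(self, mode: bool):
        self.bn.training = mode


class MLP:
    """Plain feed-forward network with ReLU hidden activations."""

    def __init__(self, sizes, rng: np.random.Generator, final_activation=None):
        self.layers = [Dense(a, b, rng) for a, b in zip(sizes[:-1], sizes[1:])]
        self.final_activation = final_activation

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers[:-1]:
            x = layer(x).relu()
        x = self.layers[-1](x)
        if self.final_activation is not None:
            x = self.final_activation(x)
        return x

    def params(self):
        return [p for layer in self.layers for p in layer.params()]


class AdamW:
    """AdamW optimizer (decoupled weight decay), updating tensors in place."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8, weight_decay=0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            if self.weight_decay:
                p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(base_lr: float, step: int, total_steps: int, floor: float = 1e-6) -> float:
    """Cosine annealing from ``base_lr`` down to ``floor``."""
    frac = min(step / max(total_steps, 1), 1.0)
    return floor + 0.5 * (base_lr - floor) * (1 + np.cos(np.pi * frac))


def timestep_embedding(t: np.ndarray, dim: int, max_period: float = 10000.0) -> np.ndarray:
    """Sinusoidal embedding of integer timesteps, shape (len(t), dim)."""
    half = dim // 2
    freqs = np.exp(-np.log(max_period) * np.arange(half) / max(half - 1, 1))
    args = np.asarray(t, dtype=np.float64)[:, None] * freqs[None, :]
    emb = np.concatenate([np.sin(args), np.cos(args)], axis=1)
    if dim % 2:
        emb = np.concatenate([emb, np.zeros((emb.shape[0], 1))], axis=1)
    return emb
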