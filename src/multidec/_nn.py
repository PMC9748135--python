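"""Dense layers, batch normalization and optimizers on the autodiff engine.

Hidden layers follow the model's convention: affine -> batch normalization ->
ELU. Batch-norm keeps running statistics; in evaluation mode (used whenever
the latent space is read out for clustering decisions) the running statistics
are frozen so inference is deterministic.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import DTYPE, Tensor, parameter


class Dense:
    """Affine map with fan-in-scaled Gaussian initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(1.0 / n_in)
        self.W = parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.b = parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class BatchNorm:
    def __init__(self, n: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = parameter(np.ones(n))
        self.beta = parameter(np.zeros(n))
        self.running_mean = np.zeros(n, dtype=DTYPE)
        self.running_var = np.ones(n, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        if training:
            mu = x.mean(axis=0, keepdims=True)
            var = ((x - mu) ** 2).mean(axis=0, keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.ravel()
            self.running_var = (1 - m) * self.running_var + m * var.data.ravel()
            xn = (x - mu) / (var + self.eps).sqrt()
        else:
            xn = (x - Tensor(self.running_mean)) / Tensor(np.sqrt(self.running_var + self.eps))
        return xn * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class HiddenStack:
    """Sequence of (Dense -> BatchNorm -> ELU) blocks."""

    def __init__(self, n_in: int, widths: list[int], rng: np.random.Generator):
        self.blocks = []
        d = n_in
        for w in widths:
            self.blocks.append((Dense(d, w, rng), BatchNorm(w)))
            d = w
        self.n_out = d

    def __call__(self, x: Tensor, training: bool) -> Tensor:
        for dense, bn in self.blocks:
            x = bn(dense(x), training).elu()
        return x

    def parameters(self):
        out = []
        for dense, bn in self.blocks:
            out += dense.parameters() + bn.parameters()
        return out


class Adam:
    """Adam with the AMSGrad variant."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8,
                 amsgrad: bool = True):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.amsgrad = amsgrad
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.vhat = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        bc1 = 1 - self.b1 ** self.t
        bc2 = 1 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            if self.amsgrad:
                np.maximum(self.vhat[i], self.v[i], out=self.vhat[i])
                denom = np.sqrt(self.vhat[i] / bc2) + self.eps
            else:
                denom = np.sqrt(self.v[i] / bc2) + self.eps
            p.data -= self.lr * (self.m[i] / bc1) / denom


class Adadelta:
    def __init__(self, params, lr: float = 1.0, rho: float = 0.95, eps: float = 1e-6):
        self.params = list(params)
        self.lr, self.rho, self.eps = lr, rho, eps
        self.sq_grad = [np.zeros_like(p.data) for p in self.params]
        self.sq_delta = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.sq_grad[i] = self.rho * self.sq_grad[i] + (1 - self.rho) * g * g
            delta = np.sqrt((self.sq_delta[i] + self.eps) / (self.sq_grad[i] + self.eps)) * g
            self.sq_delta[i] = self.rho * self.sq_delta[i] + (1 - self.rho) * delta * delta
            p.data -= self.lr * delta
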