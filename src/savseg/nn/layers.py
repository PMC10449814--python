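"""Parameterised layers and the Adam optimiser for the numpy autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, conv2d, relu

__all__ = ["Conv2d", "ConvRelu", "Module", "Adam"]


class Module:
    """Base class: recursively collects parameter Tensors from attributes."""

    def parameters(self):
        params = []

        def collect(v):
            if isinstance(v, Tensor):
                if v.requires_grad:
                    params.append(v)
            elif isinstance(v, Module):
                for item in vars(v).values():
                    collect(item)
            elif isinstance(v, (list, tuple)):
                for item in v:
                    collect(item)

        for v in vars(self).values():
            collect(v)
        # deduplicate while preserving order (shared submodules appear once)
        seen, unique = set(), []
        for p in params:
            if id(p) not in seen:
                seen.add(id(p))
                unique.append(p)
        return unique

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_dict(self):
        return {f"p{i}": p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state):
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError("state dict does not match model parameters")
        for i, p in enumerate(params):
            arr = np.asarray(state[f"p{i}"])
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i} shape mismatch")
            p.data = arr.astype(np.float64)


class Conv2d(Module):
    """Stride-1 'same' convolution with He-normal init."""

    def __init__(self, c_in: int, c_out: int, kernel: int, rng: np.random.Generator,
                 dilation: int = 1):
        fan_in = c_in * kernel * kernel
        std = np.sqrt(2.0 / fan_in)
        self.w = Tensor(rng.normal(0.0, std, (c_out, c_in, kernel, kernel)),
                        requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)
        self.dilation = dilation

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.w, self.b, dilation=self.dilation)


class ConvRelu(Module):
    def __init__(self, c_in, c_out, kernel, rng, dilation=1):
        self.conv = Conv2d(c_in, c_out, kernel, rng, dilation=dilation)

    def __call__(self, x: Tensor) -> Tensor:
        return relu(self.conv(x))


class Adam:
    """Adam with the study's defaults (alpha 1e-4, beta1 0.9, beta2 0.999)."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
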