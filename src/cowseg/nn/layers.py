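"""Neural-network modules built on the autograd core."""

from __future__ import annotations

import numpy as np

from .autograd import DTYPE, Parameter, Tensor, conv2d


class Module:
    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            params.extend(_collect(v))
        return params

    def modules(self) -> list["Module"]:
        mods = [self]
        for v in self.__dict__.values():
            mods.extend(_collect_modules(v))
        return mods

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    # checkpointing -----------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for i, p in enumerate(self.parameters()):
            state[f"p{i}"] = p.data
        for j, (m, name) in enumerate(self._buffers()):
            state[f"b{j}_{name}"] = getattr(m, name)
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        for i, p in enumerate(self.parameters()):
            arr = state[f"p{i}"]
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for parameter {i}: {arr.shape} vs {p.data.shape}")
            p.data = arr.astype(DTYPE)
        for j, (m, name) in enumerate(self._buffers()):
            setattr(m, name, state[f"b{j}_{name}"].astype(DTYPE))

    def _buffers(self):
        out = []
        for m in self.modules():
            if isinstance(m, BatchNorm2d):
                out.append((m, "running_mean"))
                out.append((m, "running_var"))
        return out


def _collect(v) -> list[Parameter]:
    if isinstance(v, Parameter):
        return [v]
    if isinstance(v, Module):
        return v.parameters()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect(item))
        return out
    return []


def _collect_modules(v) -> list[Module]:
    if isinstance(v, Module):
        return v.modules()
    if isinstance(v, (list, tuple)):
        out = []
        for item in v:
            out.extend(_collect_modules(item))
        return out
    return []


class Conv2d(Module):
    """2-D convolution (He-initialized); supports stride, padding, dilation
    and non-square kernels."""

    def __init__(self, c_in, c_out, kernel_size, stride=1, padding=0, dilation=1,
                 bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        kh, kw = (kernel_size, kernel_size) if isinstance(kernel_size, int) else kernel_size
        fan_in = c_in * kh * kw
        std = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(c_out, c_in, kh, kw)))
        self.bias = Parameter(np.zeros(c_out)) if bias else None
        self.stride, self.padding, self.dilation = stride, padding, dilation

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, self.stride, self.padding, self.dilation)


class Linear(Module):
    def __init__(self, n_in, n_out, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        std = np.sqrt(2.0 / n_in)
        self.weight = Parameter(rng.normal(0.0, std, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


class BatchNorm2d(Module):
    """Batch normalization over (N,H,W) per channel, with running statistics
    for evaluation mode."""

    def __init__(self, c, momentum=0.1, eps=1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(c))
        self.beta = Parameter(np.zeros(c))
        self.running_mean = np.zeros(c, dtype=DTYPE)
        self.running_var = np.ones(c, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2.0).mean(axis=(0, 2, 3), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.reshape(-1))
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.reshape(-1))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        else:
            mu = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
            xhat = (x - mu) * (var + self.eps) ** -0.5
        return xhat * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class Sequential(Module):
    def __init__(self, *mods: Module):
        super().__init__()
        self.mods = list(mods)

    def forward(self, x: Tensor) -> Tensor:
        for m in self.mods:
            x = m(x)
        return x


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class SGD:
    """Stochastic gradient descent with momentum and decoupled L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.9,
                 weight_decay: float = 0.0):
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.velocity = [np.zeros_like(p.data) for p in params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self.velocity):
            if p.grad is None:
                continue
            g = p.grad + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
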