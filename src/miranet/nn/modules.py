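"""Parameter containers and the Adam optimizer for the numpy autograd engine."""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, add, conv2d, matmul


class Module:
    """Base class: recursively exposes named parameters for optimization/IO."""

    def parameters(self) -> dict[str, Tensor]:
        out: dict[str, Tensor] = {}
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out[name] = val
            elif isinstance(val, Module):
                for sub, t in val.parameters().items():
                    out[f"{name}.{sub}"] = t
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            out[f"{name}.{i}.{sub}"] = t
        return out

    def zero_grad(self) -> None:
        for t in self.parameters().values():
            t.grad = None

    def n_parameters(self) -> int:
        return sum(t.data.size for t in self.parameters().values())

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        missing = set(params) ^ set(state)
        if missing:
            raise KeyError(f"state dict mismatch on keys: {sorted(missing)}")
        for k, t in params.items():
            if t.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for {k}")
            t.data = np.ascontiguousarray(state[k], dtype=np.float32)


class Conv2d(Module):
    """3x3 (or kxk) convolution with He-normal weights and zero bias.

    Activations are channels-last (NHWC); weights are (kh, kw, C_in, C_out).
    """

    def __init__(self, c_in: int, c_out: int, kernel: int = 3, stride: int = 1,
                 pad: int | None = None, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / (c_in * kernel * kernel))
        self.weight = Tensor(rng.normal(0.0, scale, (kernel, kernel, c_in, c_out)),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(c_out), requires_grad=True)
        self.stride = stride
        self.pad = kernel // 2 if pad is None else pad

    def __call__(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias, stride=self.stride, pad=self.pad)


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator | None = None,
                 zero_init: bool = False):
        rng = rng or np.random.default_rng(0)
        if zero_init:
            w = np.zeros((d_in, d_out))
        else:
            w = rng.normal(0.0, np.sqrt(2.0 / d_in), (d_in, d_out))
        self.weight = Tensor(w, requires_grad=True)
        self.bias = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return add(matmul(x, self.weight), self.bias)


class Adam:
    """Adaptive moment estimation with the standard bias correction."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 lr_scale: dict[str, float] | None = None):
        self.params = params
        self.lr = lr
        self.lr_scale = lr_scale or {}
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(p.data) for k, p in params.items()}
        self.v = {k: np.zeros_like(p.data) for k, p in params.items()}

    def step(self) -> None:
        self.t += 1
        c1 = 1.0 - self.b1 ** self.t
        c2 = 1.0 - self.b2 ** self.t
        for k, p in self.params.items():
            if p.grad is None:  # parameter not on the loss path this step
                continue
            g = p.grad
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            lr = self.lr * self.lr_scale.get(k, 1.0)
            p.data = p.data - lr * (self.m[k] / c1) / (np.sqrt(self.v[k] / c2) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None
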