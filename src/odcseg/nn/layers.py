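"""Layer/module abstractions over the autodiff core.

Modules hold named parameters (:class:`~odcseg.nn.autodiff.Tensor` with
``requires_grad=True``) plus non-trainable buffers (batch-norm running
statistics).  Initialisation is He-style and driven by an explicit
``numpy.random.Generator`` so model builds are reproducible.
"""

from __future__ import annotations

import numpy as np

from .autodiff import (
    DTYPE,
    Tensor,
    batch_norm2d,
    conv2d,
    max_pool2d,
    upsample_bilinear2d,
)

__all__ = ["Module", "Conv2d", "BatchNorm2d", "ReLU", "LeakyReLU",
           "MaxPool2d", "Sequential"]


class Module:
    """Base class: parameter registry, train/eval mode, state (de)serialisation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        super().__setattr__(name, value)

    def register_parameter(self, name: str, value: np.ndarray) -> Tensor:
        t = Tensor(value, requires_grad=True)
        self._params[name] = t
        setattr(self, name, t)
        return t

    def register_buffer(self, name: str, value: np.ndarray) -> np.ndarray:
        arr = np.asarray(value, dtype=DTYPE)
        self._buffers[name] = arr
        setattr(self, name, arr)
        return arr

    # ------------------------------------------------------------------
    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield prefix + name, p
        for mod_name, mod in self._modules.items():
            yield from mod.named_parameters(prefix + mod_name + ".")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield prefix + name, b
        for mod_name, mod in self._modules.items():
            yield from mod.named_buffers(prefix + mod_name + ".")

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self, mode: bool = True) -> "Module":
        self.training = mode
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self) -> "Module":
        return self.train(False)

    # ------------------------------------------------------------------
    def state_dict(self) -> dict[str, np.ndarray]:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        state.update({"buffer:" + n: b.copy() for n, b in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self.named_buffers())
        for key, value in state.items():
            if key.startswith("buffer:"):
                buf = buffers[key[len("buffer:"):]]
                buf[...] = value
            else:
                p = params[key]
                if p.data.shape != value.shape:
                    raise ValueError(f"shape mismatch for parameter {key!r}")
                p.data = np.asarray(value, dtype=DTYPE).copy()

    def num_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, *,
                 rng: np.random.Generator):
        super().__init__()
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        std = np.sqrt(2.0 / fan_in)
        w = rng.normal(0.0, std, (out_channels, in_channels,
                                  kernel_size, kernel_size))
        self.register_parameter("weight", w.astype(DTYPE))
        self.register_parameter("bias", np.zeros(out_channels, dtype=DTYPE))

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.weight, self.bias,
                      stride=self.stride, padding=self.padding)


class BatchNorm2d(Module):
    def __init__(self, num_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        super().__init__()
        self.momentum = momentum
        self.eps = eps
        self.register_parameter("gamma", np.ones(num_features, dtype=DTYPE))
        self.register_parameter("beta", np.zeros(num_features, dtype=DTYPE))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        return batch_norm2d(x, self.gamma, self.beta,
                            self.running_mean, self.running_var,
                            training=self.training,
                            momentum=self.momentum, eps=self.eps)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.negative_slope)


class MaxPool2d(Module):
    def __init__(self, kernel: int = 2):
        super().__init__()
        self.kernel = kernel

    def forward(self, x: Tensor) -> Tensor:
        return max_pool2d(x, self.kernel)


class Upsample(Module):
    """Bilinear spatial resize to ``scale``× the input size."""

    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x: Tensor) -> Tensor:
        _, _, h, w = x.shape
        return upsample_bilinear2d(x, (h * self.scale, w * self.scale))


class Sequential(Module):
    def __init__(self, *modules: Module):
        super().__init__()
        self._seq = list(modules)
        for i, mod in enumerate(modules):
            setattr(self, f"layer{i}", mod)

    def forward(self, x: Tensor) -> Tensor:
        for mod in self._seq:
            x = mod(x)
        return x
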