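"""Neural-network building blocks on top of :mod:`mcvbmd.nn.autodiff`.

Follows the familiar module pattern: each layer owns named parameters,
``forward`` builds the autodiff graph, and ``train()``/``eval()`` toggle
behaviour of dropout and batch normalisation.
"""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor

__all__ = [
    "Module", "Sequential", "Conv", "BatchNorm", "ReLU", "LeakyReLU",
    "MaxPool", "Upsample", "Dropout", "Sigmoid",
]


class Module:
    """Base class: parameter registry plus train/eval mode propagation."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._children: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Module):
            self.__dict__.setdefault("_children", {})[name] = value
        super().__setattr__(name, value)

    def register(self, name: str, array: np.ndarray) -> Tensor:
        t = Tensor(array, requires_grad=True)
        self._params[name] = t
        return t

    def parameters(self) -> list[Tensor]:
        out = list(self._params.values())
        for child in self._children.values():
            out.extend(child.parameters())
        return out

    def named_parameters(self, prefix: str = "") -> dict[str, Tensor]:
        out = {prefix + name: t for name, t in self._params.items()}
        for cname, child in self._children.items():
            out.update(child.named_parameters(prefix + cname + "."))
        return out

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {}
        for cname, child in self._children.items():
            out.update(child.buffers(prefix + cname + "."))
        return out

    def train(self):
        self.training = True
        for child in self._children.values():
            child.train()
        return self

    def eval(self):
        self.training = False
        for child in self._children.values():
            child.eval()
        return self

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out = {k: v.data.copy() for k, v in self.named_parameters().items()}
        out.update({"buffer:" + k: v.copy() for k, v in self.buffers().items()})
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.named_parameters()
        buffers = self.buffers()
        for key, value in state.items():
            if key.startswith("buffer:"):
                buffers[key[len("buffer:"):]][...] = value
            else:
                params[key].data[...] = value

    def __call__(self, *args) -> Tensor:
        return self.forward(*args)

    def forward(self, *args) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            self._children[str(i)] = layer

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


class Conv(Module):
    """N-d convolution (2-D or 3-D inferred from the input) with He init."""

    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 ndim: int, stride: int = 1, padding: int | None = None,
                 bias: bool = True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng()
        self.stride = stride
        self.padding = kernel_size // 2 if padding is None else padding
        fan_in = in_channels * kernel_size**ndim
        std = np.sqrt(2.0 / fan_in)
        shape = (out_channels, in_channels) + (kernel_size,) * ndim
        self.weight = self.register("weight", rng.normal(0.0, std, shape))
        self.bias = self.register("bias", np.zeros(out_channels)) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        return x.conv(self.weight, self.bias, stride=self.stride,
                      padding=self.padding)


class BatchNorm(Module):
    """Batch normalisation over (batch, *spatial) with running statistics."""

    def __init__(self, num_channels: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        self.gamma = self.register("gamma", np.ones(num_channels))
        self.beta = self.register("beta", np.zeros(num_channels))
        self.running_mean = np.zeros(num_channels, dtype=np.float32)
        self.running_var = np.ones(num_channels, dtype=np.float32)

    def buffers(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + "running_mean": self.running_mean,
               prefix + "running_var": self.running_var}
        out.update(super().buffers(prefix))
        return out

    def forward(self, x: Tensor) -> Tensor:
        axes = (0,) + tuple(range(2, x.ndim))
        bshape = (1, -1) + (1,) * (x.ndim - 2)
        if self.training:
            mean = x.mean(axis=axes, keepdims=True)
            var = ((x - mean) ** 2.0).mean(axis=axes, keepdims=True)
            m = self.momentum
            self.running_mean += m * (mean.data.reshape(-1) - self.running_mean)
            self.running_var += m * (var.data.reshape(-1) - self.running_var)
        else:
            mean = Tensor(self.running_mean.reshape(bshape))
            var = Tensor(self.running_var.reshape(bshape))
        xhat = (x - mean) * ((var + self.eps) ** -0.5)
        return xhat * self.gamma.reshape(*bshape) + self.beta.reshape(*bshape)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.01):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.negative_slope)


class MaxPool(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return x.max_pool(self.factor)


class Upsample(Module):
    def __init__(self, factor: int = 2):
        super().__init__()
        self.factor = factor

    def forward(self, x: Tensor) -> Tensor:
        return x.upsample_nearest(self.factor)


class Dropout(Module):
    """Inverted dropout; active in training mode only."""

    def __init__(self, p: float, rng: np.random.Generator | None = None):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng()

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * Tensor(mask)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()
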