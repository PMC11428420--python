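"""Network layer primitives built on the autodiff engine.

Provides a small ``Module`` hierarchy (convolution, instance/batch
normalization, spectral normalization, activations, Sequential) plus the Adam
optimizer and Xavier-uniform initialization used across the generator and
discriminator stacks.
"""

from __future__ import annotations

from typing import Iterator

import numpy as np

from .autodiff import Tensor, as_tensor, conv2d, no_grad

__all__ = [
    "Module",
    "Parameter",
    "Conv2d",
    "SpectralNorm",
    "InstanceNorm2d",
    "BatchNorm2d",
    "LeakyReLU",
    "Sigmoid",
    "Sequential",
    "Identity",
    "Adam",
    "xavier_uniform_",
    "xavier_bound",
]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Base class: parameter/buffer registration, train/eval mode, state dict."""

    def __init__(self):
        self._parameters: dict[str, Parameter] = {}
        self._buffers: dict[str, np.ndarray] = {}
        self._modules: dict[str, "Module"] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self.__dict__.setdefault("_parameters", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def register_buffer(self, name: str, value: np.ndarray) -> None:
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def set_buffer(self, name: str, value: np.ndarray) -> None:
        if name not in self._buffers:
            raise KeyError(name)
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for name, p in self._parameters.items():
            yield prefix + name, p
        for mname, m in self._modules.items():
            yield from m.named_parameters(prefix + mname + ".")

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = "") -> Iterator[tuple[str, np.ndarray]]:
        for name in self._buffers:
            yield prefix + name, self._buffers[name]
        for mname, m in self._modules.items():
            yield from m.named_buffers(prefix + mname + ".")

    def modules(self) -> Iterator["Module"]:
        yield self
        for m in self._modules.values():
            yield from m.modules()

    def train(self, mode: bool = True) -> "Module":
        for m in self.modules():
            m.training = mode
        return self

    def astype(self, dtype) -> "Module":
        """Cast all parameters and buffers in the module tree."""
        dtype = np.dtype(dtype)
        for m in self.modules():
            for p in m._parameters.values():
                p.data = p.data.astype(dtype)
            for name, buf in list(m._buffers.items()):
                if np.issubdtype(buf.dtype, np.floating):
                    m.set_buffer(name, buf.astype(dtype))
        return self

    def eval(self) -> "Module":
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        state = {f"param:{k}": v.data.copy() for k, v in self.named_parameters()}
        state.update({f"buffer:{k}": v.copy() for k, v in self.named_buffers()})
        return state

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for key, value in state.items():
            kind, _, name = key.partition(":")
            if kind == "param":
                params[name].data = np.asarray(value).copy()
            elif kind == "buffer":
                mod = self
                parts = name.split(".")
                for part in parts[:-1]:
                    mod = mod._modules[part]
                mod.set_buffer(parts[-1], np.asarray(value).copy())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def forward(self, *args, **kwargs):  # pragma: no cover - abstract
        raise NotImplementedError


class Conv2d(Module):
    def __init__(self, in_channels: int, out_channels: int, kernel_size: int,
                 stride: int = 1, padding: int = 0, pad_mode: str = "zero",
                 bias: bool = True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.pad_mode = pad_mode
        k = kernel_size
        fan_in = in_channels * k * k
        # Kaiming-ish default; trainer.init_weights re-initializes with Xavier.
        scale = 1.0 / np.sqrt(fan_in)
        rng = np.random.default_rng(0)
        self.weight = Parameter(rng.uniform(-scale, scale, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None

    def effective_weight(self) -> Tensor:
        return self.weight

    def forward(self, x: Tensor) -> Tensor:
        return conv2d(x, self.effective_weight(), self.bias,
                      stride=self.stride, padding=self.padding,
                      pad_mode=self.pad_mode)


class SpectralNorm(Module):
    """Wraps a Conv2d, dividing its weight by the leading singular value.

    The singular value is estimated with one power-iteration step per training
    forward pass; the left singular vector persists in a buffer.  Gradients
    flow through both the weight and the sigma estimate (u, v held constant).
    """

    def __init__(self, conv: Conv2d, n_power_iterations: int = 1, eps: float = 1e-12):
        super().__init__()
        self.conv = conv
        self.n_power_iterations = n_power_iterations
        self.eps = eps
        o = conv.weight.shape[0]
        rng = np.random.default_rng(1)
        u = rng.normal(size=o)
        self.register_buffer("u", u / np.linalg.norm(u))
        # expose the wrapped conv's geometry
        self.stride = conv.stride
        self.padding = conv.padding
        self.kernel_size = conv.kernel_size
        self.in_channels = conv.in_channels
        self.out_channels = conv.out_channels

    def _power_iteration(self) -> tuple[np.ndarray, np.ndarray]:
        w2d = self.conv.weight.data.reshape(self.conv.weight.shape[0], -1)
        u = self.u
        v = None
        for _ in range(self.n_power_iterations):
            v = w2d.T @ u
            v = v / (np.linalg.norm(v) + self.eps)
            u = w2d @ v
            u = u / (np.linalg.norm(u) + self.eps)
        if self.training:
            self.set_buffer("u", u)
        return u, v

    def effective_weight(self) -> Tensor:
        u, v = self._power_iteration()
        o = self.conv.weight.shape[0]
        w2d = self.conv.weight.reshape(o, -1)
        sigma = (as_tensor(u).reshape(1, -1) @ w2d @ as_tensor(v).reshape(-1, 1)).reshape(())
        return (w2d / sigma).reshape(self.conv.weight.shape)

    @property
    def bias(self):
        return self.conv.bias

    @property
    def weight(self):
        return self.conv.weight

    def forward(self, x: Tensor) -> Tensor:
        from .autodiff import conv2d as _conv2d

        return _conv2d(x, self.effective_weight(), self.conv.bias,
                       stride=self.conv.stride, padding=self.conv.padding,
                       pad_mode=self.conv.pad_mode)


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over the spatial axes."""

    def __init__(self, num_features: int, eps: float = 1e-5, affine: bool = True):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.affine = affine
        if affine:
            self.gamma = Parameter(np.ones(num_features))
            self.beta = Parameter(np.zeros(num_features))

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        var = ((x - mu) ** 2).mean(axis=(2, 3), keepdims=True)
        y = (x - mu) / ((var + self.eps) ** 0.5)
        if self.affine:
            y = y * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)
        return y


class BatchNorm2d(Module):
    """Batch normalization over (N, H, W) with running statistics."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1):
        super().__init__()
        self.num_features = num_features
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self.register_buffer("running_mean", np.zeros(num_features))
        self.register_buffer("running_var", np.ones(num_features))

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            self.set_buffer(
                "running_mean",
                (1 - m) * self.running_mean + m * mu.data.reshape(-1),
            )
            self.set_buffer(
                "running_var",
                (1 - m) * self.running_var + m * var.data.reshape(-1),
            )
        else:
            mu = as_tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = as_tensor(self.running_var.reshape(1, -1, 1, 1))
        y = (x - mu) / ((var + self.eps) ** 0.5)
        return y * self.gamma.reshape(1, -1, 1, 1) + self.beta.reshape(1, -1, 1, 1)


class LeakyReLU(Module):
    def __init__(self, negative_slope: float = 0.2):
        super().__init__()
        self.negative_slope = negative_slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.negative_slope)


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Identity(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x


class Sequential(Module):
    def __init__(self, *layers: Module):
        super().__init__()
        self.layers = list(layers)
        for i, layer in enumerate(layers):
            setattr(self, f"layer{i}", layer)

    def __iter__(self):
        return iter(self.layers)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x


# -- initialization -----------------------------------------------------------


def xavier_bound(weight_shape: tuple) -> float:
    """Uniform bound sqrt(6 / (fan_in + fan_out)) for a conv/linear weight."""
    if len(weight_shape) == 4:
        o, i, kh, kw = weight_shape
        fan_in = i * kh * kw
        fan_out = o * kh * kw
    elif len(weight_shape) == 2:
        o, i = weight_shape
        fan_in, fan_out = i, o
    else:
        raise ValueError(f"unsupported weight shape {weight_shape}")
    return float(np.sqrt(6.0 / (fan_in + fan_out)))


def xavier_uniform_(module: Module, rng: np.random.Generator) -> Module:
    """Xavier-uniform weights, zero biases, for every conv in the module tree."""
    for m in module.modules():
        if isinstance(m, Conv2d):
            bound = xavier_bound(m.weight.shape)
            m.weight.data = rng.uniform(-bound, bound, m.weight.shape)
            if m.bias is not None:
                m.bias.data = np.zeros_like(m.bias.data)
        elif isinstance(m, (InstanceNorm2d, BatchNorm2d)):
            if getattr(m, "affine", True):
                m.gamma.data = np.ones_like(m.gamma.data)
                m.beta.data = np.zeros_like(m.beta.data)
    return module


# -- optimizer ----------------------------------------------------------------


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        if lr < 0:
            raise ValueError("lr must be >= 0")
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        with no_grad():
            for i, p in enumerate(self.params):
                if p.grad is None:
                    continue
                g = p.grad
                self.m[i] = b1 * self.m[i] + (1 - b1) * g
                self.v[i] = b2 * self.v[i] + (1 - b2) * g * g
                m_hat = self.m[i] / (1 - b1 ** self.t)
                v_hat = self.v[i] / (1 - b2 ** self.t)
                p.data = p.data - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)

    def state_dict(self) -> dict:
        return {
            "t": self.t,
            "m": [m.copy() for m in self.m],
            "v": [v.copy() for v in self.v],
        }

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.asarray(m).copy() for m in state["m"]]
        self.v = [np.asarray(v).copy() for v in state["v"]]
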