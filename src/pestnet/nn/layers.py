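"""Neural-network layers on top of the autodiff engine.

Initialisation is fully deterministic: every layer draws its weights from a
``numpy.random.Generator`` passed at construction, so two models built from
the same seed are bit-identical.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv2d, matmul

__all__ = [
    "Module", "Parameter", "Conv2d", "BatchNorm2d", "Linear", "Sequential",
    "ReLU", "Identity", "softmax", "log_softmax", "avg_pool2d",
]


def Parameter(data) -> Tensor:
    return Tensor(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Minimal module container: parameter discovery, mode flag, state dict."""

    def __init__(self):
        self.training = True

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)

    def named_parameters(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Tensor) and value.requires_grad:
                yield full, value
            elif isinstance(value, Module):
                yield from value.named_parameters(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{full}.{i}.")

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def modules(self):
        yield self
        for value in vars(self).values():
            if isinstance(value, Module):
                yield from value.modules()
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        yield from item.modules()

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    # buffers (running stats) live in _buffers dicts on the layers that need them
    def named_buffers(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value.named_buffers(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{full}.{i}.")
        for bname, arr in getattr(self, "_buffers", {}).items():
            yield f"{prefix}{bname}", arr

    def state_dict(self) -> dict:
        state = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, arr in self.named_buffers():
            state[name] = np.array(arr, copy=True)
        return state

    def load_state_dict(self, state: dict):
        params = dict(self.named_parameters())
        own = dict(self._walk_buffer_slots())
        for name, value in state.items():
            if name in params:
                if params[name].data.shape != value.shape:
                    raise ValueError(f"shape mismatch for {name}")
                params[name].data = np.asarray(value, dtype=np.float64).copy()
            elif name in own:
                holder, key = own[name]
                holder._buffers[key] = np.asarray(value, dtype=np.float64).copy()
            else:
                raise KeyError(f"unexpected state entry {name}")

    def _walk_buffer_slots(self, prefix=""):
        for name, value in vars(self).items():
            full = f"{prefix}{name}"
            if isinstance(value, Module):
                yield from value._walk_buffer_slots(full + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        yield from item._walk_buffer_slots(f"{full}.{i}.")
        for bname in getattr(self, "_buffers", {}):
            yield f"{prefix}{bname}", (self, bname)


class Identity(Module):
    def forward(self, x):
        return x


class ReLU(Module):
    def forward(self, x):
        return x.relu()


class Conv2d(Module):
    """2-D convolution, He-normal initialised."""

    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, bias=True, rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        k = kernel_size
        fan_in = in_channels * k * k
        scale = np.sqrt(2.0 / fan_in)
        self.weight = Parameter(rng.normal(0.0, scale, (out_channels, in_channels, k, k)))
        self.bias = Parameter(np.zeros(out_channels)) if bias else None
        self.stride = stride
        self.padding = padding

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.padding)


class BatchNorm2d(Module):
    """Batch normalisation over (B, H, W) per channel.

    ``bypass=True`` turns the layer into an exact identity — used by unit
    tests to check attention algebra without normalisation statistics.
    """

    def __init__(self, num_features, eps=1e-5, momentum=0.1, bypass=False):
        super().__init__()
        self.bypass = bypass
        self.eps = eps
        self.momentum = momentum
        self.gamma = Parameter(np.ones(num_features))
        self.beta = Parameter(np.zeros(num_features))
        self._buffers = {
            "running_mean": np.zeros(num_features),
            "running_var": np.ones(num_features),
        }

    def forward(self, x):
        if self.bypass:
            return x
        c = x.shape[1]
        shape = (1, c, 1, 1)
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            m = self.momentum
            n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
            unbias = n / max(n - 1, 1)
            self._buffers["running_mean"] = (
                (1 - m) * self._buffers["running_mean"] + m * mean.data.reshape(c)
            )
            self._buffers["running_var"] = (
                (1 - m) * self._buffers["running_var"] + m * unbias * var.data.reshape(c)
            )
        else:
            mean = Tensor(self._buffers["running_mean"].reshape(shape))
            var = Tensor(self._buffers["running_var"].reshape(shape))
        xhat = (x - mean) / ((var + self.eps) ** 0.5)
        return xhat * self.gamma.reshape(shape) + self.beta.reshape(shape)


class Linear(Module):
    def __init__(self, in_features, out_features, bias=True,
                 rng: np.random.Generator | None = None):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        scale = np.sqrt(2.0 / in_features)
        self.weight = Parameter(rng.normal(0.0, scale, (in_features, out_features)))
        self.bias = Parameter(np.zeros(out_features)) if bias else None

    def forward(self, x):
        out = matmul(x, self.weight)
        if self.bias is not None:
            out = out + self.bias
        return out


class Sequential(Module):
    def __init__(self, *layers):
        super().__init__()
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x)
        return x


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shift = x - Tensor(x.data.max(axis=axis, keepdims=True))  # detached max
    return shift - shift.exp().sum(axis=axis, keepdims=True).log()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    return log_softmax(x, axis=axis).exp()


def avg_pool2d(x: Tensor, k: int = 2) -> Tensor:
    """Non-overlapping k×k average pooling; spatial dims must divide by k."""
    b, c, h, w = x.shape
    if h % k or w % k:
        raise ValueError(f"spatial dims {(h, w)} not divisible by pool size {k}")
    return (
        x.reshape(b, c, h // k, k, w // k, k).mean(axis=(3, 5))
    )
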