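"""Neural-network modules built on the autodiff engine.

Layout convention is NCHW throughout.  Parameters are float32 by default
(float64 is available for gradient-checking tests via ``dtype``).
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, col2im, im2col

__all__ = [
    "Module",
    "Parameter",
    "Linear",
    "Conv2d",
    "ConvTranspose2d",
    "InstanceNorm2d",
    "LeakyReLU",
    "ReLU",
    "Sigmoid",
    "Flatten",
    "Sequential",
]


class Parameter(Tensor):
    def __init__(self, data, dtype=np.float32):
        super().__init__(np.asarray(data, dtype=dtype), requires_grad=True)


class Module:
    """Minimal parameter container with recursive discovery."""

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        seen: set[int] = set()
        for value in vars(self).values():
            if isinstance(value, Parameter):
                if id(value) not in seen:
                    seen.add(id(value))
                    params.append(value)
            elif isinstance(value, Module):
                for p in value.parameters():
                    if id(p) not in seen:
                        seen.add(id(p))
                        params.append(p)
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        for p in item.parameters():
                            if id(p) not in seen:
                                seen.add(id(p))
                                params.append(p)
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(
                f"checkpoint has {len(state)} arrays, model has {len(params)} parameters"
            )
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_normal(rng: np.random.Generator, shape, fan_in: int, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(dtype)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator,
                 dtype=np.float32):
        self.w = Parameter(_he_normal(rng, (in_features, out_features), in_features, dtype),
                           dtype=dtype)
        self.b = Parameter(np.zeros(out_features), dtype=dtype)

    def forward(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b


class Conv2d(Module):
    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        self.w = Parameter(_he_normal(rng, (out_ch, in_ch, kernel, kernel), fan_in, dtype),
                           dtype=dtype)
        self.b = Parameter(np.zeros(out_ch), dtype=dtype)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.padding
        if p:
            x = x.embed((n, c, h + 2 * p, w + 2 * p),
                        (slice(None), slice(None), slice(p, p + h), slice(p, p + w)))
            h, w = h + 2 * p, w + 2 * p
        oh = (h - k) // s + 1
        ow = (w - k) // s + 1
        cols = im2col(x, k, k, s)                      # (n, c*k*k, oh*ow)
        wm = self.w.reshape((self.out_ch, c * k * k))  # (F, c*k*k)
        out = wm @ cols                                # (n, F, oh*ow)
        out = out + self.b.reshape((1, self.out_ch, 1))
        return out.reshape((n, self.out_ch, oh, ow))


class ConvTranspose2d(Module):
    """Transposed convolution (stride-s upsampling), adjoint of Conv2d."""

    def __init__(self, in_ch: int, out_ch: int, kernel: int, rng: np.random.Generator,
                 stride: int = 1, padding: int = 0, dtype=np.float32):
        fan_in = in_ch * kernel * kernel
        self.w = Parameter(_he_normal(rng, (in_ch, out_ch, kernel, kernel), fan_in, dtype),
                           dtype=dtype)
        self.b = Parameter(np.zeros(out_ch), dtype=dtype)
        self.kernel, self.stride, self.padding = kernel, stride, padding
        self.in_ch, self.out_ch = in_ch, out_ch

    def forward(self, x: Tensor) -> Tensor:
        n, c, h, w = x.shape
        if c != self.in_ch:
            raise ValueError(f"expected {self.in_ch} input channels, got {c}")
        k, s, p = self.kernel, self.stride, self.padding
        hp = (h - 1) * s + k
        wp = (w - 1) * s + k
        wm = self.w.reshape((self.in_ch, self.out_ch * k * k))
        cols = wm.swap_last2() @ x.reshape((n, c, h * w))   # (n, out*k*k, h*w)
        full = col2im(cols, (n, self.out_ch, hp, wp), k, k, s)
        out = full[:, :, p : hp - p, p : wp - p]
        return out + self.b.reshape((1, self.out_ch, 1, 1))


class InstanceNorm2d(Module):
    """Per-sample, per-channel normalization over spatial dims, with affine scale."""

    def __init__(self, channels: int, eps: float = 1e-5, dtype=np.float32):
        self.gamma = Parameter(np.ones(channels), dtype=dtype)
        self.beta = Parameter(np.zeros(channels), dtype=dtype)
        self.eps = eps
        self.channels = channels

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=(2, 3), keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=(2, 3), keepdims=True)
        xhat = xc * (var + self.eps) ** -0.5
        g = self.gamma.reshape((1, self.channels, 1, 1))
        b = self.beta.reshape((1, self.channels, 1, 1))
        return xhat * g + b


class LeakyReLU(Module):
    def __init__(self, slope: float = 0.01):
        self.slope = slope

    def forward(self, x: Tensor) -> Tensor:
        return x.leaky_relu(self.slope)


class ReLU(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.relu()


class Sigmoid(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.sigmoid()


class Flatten(Module):
    def forward(self, x: Tensor) -> Tensor:
        return x.reshape((x.shape[0], -1))


class Sequential(Module):
    def __init__(self, *modules: Module):
        self.layers = list(modules)

    def forward(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        return x
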