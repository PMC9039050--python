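"""Minimal CPU neural-network layers with explicit backpropagation.

The package trains small convolutional networks end to end on a single
CPU, so the layer zoo is deliberately tiny: strided convolution, batch
normalisation, ReLU, max pooling, global average pooling and linear
layers, composed by :class:`Sequential` and :class:`ResidualBlock`.
Every layer implements ``forward(x, training)`` and ``backward(grad)``;
parameter gradients accumulate on :class:`Param` objects and are
consumed by :class:`Adam`.

All tensors are ``float32`` and image tensors are channels-first
``(B, C, H, W)``.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Param",
    "Module",
    "Conv2d",
    "BatchNorm2d",
    "ReLU",
    "MaxPool2d",
    "Dropout",
    "GlobalAvgPool",
    "Flatten",
    "Linear",
    "Sequential",
    "ResidualBlock",
    "Adam",
    "he_normal",
]


def he_normal(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int) -> np.ndarray:
    """He-normal initialisation, the standard choice for ReLU networks."""
    std = np.sqrt(2.0 / float(fan_in))
    return rng.normal(0.0, std, size=shape).astype(np.float32)


class Param:
    """A trainable array plus its accumulated gradient."""

    __slots__ = ("data", "grad", "name")

    def __init__(self, data: np.ndarray, name: str = "") -> None:
        self.data = np.ascontiguousarray(data, dtype=np.float32)
        self.grad = np.zeros_like(self.data)
        self.name = name


class Module:
    """Base class: parameter discovery, zero_grad, state (de)serialisation."""

    training: bool = True

    def parameters(self) -> list[Param]:
        out: list[Param] = []
        for value in self.__dict__.values():
            if isinstance(value, Param):
                out.append(value)
            elif isinstance(value, Module):
                out.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad[...] = 0.0

    # -- named state, used for checkpoints and backbone weight transfer --
    def named_state(self, prefix: str = "") -> dict[str, np.ndarray]:
        state: dict[str, np.ndarray] = {}
        for key, value in self.__dict__.items():
            path = f"{prefix}{key}"
            if isinstance(value, Param):
                state[path] = value.data
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                state[path] = value
            elif isinstance(value, Module):
                state.update(value.named_state(path + "."))
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        state.update(item.named_state(f"{path}.{i}."))
        return state

    def load_state(self, state: dict[str, np.ndarray], prefix: str = "") -> None:
        for key, value in self.__dict__.items():
            path = f"{prefix}{key}"
            if isinstance(value, Param):
                src = state[path]
                if src.shape != value.data.shape:
                    raise ValueError(
                        f"shape mismatch for {path}: {src.shape} vs {value.data.shape}"
                    )
                value.data[...] = src
            elif isinstance(value, np.ndarray) and key.startswith("running_"):
                value[...] = state[path]
            elif isinstance(value, Module):
                value.load_state(state, path + ".")
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        item.load_state(state, f"{path}.{i}.")

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training)


# ---------------------------------------------------------------------------
# im2col helpers


def _window_view(xp: np.ndarray, k: int, stride: int) -> np.ndarray:
    """(B,C,Hp,Wp) -> (B,C,Ho,Wo,k,k) strided window view."""
    v = np.lib.stride_tricks.sliding_window_view(xp, (k, k), axis=(2, 3))
    return v[:, :, ::stride, ::stride]


def _accumulate_windows(
    dwin: np.ndarray, x_shape: tuple[int, int, int, int], k: int, stride: int, pad: int
) -> np.ndarray:
    """Scatter-add window gradients (B,C,Ho,Wo,k,k) back to the input."""
    B, C, H, W = x_shape
    Ho, Wo = dwin.shape[2], dwin.shape[3]
    dxp = np.zeros((B, C, H + 2 * pad, W + 2 * pad), dtype=np.float32)
    for i in range(k):
        for j in range(k):
            dxp[:, :, i : i + stride * Ho : stride, j : j + stride * Wo : stride] += dwin[
                :, :, :, :, i, j
            ]
    if pad:
        return dxp[:, :, pad : pad + H, pad : pad + W]
    return dxp


class Conv2d(Module):
    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        stride: int = 1,
        padding: int = 0,
        bias: bool = True,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        fan_in = in_channels * kernel_size * kernel_size
        self.weight = Param(he_normal(rng, (out_channels, fan_in), fan_in), "conv.weight")
        self.bias = Param(np.zeros(out_channels, dtype=np.float32), "conv.bias") if bias else None
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p))) if p else x
        win = _window_view(xp, k, s)  # (B,C,Ho,Wo,k,k)
        B, C, Ho, Wo = win.shape[:4]
        cols = win.transpose(0, 1, 4, 5, 2, 3).reshape(B, C * k * k, Ho * Wo)
        out = self.weight.data @ cols  # (B,cout,L)
        if self.bias is not None:
            out = out + self.bias.data[None, :, None]
        self._cache = (x.shape, cols)
        return np.ascontiguousarray(out.reshape(B, self.out_channels, Ho, Wo))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, cols = self._cache  # type: ignore[misc]
        k, s, p = self.kernel_size, self.stride, self.padding
        B, _, Ho, Wo = grad.shape
        g = grad.reshape(B, self.out_channels, Ho * Wo)
        self.weight.grad += np.einsum("bol,bkl->ok", g, cols, optimize=True)
        if self.bias is not None:
            self.bias.grad += g.sum(axis=(0, 2))
        dcols = np.einsum("ok,bol->bkl", self.weight.data, g, optimize=True)
        dwin = dcols.reshape(B, self.in_channels, k, k, Ho, Wo).transpose(0, 1, 4, 5, 2, 3)
        return _accumulate_windows(dwin, x_shape, k, s, p)


class BatchNorm2d(Module):
    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5) -> None:
        self.gamma = Param(np.ones(channels, dtype=np.float32), "bn.gamma")
        self.beta = Param(np.zeros(channels, dtype=np.float32), "bn.beta")
        self.running_mean = np.zeros(channels, dtype=np.float32)
        self.running_var = np.ones(channels, dtype=np.float32)
        self.momentum = momentum
        self.eps = eps
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            mean = x.mean(axis=(0, 2, 3))
            var = x.var(axis=(0, 2, 3))
            self.running_mean = (1 - self.momentum) * self.running_mean + self.momentum * mean
            self.running_var = (1 - self.momentum) * self.running_var + self.momentum * var
        else:
            mean, var = self.running_mean, self.running_var
        inv = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mean[None, :, None, None]) * inv[None, :, None, None]
        self._cache = (xhat, inv, x.shape)
        return self.gamma.data[None, :, None, None] * xhat + self.beta.data[None, :, None, None]

    def backward(self, grad: np.ndarray) -> np.ndarray:
        xhat, inv, x_shape = self._cache  # type: ignore[misc]
        B, _, H, W = x_shape
        n = B * H * W
        self.gamma.grad += (grad * xhat).sum(axis=(0, 2, 3))
        self.beta.grad += grad.sum(axis=(0, 2, 3))
        g = grad * self.gamma.data[None, :, None, None]
        gsum = g.sum(axis=(0, 2, 3), keepdims=True)
        gxsum = (g * xhat).sum(axis=(0, 2, 3), keepdims=True)
        return (inv[None, :, None, None] / n) * (n * g - gsum - xhat * gxsum)


class ReLU(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._mask = x > 0
        return np.where(self._mask, x, 0.0).astype(np.float32, copy=False)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return np.where(self._mask, grad, 0.0).astype(np.float32, copy=False)


class MaxPool2d(Module):
    def __init__(self, kernel_size: int, stride: int, padding: int = 0) -> None:
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self._cache: tuple | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        k, s, p = self.kernel_size, self.stride, self.padding
        if p:
            xp = np.pad(x, ((0, 0), (0, 0), (p, p), (p, p)), constant_values=-np.inf)
        else:
            xp = x
        win = _window_view(xp, k, s)  # (B,C,Ho,Wo,k,k)
        flat = win.reshape(*win.shape[:4], k * k)
        idx = flat.argmax(axis=-1)
        self._cache = (x.shape, idx, win.shape)
        return np.ascontiguousarray(flat.max(axis=-1))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        x_shape, idx, win_shape = self._cache  # type: ignore[misc]
        k, s, p = self.kernel_size, self.stride, self.padding
        dflat = np.zeros((*win_shape[:4], k * k), dtype=np.float32)
        np.put_along_axis(dflat, idx[..., None], grad[..., None], axis=-1)
        return _accumulate_windows(dflat.reshape(win_shape), x_shape, k, s, p)


class Dropout(Module):
    """Inverted dropout; identity at evaluation time."""

    def __init__(self, p: float = 0.5, rng: np.random.Generator | None = None) -> None:
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)
        self._mask: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.p
        self._mask = (self.rng.random(x.shape) < keep).astype(np.float32) / keep
        return x * self._mask

    def backward(self, grad: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return grad
        return grad * self._mask


class GlobalAvgPool(Module):
    """(B,C,H,W) -> (B,C) spatial mean."""

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.mean(axis=(2, 3))

    def backward(self, grad: np.ndarray) -> np.ndarray:
        B, C, H, W = self._shape
        return np.broadcast_to(grad[:, :, None, None] / (H * W), self._shape).astype(np.float32)


class Flatten(Module):
    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        return grad.reshape(self._shape)


class Linear(Module):
    def __init__(
        self,
        in_features: int,
        out_features: int,
        rng: np.random.Generator | None = None,
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.in_features = in_features
        self.out_features = out_features
        self.weight = Param(he_normal(rng, (out_features, in_features), in_features), "fc.weight")
        self.bias = Param(np.zeros(out_features, dtype=np.float32), "fc.bias")
        self._x: np.ndarray | None = None

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._x = x
        return x @ self.weight.data.T + self.bias.data

    def backward(self, grad: np.ndarray) -> np.ndarray:
        self.weight.grad += grad.T @ self._x  # type: ignore[arg-type]
        self.bias.grad += grad.sum(axis=0)
        return grad @ self.weight.data


class Sequential(Module):
    def __init__(self, *layers: Module) -> None:
        self.layers = list(layers)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        for layer in self.layers:
            x = layer.forward(x, training)
        return x

    def backward(self, grad: np.ndarray) -> np.ndarray:
        for layer in reversed(self.layers):
            grad = layer.backward(grad)
        return grad


class ResidualBlock(Module):
    """y = relu(f(x) + shortcut(x)); shortcut is identity or a 1x1 conv path."""

    def __init__(self, main: Sequential, shortcut: Sequential | None = None) -> None:
        self.main = main
        self.shortcut = shortcut
        self.relu = ReLU()

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        fx = self.main.forward(x, training)
        sx = self.shortcut.forward(x, training) if self.shortcut is not None else x
        return self.relu.forward(fx + sx, training)

    def backward(self, grad: np.ndarray) -> np.ndarray:
        g = self.relu.backward(grad)
        gx = self.main.backward(g)
        if self.shortcut is not None:
            gx = gx + self.shortcut.backward(g)
        else:
            gx = gx + g
        return gx


class Adam:
    """Adam with decoupled-from-nothing L2 weight decay added to the gradient."""

    def __init__(
        self,
        params: list[Param],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
        weight_decay: float = 0.0,
    ) -> None:
        self.params = params
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            m[...] = b1 * m + (1 - b1) * g
            v[...] = b2 * v + (1 - b2) * g * g
            p.data -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
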