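"""Minimal NumPy neural-network layers with explicit backpropagation.

Data layout is channels-last: ``[batch, x, y, z, channels]`` in float32.
Convolutions are expressed as a sum of kernel-offset matmuls, which maps
the factorized kernels used here — (5,5,1) spatial, (1,1,5) spectral,
(2,2,2)/stride-2 conv-pool — onto BLAS without materializing im2col
buffers.  Every layer implements ``forward`` (caching what backward
needs) and ``backward`` (returning the input gradient and filling
parameter ``grad`` slots); plain SGD with optional momentum does the
updates.  Deterministic given the generators passed in.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Parameter",
    "Layer",
    "Conv3D",
    "ReLU",
    "Square",
    "Log",
    "BatchNorm",
    "Dropout",
    "Flatten",
    "Dense",
    "softmax",
    "cross_entropy_with_logits",
    "SGD",
]

DTYPE = np.float32


class Parameter:
    __slots__ = ("value", "grad", "name", "decay")

    def __init__(self, value: np.ndarray, name: str = "", decay: bool = True) -> None:
        self.value = np.asarray(value, dtype=DTYPE)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.decay = decay  # participates in L2 weight decay

    @property
    def size(self) -> int:
        return self.value.size


class Layer:
    name: str = "layer"

    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dy: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return in_shape


def _glorot(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Conv3D(Layer):
    """3D convolution over (x, y, z) with per-axis kernel and stride.

    ``padding='same'`` keeps spatial size at stride 1; ``'valid'`` crops.
    Weight shape is ``[kx, ky, kz, cin, cout]``.
    """

    def __init__(
        self,
        cin: int,
        cout: int,
        kernel: tuple[int, int, int],
        stride: tuple[int, int, int] = (1, 1, 1),
        padding: str = "same",
        rng: np.random.Generator | None = None,
        name: str = "conv",
        init: str = "glorot",
    ) -> None:
        rng = rng or np.random.default_rng(0)
        self.kernel = tuple(kernel)
        self.stride = tuple(stride)
        if padding not in ("same", "valid"):
            raise ValueError("padding must be 'same' or 'valid'")
        self.padding = padding
        self.name = name
        kx, ky, kz = self.kernel
        fan_in = kx * ky * kz * cin
        fan_out = kx * ky * kz * cout
        if init == "glorot":
            w = _glorot(rng, (kx, ky, kz, cin, cout), fan_in, fan_out)
        elif init == "averaging":
            # Positive near-uniform weights summing to ~1 per output
            # channel: the layer starts as (jittered) average pooling.
            w = rng.uniform(0.5, 1.5, size=(kx, ky, kz, cin, cout)) / fan_in
        else:
            raise ValueError(f"unknown init {init!r}")
        self.weight = Parameter(w, f"{name}.weight")
        self.bias = Parameter(np.zeros(cout), f"{name}.bias", decay=False)
        self._cache = None

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def _pads(self) -> tuple[tuple[int, int], ...]:
        if self.padding == "valid":
            return ((0, 0),) * 3
        return tuple(((k - 1) // 2, k - 1 - (k - 1) // 2) for k in self.kernel)

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        dims, cin = in_shape[:3], in_shape[3]
        if cin != self.weight.value.shape[3]:
            raise ValueError(f"{self.name}: expected {self.weight.value.shape[3]} input channels")
        out = []
        for d, k, s, (p0, p1) in zip(dims, self.kernel, self.stride, self._pads()):
            padded = d + p0 + p1
            if padded < k:
                raise ValueError(
                    f"layer {self.name}: dimension of size {d} smaller than "
                    f"kernel {k} (padding={self.padding})"
                )
            out.append((padded - k) // s + 1)
        return (*out, self.weight.value.shape[4])

    def _wmat(self) -> np.ndarray:
        # (kx,ky,kz,cin,cout) -> (cin*kx*ky*kz, cout), matching the
        # trailing axis order of the im2col patch matrix.
        w = self.weight.value
        return np.ascontiguousarray(w.transpose(3, 0, 1, 2, 4)).reshape(
            -1, w.shape[4]
        )

    def _im2col(self, xp: np.ndarray, ox: int, oy: int, oz: int) -> np.ndarray:
        kx, ky, kz = self.kernel
        sx, sy, sz = self.stride
        windows = np.lib.stride_tricks.sliding_window_view(
            xp, (kx, ky, kz), axis=(1, 2, 3)
        )  # (B, X', Y', Z', Cin, kx, ky, kz)
        windows = windows[:, : sx * ox : sx, : sy * oy : sy, : sz * oz : sz]
        return windows.reshape(windows.shape[0] * ox * oy * oz, -1)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        kx, ky, kz = self.kernel
        sx, sy, sz = self.stride
        self.output_shape(x.shape[1:])  # shape validation
        pads = self._pads()
        xp = np.pad(x, ((0, 0), *pads, (0, 0))) if self.padding == "same" else x
        ox = (xp.shape[1] - kx) // sx + 1
        oy = (xp.shape[2] - ky) // sy + 1
        oz = (xp.shape[3] - kz) // sz + 1
        col = self._im2col(xp, ox, oy, oz)
        out = col @ self._wmat() + self.bias.value
        if training:
            self._cache = (col, xp.shape, (ox, oy, oz))
        return out.reshape(x.shape[0], ox, oy, oz, -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._cache is None:
            raise RuntimeError("backward before training-mode forward")
        col, xp_shape, (ox, oy, oz) = self._cache
        self._cache = None
        kx, ky, kz = self.kernel
        sx, sy, sz = self.stride
        b, cin = xp_shape[0], xp_shape[4]
        cout = dy.shape[-1]
        dy_flat = dy.reshape(-1, cout)
        self.bias.grad[:] = dy_flat.sum(axis=0)
        dw = (col.T @ dy_flat).reshape(cin, kx, ky, kz, cout)
        self.weight.grad[:] = dw.transpose(1, 2, 3, 0, 4)
        dcol = (dy_flat @ self._wmat().T).reshape(
            b, ox, oy, oz, cin, kx, ky, kz
        )
        dxp = np.zeros(xp_shape, dtype=dy.dtype)
        for i in range(kx):
            for j in range(ky):
                for k in range(kz):
                    dxp[
                        :,
                        i : i + sx * ox : sx,
                        j : j + sy * oy : sy,
                        k : k + sz * oz : sz,
                        :,
                    ] += dcol[:, :, :, :, :, i, j, k]
        if self.padding == "valid":
            return dxp
        (px0, _), (py0, _), (pz0, _) = self._pads()
        nx = xp_shape[1] - sum(self._pads()[0])
        ny = xp_shape[2] - sum(self._pads()[1])
        nz = xp_shape[3] - sum(self._pads()[2])
        return dxp[:, px0 : px0 + nx, py0 : py0 + ny, pz0 : pz0 + nz, :]


class ReLU(Layer):
    name = "relu"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        y = np.maximum(x, 0)
        if training:
            self._mask = x > 0
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._mask


class Square(Layer):
    name = "square"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x * x

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return 2.0 * self._x * dy


class Log(Layer):
    """Elementwise natural log with a floor: log(max(x, eps)).

    Pooled squared activations can be arbitrarily close to zero; the
    floor keeps the log (and its gradient) finite.
    """

    name = "log"

    def __init__(self, eps: float = 1e-6) -> None:
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        xc = np.maximum(x, self.eps)
        if training:
            self._xc = xc
            self._live = x > self.eps
        return np.log(xc)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._live / self._xc


class BatchNorm(Layer):
    """Per-channel batch normalization over all non-channel axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 name: str = "bn") -> None:
        self.gamma = Parameter(np.ones(channels), f"{name}.gamma", decay=False)
        self.beta = Parameter(np.zeros(channels), f"{name}.beta", decay=False)
        self.running_mean = np.zeros(channels, dtype=DTYPE)
        self.running_var = np.ones(channels, dtype=DTYPE)
        self.momentum = momentum
        self.eps = eps
        self.name = name

    def params(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        axes = tuple(range(x.ndim - 1))
        if training:
            mean = x.mean(axis=axes)
            var = x.var(axis=axes)
            m = self.momentum
            self.running_mean = ((1 - m) * self.running_mean + m * mean).astype(DTYPE)
            self.running_var = ((1 - m) * self.running_var + m * var).astype(DTYPE)
            std = np.sqrt(var + self.eps)
            xhat = (x - mean) / std
            self._cache = (xhat, std, axes)
            return self.gamma.value * xhat + self.beta.value
        std = np.sqrt(self.running_var + self.eps)
        return self.gamma.value * (x - self.running_mean) / std + self.beta.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, std, axes = self._cache
        n = dy.size // dy.shape[-1]
        self.gamma.grad[:] = (dy * xhat).sum(axis=axes)
        self.beta.grad[:] = dy.sum(axis=axes)
        g = self.gamma.value
        dxhat = dy * g
        return (
            dxhat
            - dxhat.mean(axis=axes)
            - xhat * (dxhat * xhat).sum(axis=axes) / n
        ) / std


class Dropout(Layer):
    """Inverted dropout; identity in eval mode."""

    name = "dropout"

    def __init__(self, p: float, rng: np.random.Generator | None = None) -> None:
        if not (0 <= p < 1):
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng = rng or np.random.default_rng(0)

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if not training or self.p == 0:
            return x
        self._mask = (self.rng.random(x.shape) >= self.p).astype(DTYPE) / (1 - self.p)
        return x * self._mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self.p == 0:
            return dy
        return dy * self._mask


class Flatten(Layer):
    name = "flatten"

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy.reshape(self._shape)

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return (int(np.prod(in_shape)),)


class Dense(Layer):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator | None = None,
                 name: str = "dense") -> None:
        rng = rng or np.random.default_rng(0)
        self.weight = Parameter(_glorot(rng, (n_in, n_out), n_in, n_out), f"{name}.weight")
        self.bias = Parameter(np.zeros(n_out), f"{name}.bias", decay=False)
        self.name = name

    def params(self) -> list[Parameter]:
        return [self.weight, self.bias]

    def forward(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        if training:
            self._x = x
        return x @ self.weight.value + self.bias.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        self.weight.grad[:] = self._x.T @ dy
        self.bias.grad[:] = dy.sum(axis=0)
        return dy @ self.weight.value.T

    def output_shape(self, in_shape: tuple[int, ...]) -> tuple[int, ...]:
        return (self.weight.value.shape[1],)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def cross_entropy_with_logits(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray]:
    """Mean NLL of the softmax distribution and its logits gradient."""
    n = logits.shape[0]
    z = logits - logits.max(axis=-1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=-1, keepdims=True))
    loss = float(-logp[np.arange(n), labels].mean())
    grad = np.exp(logp)
    grad[np.arange(n), labels] -= 1.0
    return loss, (grad / n).astype(DTYPE)


class SGD:
    """Minibatch SGD with optional momentum and L2 weight decay.

    Decay applies only to parameters flagged ``decay`` (weights, not
    biases or normalization scales).
    """

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.0,
                 weight_decay: float = 0.0) -> None:
        self.params = params
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.value) for p in params] if momentum else None

    def step(self) -> None:
        for i, p in enumerate(self.params):
            g = p.grad
            if self.weight_decay and p.decay:
                g = g + self.weight_decay * p.value
            if self._velocity is not None:
                self._velocity[i] = self.momentum * self._velocity[i] - self.lr * g
                p.value += self._velocity[i]
            else:
                p.value -= self.lr * g
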