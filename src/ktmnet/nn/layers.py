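"""Neural-network layers with explicit forward/backward passes.

All layers cache what they need during ``forward`` and return the gradient
with respect to their input from ``backward``; parameter gradients are
accumulated on :class:`Parameter` objects.  Data layout is channels-last:
dense inputs are ``(batch, features)``, spatial inputs ``(batch, H, W, C)``.
"""

from __future__ import annotations

import numpy as np


class Parameter:
    """A trainable array with its gradient buffer.

    ``l1`` marks parameters that contribute an L1 penalty to the training
    loss (the task-head weights).
    """

    __slots__ = ("name", "value", "grad", "l1")

    def __init__(self, value: np.ndarray, name: str, l1: bool = False):
        self.value = np.asarray(value, dtype=float)
        self.grad = np.zeros_like(self.value)
        self.name = name
        self.l1 = l1

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def glorot_uniform(rng: np.random.Generator, shape: tuple[int, ...], fan_in: int, fan_out: int) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


def softmax(z: np.ndarray) -> np.ndarray:
    """Row-wise softmax, numerically stabilized."""
    z = z - z.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def softplus_inverse(y: float) -> float:
    return float(np.log(np.expm1(y)))


class Layer:
    def params(self) -> list[Parameter]:
        return []

    def forward(self, x: np.ndarray, training: bool = False, rng: np.random.Generator | None = None) -> np.ndarray:
        raise NotImplementedError

    def backward(self, grad: np.ndarray) -> np.ndarray:
        raise NotImplementedError


class Dense(Layer):
    """Fully connected layer, activation in {'linear', 'relu'}."""

    def __init__(self, n_in: int, n_out: int, activation: str = "linear", *,
                 rng: np.random.Generator, name: str = "dense", l1: bool = False):
        if n_in <= 0 or n_out <= 0:
            raise ValueError(f"invalid dense dimensions {n_in}->{n_out}")
        if activation not in ("linear", "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        self.activation = activation
        self.W = Parameter(glorot_uniform(rng, (n_in, n_out), n_in, n_out), f"{name}.W", l1=l1)
        self.b = Parameter(np.zeros(n_out), f"{name}.b")

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def forward(self, x, training=False, rng=None):
        self._x = x
        z = x @ self.W.value + self.b.value
        if self.activation == "relu":
            self._mask = z > 0
            return np.where(self._mask, z, 0.0)
        return z

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        self.W.grad += self._x.T @ grad
        self.b.grad += grad.sum(axis=0)
        return grad @ self.W.value.T


class RBF(Layer):
    """Gaussian-kernel (radial basis function) layer.

    Unit j outputs ``exp(-||x - c_j||^2 / (2 sigma_j^2))`` with a learnable
    center ``c_j`` and a learnable positive bandwidth ``sigma_j``, kept
    positive through a softplus reparameterization.  Outputs lie in (0, 1].

    Centers are initialized from a unit Gaussian.  Bandwidths start at
    ``sqrt(n_in)``: for z-scored inputs and unit-Gaussian centers the
    expected squared distance is ``2 n_in``, so this puts the exponent at
    O(1) instead of saturating every unit at 0.
    """

    def __init__(self, n_in: int, units: int, *, rng: np.random.Generator,
                 name: str = "rbf", sigma_init: float | None = None):
        if sigma_init is None:
            sigma_init = float(np.sqrt(n_in))
        self.centers = Parameter(rng.standard_normal((units, n_in)), f"{name}.centers")
        self.rho = Parameter(np.full(units, softplus_inverse(sigma_init)), f"{name}.rho")

    def params(self) -> list[Parameter]:
        return [self.centers, self.rho]

    def forward(self, x, training=False, rng=None):
        C = self.centers.value
        self._x = x
        self._sigma = softplus(self.rho.value)  # (units,)
        # squared distances (batch, units)
        self._d2 = (
            (x * x).sum(axis=1, keepdims=True)
            - 2.0 * x @ C.T
            + (C * C).sum(axis=1)[None, :]
        )
        np.maximum(self._d2, 0.0, out=self._d2)
        self._out = np.exp(-self._d2 / (2.0 * self._sigma**2))
        return self._out

    def backward(self, grad):
        C = self.centers.value
        sig = self._sigma
        # dL/d(d2): elementwise
        g_d2 = grad * self._out * (-0.5 / sig**2)[None, :]
        # d2 = ||x||^2 - 2 x.c + ||c||^2
        gx = 2.0 * (g_d2.sum(axis=1, keepdims=True) * self._x - g_d2 @ C)
        self.centers.grad += 2.0 * (g_d2.sum(axis=0)[:, None] * C - g_d2.T @ self._x)
        # dL/dsigma = sum_b grad * out * d2 / sigma^3
        g_sigma = (grad * self._out * self._d2).sum(axis=0) / sig**3
        self.rho.grad += g_sigma / (1.0 + np.exp(-self.rho.value))  # d softplus
        return gx


class Reshape(Layer):
    """Row-major reshape of the trailing dimensions (e.g. 100 -> 10x10x1)."""

    def __init__(self, target: tuple[int, ...]):
        self.target = tuple(target)

    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        expected = int(np.prod(self.target))
        if int(np.prod(x.shape[1:])) != expected:
            raise ValueError(f"cannot reshape {x.shape[1:]} to {self.target}")
        return x.reshape((x.shape[0],) + self.target)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Flatten(Layer):
    def forward(self, x, training=False, rng=None):
        self._shape = x.shape
        return x.reshape(x.shape[0], -1)

    def backward(self, grad):
        return grad.reshape(self._shape)


class Dropout(Layer):
    """Inverted dropout; identity at inference."""

    def __init__(self, rate: float):
        if not 0.0 <= rate < 1.0:
            raise ValueError(f"invalid dropout rate {rate}")
        self.rate = rate

    def forward(self, x, training=False, rng=None):
        if not training or self.rate == 0.0:
            self._mask = None
            return x
        if rng is None:
            raise ValueError("dropout in training mode requires an rng")
        self._mask = (rng.random(x.shape) >= self.rate) / (1.0 - self.rate)
        return x * self._mask

    def backward(self, grad):
        if self._mask is None:
            return grad
        return grad * self._mask


class Conv2D(Layer):
    """2D convolution, stride 1, optional dilation, 'valid' or 'same' padding.

    With ``transposed=True`` the layer is a stride-1 'same' transposed
    convolution: for stride 1 and the symmetric padding of an odd effective
    kernel, the transposed operator equals a 'same' convolution with the
    spatially flipped kernel, which is how it is evaluated here.
    """

    def __init__(self, in_channels: int, filters: int, kernel_size: tuple[int, int],
                 *, rng: np.random.Generator, dilation: int = 1, padding: str = "valid",
                 activation: str = "linear", transposed: bool = False, name: str = "conv"):
        kh, kw = kernel_size
        if padding not in ("valid", "same"):
            raise ValueError(f"unsupported padding {padding!r}")
        if activation not in ("linear", "relu"):
            raise ValueError(f"unsupported activation {activation!r}")
        if transposed and padding != "same":
            raise ValueError("transposed convolution is implemented for 'same' padding")
        self.kh, self.kw = kh, kw
        self.dilation = dilation
        self.padding = padding
        self.activation = activation
        self.transposed = transposed
        fan_in = kh * kw * in_channels
        fan_out = kh * kw * filters
        self.W = Parameter(
            glorot_uniform(rng, (kh, kw, in_channels, filters), fan_in, fan_out), f"{name}.W"
        )
        self.b = Parameter(np.zeros(filters), f"{name}.b")

    def params(self) -> list[Parameter]:
        return [self.W, self.b]

    def _effective_extent(self) -> tuple[int, int]:
        d = self.dilation
        return (self.kh - 1) * d + 1, (self.kw - 1) * d + 1

    def output_spatial(self, h: int, w: int) -> tuple[int, int]:
        eh, ew = self._effective_extent()
        if self.padding == "same":
            return h, w
        oh, ow = h - eh + 1, w - ew + 1
        if oh <= 0 or ow <= 0:
            raise ValueError(
                f"kernel extent {eh}x{ew} does not fit input {h}x{w} with valid padding"
            )
        return oh, ow

    def _kernel(self) -> np.ndarray:
        if self.transposed:
            return self.W.value[::-1, ::-1]
        return self.W.value

    def forward(self, x, training=False, rng=None):
        b, h, w, _ = x.shape
        eh, ew = self._effective_extent()
        oh, ow = self.output_spatial(h, w)
        if self.padding == "same":
            ph, pw = (eh - 1) // 2, (ew - 1) // 2
            x = np.pad(x, ((0, 0), (ph, eh - 1 - ph), (pw, ew - 1 - pw), (0, 0)))
        self._xp = x
        self._out_spatial = (oh, ow)
        K = self._kernel()
        d = self.dilation
        out = np.tile(self.b.value, (b, oh, ow, 1))
        for i in range(self.kh):
            for j in range(self.kw):
                patch = x[:, i * d : i * d + oh, j * d : j * d + ow, :]
                out += np.tensordot(patch, K[i, j], axes=([3], [0]))
        if self.activation == "relu":
            self._mask = out > 0
            return np.where(self._mask, out, 0.0)
        return out

    def backward(self, grad):
        if self.activation == "relu":
            grad = grad * self._mask
        d = self.dilation
        oh, ow = self._out_spatial
        xp = self._xp
        dK = np.zeros_like(self.W.value)
        dxp = np.zeros_like(xp)
        K = self._kernel()
        for i in range(self.kh):
            for j in range(self.kw):
                patch = xp[:, i * d : i * d + oh, j * d : j * d + ow, :]
                ki, kj = (self.kh - 1 - i, self.kw - 1 - j) if self.transposed else (i, j)
                dK[ki, kj] += np.tensordot(patch, grad, axes=([0, 1, 2], [0, 1, 2]))
                dxp[:, i * d : i * d + oh, j * d : j * d + ow, :] += np.tensordot(
                    grad, K[i, j], axes=([3], [1])
                )
        self.W.grad += dK
        self.b.grad += grad.sum(axis=(0, 1, 2))
        if self.padding == "same":
            eh, ew = self._effective_extent()
            ph, pw = (eh - 1) // 2, (ew - 1) // 2
            h = xp.shape[1] - (eh - 1)
            w = xp.shape[2] - (ew - 1)
            return dxp[:, ph : ph + h, pw : pw + w, :]
        return dxp


class ConcatChannels(Layer):
    """Apply several spatial branches to the same input; concatenate on depth."""

    def __init__(self, branches: list[Layer]):
        self.branches = branches

    def params(self) -> list[Parameter]:
        return [p for br in self.branches for p in br.params()]

    def forward(self, x, training=False, rng=None):
        outs = [br.forward(x, training=training, rng=rng) for br in self.branches]
        self._splits = np.cumsum([o.shape[-1] for o in outs])[:-1]
        return np.concatenate(outs, axis=-1)

    def backward(self, grad):
        grads = np.split(grad, self._splits, axis=-1)
        gx = None
        for br, g in zip(self.branches, grads):
            gi = br.backward(np.ascontiguousarray(g))
            gx = gi if gx is None else gx + gi
        return gx
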