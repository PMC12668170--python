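"""Layer primitives for the 1-D U-Net, built on :mod:`ventseg.nn.tensor`.

Weights are He-initialized (fan-in scaled normal), appropriate for the
LeakyReLU nonlinearities used throughout the trunk.  All randomness (init and
dropout masks) flows through explicitly passed numpy Generators.
"""

from __future__ import annotations

import numpy as np

from .tensor import Tensor, conv1d, conv_transpose1d

__all__ = ["Module", "Conv1d", "ConvTranspose1d", "LayerNorm", "Dropout", "AttentionGate1d"]

_DTYPE = np.float32


class Module:
    """Tiny module base: recursive parameter collection and train/eval mode."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for value in vars(self).values():
            if isinstance(value, Tensor) and value.requires_grad:
                params.append(value)
            elif isinstance(value, Module):
                params.extend(value.parameters())
            elif isinstance(value, (list, tuple)):
                for item in value:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        return {str(i): p.data.copy() for i, p in enumerate(self.parameters())}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if len(state) != len(params):
            raise ValueError(f"state has {len(state)} arrays, model has {len(params)}")
        for i, p in enumerate(params):
            arr = np.asarray(state[str(i)], dtype=p.data.dtype)
            if arr.shape != p.data.shape:
                raise ValueError(f"parameter {i}: shape {arr.shape} != {p.data.shape}")
            p.data = arr.copy()

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))


def he_normal(rng: np.random.Generator, shape: tuple, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape).astype(_DTYPE)


class Conv1d(Module):
    """Stride-1 'same' 1-D convolution, (N, L, C_in) -> (N, L, C_out)."""

    def __init__(self, c_in: int, c_out: int, kernel_size: int, rng: np.random.Generator, dilation: int = 1):
        self.dilation = dilation
        self.weight = Tensor(
            he_normal(rng, (kernel_size, c_in, c_out), kernel_size * c_in), requires_grad=True
        )
        self.bias = Tensor(np.zeros(c_out, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.weight, self.bias, dilation=self.dilation)


class ConvTranspose1d(Module):
    """Kernel-2 stride-2 transposed convolution: exact 2x temporal upsampling."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator):
        self.weight = Tensor(he_normal(rng, (2, c_in, c_out), c_in), requires_grad=True)
        self.bias = Tensor(np.zeros(c_out, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv_transpose1d(x, self.weight, self.bias)


class LayerNorm(Module):
    """Normalization over the channel axis with learned scale and shift."""

    def __init__(self, channels: int, eps: float = 1e-5):
        self.eps = eps
        self.gamma = Tensor(np.ones(channels, dtype=_DTYPE), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=_DTYPE), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered * centered).mean(axis=-1, keepdims=True)
        return centered * ((var + self.eps) ** -0.5) * self.gamma + self.beta


class Dropout(Module):
    def __init__(self, p: float):
        if not (0 <= p < 1):
            raise ValueError("dropout probability must lie in [0, 1)")
        self.p = p

    def __call__(self, x: Tensor, rng: np.random.Generator | None, training: bool) -> Tensor:
        if not training or self.p == 0:
            return x
        if rng is None:
            raise ValueError("training-mode dropout needs a Generator")
        mask = (rng.random(x.shape) >= self.p).astype(x.data.dtype) / (1.0 - self.p)
        return x * Tensor(mask)


class AttentionGate1d(Module):
    """Additive attention gate for U-Net skip connections.

    The encoder skip ``x`` and the decoder gating signal ``g`` (same length,
    possibly different channel counts) each pass a 1x1 convolution to an
    intermediate width, are summed and ReLU-ed; a second 1x1 convolution to a
    single channel plus a sigmoid yields per-timestep coefficients in (0, 1)
    that multiply the skip before concatenation.
    """

    def __init__(self, skip_channels: int, gate_channels: int, rng: np.random.Generator):
        inter = max(skip_channels // 2, 1)
        self.theta_x = Conv1d(skip_channels, inter, 1, rng)
        self.phi_g = Conv1d(gate_channels, inter, 1, rng)
        self.psi = Conv1d(inter, 1, 1, rng)

    def coefficients(self, x: Tensor, g: Tensor) -> Tensor:
        return self.psi((self.theta_x(x) + self.phi_g(g)).relu()).sigmoid()

    def __call__(self, x: Tensor, g: Tensor) -> Tensor:
        return x * self.coefficients(x, g)
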