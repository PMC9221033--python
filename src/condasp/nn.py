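"""Shared neural-network primitives: parameter init, 1D convolution, Adam.

Convolutions are "same" (zero-padded), stride 1 everywhere — the architecture
deliberately never pools or strides, because every residue needs a label.
"""

from __future__ import annotations

from typing import Iterable

import numpy as np

from .autograd import Tensor, pad_rows, take

__all__ = ["init_kernel", "conv1d", "Adam", "ParamDict"]


def init_kernel(rng: np.random.Generator, *shape: int) -> np.ndarray:
    """Fan-in-scaled uniform init, U(-1/sqrt(fan_in), 1/sqrt(fan_in)).

    For a conv kernel (K, C_in, C_out) the fan-in is K*C_in; for a dense
    matrix (C_in, C_out) it is C_in.
    """
    fan_in = int(np.prod(shape[:-1]))
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return rng.uniform(-bound, bound, size=shape)


def conv1d(x: Tensor, w: Tensor, b: Tensor | None = None, dilation: int = 1) -> Tensor:
    """Centered dilated 1D convolution of x (n, C_in) with w (K, C_in, C_out).

    output[i] = sum_k x[i + dilation*(k - (K-1)/2)] . w[k]  (+ b), with zero
    padding outside the sequence; stride 1, so length is preserved. K must be
    odd for the output to align with the input.
    """
    K, c_in, c_out = w.shape
    if x.shape[-1] != c_in:
        raise ValueError(f"channel mismatch: input has {x.shape[-1]}, kernel expects {c_in}")
    if K % 2 == 0:
        raise ValueError("kernel width must be odd")
    n = x.shape[0]
    if K == 1 and dilation == 1:
        out = x @ w.reshape(c_in, c_out)
    else:
        half = dilation * (K - 1) // 2
        xp = pad_rows(x, half, half)
        # im2col: row i gathers the K dilated taps centred at i
        idx = np.arange(n)[:, None] + dilation * np.arange(K)[None, :]
        cols = take(xp, idx).reshape(n, K * c_in)
        out = cols @ w.reshape(K * c_in, c_out)
    if b is not None:
        out = out + b
    return out


class ParamDict(dict):
    """name -> Tensor mapping with convenience constructors."""

    def tensor(self, name: str, data: np.ndarray) -> Tensor:
        t = Tensor(data, requires_grad=True)
        self[name] = t
        return t

    def zero_grads(self) -> None:
        for t in self.values():
            t.zero_grad()

    def state(self) -> dict[str, np.ndarray]:
        return {k: t.data.copy() for k, t in self.items()}

    def load_state(self, state: dict[str, np.ndarray]) -> None:
        for k, t in self.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != t.data.shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            t.data = arr.copy()


class Adam:
    """Adam optimizer (beta1=0.9, beta2=0.999, eps=1e-8)."""

    def __init__(self, params: Iterable[Tensor], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1.0 - self.b1) * (g - m)
            v += (1.0 - self.b2) * (g * g - v)
            p.data -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()
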