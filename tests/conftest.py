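"""Shared fixtures and independent reference oracles.

The reference implementations here are deliberately naive (index loops,
exhaustive enumeration) and never call the package's numeric paths they are
used to check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from condasp.train_eval import EnsembleConfig, TrainConfig


@pytest.fixture
def tiny_model_cfg() -> EnsembleConfig:
    """Smallest config that still exercises every architectural element."""
    return EnsembleConfig(
        condgcnn_blocks=1, node_size=6, experts=2, blstm_layers=1,
        hidden_size=5, asp_rates=(2, 4, 8), asp_node_size=4, head_hidden=4,
        dropout=0.1)


@pytest.fixture
def fast_train_cfg() -> TrainConfig:
    return TrainConfig(initial_lr=0.003, lr_milestones=(2,), epochs=3,
                       batch_size=4, seed=0)


# ----------------------------------------------------------------- oracles

def ref_dilated_conv(x: np.ndarray, w: np.ndarray, b: np.ndarray | None,
                     rate: int) -> np.ndarray:
    """Index-loop dilated convolution, centered form with zero padding:
    y[i, o] = sum_k sum_c x[i + rate*(k - (K-1)/2), c] * w[k, c, o] + b[o]."""
    n, _ = x.shape
    K, c_in, c_out = w.shape
    half = (K - 1) // 2
    y = np.zeros((n, c_out))
    for i in range(n):
        for k in range(K):
            j = i + rate * (k - half)
            if 0 <= j < n:
                for o in range(c_out):
                    y[i, o] += float(x[j] @ w[k, :, o])
    if b is not None:
        y += b
    return y


def ref_lstm_step(x, h_prev, c_prev, W_x, W_h, b, literal_cell=False):
    """Scalar-loop evaluation of the six cell equations."""
    H = len(h_prev)
    pre = np.array([
        sum(x[j] * W_x[j, col] for j in range(len(x)))
        + sum(h_prev[j] * W_h[j, col] for j in range(H))
        + b[col]
        for col in range(4 * H)
    ])
    sig = lambda v: 1.0 / (1.0 + np.exp(-v))
    i = sig(pre[0:H])
    f = sig(pre[H:2 * H])
    o = sig(pre[2 * H:3 * H])
    g = np.tanh(pre[3 * H:4 * H])
    c = f * c_prev + i * g
    if literal_cell:
        c = sig(c)
    h = o * np.tanh(c)
    return h, c


def brute_force_posteriors(initial, transition, emissions, obs):
    """Exact smoothing posteriors by summation over all |S|^n state paths."""
    n = len(obs)
    S = len(initial)
    post = np.zeros((n, S))
    total = 0.0
    for path in itertools.product(range(S), repeat=n):
        p = initial[path[0]] * emissions[path[0], obs[0]]
        for t in range(1, n):
            p *= transition[path[t - 1], path[t]] * emissions[path[t], obs[t]]
        total += p
        for t in range(n):
            post[t, path[t]] += p
    return post / total
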