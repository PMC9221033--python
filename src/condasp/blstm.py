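"""Stacked bidirectional LSTM encoder.

Two LSTMs per layer run over the residue axis in opposite directions; their
per-position hidden states are concatenated (width 2H), and N such layers
are stacked (default N=2, H=512). Gates follow the standard cell:

    i = sigmoid(x W_i + h W'_i + b_i)      f = sigmoid(... )
    o = sigmoid(...)                        g = tanh(...)
    c_t = f * c_{t-1} + i * g               h_t = o * tanh(c_t)

A nonstandard variant that additionally squashes the cell update through a
sigmoid (bounding c in (0,1)) is available behind ``literal_cell=True``; it
is off by default because it departs from the standard cell the rest of the
literature uses.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, concat, dropout
from .nn import ParamDict, init_kernel

# gate packing order along the 4H axis
_GATES = ("i", "f", "o", "g")


def lstm_step(x_t: Tensor, h_prev: Tensor, c_prev: Tensor,
              params: dict[str, Tensor], literal_cell: bool = False
              ) -> tuple[Tensor, Tensor]:
    """One cell update. x_t, h_prev, c_prev are (1, *) row tensors; params
    holds W_x (in,4H), W_h (H,4H), b (4H,) with gates packed i|f|o|g."""
    H = h_prev.shape[1]
    pre = x_t @ params["W_x"] + h_prev @ params["W_h"] + params["b"]
    i = pre[:, 0:H].sigmoid()
    f = pre[:, H:2 * H].sigmoid()
    o = pre[:, 2 * H:3 * H].sigmoid()
    g = pre[:, 3 * H:4 * H].tanh()
    c = f * c_prev + i * g
    if literal_cell:
        c = c.sigmoid()
    h = o * c.tanh()
    return h, c


def _run_direction(X: Tensor, params: dict[str, Tensor], H: int,
                   reverse: bool, literal_cell: bool) -> Tensor:
    n = X.shape[0]
    # hoist the input projection out of the recurrence: one big matmul
    xp = X @ params["W_x"] + params["b"]
    h = Tensor(np.zeros((1, H)))
    c = Tensor(np.zeros((1, H)))
    outs: list[Tensor | None] = [None] * n
    order = range(n - 1, -1, -1) if reverse else range(n)
    W_h = params["W_h"]
    for t in order:
        pre = xp[t:t + 1] + h @ W_h
        i = pre[:, 0:H].sigmoid()
        f = pre[:, H:2 * H].sigmoid()
        o = pre[:, 2 * H:3 * H].sigmoid()
        g = pre[:, 3 * H:4 * H].tanh()
        c = f * c + i * g
        if literal_cell:
            c = c.sigmoid()
        h = o * c.tanh()
        outs[t] = h
    return concat(outs, axis=0)  # type: ignore[arg-type]


class BLSTMEncoder:
    """N stacked bidirectional layers; output width 2*hidden_size.

    Weights use fan-in-scaled uniform init; biases start at zero except the
    forget gate, initialized to 1 so early training does not erase the cell
    state (standard practice).
    """

    def __init__(self, in_dim: int = 42, hidden_size: int = 512, layers: int = 2,
                 dropout_rate: float = 0.2, literal_cell: bool = False,
                 rng: np.random.Generator | None = None):
        if layers < 1 or hidden_size < 1:
            raise ValueError("invalid bLSTM configuration")
        rng = rng or np.random.default_rng(0)
        self.hidden_size = hidden_size
        self.layers = layers
        self.dropout_rate = dropout_rate
        self.literal_cell = literal_cell
        H = hidden_size
        p = ParamDict()
        for k in range(layers):
            d_in = in_dim if k == 0 else 2 * H
            for direction in ("fwd", "bwd"):
                pre = f"layer{k}.{direction}"
                p.tensor(f"{pre}.W_x", init_kernel(rng, d_in, 4 * H))
                p.tensor(f"{pre}.W_h", init_kernel(rng, H, 4 * H))
                b = np.zeros(4 * H)
                b[H:2 * H] = 1.0  # forget-gate bias
                p.tensor(f"{pre}.b", b)
        self.params = p

    def _dir_params(self, k: int, direction: str) -> dict[str, Tensor]:
        pre = f"layer{k}.{direction}"
        return {n: self.params[f"{pre}.{n}"] for n in ("W_x", "W_h", "b")}

    def forward(self, F: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if F.shape[0] == 0:
            raise ValueError("empty sequence")
        H = self.hidden_size
        X = F
        for k in range(self.layers):
            fwd = _run_direction(X, self._dir_params(k, "fwd"), H,
                                 reverse=False, literal_cell=self.literal_cell)
            bwd = _run_direction(X, self._dir_params(k, "bwd"), H,
                                 reverse=True, literal_cell=self.literal_cell)
            X = concat([fwd, bwd], axis=1)
            if training and rng is not None and k < self.layers - 1:
                X = dropout(X, self.dropout_rate, rng)  # inter-layer only
        return X


def blstm_encode(F: np.ndarray | Tensor, stack: BLSTMEncoder,
                 training_mode: bool = False,
                 rng: np.random.Generator | None = None) -> Tensor:
    """Encode an n x C feature matrix to n x 2*hidden_size."""
    if not isinstance(F, Tensor):
        F = Tensor(F)
    return stack.forward(F, training=training_mode, rng=rng)
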