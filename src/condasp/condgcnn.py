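"""Conditionally parameterized gated convolutional (CondGCNN) encoder.

Each layer runs two parallel width-3 convolutions over the residue axis:

* a CondConv branch whose kernel is an input-dependent mixture of ``n``
  expert kernels, W_cond = sum_i alpha_i W_i, with routing weights
  alpha = sigmoid(GlobalAveragePool(X) . R) computed per protein
  ("example-dependent": the pool is over sequence positions);
* a plain convolutional gate, squashed through a sigmoid.

The layer output is the element-wise product of the two branches
(V = CondConv(X) * sigmoid(Conv_g(X))). Two layers form a residual block;
the encoder stacks M blocks at constant channel width (node_size) after a
window-1 input projection from the 42-dim residue features. Expert biases
are mixed with the same routing weights as the kernels, which keeps the
whole CondConv branch exactly linear in (W_i, b_i) for fixed alpha.
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor, dropout
from .nn import ParamDict, conv1d, init_kernel

KERNEL_WIDTH = 3


def routing_weights(X: Tensor, R: Tensor) -> Tensor:
    """Per-protein expert weights: sigmoid(mean over positions of X, times R)."""
    if X.shape[0] == 0:
        raise ValueError("cannot route a zero-length sequence")
    pooled = X.mean(axis=0, keepdims=True)  # (1, C)
    return (pooled @ R).reshape(R.shape[1]).sigmoid()


def mix_kernels(alpha: Tensor, experts: Tensor, expert_biases: Tensor
                ) -> tuple[Tensor, Tensor]:
    """W_cond = sum_i alpha_i W_i, b_cond = sum_i alpha_i b_i (elementwise)."""
    n = experts.shape[0]
    if alpha.shape != (n,):
        raise ValueError(f"expected {n} routing weights, got shape {alpha.shape}")
    w = (alpha.reshape(n, 1, 1, 1) * experts).sum(axis=0)
    b = (alpha.reshape(n, 1) * expert_biases).sum(axis=0)
    return w, b


def condconv1d(X: Tensor, experts: Tensor, expert_biases: Tensor, R: Tensor) -> Tensor:
    """Width-3, same-padded, stride-1 convolution with the routed mixed kernel."""
    if X.shape[1] != experts.shape[2]:
        raise ValueError(
            f"channel mismatch: input has {X.shape[1]}, experts expect {experts.shape[2]}")
    alpha = routing_weights(X, R)
    w, b = mix_kernels(alpha, experts, expert_biases)
    return conv1d(X, w, b)


def condgcnn_layer(X: Tensor, layer: dict[str, Tensor]) -> Tensor:
    """V = CondConv(X) * sigmoid(Conv_g(X)), both branches length-preserving."""
    cond = condconv1d(X, layer["experts"], layer["expert_biases"], layer["R"])
    gate = conv1d(X, layer["gate_w"], layer["gate_b"]).sigmoid()
    return cond * gate


def condgcnn_block(X: Tensor, layers: tuple[dict, dict]) -> Tensor:
    """Residual block: X + layer2(layer1(X))."""
    return X + condgcnn_layer(condgcnn_layer(X, layers[0]), layers[1])


class CondGCNNEncoder:
    """Window-1 input projection followed by M two-layer residual blocks.

    Kernels use fan-in-scaled uniform init; biases and routing matrices start
    at zero, so training begins at the symmetric routing point alpha = 0.5.
    """

    def __init__(self, in_dim: int = 42, node_size: int = 64, blocks: int = 32,
                 experts: int = 3, dropout_rate: float = 0.2,
                 rng: np.random.Generator | None = None):
        if experts < 1 or blocks < 0 or node_size < 1:
            raise ValueError("invalid CondGCNN configuration")
        rng = rng or np.random.default_rng(0)
        self.node_size = node_size
        self.blocks = blocks
        self.dropout_rate = dropout_rate
        p = ParamDict()
        p.tensor("proj_w", init_kernel(rng, 1, in_dim, node_size))
        p.tensor("proj_b", np.zeros(node_size))
        for m in range(blocks):
            for l in range(2):
                pre = f"block{m}.layer{l}"
                p.tensor(f"{pre}.experts",
                         np.stack([init_kernel(rng, KERNEL_WIDTH, node_size, node_size)
                                   for _ in range(experts)]))
                p.tensor(f"{pre}.expert_biases", np.zeros((experts, node_size)))
                p.tensor(f"{pre}.R", np.zeros((node_size, experts)))
                p.tensor(f"{pre}.gate_w", init_kernel(rng, KERNEL_WIDTH, node_size, node_size))
                p.tensor(f"{pre}.gate_b", np.zeros(node_size))
        self.params = p

    def _layer(self, m: int, l: int) -> dict[str, Tensor]:
        pre = f"block{m}.layer{l}"
        return {k: self.params[f"{pre}.{k}"]
                for k in ("experts", "expert_biases", "R", "gate_w", "gate_b")}

    def forward(self, F: Tensor, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        if F.shape[0] == 0:
            raise ValueError("empty sequence")
        X = conv1d(F, self.params["proj_w"], self.params["proj_b"])
        for m in range(self.blocks):
            X = condgcnn_block(X, (self._layer(m, 0), self._layer(m, 1)))
            if training and rng is not None:
                X = dropout(X, self.dropout_rate, rng)
        return X


def condgcnn_encode(F: np.ndarray | Tensor, stack: CondGCNNEncoder,
                    training_mode: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
    """Encode an n x 42 feature matrix to n x node_size."""
    if not isinstance(F, Tensor):
        F = Tensor(F)
    return stack.forward(F, training=training_mode, rng=rng)
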