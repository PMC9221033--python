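"""1D atrous spatial pyramid (ASP) generation module and output head.

The pyramid runs four parallel length-preserving convolutions over the
ensemble features — a window-1 branch and three width-3 dilated branches at
rates (2, 4, 8) — each followed by a ReLU, and concatenates their outputs
with a skip copy of the input. A dilated (atrous) convolution samples its
taps r positions apart:

    y[i] = sum_k x[i + r*(k - (K-1)/2)] . w[k] + b,

so a width-3, rate-r kernel sees a window of 2r+1 positions at the cost of
three taps. There is no pooling and no striding anywhere: every residue
keeps its own feature row, because every residue gets its own label.

The head maps the concatenated pyramid output to 8 logits per residue with
window-1 convolutions (default: to 100 channels, ReLU, then to 8; set
``head_hidden=None`` for a single window-1 convolution straight to 8).
"""

from __future__ import annotations

import numpy as np

from .autograd import Tensor
from .io_features import SSAlphabet
from .nn import ParamDict, conv1d, init_kernel

DEFAULT_RATES = (2, 4, 8)


def atrous_conv1d(x: Tensor, w: Tensor, b: Tensor | None, rate: int) -> Tensor:
    """Centered same-padded dilated convolution, stride 1; rate 1 is the
    standard convolution."""
    if rate < 1:
        raise ValueError("dilation rate must be >= 1")
    return conv1d(x, w, b, dilation=rate)


class ASPHead:
    """Pyramid branches + window-1 output head producing n x 8 logits."""

    def __init__(self, in_dim: int, node_size: int = 100,
                 rates: tuple[int, ...] = DEFAULT_RATES,
                 head_hidden: int | None = 100,
                 rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng(0)
        self.in_dim = in_dim
        self.node_size = node_size
        self.rates = tuple(rates)
        self.head_hidden = head_hidden
        p = ParamDict()
        p.tensor("conv1_w", init_kernel(rng, 1, in_dim, node_size))
        p.tensor("conv1_b", np.zeros(node_size))
        for r in self.rates:
            p.tensor(f"rate{r}_w", init_kernel(rng, 3, in_dim, node_size))
            p.tensor(f"rate{r}_b", np.zeros(node_size))
        concat_dim = in_dim + (1 + len(self.rates)) * node_size
        self.concat_dim = concat_dim
        if head_hidden is None:
            p.tensor("head_w", init_kernel(rng, 1, concat_dim, 8))
            p.tensor("head_b", np.zeros(8))
        else:
            p.tensor("head1_w", init_kernel(rng, 1, concat_dim, head_hidden))
            p.tensor("head1_b", np.zeros(head_hidden))
            p.tensor("head2_w", init_kernel(rng, 1, head_hidden, 8))
            p.tensor("head2_b", np.zeros(8))
        self.params = p


def asp_forward(F: np.ndarray | Tensor, head: ASPHead,
                training_mode: bool = False) -> Tensor:
    """Concatenate [skip | window-1 | dilated branches], ReLU on each branch."""
    if not isinstance(F, Tensor):
        F = Tensor(F)
    if F.shape[0] == 0:
        raise ValueError("empty sequence")
    if F.shape[1] != head.in_dim:
        raise ValueError(f"expected {head.in_dim} input channels, got {F.shape[1]}")
    from .autograd import concat

    p = head.params
    branches = [F, conv1d(F, p["conv1_w"], p["conv1_b"]).relu()]
    for r in head.rates:
        branches.append(atrous_conv1d(F, p[f"rate{r}_w"], p[f"rate{r}_b"], r).relu())
    return concat(branches, axis=1)


def output_logits(A: Tensor, head: ASPHead) -> Tensor:
    """Window-1 head: logits at position i depend only on row i of A."""
    p = head.params
    if head.head_hidden is None:
        return conv1d(A, p["head_w"], p["head_b"])
    hidden = conv1d(A, p["head1_w"], p["head1_b"]).relu()
    return conv1d(hidden, p["head2_w"], p["head2_b"])


def masked_cross_entropy(logits: Tensor, labels: np.ndarray,
                         mask: np.ndarray | None = None) -> Tensor:
    """Mean over masked positions of -log softmax(logits)[label].

    Positions where mask is False contribute nothing — neither to the value
    nor to the gradient — so padding content is irrelevant.
    """
    labels = np.asarray(labels, dtype=np.int64)
    n, k = logits.shape
    if labels.shape != (n,):
        raise ValueError("labels length does not match logits")
    if mask is None:
        mask = np.ones(n, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (n,):
        raise ValueError("mask length does not match logits")
    if not mask.any():
        raise ValueError("mask selects no positions")
    sel = np.flatnonzero(mask)
    z = logits[sel]  # autograd gather of scored rows
    zmax = Tensor(z.data.max(axis=1, keepdims=True))  # detached, shift only
    zs = z - zmax
    lse = zs.exp().sum(axis=1, keepdims=True).log()
    logp = zs - lse
    onehot = np.zeros((len(sel), k))
    onehot[np.arange(len(sel)), labels[sel]] = 1.0
    picked = (logp * Tensor(onehot)).sum(axis=1)
    return -picked.mean()


def predict_labels(logits: np.ndarray | Tensor) -> str:
    """Per-position argmax through the 8-state alphabet; ties break toward
    the lowest class index."""
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    return SSAlphabet.to_string(np.argmax(arr, axis=1))


def softmax_probs(logits: np.ndarray | Tensor) -> np.ndarray:
    arr = logits.data if isinstance(logits, Tensor) else np.asarray(logits)
    z = arr - arr.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)
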