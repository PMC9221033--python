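"""Ensemble model assembly, training, and evaluation.

The full model encodes each protein's n x 42 features twice — through the
CondGCNN stack (n x node_size) and the stacked bLSTM (n x 2*hidden) — and
concatenates the two encodings into the ensemble feature fed to the ASP
generation module, whose window-1 head emits 8 logits per residue.

Training minimizes masked cross-entropy with Adam under a multi-step
learning-rate schedule (initial 0.001, x0.1 at each milestone). After every
epoch the per-protein mean Q8 on the validation split is computed and the
parameters with the best validation score are the ones kept.

Evaluation reports residue-pooled Q8, the unweighted per-protein mean and
sample standard deviation of Q8 (the convention used for published test-set
tables), and boundary Q8: accuracy restricted to boundary residues, i.e.
residues whose true label differs from at least one adjacent residue's.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import numpy as np

from .asp import ASPHead, asp_forward, masked_cross_entropy, output_logits, \
    predict_labels, softmax_probs
from .autograd import Tensor, concat
from .blstm import BLSTMEncoder
from .condgcnn import CondGCNNEncoder
from .io_features import ProteinRecord, SSAlphabet, build_features
from .nn import Adam, ParamDict
from .synthetic import GeneratedDataset

logger = logging.getLogger(__name__)


# --------------------------------------------------------------- configuration

@dataclasses.dataclass
class EnsembleConfig:
    """Architecture hyper-parameters; defaults are the best-found settings
    (32 CondGCNN blocks, node 64, 3 experts; 2 bLSTM layers, hidden 512;
    ASP rates 2/4/8 at node 100 with a window-1 conv head; dropout 0.2)."""

    condgcnn_blocks: int = 32
    node_size: int = 64
    experts: int = 3
    blstm_layers: int = 2
    hidden_size: int = 512
    asp_rates: tuple[int, ...] = (2, 4, 8)
    asp_node_size: int = 100
    head_hidden: int | None = 100
    dropout: float = 0.2
    pssm_transform: str = "raw"
    paper_literal_cell: bool = False

    def __post_init__(self) -> None:
        self.asp_rates = tuple(int(r) for r in self.asp_rates)
        if min(self.condgcnn_blocks, self.experts, self.blstm_layers,
               self.hidden_size, self.node_size, self.asp_node_size) < 0 \
                or self.blstm_layers < 1:
            raise ValueError("architecture sizes must be positive")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")
        if self.pssm_transform not in ("raw", "logistic"):
            raise ValueError("pssm_transform must be 'raw' or 'logistic'")


@dataclasses.dataclass
class TrainConfig:
    """Optimization settings: Adam, initial LR 0.001, multi-step decay x0.1
    at the milestone epochs."""

    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_milestones: tuple[int, ...] = (30, 50)
    epochs: int = 60
    batch_size: int = 16
    seed: int = 0

    def __post_init__(self) -> None:
        self.lr_milestones = tuple(int(m) for m in self.lr_milestones)
        if self.initial_lr <= 0 or self.epochs < 1 or self.batch_size < 1:
            raise ValueError("invalid training configuration")
        if list(self.lr_milestones) != sorted(set(self.lr_milestones)):
            raise ValueError("lr_milestones must be strictly increasing")
        if self.lr_milestones and self.lr_milestones[-1] >= self.epochs:
            raise ValueError("lr_milestones must be < epochs")


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """initial_lr * factor^(#milestones <= epoch)."""
    if not 0 <= epoch < cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs})")
    k = sum(1 for m in cfg.lr_milestones if m <= epoch)
    return cfg.initial_lr * cfg.lr_decay_factor**k


# --------------------------------------------------------------------- model

class EnsembleModel:
    """CondGCNN + bLSTM encoders feeding the ASP generation module."""

    def __init__(self, cfg: EnsembleConfig, seed: int = 0):
        self.cfg = cfg
        ss = np.random.SeedSequence(seed)
        rng_c, rng_b, rng_a = (np.random.default_rng(s) for s in ss.spawn(3))
        self.condgcnn = CondGCNNEncoder(
            in_dim=42, node_size=cfg.node_size, blocks=cfg.condgcnn_blocks,
            experts=cfg.experts, dropout_rate=cfg.dropout, rng=rng_c)
        self.blstm = BLSTMEncoder(
            in_dim=42, hidden_size=cfg.hidden_size, layers=cfg.blstm_layers,
            dropout_rate=cfg.dropout, literal_cell=cfg.paper_literal_cell, rng=rng_b)
        ensemble_dim = cfg.node_size + 2 * cfg.hidden_size
        self.asp = ASPHead(in_dim=ensemble_dim, node_size=cfg.asp_node_size,
                           rates=cfg.asp_rates, head_hidden=cfg.head_hidden, rng=rng_a)
        self.params = ParamDict()
        for prefix, sub in (("condgcnn", self.condgcnn),
                            ("blstm", self.blstm),
                            ("asp", self.asp)):
            for k, t in sub.params.items():
                self.params[f"{prefix}.{k}"] = t

    def forward(self, record: ProteinRecord, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
        F = Tensor(build_features(record, self.cfg.pssm_transform))
        enc_c = self.condgcnn.forward(F, training=training, rng=rng)
        enc_b = self.blstm.forward(F, training=training, rng=rng)
        ensemble = concat([enc_c, enc_b], axis=1)
        A = asp_forward(ensemble, self.asp, training_mode=training)
        return output_logits(A, self.asp)

    def predict(self, record: ProteinRecord) -> tuple[str, np.ndarray]:
        """Evaluation-mode prediction: (label string, n x 8 class probabilities)."""
        logits = self.forward(record, training=False)
        return predict_labels(logits), softmax_probs(logits)


def ensemble_forward(record: ProteinRecord, model: EnsembleModel,
                     training_mode: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
    return model.forward(record, training=training_mode, rng=rng)


# ------------------------------------------------------------------- metrics

def q8_accuracy(pred: str, truth: str, mask: np.ndarray | None = None) -> float:
    """Fraction of (masked) positions where predicted == true label."""
    if len(pred) != len(truth):
        raise ValueError("label strings differ in length")
    hits = np.array([a == b for a, b in zip(pred, truth)])
    if mask is None:
        mask = np.ones(len(truth), dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != (len(truth),):
        raise ValueError("mask length mismatch")
    if not mask.any():
        raise ValueError("mask selects no positions")
    return float(hits[mask].mean())


def per_protein_q8(predictions: Sequence[str], truths: Sequence[str]
                   ) -> tuple[float, float]:
    """Unweighted mean and sample sd (ddof=1) of per-protein Q8; sd is 0 for
    a single protein."""
    if len(predictions) != len(truths) or not predictions:
        raise ValueError("need >= 1 prediction/truth pair of equal count")
    qs = np.array([q8_accuracy(p, t) for p, t in zip(predictions, truths)])
    sd = float(qs.std(ddof=1)) if len(qs) > 1 else 0.0
    return float(qs.mean()), sd


def boundary_mask(labels: str) -> np.ndarray:
    """True where the label differs from the left or right neighbor's."""
    if not labels:
        raise ValueError("empty label string")
    arr = np.frombuffer(labels.encode(), dtype="S1")
    mask = np.zeros(len(labels), dtype=bool)
    if len(labels) > 1:
        diff = arr[1:] != arr[:-1]
        mask[1:] |= diff
        mask[:-1] |= diff
    return mask


def boundary_q8(pred: str, truth: str) -> float:
    """Q8 restricted to boundary residues of the true labeling."""
    mask = boundary_mask(truth)
    if not mask.any():
        raise ValueError("truth contains no boundary residues")
    return q8_accuracy(pred, truth, mask)


@dataclasses.dataclass
class EvalReport:
    overall_q8: float
    per_protein_mean: float
    per_protein_sd: float
    boundary_q8: float
    n_proteins: int
    n_residues: int
    n_boundary_residues: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1)

    def table(self) -> str:
        rows = [
            ("proteins", f"{self.n_proteins}"),
            ("residues", f"{self.n_residues}"),
            ("boundary residues", f"{self.n_boundary_residues}"),
            ("Q8 (residue-pooled)", f"{self.overall_q8:.4f}"),
            ("Q8 (per-protein mean +/- sd)",
             f"{self.per_protein_mean:.4f} +/- {self.per_protein_sd:.4f}"),
            ("boundary Q8", f"{self.boundary_q8:.4f}"),
        ]
        width = max(len(k) for k, _ in rows)
        return "\n".join(f"{k:<{width}}  {v}" for k, v in rows)


def evaluate(model: EnsembleModel, records: Sequence[ProteinRecord]) -> EvalReport:
    """Predict every record and report pooled, per-protein, and boundary Q8."""
    if not records:
        raise ValueError("no records to evaluate")
    preds, truths = [], []
    for r in records:
        if r.labels is None:
            raise ValueError(f"record {r.id!r} carries no labels")
        pred, _ = model.predict(r)
        preds.append(pred)
        truths.append(r.labels)
    return report_from_predictions(preds, truths)


def report_from_predictions(preds: Sequence[str], truths: Sequence[str]) -> EvalReport:
    n_res = sum(len(t) for t in truths)
    pooled_hits = sum(sum(a == b for a, b in zip(p, t)) for p, t in zip(preds, truths))
    mean, sd = per_protein_q8(preds, truths)
    b_hits = b_total = 0
    for p, t in zip(preds, truths):
        m = boundary_mask(t)
        b_total += int(m.sum())
        b_hits += int(sum(1 for i in np.flatnonzero(m) if p[i] == t[i]))
    if b_total == 0:
        raise ValueError("evaluation set contains no boundary residues")
    return EvalReport(
        overall_q8=pooled_hits / n_res,
        per_protein_mean=mean,
        per_protein_sd=sd,
        boundary_q8=b_hits / b_total,
        n_proteins=len(preds),
        n_residues=n_res,
        n_boundary_residues=b_total,
    )


# ------------------------------------------------------------------ training

def train(dataset: GeneratedDataset | tuple[Sequence[ProteinRecord], Sequence[ProteinRecord]],
          model_cfg: EnsembleConfig, train_cfg: TrainConfig,
          verbose: bool = False) -> tuple[EnsembleModel, list[dict]]:
    """Train on (train, valid) splits; returns the model restored to its
    best-validation parameters, plus the per-epoch history.

    Per batch the loss is the mean over all scored residues of the batch
    (per-protein losses weighted by residue count), matching a padded batch
    with a loss mask. History rows: epoch, lr, loss, val_q8. Everything is a
    pure function of (data, configs, seed).
    """
    if isinstance(dataset, GeneratedDataset):
        train_recs, valid_recs = dataset.train, dataset.valid
    else:
        train_recs, valid_recs = dataset
    if not train_recs or not valid_recs:
        raise ValueError("train and validation splits must be nonempty")
    for r in train_recs:
        if r.labels is None:
            raise ValueError(f"training record {r.id!r} carries no labels")

    ss = np.random.SeedSequence(train_cfg.seed)
    init_ss, shuffle_ss, drop_ss = ss.spawn(3)
    model = EnsembleModel(model_cfg, seed=init_ss.generate_state(1)[0] % 2**31)
    shuffle_rng = np.random.default_rng(shuffle_ss)
    drop_rng = np.random.default_rng(drop_ss)
    opt = Adam(model.params.values(), lr=train_cfg.initial_lr)

    history: list[dict] = []
    best_q8 = -1.0
    best_state = model.params.state()
    n_train = len(train_recs)
    for epoch in range(train_cfg.epochs):
        lr = lr_at_epoch(train_cfg, epoch)
        opt.lr = lr
        order = shuffle_rng.permutation(n_train)
        epoch_loss = 0.0
        epoch_residues = 0
        for start in range(0, n_train, train_cfg.batch_size):
            batch = [train_recs[i] for i in order[start:start + train_cfg.batch_size]]
            total = sum(len(r) for r in batch)
            opt.zero_grad()
            for rec in batch:
                logits = model.forward(rec, training=True, rng=drop_rng)
                loss = masked_cross_entropy(logits, rec.label_indices)
                loss.backward(grad=len(rec) / total)  # residue-count weighting
                epoch_loss += float(loss.data) * len(rec)
            epoch_residues += total
            opt.step()
        val_preds = [model.predict(r)[0] for r in valid_recs]
        val_q8, _ = per_protein_q8(val_preds, [r.labels for r in valid_recs])
        history.append({"epoch": epoch, "lr": lr,
                        "loss": epoch_loss / epoch_residues, "val_q8": val_q8})
        if val_q8 > best_q8:
            best_q8 = val_q8
            best_state = model.params.state()
        if verbose:
            logger.info("epoch %d  lr %.2g  loss %.4f  val Q8 %.4f",
                        epoch, lr, history[-1]["loss"], val_q8)
    model.params.load_state(best_state)
    return model, history


# ---------------------------------------------------------------- persistence

def save_checkpoint(model: EnsembleModel, train_cfg: TrainConfig | None,
                    history: list[dict], path: str | Path) -> None:
    """Single JSON archive: configs + seed-bearing history + named parameter
    groups. Floats use shortest round-trip repr, so reload is bit-stable."""
    obj = {
        "format": "condasp-checkpoint-v1",
        "model_config": dataclasses.asdict(model.cfg),
        "train_config": dataclasses.asdict(train_cfg) if train_cfg else None,
        "history": history,
        "params": {k: t.data.tolist() for k, t in model.params.items()},
    }
    Path(path).write_text(json.dumps(obj))


def load_checkpoint(path: str | Path) -> tuple[EnsembleModel, dict]:
    obj = json.loads(Path(path).read_text())
    if obj.get("format") != "condasp-checkpoint-v1":
        raise ValueError(f"{path}: not a recognized checkpoint")
    mc = obj["model_config"]
    mc["asp_rates"] = tuple(mc["asp_rates"])
    model = EnsembleModel(EnsembleConfig(**mc), seed=0)
    model.params.load_state({k: np.asarray(v) for k, v in obj["params"].items()})
    return model, obj


def write_predictions(model: EnsembleModel, records: Sequence[ProteinRecord],
                      out_dir: str | Path) -> None:
    """FASTA-like predicted 8-state strings plus a per-residue TSV
    (id, 1-based position, residue, true label if any, predicted label,
    8 class probabilities)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "predictions.fasta", "w") as fa, \
            open(out / "predictions.tsv", "w") as tsv:
        tsv.write("id\tposition\tresidue\ttrue\tpredicted\t"
                  + "\t".join(f"p_{c}" for c in SSAlphabet.labels) + "\n")
        for r in records:
            pred, probs = model.predict(r)
            fa.write(f">{r.id}\n{pred}\n")
            for i, (aa, pc) in enumerate(zip(r.sequence, pred)):
                true_c = r.labels[i] if r.labels else "."
                row = "\t".join(f"{v:.6f}" for v in probs[i])
                tsv.write(f"{r.id}\t{i + 1}\t{aa}\t{true_c}\t{pc}\t{row}\n")
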