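"""Run configuration: defaults, flat YAML config files, and flag overrides.

Precedence is defaults < config file < command-line flags. The resolved
configuration is echoed (as YAML) into every output directory so a run is
reproducible from its output alone.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import yaml

from .train_eval import EnsembleConfig, TrainConfig


@dataclasses.dataclass
class RunConfig:
    """Everything a run needs: architecture, optimization, generator knobs."""

    # architecture
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
    # optimization
    initial_lr: float = 0.001
    lr_decay_factor: float = 0.1
    lr_milestones: tuple[int, ...] = (30, 50)
    epochs: int = 60
    batch_size: int = 16
    seed: int = 0
    # synthetic generator
    n_proteins: int = 100
    length_min: int = 50
    length_max: int = 200
    p_stay: float = 0.85
    emission_concentration: float = 0.3
    pssm_noise_sd: float = 1.0

    def ensemble_config(self) -> EnsembleConfig:
        return EnsembleConfig(
            condgcnn_blocks=self.condgcnn_blocks, node_size=self.node_size,
            experts=self.experts, blstm_layers=self.blstm_layers,
            hidden_size=self.hidden_size, asp_rates=tuple(self.asp_rates),
            asp_node_size=self.asp_node_size, head_hidden=self.head_hidden,
            dropout=self.dropout, pssm_transform=self.pssm_transform,
            paper_literal_cell=self.paper_literal_cell)

    def train_config(self) -> TrainConfig:
        return TrainConfig(
            initial_lr=self.initial_lr, lr_decay_factor=self.lr_decay_factor,
            lr_milestones=tuple(self.lr_milestones), epochs=self.epochs,
            batch_size=self.batch_size, seed=self.seed)

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["asp_rates"] = list(self.asp_rates)
        d["lr_milestones"] = list(self.lr_milestones)
        return yaml.safe_dump(d, sort_keys=True)


_FIELDS = {f.name: f for f in dataclasses.fields(RunConfig)}


def parse_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Resolve defaults < config file < overrides; unknown keys are errors.

    Overrides with value None (unset CLI flags) are ignored.
    """
    merged: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(loaded, dict):
            raise ValueError(f"{path}: config must be a flat key: value mapping")
        merged.update(loaded)
    merged.update({k: v for k, v in overrides.items() if v is not None})
    for key in merged:
        if key not in _FIELDS:
            raise ValueError(f"unknown configuration key {key!r}")
    if "asp_rates" in merged:
        merged["asp_rates"] = tuple(merged["asp_rates"])
    if "lr_milestones" in merged:
        merged["lr_milestones"] = tuple(merged["lr_milestones"])
    cfg = RunConfig(**merged)
    # dataclass-level validation of the two sub-configs plus generator checks
    cfg.ensemble_config()
    cfg.train_config()
    if cfg.length_min < 2 or cfg.length_max < cfg.length_min:
        raise ValueError("length range must satisfy 2 <= min <= max")
    if not 0.0 < cfg.p_stay < 1.0:
        raise ValueError("p_stay must lie in (0, 1)")
    if cfg.pssm_noise_sd < 0 or cfg.emission_concentration <= 0:
        raise ValueError("generator noise/concentration out of range")
    return cfg


def echo_config(cfg: RunConfig, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.yaml").write_text(cfg.to_yaml())
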