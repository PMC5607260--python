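"""Run configuration for the end-to-end pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from . import io as ltio
from .network import SCREEN_DOSES


@dataclass
class RunConfig:
    """Fully serializable description of one pipeline run; a completed
    run's config plus its seeds reproduce the run."""

    seed: int = 0
    n_lines: int = 58
    fixture: bool = False
    variant: str = "full"
    doses: dict[str, float] = field(default_factory=lambda: dict(SCREEN_DOSES))
    responder_threshold: float = 1.20
    alpha: float = 0.05
    effect: float = 0.35
    label_noise: float = 0.10
    n_trees: int = 50
    depth_limit: int = 4
    min_leaf: int = 3
    n_reps: int = 500
    train_fraction: float = 0.7
    exclude_ligands: tuple[str, ...] = ("IGF1",)
    outdir: str = "ligandtree_run"

    def __post_init__(self):
        if not 0 < self.train_fraction < 1:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.responder_threshold <= 1:
            raise ValueError("responder_threshold must exceed 1")
        self.exclude_ligands = tuple(self.exclude_ligands)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["exclude_ligands"] = list(self.exclude_ligands)
        return d

    @property
    def hash(self) -> str:
        return ltio.config_hash(self.to_dict())

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))
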