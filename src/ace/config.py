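"""Structured run configuration with strict key validation and seed fan-out.

The configuration mirrors each stage's interface; unknown keys are rejected
with the offending key named.  Defaults are the published hyperparameters:
temperature 0.1; alignment training lr 2e-4, batch 512, 100 epochs;
specific-model training lr 1.75e-4, batch 512, 10 epochs; latent dimension
256; imputation k = 2.  A single global seed fans out to per-stage seeds via
CRC32 of the stage name (kept below 2**31), so stages are individually
re-runnable yet jointly reproducible.
"""

from __future__ import annotations

import copy
import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml


class ConfigError(ValueError):
    pass


@dataclass
class ReductionConfig:
    method: str = "pca"  # pca | tfidf_lsi | passthrough
    p: int = 100
    drop_first: bool = False


@dataclass
class CorrectionConfig:
    method: str = "center"  # harmony | center | none


@dataclass
class ModalityConfig:
    reduction: ReductionConfig = field(default_factory=ReductionConfig)
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    layer_dims: list[int] | None = None  # encoder architecture override


@dataclass
class LossSection:
    tau: float = 0.1
    include_intra_negatives: bool = True


@dataclass
class TrainSection:
    lr: float = 2e-4
    batch_size: int = 512
    epochs: int = 100


@dataclass
class SpecTrainSection:
    lr: float = 1.75e-4
    batch_size: int = 512
    epochs: int = 10


@dataclass
class ImputeSection:
    k: int = 2
    metric: str = "cosine"


@dataclass
class ConsensusSection:
    weights: dict[str, float] | None = None  # None -> default one-hot scheme


@dataclass
class EvaluateSection:
    n_neighbors_ilisi: int = 90
    clustering: str = "louvain"
    resolution: float = 1.0


@dataclass
class SimulateSection:
    enabled: bool = True
    easy: bool = True  # use the canonical 700-cell fixture
    data_seed: int = 7


@dataclass
class RunConfig:
    seed: int = 0
    input_dir: str | None = None  # mosaic directory (when simulate disabled)
    modalities: dict[str, ModalityConfig] = field(default_factory=dict)
    loss: LossSection = field(default_factory=LossSection)
    train: TrainSection = field(default_factory=TrainSection)
    spec_train: SpecTrainSection = field(default_factory=SpecTrainSection)
    impute: ImputeSection = field(default_factory=ImputeSection)
    consensus: ConsensusSection = field(default_factory=ConsensusSection)
    evaluate: EvaluateSection = field(default_factory=EvaluateSection)
    simulate: SimulateSection = field(default_factory=SimulateSection)

    def stage_seed(self, stage: str) -> int:
        """Per-stage seed derived from the global seed (documented fan-out)."""
        return (self.seed * 2654435761 + zlib.crc32(stage.encode())) % (2**31)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


_SECTION_TYPES = {
    "loss": LossSection,
    "train": TrainSection,
    "spec_train": SpecTrainSection,
    "impute": ImputeSection,
    "consensus": ConsensusSection,
    "evaluate": EvaluateSection,
    "simulate": SimulateSection,
}


def _build(cls, data: Mapping[str, Any], path: str):
    kwargs = {}
    fields = {f.name: f for f in cls.__dataclass_fields__.values()}  # type: ignore[attr-defined]
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown config key {path + key!r}")
        kwargs[key] = value
    return cls(**kwargs)


def config_from_dict(data: Mapping[str, Any]) -> RunConfig:
    """Validate a nested mapping into a RunConfig; unknown keys are rejected."""
    data = copy.deepcopy(dict(data))
    cfg = RunConfig()
    for key, value in data.items():
        if key in _SECTION_TYPES:
            setattr(cfg, key, _build(_SECTION_TYPES[key], value, f"{key}."))
        elif key == "modalities":
            mods = {}
            for mod, mcfg in value.items():
                mc = ModalityConfig()
                for mkey, mval in mcfg.items():
                    if mkey == "reduction":
                        mc.reduction = _build(ReductionConfig, mval, f"modalities.{mod}.reduction.")
                    elif mkey == "correction":
                        mc.correction = _build(CorrectionConfig, mval, f"modalities.{mod}.correction.")
                    elif mkey == "layer_dims":
                        mc.layer_dims = list(mval)
                    else:
                        raise ConfigError(f"unknown config key 'modalities.{mod}.{mkey}'")
                mods[mod] = mc
            cfg.modalities = mods
        elif key in {"seed", "input_dir"}:
            setattr(cfg, key, value)
        else:
            raise ConfigError(f"unknown config key {key!r}")
    return cfg


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def dump_config(cfg: RunConfig, path=None) -> str:
    text = yaml.safe_dump(asdict(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
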