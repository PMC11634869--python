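"""Run configuration: one YAML file drives the whole pipeline.

All numeric pipeline math is float64.  Every stochastic stage derives its
seed from the single global seed, so a config file plus seed fully
determines a run.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import yaml

from .embedding import AugmentationConfig, EncoderConfig
from .synthetic import SyntheticSpec
from .transfer import MMDConfig

__all__ = ["MatchingConfig", "RunConfig"]


@dataclass
class MatchingConfig:
    m_target: int = 1600
    neighbor_radius: float = 0.2
    separation: float = 0.2
    restarts: int = 1000
    metric: str = "cosine"
    centering: str = "double"
    max_iter: int = 100


@dataclass
class RunConfig:
    encoder_a: EncoderConfig = field(default_factory=EncoderConfig)
    encoder_b: EncoderConfig = field(default_factory=EncoderConfig)
    augment_a: AugmentationConfig = field(default_factory=AugmentationConfig)
    augment_b: AugmentationConfig = field(default_factory=AugmentationConfig)
    matching: MatchingConfig = field(default_factory=MatchingConfig)
    mmd: MMDConfig = field(default_factory=MMDConfig)
    synthetic: SyntheticSpec | None = None
    finetune: bool = True
    grid_tau: list | None = None
    grid_gain: list | None = None
    seed: int = 0
    out_dir: str | None = None

    def to_dict(self) -> dict:
        d = {
            "encoder_a": self.encoder_a.to_dict(),
            "encoder_b": self.encoder_b.to_dict(),
            "augment_a": asdict(self.augment_a),
            "augment_b": asdict(self.augment_b),
            "matching": asdict(self.matching),
            "mmd": self.mmd.to_dict(),
            "synthetic": None if self.synthetic is None else {
                **asdict(self.synthetic),
                "obs_dims": list(self.synthetic.obs_dims)},
            "finetune": self.finetune,
            "grid_tau": self.grid_tau,
            "grid_gain": self.grid_gain,
            "seed": self.seed,
            "out_dir": self.out_dir,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        syn = d.get("synthetic")
        if syn is not None:
            syn = SyntheticSpec(**{**syn, "obs_dims": tuple(syn["obs_dims"])})
        return cls(
            encoder_a=EncoderConfig(**d.get("encoder_a", {})),
            encoder_b=EncoderConfig(**d.get("encoder_b", {})),
            augment_a=AugmentationConfig(**d.get("augment_a", {})),
            augment_b=AugmentationConfig(**d.get("augment_b", {})),
            matching=MatchingConfig(**d.get("matching", {})),
            mmd=MMDConfig(**d.get("mmd", {})),
            synthetic=syn,
            finetune=d.get("finetune", True),
            grid_tau=d.get("grid_tau"),
            grid_gain=d.get("grid_gain"),
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir"),
        )

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text))
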