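"""Run configuration: a validated, hashable bundle of stage parameters.

Unknown keys are rejected so typos fail loudly, and every analysis
output embeds a provenance block (config hash + package version) so any
table on disk can be regenerated from config + seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    experiment: str = "both"            # forward | backward | both
    n_participants: int = 8
    n_trials: int = 400
    seed: int = 0

    # simulation overrides (SimParams field name -> value)
    sim: dict = field(default_factory=dict)
    inject_default_effects: bool = True

    # preprocessing
    filter_low: float = 0.1
    filter_high: float = 30.0
    ica_threshold: float = 0.5
    reject_budget_uv: float = 200.0
    epoch_tmin: float = -0.1
    epoch_tmax: float = 1.0
    baseline: tuple = (-0.060, 0.040)

    # behaviour
    sided: str = "one"
    alpha: float = 0.05

    # erp
    erp_summary: str = "median"

    # classifier
    run_classifier: bool = False
    net_epochs: int = 80
    net_batch_size: int = 32
    search_draws: int = 0
    cv_seeds: tuple = (11, 22, 33)

    # questionnaires
    latent_coupling: float = 0.0

    out_dir: str = None

    def __post_init__(self):
        if self.experiment not in ("forward", "backward", "both"):
            raise ValueError(f"experiment must be forward/backward/both, got {self.experiment!r}")
        if self.sided not in ("one", "two"):
            raise ValueError("sided must be 'one' or 'two'")

    @property
    def experiments(self) -> list:
        return ["forward", "backward"] if self.experiment == "both" else [self.experiment]

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["baseline"] = list(self.baseline)
        d["cv_seeds"] = list(self.cv_seeds)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]

    def provenance(self) -> dict:
        from . import __version__
        return {"config_hash": self.config_hash(), "package_version": __version__,
                "seed": self.seed}

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for k in ("baseline", "cv_seeds"):
            if k in d and isinstance(d[k], list):
                d[k] = tuple(d[k])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
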