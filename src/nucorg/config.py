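"""Run configuration: one serializable object that fixes every analysis knob."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError


@dataclass
class RunConfig:
    """All tunable parameters of a pipeline run.

    Round-trips unchanged through YAML so a report's manifest fully
    reproduces the run.
    """

    index_mode: str = "volume"          # "volume" (rho^3) or "linear" (rho)
    n_shells: int = 10_000
    window_mbp: float = 1.0             # K_mean window when no per-gene value
    per_gene_window_mbp: dict[str, float] = field(default_factory=dict)
    fc_threshold: float = 2.0
    alpha_de: float = 0.01
    alpha_spatial: float = 0.05
    mobility_threshold_mbp: float = 50.0
    feret_source: str = "model"         # "model" (2a) or "mask"
    pairing: str = "nearest"            # gene-centromere pairing within a nucleus
    include_goi_in_neighborhood: bool = False
    bh_across_loci: bool = False
    rho_tolerance: float = 0.05
    seed: int = 0
    input_dir: str = "."
    output_dir: str = "results"

    def __post_init__(self) -> None:
        if self.index_mode not in ("volume", "linear"):
            raise ConfigError(f"index_mode must be 'volume' or 'linear', got {self.index_mode!r}")
        if self.feret_source not in ("model", "mask"):
            raise ConfigError(f"feret_source must be 'model' or 'mask', got {self.feret_source!r}")
        if self.pairing not in ("nearest", "all"):
            raise ConfigError(f"pairing must be 'nearest' or 'all', got {self.pairing!r}")
        for name in ("n_shells", "window_mbp", "fc_threshold", "alpha_de",
                     "alpha_spatial", "mobility_threshold_mbp", "rho_tolerance"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at top level")
        known = cls.__dataclass_fields__.keys()
        unknown = set(data) - set(known)
        if unknown:
            raise ConfigError(f"{path}: unknown config keys: {sorted(unknown)}")
        return cls(**data)
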