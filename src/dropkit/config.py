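"""Run configuration (YAML-backed) for the correction pipeline."""

from __future__ import annotations

from dataclasses import asdict, dataclass
from pathlib import Path

import yaml

UMI_METHODS = ("none", "cluster", "cluster-neq", "directional", "bayesian")
ADJUSTMENTS = ("none", "uniform", "empirical")
CB_METHODS = ("none", "simple", "poisson", "known")


@dataclass
class RunConfig:
    """All pipeline knobs; enumerations are validated on construction and
    the seed is echoed into every output."""

    umi_method: str = "bayesian"
    collision_adjustment: str = "empirical"
    cb_method: str = "poisson"
    cb_whitelist: str | None = None
    cb_max_hamming: int = 2
    merge_alpha: float = 0.01
    umi_k_quantiles: int = 15
    umi_dp_step: float = 0.01
    umi_max_iterations: int = 10
    directional_ratio: float = 2.0
    quality_enabled: bool = True
    quality_keep_hi: float = 0.9
    quality_drop_lo: float = 0.1
    quality_min_genes: int = 0
    mito_genes: str | None = None
    manual_thresholds: tuple[float, float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.umi_method not in UMI_METHODS:
            raise ValueError(f"umi_method must be one of {UMI_METHODS}")
        if self.collision_adjustment not in ADJUSTMENTS:
            raise ValueError(f"collision_adjustment must be one of {ADJUSTMENTS}")
        if self.cb_method not in CB_METHODS:
            raise ValueError(f"cb_method must be one of {CB_METHODS}")
        if self.cb_method == "known" and not self.cb_whitelist:
            raise ValueError("cb_method 'known' requires a whitelist path")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        if isinstance(raw.get("manual_thresholds"), list):
            raw["manual_thresholds"] = tuple(raw["manual_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = asdict(self)
        if d["manual_thresholds"] is not None:
            d["manual_thresholds"] = list(d["manual_thresholds"])
        return d
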