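"""Pipeline configuration: defaults, YAML round-trip, provenance hash."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass
from importlib import resources
from pathlib import Path

import yaml

from .mcg_params import ScoreThresholds

__all__ = ["PipelineConfig", "load_config", "default_score_thresholds"]


def default_score_thresholds() -> ScoreThresholds:
    """Healthy-reference (mean, sd) constants shipped with the package.

    Derived once from a healthy synthetic calibration cohort; callers can
    substitute their own calibration set.
    """
    text = resources.files("cardiomag.data").joinpath("score_reference.yaml").read_text()
    raw = yaml.safe_load(text)
    return ScoreThresholds(**{k: tuple(v) for k, v in raw.items()})


@dataclass(frozen=True)
class PipelineConfig:
    """Every tunable of the extraction + classification pipeline."""

    filter_low_hz: float = 0.3
    filter_high_hz: float = 100.0
    filter_order: int = 4
    isoline_fraction: float = 0.05
    monopolarity_variant: str = "normalized_sum"
    flux_operator: str = "product"          # product | convolution
    dipole_depth_m: float = 0.06
    dipole_positions: int = 5               # coarse search grid per axis
    map_upsample: int = 4
    lda_max_features: int = 3
    lda_entry_p: float = 0.05
    loocv_reselect: bool = False
    bh_q: float = 0.05
    auc_bootstrap_seed: int = 20250825

    def __post_init__(self):
        if not 0 < self.filter_low_hz < self.filter_high_hz:
            raise ValueError("invalid filter band")
        if self.monopolarity_variant not in ("normalized_sum", "mean_square"):
            raise ValueError("unknown monopolarity variant")
        if self.flux_operator not in ("product", "convolution"):
            raise ValueError("unknown flux operator")

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))


def load_config(path: str | Path | None = None, **overrides) -> PipelineConfig:
    """Config from YAML (optional) with keyword overrides taking precedence."""
    base = {}
    if path is not None:
        base = yaml.safe_load(Path(path).read_text()) or {}
    base.update(overrides)
    return PipelineConfig(**base)
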