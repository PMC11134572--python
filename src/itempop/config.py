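"""Pipeline configuration: defaults, YAML loading, validation.

The defaults encode the analysis constants: binding-hit Z cutoffs 1.64
("hit") and 1.28 ("likely"), the >1% carrier-frequency panel filter, the >5%
joint-probability and difference cutoffs for differential pairs, 100
frequency resamples, and the 0.05 significance level.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml

from .stats import ADJUSTMENT_METHODS, EFFECT_SIZE_SCHEMES


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    matrix_dir: str | None = None
    proteins: str | None = None
    registry: str | None = None
    frequencies: str | None = None  # aggregated table CSV
    studies: str | None = None  # per-study CSV (aggregated if given)
    background: str | None = None  # None = uniform
    hit_threshold: float = 1.64
    likely_threshold: float = 1.28
    panel_min_freq: float = 0.01
    jp_min: float = 0.05
    diff_min: float = 0.05
    n_resamples: int = 100
    seed: int = 0
    alpha: float = 0.05
    adjust_methods: list[str] = field(
        default_factory=lambda: list(ADJUSTMENT_METHODS)
    )
    effect_schemes: list[str] = field(default_factory=lambda: ["cohen", "funder_ozer"])
    out_dir: str = "itempop_out"

    def __post_init__(self) -> None:
        if not self.likely_threshold < self.hit_threshold:
            raise ConfigError("likely threshold must be below hit threshold")
        for name, lo, hi in [
            ("panel_min_freq", 0.0, 1.0),
            ("jp_min", 0.0, 1.0),
            ("diff_min", 0.0, 1.0),
            ("alpha", 0.0, 1.0),
        ]:
            v = getattr(self, name)
            if not lo < v < hi:
                raise ConfigError(f"{name}={v} outside ({lo}, {hi})")
        if self.n_resamples < 1:
            raise ConfigError("n_resamples must be >= 1")
        unknown = [m for m in self.adjust_methods if m not in ADJUSTMENT_METHODS]
        if unknown:
            raise ConfigError(f"unknown adjustment methods: {unknown}")
        unknown = [s for s in self.effect_schemes if s not in EFFECT_SIZE_SCHEMES]
        if unknown:
            raise ConfigError(f"unknown effect-size schemes: {unknown}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = [k for k in data if k not in known]
        if bad:
            raise ConfigError(f"unknown config keys: {bad}")
        return cls(**data)

    def to_dict(self) -> dict:
        return asdict(self)
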