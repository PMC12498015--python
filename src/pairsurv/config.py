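"""Pipeline configuration: thresholds, paths, validation."""
from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "ConfigError"]


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Everything the end-to-end run needs, with validated thresholds."""

    expression: str | None = None
    clinical: str | None = None
    classes: str | None = None
    gmt: str | None = None
    out_dir: str = "pairsurv_out"
    seed: int = 0
    # gene screen
    de_alpha: float = 0.001
    surv_alpha: float = 0.05
    hr_low: float = 0.8
    hr_high: float = 1.2
    cutoffs: list[str] = field(default_factory=lambda: ["median", "quartile"])
    force_include: list[str] = field(default_factory=list)
    # pair screen
    horizon_days: float = 1825.0
    min_cell_n: int = 5
    hr_diff_threshold: float = 0.10
    hr_diff_mode: str = "relative"
    trend_tol: float = 0.0
    # enrichment / overlap
    r_threshold: float = 0.3
    same_sign: bool = False
    min_set: int = 10
    fdr_cut: float = 0.05
    top_sets: int = 10
    min_pairs: int = 3

    def __post_init__(self):
        checks = [
            (0 < self.de_alpha < 1, "de_alpha must be in (0, 1)"),
            (0 < self.surv_alpha < 1, "surv_alpha must be in (0, 1)"),
            (0 < self.hr_low < 1 < self.hr_high,
             "require 0 < hr_low < 1 < hr_high"),
            (self.horizon_days > 0, "horizon_days must be > 0"),
            (self.min_cell_n >= 1, "min_cell_n must be >= 1"),
            (self.hr_diff_threshold >= 0, "hr_diff_threshold must be >= 0"),
            (self.hr_diff_mode in ("relative", "absolute"),
             "hr_diff_mode must be 'relative' or 'absolute'"),
            (self.trend_tol >= 0, "trend_tol must be >= 0"),
            (0 < self.r_threshold < 1, "r_threshold must be in (0, 1)"),
            (self.min_set >= 1, "min_set must be >= 1"),
            (0 < self.fdr_cut < 1, "fdr_cut must be in (0, 1)"),
            (self.top_sets >= 1, "top_sets must be >= 1"),
            (self.min_pairs >= 1, "min_pairs must be >= 1"),
        ]
        for ok, message in checks:
            if not ok:
                raise ConfigError(message)
        unknown = set(self.cutoffs) - {"median", "quartile"}
        if unknown:
            raise ConfigError(f"unknown cutoffs: {sorted(unknown)}")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(data)

    def thresholds(self) -> dict:
        """All applied thresholds, for audit logging."""
        skip = {"expression", "clinical", "classes", "gmt", "out_dir"}
        return {f.name: getattr(self, f.name) for f in fields(self)
                if f.name not in skip}
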