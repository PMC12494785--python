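"""Pipeline configuration: every tunable threshold in one place."""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import yaml

from .exceptions import ConfigurationError


@dataclass
class PipelineConfig:
    """Thresholds and paths for one end-to-end pipeline run.

    ``cutoff=None`` means the prognostic mGE threshold is discovered by
    maximally selected rank statistics on the palliative patients; a fixed
    positive value skips discovery.
    """

    input_dir: str = "."
    output_dir: str = "out"
    tissue_vaf: float = 0.03
    germline_vaf: float = 0.25
    gnomad_max: float = 0.03
    min_consensus_reads: int = 5
    rescue_min_reads: int = 1
    normal_override_vaf: float = 0.05
    normal_override_max_normal_vaf: float = 0.002
    amplified_cn_threshold: int = 5
    minprop: float = 0.1
    cutoff: Optional[float] = None
    band: float = 25.0
    min_frac_concordance: float = 0.02
    detect_floor: float = 0.02
    death_window_months: float = 3.0
    seed: int = 0
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        for name in ("tissue_vaf", "germline_vaf", "gnomad_max", "normal_override_vaf",
                     "normal_override_max_normal_vaf", "minprop",
                     "min_frac_concordance", "detect_floor"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v}")
        for name in ("min_consensus_reads", "rescue_min_reads", "amplified_cn_threshold"):
            v = getattr(self, name)
            if v < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {v}")
        if self.cutoff is not None and self.cutoff <= 0:
            raise ConfigurationError(f"cutoff must be positive or None (discover), "
                                     f"got {self.cutoff}")
        if self.band < 0:
            raise ConfigurationError(f"band must be >= 0, got {self.band}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__ if f != "extra"}
        kwargs = {k: v for k, v in raw.items() if k in known}
        extra = {k: v for k, v in raw.items() if k not in known}
        cfg = cls(**kwargs, extra=extra)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        return asdict(self)
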