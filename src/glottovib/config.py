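"""Pipeline configuration: one YAML file, strict keys, documented defaults."""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml

from .errors import ConfigError

__all__ = ["PipelineConfig", "load_config"]


@dataclass
class PipelineConfig:
    """All tunable pipeline settings with their defaults.

    ``opening_eps_frac`` is the openness threshold as a fraction of the
    recording's maximum gap width; ``middle_third`` bounds the positions
    counted as the glottal middle third; ``alpha`` is the significance
    level used for normality routing and omnibus/post hoc decisions.
    """

    fps: float = 3200.0
    n_frames: int = 2000
    n_positions: int = 64
    opening_eps_frac: float = 0.05
    middle_third: tuple[float, float] = (1.0 / 3.0, 2.0 / 3.0)
    confidence_threshold: float = 0.3
    alpha: float = 0.05
    roc_variants: tuple[str, ...] = ("norm_vs_lesion", "benign_vs_malignant")
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must lie in (0, 1)")
        if not 0 < self.opening_eps_frac < 1:
            raise ConfigError("opening_eps_frac must lie in (0, 1)")
        if self.fps <= 0 or self.n_frames < 2 or self.n_positions < 8:
            raise ConfigError("invalid recording geometry")
        lo, hi = self.middle_third
        if not 0 <= lo < hi <= 1:
            raise ConfigError("middle_third bounds must satisfy 0 <= lo < hi <= 1")

    def digest(self) -> str:
        """Short stable hash of the configuration, for run logging."""
        payload = json.dumps(asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path) -> PipelineConfig:
    """Load a YAML config, rejecting unknown keys."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    known = {f.name for f in fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    if "middle_third" in raw:
        raw["middle_third"] = tuple(raw["middle_third"])
    if "roc_variants" in raw:
        raw["roc_variants"] = tuple(raw["roc_variants"])
    try:
        return PipelineConfig(**raw)
    except TypeError as exc:  # wrong value type
        raise ConfigError(str(exc)) from exc
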