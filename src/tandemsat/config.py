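"""Pipeline configuration: defaults, validation, and a flat key=value format.

Defaults equal the published analysis parameters: similarity cutoff 90% over
55% of the longer read, k = 17, minimal seed k-mer frequency 1e-4, extension
threshold 10%, stretch factor 3.0 kb/um, genome size 840 Mb.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

from .errors import ConfigError


@dataclass
class PipelineConfig:
    k: int = 17
    identity_cutoff_pct: float = 90.0
    coverage_cutoff_frac: float = 0.55
    seed_min_freq: float = 0.0001
    extension_threshold: float = 0.10
    stretch_kb_per_um: float = 3.0
    genome_size_mb: float = 840.0
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 11 <= self.k <= 31:
            raise ConfigError("k must be within [11, 31]")
        if not 0 < self.identity_cutoff_pct <= 100:
            raise ConfigError("identity_cutoff_pct must be in (0, 100]")
        if not 0 < self.coverage_cutoff_frac <= 1:
            raise ConfigError("coverage_cutoff_frac must be in (0, 1]")
        if not 0 < self.seed_min_freq < 1:
            raise ConfigError("seed_min_freq must be in (0, 1)")
        if not 0 < self.extension_threshold < 1:
            raise ConfigError("extension_threshold must be in (0, 1)")
        if self.stretch_kb_per_um <= 0:
            raise ConfigError("stretch_kb_per_um must be > 0")
        if self.genome_size_mb <= 0:
            raise ConfigError("genome_size_mb must be > 0")


_FLOAT_FIELDS = {
    "identity_cutoff_pct",
    "coverage_cutoff_frac",
    "seed_min_freq",
    "extension_threshold",
    "stretch_kb_per_um",
    "genome_size_mb",
}
_INT_FIELDS = {"k", "seed"}


def load_config(path: str | Path) -> PipelineConfig:
    """Read a flat ``key = value`` text file ('#' starts a comment)."""
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"{path}: no such config file")
    known = {f.name for f in fields(PipelineConfig)}
    kwargs: dict = {}
    paths: dict = {}
    for lineno, line in enumerate(path.read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ConfigError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        if key in _INT_FIELDS:
            kwargs[key] = int(value)
        elif key in _FLOAT_FIELDS:
            kwargs[key] = float(value)
        elif key in known:
            kwargs[key] = value
        else:
            paths[key] = value
    return PipelineConfig(paths=paths, **kwargs)
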