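"""Run configuration: defaults for every threshold, loadable from YAML/JSON.

Unknown keys are rejected at load time so typos fail loudly instead of
silently falling back to defaults. CLI flags override file values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

from .balance import DEFAULT_VMAX_UL, DEFAULT_VMIN_UL
from .covprofile import DEFAULT_MIN_REGION_BINS, DEFAULT_REL_THRESHOLD
from .errors import ConfigurationError
from .libqc import (
    DEFAULT_ADAPTER_TOTAL_BP,
    DEFAULT_CONTAMINATION_THRESHOLD,
    DEFAULT_MAX_BASE_SKEW,
    DEFAULT_MAX_DUPLICATION,
    DEFAULT_RNA_DNA_OFFSET_NT,
)
from .platform import DEFAULT_GENOME_SIZE_BP

__all__ = ["RunConfig"]


@dataclass(frozen=True)
class RunConfig:
    """All tunables in one place; defaults match the module-level constants."""

    genome_size_bp: float = DEFAULT_GENOME_SIZE_BP
    contamination_threshold: float = DEFAULT_CONTAMINATION_THRESHOLD
    max_duplication: float = DEFAULT_MAX_DUPLICATION
    max_base_skew: float = DEFAULT_MAX_BASE_SKEW
    rna_dna_offset_nt: float = DEFAULT_RNA_DNA_OFFSET_NT
    adapter_total_bp: float = DEFAULT_ADAPTER_TOTAL_BP
    rel_threshold: float = DEFAULT_REL_THRESHOLD
    min_region_bins: int = DEFAULT_MIN_REGION_BINS
    remaining_runs: int = 2
    per_run_reads: float = 1e7
    vmax: float = DEFAULT_VMAX_UL
    vmin: float = DEFAULT_VMIN_UL
    seed: int = 42

    def __post_init__(self) -> None:
        if not 0 < self.contamination_threshold <= 1:
            raise ConfigurationError("contamination_threshold must be in (0, 1]")
        if self.genome_size_bp <= 0:
            raise ConfigurationError("genome_size_bp must be > 0")
        if not self.vmax > self.vmin >= 0:
            raise ConfigurationError("need vmax > vmin >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Load from YAML or JSON; unknown keys are an error."""
        text = Path(path).read_text()
        data = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a mapping at top level")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**data)

    def asdict(self) -> dict:
        return dataclasses.asdict(self)

    def override(self, **kwargs) -> "RunConfig":
        """New config with the given non-None overrides applied."""
        updates = {k: v for k, v in kwargs.items() if v is not None}
        return dataclasses.replace(self, **updates)
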