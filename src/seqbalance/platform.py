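"""Sequencing-platform specifications and deterministic planning arithmetic.

The planning model is the standard one for short-read instruments: a reagent
kit carries a fixed cycle budget, each sequenced base (read or index) consumes
one cycle, and the per-flow-cell yield is ``clusters x read_length x 2`` for
paired-end runs. Expected coverage follows the Lander-Waterman identity
``coverage = yield / genome_size``.

Units: lengths in bases (bp), yields in bp, genome size in bp. One Gb is
decimal (1e9 bp) throughout; platform yield labels such as "97Gb" are
reproduced by rounding the decimal-Gb yield to the nearest integer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources

from .errors import InvalidBudgetError, InvalidParameterError

__all__ = [
    "CycleBudget",
    "PlatformSpec",
    "CoveragePlan",
    "max_symmetric_read_length",
    "run_yield_bp",
    "expected_coverage",
    "flowcells_needed",
    "load_platform_presets",
    "get_preset",
]

#: Default human genome size for coverage arithmetic, in bp. A 90 Gb run at
#: 3.0e9 bp computes to exactly 30x, matching how coverage targets are quoted.
DEFAULT_GENOME_SIZE_BP = 3.0e9


@dataclass(frozen=True)
class CycleBudget:
    """Chemistry cycles available in a reagent kit and how they are spent.

    ``kit_nominal_cycles`` is the marketing label (e.g. a "300-cycle" kit);
    ``actual_cycles`` is what the kit really contains (kits ship spare cycles
    to cover index reads: a HiSeq 300-cycle SBS kit holds 325 cycles, a
    NovaSeq 300-cycle kit 338).
    """

    kit_nominal_cycles: int
    actual_cycles: int
    index1_cycles: int = 0
    index2_cycles: int = 0

    def __post_init__(self) -> None:
        if self.kit_nominal_cycles < 0 or self.actual_cycles < self.kit_nominal_cycles:
            raise InvalidBudgetError(
                f"need actual_cycles >= kit_nominal_cycles >= 0, got "
                f"{self.actual_cycles} < {self.kit_nominal_cycles}"
            )
        if self.index1_cycles < 0 or self.index2_cycles < 0:
            raise InvalidBudgetError("index cycles must be >= 0")
        if self.index1_cycles + self.index2_cycles > self.actual_cycles:
            raise InvalidBudgetError(
                f"index cycles ({self.index1_cycles}+{self.index2_cycles}) "
                f"exceed actual cycles ({self.actual_cycles})"
            )

    @property
    def read_cycles(self) -> int:
        """Cycles left for Read 1 + Read 2 after index reads."""
        return self.actual_cycles - self.index1_cycles - self.index2_cycles


@dataclass(frozen=True)
class PlatformSpec:
    """One sequencing platform/protocol row: flow-cell capacity and read geometry."""

    name: str
    clusters_per_flowcell: float
    flowcells_per_run: int
    read_length_bp: int
    paired: bool = True
    yield_label: str = ""
    mode: str = ""

    def __post_init__(self) -> None:
        if self.clusters_per_flowcell <= 0:
            raise InvalidParameterError("clusters_per_flowcell must be > 0")
        if self.read_length_bp <= 0:
            raise InvalidParameterError("read_length_bp must be > 0")
        if self.flowcells_per_run < 1:
            raise InvalidParameterError("flowcells_per_run must be >= 1")

    @property
    def flowcell_yield_bp(self) -> float:
        return run_yield_bp(self.clusters_per_flowcell, self.read_length_bp, self.paired)


@dataclass(frozen=True)
class CoveragePlan:
    """Coverage demand for a batch of samples."""

    target_coverage: float
    n_samples: int = 1
    genome_size_bp: float = DEFAULT_GENOME_SIZE_BP
    per_sample_yield_bp: float = field(init=False)

    def __post_init__(self) -> None:
        if self.genome_size_bp <= 0:
            raise InvalidParameterError("genome_size_bp must be > 0")
        if self.target_coverage < 0:
            raise InvalidParameterError("target_coverage must be >= 0")
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")
        object.__setattr__(
            self, "per_sample_yield_bp", self.target_coverage * self.genome_size_bp
        )


def max_symmetric_read_length(budget: CycleBudget) -> int:
    """Longest symmetric paired read length a cycle budget supports.

    Splits the cycles left after index reads evenly between Read 1 and
    Read 2: ``floor((actual - index1 - index2) / 2)``. Running one sample per
    flow cell with no index reads frees the index cycles for the reads
    themselves — a 325-cycle kit then supports 162 bp PE; with 8+8 bp dual
    indexes a 338-cycle kit supports 161 bp PE.
    """
    avail = budget.read_cycles
    if avail < 0:  # pragma: no cover - CycleBudget already rejects this
        raise InvalidBudgetError("negative available cycles")
    return avail // 2


def run_yield_bp(clusters: float, read_length: int, paired: bool = True) -> float:
    """Base yield of a flow cell: ``clusters x read_length x (2 if paired)``."""
    if clusters < 0 or read_length < 0:
        raise InvalidParameterError("clusters and read_length must be >= 0")
    return float(clusters) * float(read_length) * (2.0 if paired else 1.0)


def expected_coverage(
    yield_bp: float, genome_size_bp: float = DEFAULT_GENOME_SIZE_BP
) -> float:
    """Mean fold coverage implied by a base yield: ``yield / genome_size``."""
    if genome_size_bp <= 0:
        raise InvalidParameterError("genome_size_bp must be > 0")
    return yield_bp / genome_size_bp


def flowcells_needed(
    plan: CoveragePlan, per_flowcell_yield_bp: float, samples_per_pool: int = 96
) -> int:
    """Flow cells required to hit a coverage plan at a given per-flow-cell yield.

    ``ceil(n_samples x target_coverage x genome_size / per_flowcell_yield)``.
    ``samples_per_pool`` records the pooling scheme (validated >= 1); the
    demand arithmetic depends only on total bases required.
    """
    if per_flowcell_yield_bp <= 0:
        raise InvalidParameterError("per_flowcell_yield_bp must be > 0")
    if samples_per_pool < 1:
        raise InvalidParameterError("samples_per_pool must be >= 1")
    demand = plan.n_samples * plan.per_sample_yield_bp
    return math.ceil(demand / per_flowcell_yield_bp)


def load_platform_presets() -> dict[str, PlatformSpec]:
    """Load the shipped platform preset table (JSON) keyed by preset id."""
    text = resources.files("seqbalance").joinpath("data/platform_presets.json").read_text()
    raw = json.loads(text)
    presets: dict[str, PlatformSpec] = {}
    for entry in raw["presets"]:
        key = entry.pop("id")
        presets[key] = PlatformSpec(**entry)
    return presets


def get_preset(name: str) -> PlatformSpec:
    presets = load_platform_presets()
    try:
        return presets[name]
    except KeyError:
        raise InvalidParameterError(
            f"unknown platform preset {name!r}; available: {sorted(presets)}"
        ) from None
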