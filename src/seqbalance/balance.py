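"""Relative quantification and re-pooling: the core data-equalization math.

A 96-plex pool sequenced in equal volumes returns, through demultiplexing, a
per-sample read count whose share of the run (the *index ratio*) estimates
each library's relative molar concentration. iDeal (initial-run-based data
equalization) exploits this: sequence the equal-volume pool on the first flow
cell(s), infer relative concentrations from the index ratios, then re-pool
with per-sample volumes chosen so that the *cumulative* reads after the
remaining flow cells come out as even as possible.

Given round-1 totals ``t_i``, relative concentrations ``c_i``, and ``K``
remaining runs of ``R`` reads each, the equal final target is
``T = (sum_i t_i + K R) / n``; each sample's deficit ``d_i = max(T - t_i, 0)``
must be produced in proportion to its share of the re-pool, which for
multinomial read allocation is ``c_i v_i / sum_j c_j v_j``. Setting
``v_i ∝ d_i / c_i`` delivers exactly the deficits in the noiseless limit.
Volumes are scaled so the largest equals ``vmax`` (pipetting headroom) and
sub-``vmin`` volumes are raised to ``vmin`` with a flag. Samples whose
deficit is already met are left out of the re-pool, and libraries that failed
round 1 (zero reads) are excluded for a fresh pool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import EmptyPlanError, InvalidInputError, InvalidParameterError

__all__ = [
    "DemuxEntry",
    "DemuxCounts",
    "RelativeConcentrations",
    "PlanEntry",
    "RebalancePlan",
    "SpreadMetrics",
    "relative_concentration",
    "rebalance_volumes",
    "cumulative_totals",
    "spread_metrics",
    "DEFAULT_VMAX_UL",
    "DEFAULT_VMIN_UL",
]

DEFAULT_VMAX_UL = 30.0
DEFAULT_VMIN_UL = 1.0

EXCLUDE_DEFICIT_MET = "deficit-met"
EXCLUDE_FAILED_LIBRARY = "failed-library"
FLAG_BELOW_PIPETTABLE = "below-pipettable"


@dataclass(frozen=True)
class DemuxEntry:
    """One sample's demultiplexed read count and the volume it was pooled at."""

    sample_id: str
    reads: float
    pooled_volume: float = 1.0  # uL

    def __post_init__(self) -> None:
        if self.reads < 0:
            raise InvalidInputError(f"{self.sample_id}: reads must be >= 0")
        if self.pooled_volume <= 0:
            raise InvalidInputError(f"{self.sample_id}: pooled_volume must be > 0")


@dataclass(frozen=True)
class DemuxCounts:
    """Demultiplexing stats for one run: per-sample reads plus pooling volumes."""

    run_id: str
    entries: tuple[DemuxEntry, ...]

    def __post_init__(self) -> None:
        if len(self.entries) < 2:
            raise InvalidInputError("a demultiplexed run needs >= 2 samples")
        ids = [e.sample_id for e in self.entries]
        if len(set(ids)) != len(ids):
            raise InvalidInputError(f"duplicate sample ids in run {self.run_id!r}")

    @property
    def total_reads(self) -> float:
        return float(sum(e.reads for e in self.entries))

    @property
    def sample_ids(self) -> list[str]:
        return [e.sample_id for e in self.entries]

    def reads_by_sample(self) -> dict[str, float]:
        return {e.sample_id: float(e.reads) for e in self.entries}

    @classmethod
    def from_reads(
        cls,
        run_id: str,
        reads: dict[str, float],
        volumes: dict[str, float] | float = 1.0,
    ) -> "DemuxCounts":
        """Build from a mapping of sample id -> reads; volumes scalar or per-sample."""
        entries = []
        for sid, r in reads.items():
            v = volumes if isinstance(volumes, (int, float)) else volumes[sid]
            entries.append(DemuxEntry(sid, float(r), float(v)))
        return cls(run_id, tuple(entries))


@dataclass(frozen=True)
class RelativeConcentrations:
    """Per-sample relative concentrations, normalized to mean 1 over usable samples.

    ``failed`` lists samples with zero reads in the source run; they carry no
    concentration estimate and are excluded from the normalization.
    """

    values: dict[str, float]
    failed: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        usable = [v for k, v in self.values.items() if k not in self.failed]
        if not usable:
            raise InvalidInputError("no usable samples with positive concentration")
        if any(v <= 0 for v in usable):
            raise InvalidInputError("relative concentrations must be > 0")

    def __getitem__(self, sample_id: str) -> float:
        return self.values[sample_id]


@dataclass(frozen=True)
class PlanEntry:
    sample_id: str
    volume: float  # uL; 0 for excluded samples
    excluded: bool = False
    reason: str = ""  # deficit-met | failed-library
    flags: frozenset[str] = frozenset()
    expected_final_reads: float = 0.0


@dataclass(frozen=True)
class RebalancePlan:
    """Re-pooling volumes for the remaining runs, with exclusions and projections."""

    entries: tuple[PlanEntry, ...]
    target_reads: float
    remaining_runs: int
    per_run_reads: float

    @property
    def volumes(self) -> dict[str, float]:
        return {e.sample_id: e.volume for e in self.entries}

    @property
    def excluded(self) -> dict[str, str]:
        return {e.sample_id: e.reason for e in self.entries if e.excluded}

    @property
    def planned(self) -> tuple[PlanEntry, ...]:
        return tuple(e for e in self.entries if not e.excluded)


@dataclass(frozen=True)
class SpreadMetrics:
    """Dispersion of per-sample totals: max/min ratio, max % deviation, CV %."""

    maxmin_ratio: float
    max_rel_dev: float  # percent of mean
    cv: float  # percent, population sd / mean

    def __post_init__(self) -> None:
        if self.maxmin_ratio < 1 or self.max_rel_dev < 0 or self.cv < 0:
            raise InvalidInputError("spread metrics out of range")


def relative_concentration(counts: DemuxCounts) -> RelativeConcentrations:
    """Relative library concentrations from one equal- or known-volume run.

    The per-sample read *rate* ``reads_i / volume_i`` is proportional to
    concentration; rates are normalized to mean 1 over samples with nonzero
    reads. With equal pooling volumes this reduces to ``reads_i /
    mean(reads)``. Zero-read samples are flagged as failed libraries.
    """
    if counts.total_reads <= 0:
        raise InvalidInputError(f"run {counts.run_id!r} has no reads")
    failed = frozenset(e.sample_id for e in counts.entries if e.reads == 0)
    rates = {
        e.sample_id: e.reads / e.pooled_volume
        for e in counts.entries
        if e.sample_id not in failed
    }
    mean_rate = sum(rates.values()) / len(rates)
    values = {sid: rate / mean_rate for sid, rate in rates.items()}
    return RelativeConcentrations(values=values, failed=failed)


def rebalance_volumes(
    round1: DemuxCounts,
    conc: RelativeConcentrations | None = None,
    *,
    remaining_runs: int,
    per_run_reads: float,
    vmax: float = DEFAULT_VMAX_UL,
    vmin: float = DEFAULT_VMIN_UL,
) -> RebalancePlan:
    """Re-pooling volumes that equalize cumulative per-sample reads.

    Parameters
    ----------
    round1
        Demux stats of the initial run(s) (summed if several), giving current
        totals ``t_i``.
    conc
        Relative concentrations; derived from ``round1`` when omitted.
    remaining_runs, per_run_reads
        ``K`` runs of ``R`` reads each still to be sequenced.
    vmax, vmin
        Pipetting bounds in uL. The largest raw volume is anchored at
        ``vmax``; anything scaling below ``vmin`` is raised to ``vmin`` and
        flagged ``below-pipettable``.

    Returns a plan whose ``expected_final_reads`` are computed under the
    noiseless multinomial model ``t_i + K R (c_i v_i / sum_j c_j v_j)``; when
    neither the deficit clamp nor the ``vmin`` floor triggers these all equal
    the target ``T`` exactly.
    """
    if remaining_runs < 1:
        raise InvalidParameterError("remaining_runs must be >= 1")
    if per_run_reads <= 0:
        raise InvalidParameterError("per_run_reads must be > 0")
    if not (vmax > vmin >= 0):
        raise InvalidParameterError("need vmax > vmin >= 0")
    if conc is None:
        conc = relative_concentration(round1)

    totals = round1.reads_by_sample()
    n = len(totals)
    target = (sum(totals.values()) + remaining_runs * per_run_reads) / n

    excluded: dict[str, str] = {}
    raw: dict[str, float] = {}
    for sid, t in totals.items():
        if sid in conc.failed or conc.values.get(sid, 0.0) <= 0:
            excluded[sid] = EXCLUDE_FAILED_LIBRARY
            continue
        deficit = max(target - t, 0.0)
        if deficit == 0.0:
            excluded[sid] = EXCLUDE_DEFICIT_MET
            continue
        raw[sid] = deficit / conc[sid]

    if not raw:
        raise EmptyPlanError("every sample excluded; nothing to re-pool")

    scale = vmax / max(raw.values())
    volumes: dict[str, float] = {}
    flags: dict[str, frozenset[str]] = {}
    for sid, u in raw.items():
        v = u * scale
        if v < vmin:
            volumes[sid] = vmin
            flags[sid] = frozenset({FLAG_BELOW_PIPETTABLE})
        else:
            volumes[sid] = v
            flags[sid] = frozenset()

    # Projected finals under multinomial allocation of the remaining reads.
    denom = sum(conc[sid] * v for sid, v in volumes.items())
    expected = {
        sid: totals[sid] + remaining_runs * per_run_reads * conc[sid] * volumes[sid] / denom
        for sid in volumes
    }

    entries = []
    for sid in round1.sample_ids:
        if sid in excluded:
            entries.append(
                PlanEntry(sid, 0.0, excluded=True, reason=excluded[sid],
                          expected_final_reads=totals[sid])
            )
        else:
            entries.append(
                PlanEntry(sid, volumes[sid], flags=flags[sid],
                          expected_final_reads=expected[sid])
            )
    return RebalancePlan(
        entries=tuple(entries),
        target_reads=target,
        remaining_runs=remaining_runs,
        per_run_reads=per_run_reads,
    )


def cumulative_totals(runs: list[DemuxCounts]) -> dict[str, float]:
    """Per-sample read totals summed across runs (union of samples; missing = 0)."""
    totals: dict[str, float] = {}
    for run in runs:
        for e in run.entries:
            totals[e.sample_id] = totals.get(e.sample_id, 0.0) + e.reads
    return totals


def spread_metrics(totals: dict[str, float] | list[float] | np.ndarray) -> SpreadMetrics:
    """Spread of per-sample totals.

    ``maxmin_ratio = max/min``; ``max_rel_dev = 100 max_i |x_i - mean| /
    mean`` (the "% variation" of a rebalanced batch); ``cv`` is the
    population coefficient of variation in percent.
    """
    x = np.asarray(list(totals.values()) if isinstance(totals, dict) else totals, dtype=float)
    if x.size < 2:
        raise InvalidInputError("need >= 2 totals")
    if np.any(x <= 0):
        raise InvalidInputError("all totals must be > 0")
    mean = x.mean()
    return SpreadMetrics(
        maxmin_ratio=float(x.max() / x.min()),
        max_rel_dev=float(100.0 * np.abs(x - mean).max() / mean),
        cv=float(100.0 * x.std() / mean),
    )
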