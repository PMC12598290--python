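"""Seeded synthetic-data generators for every other module.

The simulator emulates the stochastic pipeline behind multiplexed
sequencing: per-library concentration heterogeneity out of library prep
(lognormal), read allocation on a flow cell (multinomial over pooled
concentration x volume, with per-sample multiplicative run noise), and binned
depth tracks with planted low-coverage regions. It exists so the balancing
and profiling code can be exercised end to end at desk scale with known
ground truth; it does not model base errors, duplication, index hopping or
GC bias.

All randomness flows through one :class:`numpy.random.Generator` derived
from the config seed, so a fixed seed gives byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .balance import (
    DEFAULT_VMAX_UL,
    DEFAULT_VMIN_UL,
    DemuxCounts,
    RebalancePlan,
    SpreadMetrics,
    cumulative_totals,
    rebalance_volumes,
    relative_concentration,
    spread_metrics,
)
from .covprofile import DepthTrack
from .errors import ConfigurationError, InvalidParameterError

__all__ = [
    "SimConfig",
    "IdealResult",
    "simulate_concentrations",
    "simulate_run",
    "run_ideal_experiment",
    "simulate_depth_tracks",
]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for a simulated iDeal experiment.

    Defaults mirror a 96-plex pool on three high-output flow cells: one
    equal-volume initial flow cell to read off relative concentrations, two
    re-pooled flow cells to even out the totals. Library concentrations are
    lognormal with sigma 0.2 (spread chosen so an equal-volume pool routinely
    shows a more than twofold read-count range across 96 libraries) and each
    run adds 3% multiplicative lognormal noise per sample. Reads per flow
    cell are scaled to 1e7 for desk-speed work; the balancing arithmetic is
    scale-invariant.
    """

    n_samples: int = 96
    conc_sigma: float = 0.2
    run_noise_cv: float = 0.03
    reads_per_flowcell: int = 10_000_000
    initial_runs: int = 1
    balanced_runs: int = 2
    seed: int = 42
    vmax: float = DEFAULT_VMAX_UL
    vmin: float = DEFAULT_VMIN_UL
    equal_volume: float = 10.0  # uL per sample in the initial pool
    sampling: str = "auto"  # "auto" | "multinomial" | "expected"

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise InvalidParameterError("n_samples must be >= 2")
        if self.conc_sigma < 0 or self.run_noise_cv < 0:
            raise InvalidParameterError("sigma and noise CV must be >= 0")
        if self.reads_per_flowcell <= 0:
            raise InvalidParameterError("reads_per_flowcell must be > 0")
        if self.initial_runs < 1 or self.balanced_runs < 1:
            raise InvalidParameterError("run counts must be >= 1")
        if self.sampling not in ("auto", "multinomial", "expected"):
            raise InvalidParameterError(f"unknown sampling mode {self.sampling!r}")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class IdealResult:
    """Everything a simulated iDeal experiment produced."""

    config: SimConfig
    true_concentrations: np.ndarray
    rounds: tuple[DemuxCounts, ...]
    plan: RebalancePlan
    initial_spread: SpreadMetrics
    final_spread: SpreadMetrics
    final_totals: dict[str, float]


def _lognormal_unit_mean(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    """Lognormal draws with mean exactly 1 and the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma2 = np.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def simulate_concentrations(
    cfg: SimConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """True relative library concentrations, lognormal(0, sigma) scaled to mean 1.

    sigma = 0 degenerates to all-ones.
    """
    rng = cfg.rng() if rng is None else rng
    if cfg.conc_sigma == 0:
        return np.ones(cfg.n_samples)
    c = rng.lognormal(mean=0.0, sigma=cfg.conc_sigma, size=cfg.n_samples)
    return c / c.mean()


def simulate_run(
    conc: np.ndarray,
    volumes: np.ndarray,
    total_reads: int,
    noise_cv: float,
    rng: np.random.Generator,
    run_id: str = "run",
    sample_ids: list[str] | None = None,
    sampling: str = "auto",
) -> DemuxCounts:
    """One multiplexed sequencing run of a pooled library.

    Per-sample allocation probability is ``p_i ∝ conc_i x volume_i x eps_i``
    with ``eps_i`` lognormal (mean 1, CV ``noise_cv``); reads are then drawn
    multinomially so they sum to ``total_reads`` exactly. With ``sampling=
    "expected"`` (or ``"auto"`` when ``noise_cv == 0``) the expected
    real-valued counts ``p_i x total_reads`` are returned instead, which is
    the noiseless limit used by closed-loop exactness checks.

    Samples pooled at volume 0 receive no reads.
    """
    conc = np.asarray(conc, dtype=float)
    volumes = np.asarray(volumes, dtype=float)
    if conc.shape != volumes.shape:
        raise InvalidParameterError("conc and volumes must align")
    if np.any(volumes < 0) or np.any(conc < 0):
        raise InvalidParameterError("conc and volumes must be >= 0")
    weight = conc * volumes
    if weight.sum() <= 0:
        raise InvalidParameterError("all-zero pool: nothing to sequence")
    n = conc.size
    if sample_ids is None:
        sample_ids = [f"S{i+1:03d}" for i in range(n)]

    eps = _lognormal_unit_mean(rng, noise_cv, n)
    p = weight * eps
    p = p / p.sum()
    if sampling == "auto":
        sampling = "expected" if noise_cv == 0 else "multinomial"
    if sampling == "expected":
        reads = p * float(total_reads)
    elif sampling == "multinomial":
        reads = rng.multinomial(int(total_reads), p).astype(float)
    else:
        raise InvalidParameterError(f"unknown sampling mode {sampling!r}")

    # pooled_volume must stay > 0 in DemuxCounts; volume-0 samples are
    # recorded at a nominal volume with their (necessarily zero) reads.
    vols = np.where(volumes > 0, volumes, 1.0)
    return DemuxCounts.from_reads(
        run_id,
        {sid: float(r) for sid, r in zip(sample_ids, reads)},
        {sid: float(v) for sid, v in zip(sample_ids, vols)},
    )


def run_ideal_experiment(cfg: SimConfig) -> IdealResult:
    """End-to-end simulated iDeal experiment.

    1. Draw true concentrations; sequence ``initial_runs`` equal-volume flow
       cells.
    2. Sum the initial runs, estimate relative concentrations from the index
       ratios, and compute re-pooling volumes targeting equal final totals
       over ``balanced_runs`` more flow cells.
    3. Sequence the re-pooled flow cells and report spread metrics before
       (initial totals) and after (cumulative totals) equalization.
    """
    rng = cfg.rng()
    true_conc = simulate_concentrations(cfg, rng)
    sample_ids = [f"S{i+1:03d}" for i in range(cfg.n_samples)]
    equal_vols = np.full(cfg.n_samples, cfg.equal_volume)

    rounds: list[DemuxCounts] = []
    for k in range(cfg.initial_runs):
        rounds.append(
            simulate_run(
                true_conc, equal_vols, cfg.reads_per_flowcell, cfg.run_noise_cv,
                rng, run_id=f"initial-{k+1}", sample_ids=sample_ids,
                sampling=cfg.sampling,
            )
        )

    initial_totals = cumulative_totals(rounds)
    combined = DemuxCounts.from_reads(
        "initial", initial_totals, {sid: cfg.equal_volume for sid in sample_ids}
    )
    conc_hat = relative_concentration(combined)
    plan = rebalance_volumes(
        combined,
        conc_hat,
        remaining_runs=cfg.balanced_runs,
        per_run_reads=cfg.reads_per_flowcell,
        vmax=cfg.vmax,
        vmin=cfg.vmin,
    )

    plan_vols = np.array([plan.volumes[sid] for sid in sample_ids])
    for k in range(cfg.balanced_runs):
        rounds.append(
            simulate_run(
                true_conc, plan_vols, cfg.reads_per_flowcell, cfg.run_noise_cv,
                rng, run_id=f"balanced-{k+1}", sample_ids=sample_ids,
                sampling=cfg.sampling,
            )
        )

    final_totals = cumulative_totals(rounds)
    return IdealResult(
        config=cfg,
        true_concentrations=true_conc,
        rounds=tuple(rounds),
        plan=plan,
        initial_spread=spread_metrics(initial_totals),
        final_spread=spread_metrics(final_totals),
        final_totals=final_totals,
    )


def simulate_depth_tracks(
    n_samples: int,
    n_bins: int,
    mean_depth: float,
    planted_regions: list[tuple[int, int, float]] | None = None,
    depth_noise_cv: float = 0.1,
    seed: int = 0,
    contig: str = "chr22",
    bin_size: int = 100,
) -> list[DepthTrack]:
    """Binned depth tracks with optional planted low-coverage regions.

    ``planted_regions`` is a list of ``(start_bin, end_bin, factor)`` half-open
    bin ranges whose depth is multiplied by ``factor`` (0 for a hard dropout,
    0.1 for a soft one) in every sample. Per-bin noise is multiplicative
    lognormal with the given CV; CV 0 gives exactly ``mean_depth`` outside
    plants.
    """
    if n_samples < 1 or n_bins < 1 or mean_depth < 0:
        raise InvalidParameterError("bad track dimensions")
    base = np.full(n_bins, float(mean_depth))
    occupied = np.zeros(n_bins, dtype=bool)
    for start, end, factor in planted_regions or []:
        if not (0 <= start < end <= n_bins):
            raise ConfigurationError(f"planted region [{start}, {end}) outside extent")
        if factor < 0:
            raise ConfigurationError("planted factor must be >= 0")
        if occupied[start:end].any():
            raise ConfigurationError("planted regions overlap")
        occupied[start:end] = True
        base[start:end] *= factor

    rng = np.random.default_rng(seed)
    tracks = []
    for i in range(n_samples):
        noise = _lognormal_unit_mean(rng, depth_noise_cv, n_bins)
        tracks.append(
            DepthTrack(
                sample_id=f"S{i+1:04d}",
                contig=contig,
                bin_size=bin_size,
                depths=base * noise,
            )
        )
    return tracks
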