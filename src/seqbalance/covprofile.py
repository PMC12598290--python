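"""Multi-sample coverage aggregation and accessibility classification.

Depth-of-coverage profiles from a single genome are too noisy to show which
regions a sequencing protocol can or cannot reach; averaging binned depth
over many samples (typically ~1000 per platform/protocol, each restricted to
confidently mapped reads, MAPQ >= 20) exposes systematic dropouts. Bins whose
mean depth falls below a fraction of the profile's global mean, in runs of at
least a minimum length, are classified *inaccessible*; comparing the
classifications of two protocols highlights regions one read length can map
but another cannot.

Coordinates are 0-based half-open, matching BED/bedGraph conventions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateProfileError, IncompatibleTracksError, InvalidParameterError

__all__ = [
    "DepthTrack",
    "AggregateProfile",
    "Region",
    "RegionSet",
    "aggregate_mean_coverage",
    "classify_accessibility",
    "protocol_diff",
    "DEFAULT_REL_THRESHOLD",
    "DEFAULT_MIN_REGION_BINS",
    "DEFAULT_MAPQ_FLOOR",
]

#: A bin counts as low-coverage when its mean depth is below this fraction of
#: the profile-wide mean. Package default; "inaccessible" has no universal
#: numeric definition.
DEFAULT_REL_THRESHOLD = 0.25
#: Runs shorter than this many bins are ignored (single-bin noise).
DEFAULT_MIN_REGION_BINS = 2
#: Mapping-quality floor recorded as track provenance.
DEFAULT_MAPQ_FLOOR = 20


@dataclass(frozen=True)
class DepthTrack:
    """Binned mean depth for one sample on one contig."""

    sample_id: str
    contig: str
    bin_size: int
    depths: np.ndarray
    mapq_floor: int = DEFAULT_MAPQ_FLOOR

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        object.__setattr__(self, "depths", depths)
        if self.bin_size <= 0:
            raise InvalidParameterError("bin_size must be > 0")
        if depths.ndim != 1 or depths.size == 0:
            raise InvalidParameterError("depths must be a non-empty 1-D array")
        if np.any(depths < 0):
            raise InvalidParameterError(f"{self.sample_id}: negative depths")

    @property
    def n_bins(self) -> int:
        return int(self.depths.size)


@dataclass(frozen=True)
class AggregateProfile:
    """Per-bin mean depth across samples, with the cohort size it came from."""

    contig: str
    bin_size: int
    mean_depth: np.ndarray
    n_samples: int
    global_mean: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "mean_depth", np.asarray(self.mean_depth, dtype=float))
        if self.n_samples < 1:
            raise InvalidParameterError("n_samples must be >= 1")

    @property
    def n_bins(self) -> int:
        return int(self.mean_depth.size)


@dataclass(frozen=True, order=True)
class Region:
    """Half-open genomic interval [start, end) in bp."""

    contig: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 0 or self.end <= self.start:
            raise InvalidParameterError(f"bad interval {self.contig}:{self.start}-{self.end}")


@dataclass(frozen=True)
class RegionSet:
    """Sorted, merged, non-overlapping intervals with an accessibility label."""

    intervals: tuple[Region, ...]
    label: str  # "accessible" | "inaccessible"

    def __post_init__(self) -> None:
        ivs = tuple(sorted(self.intervals))
        for a, b in zip(ivs, ivs[1:]):
            if a.contig == b.contig and b.start <= a.end:
                raise InvalidParameterError("intervals overlap or touch; merge first")
        object.__setattr__(self, "intervals", ivs)

    def __len__(self) -> int:
        return len(self.intervals)

    def total_bp(self) -> int:
        return sum(r.end - r.start for r in self.intervals)


def _check_compatible(items, what: str) -> None:
    contigs = {t.contig for t in items}
    bins = {t.bin_size for t in items}
    sizes = {t.n_bins for t in items}
    if len(contigs) > 1 or len(bins) > 1 or len(sizes) > 1:
        raise IncompatibleTracksError(
            f"{what} disagree: contigs={contigs}, bin_sizes={bins}, n_bins={sizes}"
        )


def aggregate_mean_coverage(tracks: list[DepthTrack]) -> AggregateProfile:
    """Arithmetic per-bin mean depth across samples.

    All tracks must share contig, bin size and extent. ``global_mean`` is the
    mean over bins of the aggregated profile.
    """
    if not tracks:
        raise InvalidParameterError("need at least one track")
    _check_compatible(tracks, "depth tracks")
    stack = np.stack([t.depths for t in tracks])
    mean = stack.mean(axis=0)
    return AggregateProfile(
        contig=tracks[0].contig,
        bin_size=tracks[0].bin_size,
        mean_depth=mean,
        n_samples=len(tracks),
        global_mean=float(mean.mean()),
    )


def _mask_to_regions(mask: np.ndarray, contig: str, bin_size: int, min_bins: int) -> tuple[Region, ...]:
    """Convert a boolean per-bin mask into bp intervals, dropping short runs."""
    regions = []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    for lo, hi in zip(edges[::2], edges[1::2]):
        if hi - lo >= min_bins:
            regions.append(Region(contig, int(lo) * bin_size, int(hi) * bin_size))
    return tuple(regions)


def low_coverage_mask(profile: AggregateProfile, rel_threshold: float) -> np.ndarray:
    """Boolean per-bin mask: mean depth < rel_threshold x global mean."""
    if profile.global_mean <= 0:
        raise DegenerateProfileError("profile global mean is zero")
    if not 0 < rel_threshold < 1:
        raise InvalidParameterError("rel_threshold must be in (0, 1)")
    return profile.mean_depth < rel_threshold * profile.global_mean


def classify_accessibility(
    profile: AggregateProfile,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    min_region_bins: int = DEFAULT_MIN_REGION_BINS,
) -> RegionSet:
    """Inaccessible regions of an aggregate profile.

    A bin is low when its mean depth is below ``rel_threshold x global_mean``;
    maximal runs of at least ``min_region_bins`` low bins become inaccessible
    intervals. The genomic complement is accessible.
    """
    if min_region_bins < 1:
        raise InvalidParameterError("min_region_bins must be >= 1")
    mask = low_coverage_mask(profile, rel_threshold)
    regions = _mask_to_regions(mask, profile.contig, profile.bin_size, min_region_bins)
    return RegionSet(intervals=regions, label="inaccessible")


def accessible_complement(profile: AggregateProfile, inaccessible: RegionSet) -> RegionSet:
    """Accessible regions: the profile extent minus the inaccessible intervals."""
    mask = np.ones(profile.n_bins, dtype=bool)
    for r in inaccessible.intervals:
        mask[r.start // profile.bin_size : r.end // profile.bin_size] = False
    regions = _mask_to_regions(mask, profile.contig, profile.bin_size, 1)
    return RegionSet(intervals=regions, label="accessible")


def protocol_diff(
    a: AggregateProfile,
    b: AggregateProfile,
    rel_threshold: float = DEFAULT_REL_THRESHOLD,
    min_region_bins: int = DEFAULT_MIN_REGION_BINS,
) -> RegionSet:
    """Regions accessible under protocol ``a`` but inaccessible under ``b``.

    Classifies both profiles at the same threshold, then takes the bin-level
    difference of the inaccessible calls (b minus a); useful for showing what
    a longer read length recovers over a shorter one.
    """
    _check_compatible([a, b], "aggregate profiles")
    in_a = _regions_to_mask(classify_accessibility(a, rel_threshold, min_region_bins), a)
    in_b = _regions_to_mask(classify_accessibility(b, rel_threshold, min_region_bins), b)
    diff = in_b & ~in_a
    return RegionSet(
        intervals=_mask_to_regions(diff, a.contig, a.bin_size, 1),
        label="inaccessible",
    )


def _regions_to_mask(regions: RegionSet, profile: AggregateProfile) -> np.ndarray:
    mask = np.zeros(profile.n_bins, dtype=bool)
    for r in regions.intervals:
        mask[r.start // profile.bin_size : r.end // profile.bin_size] = True
    return mask
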