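"""Pooled-library quantification and sample-level QC filters.

Covers the pre-sequencing checks for a 96-plex PCR-free pool:

* **QC1 (loading volume)** — dye-based quantification of the whole pool
  against a previously sequenced reference pool; the loading volume is scaled
  so the same DNA mass goes on the flow cell.
* **QC2 (sizing)** — PCR-free libraries carry Y-shaped adapters and migrate
  anomalously (>1000 bp) as dsDNA, so sizing is done denatured against an RNA
  ladder. Single-stranded DNA runs ~30 nt faster than the RNA ladder, so the
  observed size is corrected upward by that offset; subtracting the ~140 bp of
  adapter sequence then gives the insert size.
* **Post-sequencing filters** — contamination (freemix) exclusion and
  duplication/base-composition flags.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .errors import ConfigurationError, InvalidMeasurementError, InvalidRecordError

__all__ = [
    "PoolMeasurement",
    "SizingResult",
    "SampleQCRecord",
    "loading_volume",
    "correct_library_size",
    "insert_size",
    "size_library",
    "molar_concentration",
    "filter_contamination",
    "sequence_qc_flags",
    "DEFAULT_RNA_DNA_OFFSET_NT",
    "DEFAULT_ADAPTER_TOTAL_BP",
    "DEFAULT_CONTAMINATION_THRESHOLD",
    "DEFAULT_MAX_DUPLICATION",
    "DEFAULT_MAX_BASE_SKEW",
    "YADAPTER_ANOMALY_BP",
]

#: RNA ladders migrate ~30 nt slower than DNA ladders under denaturing
#: conditions, so ssDNA sized against an RNA ladder reads ~30 nt short.
DEFAULT_RNA_DNA_OFFSET_NT = 30
#: Total adapter sequence on a TruSeq PCR-free library molecule.
DEFAULT_ADAPTER_TOTAL_BP = 140
#: Samples at or above this freemix fraction are excluded from joint
#: genotyping (gnomAD uses a looser 0.05).
DEFAULT_CONTAMINATION_THRESHOLD = 0.03
#: Duplication/base-skew limits are package choices; the underlying criteria
#: are qualitative ("reasonably low", "not significantly skewed").
DEFAULT_MAX_DUPLICATION = 0.20
DEFAULT_MAX_BASE_SKEW = 0.02
#: dsDNA sizing of a Y-adapter library above this is the known anomalous
#: migration artifact, not a real size.
YADAPTER_ANOMALY_BP = 1000


@dataclass(frozen=True)
class PoolMeasurement:
    """Dye-based concentration of one pooled library."""

    pool_id: str
    dye_conc: float  # ng/uL
    volume: float = 1.0  # uL
    is_reference: bool = False
    reference_loading_volume: float | None = None  # uL

    def __post_init__(self) -> None:
        if self.dye_conc < 0:
            raise InvalidMeasurementError(f"{self.pool_id}: dye_conc must be >= 0")
        if self.volume <= 0:
            raise InvalidMeasurementError(f"{self.pool_id}: volume must be > 0")


@dataclass(frozen=True)
class SizingResult:
    """Full denatured-sizing chain for one pool: observed -> corrected -> insert."""

    observed_size_vs_rna_ladder: float  # nt
    rna_dna_offset: float = DEFAULT_RNA_DNA_OFFSET_NT
    adapter_total: float = DEFAULT_ADAPTER_TOTAL_BP
    corrected_library_size: float = field(init=False)
    insert_size: float = field(init=False)

    def __post_init__(self) -> None:
        corrected = correct_library_size(self.observed_size_vs_rna_ladder, self.rna_dna_offset)
        object.__setattr__(self, "corrected_library_size", corrected)
        object.__setattr__(self, "insert_size", insert_size(corrected, self.adapter_total))

    @property
    def dsdna_anomaly_suspected(self) -> bool:
        """True when the observed size lies in the Y-adapter dsDNA artifact range."""
        return self.observed_size_vs_rna_ladder > YADAPTER_ANOMALY_BP


@dataclass(frozen=True)
class SampleQCRecord:
    """Per-sample post-sequencing QC metrics; optional ones may be ``None``."""

    sample_id: str
    freemix: float
    duplication_rate: float | None = None
    base_frac_a: float | None = None
    base_frac_t: float | None = None
    base_frac_g: float | None = None
    base_frac_c: float | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.freemix <= 1.0:
            raise InvalidRecordError(
                f"{self.sample_id}: freemix {self.freemix} outside [0, 1]"
            )
        for name in ("duplication_rate", "base_frac_a", "base_frac_t", "base_frac_g", "base_frac_c"):
            v = getattr(self, name)
            if v is not None and not 0.0 <= v <= 1.0:
                raise InvalidRecordError(f"{self.sample_id}: {name} {v} outside [0, 1]")

    @property
    def at_skew(self) -> float | None:
        """|f(A) - f(T)|, or None when either fraction is absent."""
        if self.base_frac_a is None or self.base_frac_t is None:
            return None
        return abs(self.base_frac_a - self.base_frac_t)

    @property
    def gc_skew(self) -> float | None:
        """|f(G) - f(C)|, or None when either fraction is absent."""
        if self.base_frac_g is None or self.base_frac_c is None:
            return None
        return abs(self.base_frac_g - self.base_frac_c)


def loading_volume(new_pool: PoolMeasurement, reference: PoolMeasurement) -> float:
    """Loading volume (uL) for a new pool that matches the reference DNA mass.

    ``v_new = v_ref x (c_ref / c_new)`` so that ``c_new x v_new`` equals the
    known-good ``c_ref x v_ref``. Relative quantification against previously
    sequenced pools sidesteps absolute molarity calibration, assuming the new
    pool's library size matches (verified separately by sizing).
    """
    if new_pool.dye_conc <= 0 or reference.dye_conc <= 0:
        raise InvalidMeasurementError("dye concentrations must be > 0")
    if reference.reference_loading_volume is None:
        raise ConfigurationError(
            f"reference pool {reference.pool_id!r} has no reference_loading_volume"
        )
    return reference.reference_loading_volume * reference.dye_conc / new_pool.dye_conc


def correct_library_size(observed_nt: float, offset_nt: float = DEFAULT_RNA_DNA_OFFSET_NT) -> float:
    """True library size from an RNA-ladder reading: ``observed + offset``."""
    if observed_nt <= 0:
        raise InvalidMeasurementError("observed size must be > 0")
    return observed_nt + offset_nt


def insert_size(corrected_library_bp: float, adapter_total: float = DEFAULT_ADAPTER_TOTAL_BP) -> float:
    """Genomic insert size: corrected library size minus total adapter length."""
    if adapter_total >= corrected_library_bp:
        raise InvalidMeasurementError(
            f"adapter_total {adapter_total} >= library size {corrected_library_bp}"
        )
    return corrected_library_bp - adapter_total


def size_library(
    observed_nt: float,
    offset_nt: float = DEFAULT_RNA_DNA_OFFSET_NT,
    adapter_total: float = DEFAULT_ADAPTER_TOTAL_BP,
) -> SizingResult:
    """Run the whole sizing chain (e.g. 616 nt -> 646 bp library -> 506 bp insert)."""
    return SizingResult(observed_nt, rna_dna_offset=offset_nt, adapter_total=adapter_total)


def molar_concentration(dye_conc_ng_ul: float, library_size_bp: float) -> float:
    """Molarity (nM) of a dsDNA library from mass concentration and size.

    Uses 660 g/mol per bp of dsDNA: ``nM = ng/uL x 1e6 / (660 x size)``.
    """
    if dye_conc_ng_ul <= 0 or library_size_bp <= 0:
        raise InvalidMeasurementError("concentration and size must be > 0")
    return dye_conc_ng_ul * 1e6 / (660.0 * library_size_bp)


def filter_contamination(
    records: list[SampleQCRecord],
    threshold: float = DEFAULT_CONTAMINATION_THRESHOLD,
) -> tuple[list[SampleQCRecord], list[SampleQCRecord]]:
    """Partition records into (kept, excluded) on the freemix contamination rate.

    The boundary is inclusive: ``freemix >= threshold`` excludes, so a sample
    at exactly 3% contamination is dropped under the default threshold.
    """
    kept = [r for r in records if r.freemix < threshold]
    excluded = [r for r in records if r.freemix >= threshold]
    return kept, excluded


def sequence_qc_flags(
    record: SampleQCRecord,
    max_dup: float = DEFAULT_MAX_DUPLICATION,
    max_base_skew: float = DEFAULT_MAX_BASE_SKEW,
) -> frozenset[str]:
    """QC flags for one sample's read-level metrics.

    Returns a (possibly empty) set drawn from:

    * ``"high-duplication"`` — duplication rate above ``max_dup``;
    * ``"base-skew"`` — |A-T| or |G-C| base-fraction imbalance above
      ``max_base_skew``;
    * ``"duplication-not-evaluated"`` / ``"base-balance-not-evaluated"`` —
      the corresponding metric was absent.
    """
    flags: set[str] = set()
    if record.duplication_rate is None:
        flags.add("duplication-not-evaluated")
    elif record.duplication_rate > max_dup:
        flags.add("high-duplication")
    skews = [s for s in (record.at_skew, record.gc_skew) if s is not None]
    if not skews:
        flags.add("base-balance-not-evaluated")
    elif any(s > max_base_skew for s in skews):
        flags.add("base-skew")
    return frozenset(flags)
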