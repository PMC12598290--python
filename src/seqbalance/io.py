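"""Readers and writers for the text formats the tool touches.

TSV for demux stats, plans and QC tables (pandas, tab-separated, ``#``
comments allowed); a BCL-Convert/bcl2fastq "Demultiplex_Stats"-style CSV
dialect; bedGraph for depth tracks and aggregate profiles; BED for region
sets; JSON for machine-readable reports. Every writer puts a provenance
comment (tool version, config hash, seed when known) on the first line, and
every writer's output round-trips through its paired reader.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .balance import DemuxCounts, PlanEntry, RebalancePlan
from .covprofile import AggregateProfile, DepthTrack, Region, RegionSet
from .errors import InvalidInputError
from .libqc import PoolMeasurement, SampleQCRecord

__all__ = [
    "read_demux_tsv",
    "write_demux_tsv",
    "read_demux_stats_csv",
    "write_rebalance_plan_tsv",
    "read_rebalance_plan_tsv",
    "read_pool_measurements_tsv",
    "read_qc_records_tsv",
    "read_bedgraph",
    "write_bedgraph",
    "write_bed",
    "read_bed",
    "write_json_report",
    "config_hash",
    "provenance_line",
]

FLOAT_FMT = "%.4f"


def config_hash(config: dict[str, Any]) -> str:
    """Short stable hash of a configuration mapping."""
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def provenance_line(config: dict[str, Any] | None = None, seed: int | None = None) -> str:
    parts = [f"# seqbalance v{__version__}"]
    if config is not None:
        parts.append(f"config={config_hash(config)}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return " ".join(parts)


# ---------------------------------------------------------------------------
# demultiplexing statistics


def read_demux_tsv(
    path: str | Path,
    run_id: str | None = None,
    sample_col: str = "sample_id",
    reads_col: str = "reads",
    volume_col: str = "volume",
) -> DemuxCounts:
    """Generic demux-stats TSV: sample_id, reads[, volume] columns.

    A ``# run_id=...`` header comment, as written by :func:`write_demux_tsv`,
    is honoured unless ``run_id`` is given explicitly.
    """
    if run_id is None:
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                if line.startswith("# run_id="):
                    run_id = line.split("=", 1)[1].strip()
    df = pd.read_csv(path, sep="\t", comment="#")
    if sample_col not in df.columns or reads_col not in df.columns:
        raise InvalidInputError(
            f"{path}: need columns {sample_col!r} and {reads_col!r}, got {list(df.columns)}"
        )
    volumes: dict[str, float] | float = 1.0
    if volume_col in df.columns:
        volumes = dict(zip(df[sample_col].astype(str), df[volume_col].astype(float)))
    reads = dict(zip(df[sample_col].astype(str), df[reads_col].astype(float)))
    return DemuxCounts.from_reads(run_id or Path(path).stem, reads, volumes)


def write_demux_tsv(
    counts: DemuxCounts, path: str | Path, config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    """Generic demux-stats TSV writer (sample_id, reads, volume)."""
    with open(path, "w") as fh:
        fh.write(provenance_line(config, seed) + "\n")
        fh.write(f"# run_id={counts.run_id}\n")
        fh.write("sample_id\treads\tvolume\n")
        for e in counts.entries:
            fh.write(f"{e.sample_id}\t{e.reads!r}\t{FLOAT_FMT % e.pooled_volume}\n")


def read_demux_stats_csv(
    path: str | Path,
    run_id: str | None = None,
    sample_col: str = "SampleID",
    reads_col: str = "# Reads",
) -> DemuxCounts:
    """BCL-Convert/bcl2fastq ``Demultiplex_Stats.csv`` dialect.

    Comma-separated; the sample and read-count column headers are
    configurable (``SampleID``/``# Reads`` by default). Rows whose sample id
    is ``Undetermined`` are dropped, and counts for a sample split across
    lanes are summed. No comment stripping: ``#`` legitimately appears in
    column names in this dialect.
    """
    df = pd.read_csv(path, sep=",")
    if sample_col not in df.columns or reads_col not in df.columns:
        raise InvalidInputError(
            f"{path}: need columns {sample_col!r} and {reads_col!r}, got {list(df.columns)}"
        )
    df = df[df[sample_col].astype(str) != "Undetermined"]
    grouped = df.groupby(df[sample_col].astype(str))[reads_col].sum()
    return DemuxCounts.from_reads(run_id or Path(path).stem, grouped.astype(float).to_dict())


# ---------------------------------------------------------------------------
# rebalancing plans


def write_rebalance_plan_tsv(
    plan: RebalancePlan, path: str | Path, config: dict[str, Any] | None = None,
    seed: int | None = None,
) -> None:
    rows = [
        {
            "sample_id": e.sample_id,
            "volume_ul": float(FLOAT_FMT % e.volume),
            "excluded": int(e.excluded),
            "reason": e.reason or ".",
            "flags": ",".join(sorted(e.flags)) or ".",
            "expected_final_reads": float(FLOAT_FMT % e.expected_final_reads),
        }
        for e in plan.entries
    ]
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(provenance_line(config, seed) + "\n")
        fh.write(f"# target_reads={plan.target_reads!r} remaining_runs={plan.remaining_runs} "
                 f"per_run_reads={plan.per_run_reads!r}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=FLOAT_FMT)


def read_rebalance_plan_tsv(path: str | Path) -> RebalancePlan:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            for tok in line[1:].split():
                if "=" in tok:
                    k, v = tok.split("=", 1)
                    meta[k] = v
    df = pd.read_csv(path, sep="\t", comment="#")
    entries = tuple(
        PlanEntry(
            sample_id=str(r.sample_id),
            volume=float(r.volume_ul),
            excluded=bool(r.excluded),
            reason="" if r.reason == "." else str(r.reason),
            flags=frozenset() if r.flags == "." else frozenset(str(r.flags).split(",")),
            expected_final_reads=float(r.expected_final_reads),
        )
        for r in df.itertuples()
    )
    return RebalancePlan(
        entries=entries,
        target_reads=float(meta.get("target_reads", "nan")),
        remaining_runs=int(meta.get("remaining_runs", "0")),
        per_run_reads=float(meta.get("per_run_reads", "nan")),
    )


# ---------------------------------------------------------------------------
# QC tables


def read_pool_measurements_tsv(path: str | Path) -> list[PoolMeasurement]:
    """TSV with pool_id, dye_conc[, volume, is_reference, reference_loading_volume]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    out = []
    for r in df.itertuples():
        out.append(
            PoolMeasurement(
                pool_id=str(r.pool_id),
                dye_conc=float(r.dye_conc),
                volume=float(getattr(r, "volume", 1.0)),
                is_reference=bool(getattr(r, "is_reference", False)),
                reference_loading_volume=(
                    float(v) if not pd.isna(v := getattr(r, "reference_loading_volume", float("nan"))) else None
                ),
            )
        )
    return out


def read_qc_records_tsv(path: str | Path) -> list[SampleQCRecord]:
    """TSV with sample_id, freemix[, duplication_rate, base_frac_a/t/g/c]."""
    df = pd.read_csv(path, sep="\t", comment="#")

    def opt(row, name):
        v = getattr(row, name, float("nan"))
        return None if pd.isna(v) else float(v)

    return [
        SampleQCRecord(
            sample_id=str(r.sample_id),
            freemix=float(r.freemix),
            duplication_rate=opt(r, "duplication_rate"),
            base_frac_a=opt(r, "base_frac_a"),
            base_frac_t=opt(r, "base_frac_t"),
            base_frac_g=opt(r, "base_frac_g"),
            base_frac_c=opt(r, "base_frac_c"),
        )
        for r in df.itertuples()
    ]


# ---------------------------------------------------------------------------
# bedGraph / BED


def read_bedgraph(path: str | Path, sample_id: str | None = None, mapq_floor: int = 20) -> DepthTrack:
    """One uniform-bin, single-contig bedGraph track (contig, start, end, depth)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "depth"],
    )
    if df.empty:
        raise InvalidInputError(f"{path}: empty bedGraph")
    contigs = df["contig"].unique()
    if len(contigs) != 1:
        raise InvalidInputError(f"{path}: expected a single contig, got {list(contigs)}")
    widths = (df["end"] - df["start"]).unique()
    if len(widths) != 1:
        raise InvalidInputError(f"{path}: bins are not uniform")
    starts = df["start"].to_numpy()
    if not np.array_equal(starts, np.arange(len(df)) * int(widths[0])):
        raise InvalidInputError(f"{path}: bins are not contiguous from 0")
    return DepthTrack(
        sample_id=sample_id or Path(path).stem,
        contig=str(contigs[0]),
        bin_size=int(widths[0]),
        depths=df["depth"].to_numpy(dtype=float),
        mapq_floor=mapq_floor,
    )


def write_bedgraph(
    track: DepthTrack | AggregateProfile, path: str | Path,
    config: dict[str, Any] | None = None,
) -> None:
    depths = track.depths if isinstance(track, DepthTrack) else track.mean_depth
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        for i, d in enumerate(depths):
            fh.write(f"{track.contig}\t{i * track.bin_size}\t{(i + 1) * track.bin_size}\t{FLOAT_FMT % d}\n")


def write_bed(regions: RegionSet, path: str | Path, config: dict[str, Any] | None = None) -> None:
    with open(path, "w") as fh:
        fh.write(provenance_line(config) + "\n")
        for r in regions.intervals:
            fh.write(f"{r.contig}\t{r.start}\t{r.end}\t{regions.label}\n")


def read_bed(path: str | Path) -> RegionSet:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["contig", "start", "end", "label"],
    )
    label = str(df["label"].iloc[0]) if not df.empty and df["label"].notna().any() else "inaccessible"
    intervals = tuple(
        Region(str(r.contig), int(r.start), int(r.end)) for r in df.itertuples()
    )
    return RegionSet(intervals=intervals, label=label)


# ---------------------------------------------------------------------------
# reports


def write_json_report(
    payload: dict[str, Any], path: str | Path,
    config: dict[str, Any] | None = None, seed: int | None = None,
) -> None:
    """JSON report with version / config-hash / seed provenance embedded."""
    doc = {
        "tool": "seqbalance",
        "version": __version__,
        "config_hash": config_hash(config or {}),
        "seed": seed,
        **payload,
    }
    Path(path).write_text(json.dumps(doc, indent=2, default=_jsonify) + "\n")


def _jsonify(obj: Any) -> Any:
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, frozenset):
        return sorted(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
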