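"""Genomic-bin quality control: completeness estimation and retention.

A bin's profile completeness is the percentage of a universal
single-copy marker panel (137 genes by default) detected in it; bins are
kept when completeness reaches 10% or more and when at least 2 of the 4
metagenomic short-read samples support them.  Contigs shorter than
1000 bp are treated as unsupported singletons and discarded before
binning.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .reference import GenomicBin, MarkerGeneSet

__all__ = [
    "BinFilterConfig",
    "completeness",
    "duplicate_marker_report",
    "sample_support",
    "FilterDecision",
    "filter_bins",
    "contig_prefilter",
    "read_marker_hits",
    "read_contig_mapping",
]


@dataclass
class BinFilterConfig:
    """Retention thresholds; boundary values are inclusive ("10% or more",
    "at least 2 out of 4")."""

    min_completeness_pct: float = 10.0
    min_sample_support: int = 2
    n_samples: int = 4
    min_contig_bp: int = 1000
    min_contig_frac: float = 0.5  # fraction of a bin's contigs a sample must map

    def __post_init__(self) -> None:
        if not (0 <= self.min_completeness_pct <= 100):
            raise ValueError("min_completeness_pct must be within [0, 100]")
        if not (1 <= self.min_sample_support <= self.n_samples):
            raise ValueError("min_sample_support must be within [1, n_samples]")
        if self.min_contig_bp < 0:
            raise ValueError("min_contig_bp must be non-negative")


def completeness(found: Iterable[str], markers: MarkerGeneSet) -> float:
    """Profile completeness: 100 x |distinct markers found| / panel size.

    Marker observations are deduplicated (presence/absence semantics;
    multiplicity hints at contamination, not completeness) and unknown
    marker ids are rejected.  Reported to one decimal, round-half-even.
    """
    found_set = set(found)
    unknown = found_set - markers.marker_ids
    if unknown:
        raise ValueError(f"unknown marker ids: {sorted(unknown)[:5]}")
    pct = 100.0 * len(found_set) / markers.expected_count
    # one-decimal banker's rounding for deterministic reports
    return float(f"{round(pct * 10) / 10:.1f}")


def duplicate_marker_report(found: Sequence[str]) -> dict[str, int]:
    """Markers observed more than once — a contamination hint, not completeness."""
    counts: dict[str, int] = {}
    for m in found:
        counts[m] = counts.get(m, 0) + 1
    return {m: c for m, c in counts.items() if c > 1}


def sample_support(
    contig_mapped: Mapping[str, set[str]],
    bin_: GenomicBin,
    min_frac: float = 0.5,
) -> int:
    """Number of samples supporting a bin.

    A sample supports a bin iff at least *min_frac* of the bin's contigs
    receive one or more mapped reads from it.
    """
    if bin_.n_contigs == 0:
        raise ValueError(f"bin {bin_.bin_id!r} has no contigs")
    contigs = set(bin_.contigs)
    n = 0
    for sample, mapped in contig_mapped.items():
        frac = len(contigs & mapped) / len(contigs)
        supported = frac >= min_frac
        bin_.sample_support[sample] = supported
        n += supported
    return n


@dataclass
class FilterDecision:
    bin_id: str
    retained: bool
    completeness_pct: float
    support: int
    failed: list[str] = field(default_factory=list)


def filter_bins(
    bins: Sequence[GenomicBin],
    cfg: BinFilterConfig | None = None,
) -> tuple[list[GenomicBin], list[FilterDecision]]:
    """Retain bins meeting both thresholds; report the failed criterion per bin.

    Requires ``completeness_pct`` and ``sample_support`` precomputed on
    each bin.  Returns (retained bins, per-bin decisions).
    """
    cfg = cfg or BinFilterConfig()
    retained: list[GenomicBin] = []
    decisions: list[FilterDecision] = []
    for b in bins:
        if b.completeness_pct is None:
            raise ValueError(f"bin {b.bin_id!r}: completeness not computed")
        failed = []
        if b.completeness_pct < cfg.min_completeness_pct:
            failed.append(
                f"completeness {b.completeness_pct:.1f}% < {cfg.min_completeness_pct:g}%"
            )
        if b.support_count < cfg.min_sample_support:
            failed.append(f"support {b.support_count} < {cfg.min_sample_support}")
        keep = not failed
        if keep:
            retained.append(b)
        decisions.append(
            FilterDecision(
                bin_id=b.bin_id,
                retained=keep,
                completeness_pct=b.completeness_pct,
                support=b.support_count,
                failed=failed,
            )
        )
    return retained, decisions


@dataclass
class PrefilterSummary:
    n_removed: int
    bp_removed: int
    n_kept: int
    bp_kept: int


def contig_prefilter(
    contigs: Mapping[str, int],
    cfg: BinFilterConfig | None = None,
) -> tuple[dict[str, int], PrefilterSummary]:
    """Drop singleton contigs smaller than ``min_contig_bp`` (default 1000 bp).

    "Smaller than" is strict: a contig of exactly 1000 bp is kept.
    """
    cfg = cfg or BinFilterConfig()
    kept = {c: n for c, n in contigs.items() if n >= cfg.min_contig_bp}
    removed_bp = sum(n for n in contigs.values()) - sum(kept.values())
    summary = PrefilterSummary(
        n_removed=len(contigs) - len(kept),
        bp_removed=removed_bp,
        n_kept=len(kept),
        bp_kept=sum(kept.values()),
    )
    return kept, summary


# -- tabular inputs ----------------------------------------------------


def read_marker_hits(path: str | Path) -> dict[str, list[str]]:
    """TSV ``bin_id  marker_id`` -> per-bin marker observation lists."""
    hits: dict[str, list[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "bin_id":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: expected 2 columns, got {row!r}")
            hits.setdefault(row[0].strip(), []).append(row[1].strip())
    return hits


def read_contig_mapping(path: str | Path) -> dict[str, set[str]]:
    """TSV ``sample_id  contig_id`` -> per-sample mapped-contig sets."""
    mapping: dict[str, set[str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.reader(fh, delimiter="\t"):
            if not row or row[0].startswith("#") or row[0] == "sample_id":
                continue
            if len(row) < 2:
                raise ValueError(f"{path}: expected 2 columns, got {row!r}")
            mapping.setdefault(row[0].strip(), set()).add(row[1].strip())
    return mapping
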