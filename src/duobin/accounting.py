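"""Read- and annotation-accounting arithmetic.

Sequencing projects report a handful of bookkeeping percentages: how many raw
reads quality control removed, how many aligned to the host plant genome, and
what fraction of predicted genes each annotation database could label. The
operations here reproduce that arithmetic exactly as printed in study tables:
half-up decimal rounding at a caller-chosen precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from ._util import round_half_up_ratio


@dataclass(frozen=True)
class SampleReadStats:
    """Read-level bookkeeping for one sequencing sample."""

    sample: str
    total_reads: int
    qc_removed: int = 0
    host_aligned: int = 0

    def __post_init__(self) -> None:
        if self.total_reads <= 0:
            raise ValueError(f"{self.sample}: total_reads must be positive")
        if not 0 <= self.qc_removed <= self.total_reads:
            raise ValueError(f"{self.sample}: qc_removed outside [0, total_reads]")
        if not 0 <= self.host_aligned <= self.total_reads:
            raise ValueError(f"{self.sample}: host_aligned outside [0, total_reads]")


@dataclass(frozen=True)
class AnnotationStats:
    """Gene counts matched per annotation database."""

    total_genes: int
    matched: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.total_genes <= 0:
            raise ValueError("total_genes must be positive")
        for db, n in self.matched.items():
            if not 0 <= n <= self.total_genes:
                raise ValueError(f"{db}: matched count {n} outside [0, total_genes]")


def percent(numerator: int | float, denominator: int | float, decimals: int = 2) -> float:
    """100 * numerator / denominator rounded half-up to ``decimals`` places."""
    if denominator <= 0:
        raise ZeroDivisionError("denominator must be positive")
    if numerator < 0:
        raise ValueError("numerator must be non-negative")
    return round_half_up_ratio(numerator, denominator, decimals)


def qc_report(stats: SampleReadStats, decimals: int = 2,
              host_decimals: int = 3) -> dict[str, float]:
    """Retained/removed/host-aligned percentages for one sample.

    The host fraction is conventionally printed at finer precision than the
    QC fraction because plant contamination is the quantity the washing
    protocol is judged by.
    """
    removed = percent(stats.qc_removed, stats.total_reads, decimals)
    retained = percent(stats.total_reads - stats.qc_removed, stats.total_reads, decimals)
    host = percent(stats.host_aligned, stats.total_reads, host_decimals)
    return {
        "sample": stats.sample,
        "total_reads": stats.total_reads,
        "removed_percent": removed,
        "retained_percent": retained,
        "host_percent": host,
    }


def annotation_coverage(stats: AnnotationStats, decimals: int = 1) -> dict[str, float]:
    """Percentage of genes matched per database, one decimal by default."""
    return {
        db: percent(n, stats.total_genes, decimals)
        for db, n in stats.matched.items()
    }
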