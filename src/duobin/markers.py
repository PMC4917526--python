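"""Essential single-copy marker gene census, completeness and duplication.

A reference set of genes expected exactly once per bacterial genome (105 by
default, covering Firmicutes, Gammaproteobacteria and Actinobacteria) is
searched against a bin's scaffolds; the fraction of the set that is found
estimates how complete the recovered genome is, and markers seen more than
once flag contamination or strain mixture.

The HMM search itself happens upstream; this module consumes hit tables
(plain TSV or HMMER3 tblout-style) and a scaffold-to-bin membership.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import pandas as pd

from ._util import round_half_up_ratio

logger = logging.getLogger(__name__)

#: Abstract ids for the 105-gene essential single-copy reference set. The
#: real set is a collection of protein HMMs; only the identities matter for
#: the census, so the default is a plain id list and any other set can be
#: plugged in as a sequence of strings.
ESSENTIAL_GENE_IDS: tuple[str, ...] = tuple(f"ESG_{i:03d}" for i in range(1, 106))

HIT_COLUMNS = ("scaffold", "marker_id", "start", "end", "score")


@dataclass
class MarkerCensus:
    """Per-bin marker tallies plus the underlying marker multisets."""

    table: pd.DataFrame  # index bin, columns: unique_markers, total_hits, reference_size
    marker_counts: dict = field(default_factory=dict)  # bin -> Counter(marker_id)
    unassigned_hits: int = 0


def census(hits: pd.DataFrame, membership: Mapping[str, object],
           reference: Sequence[str] = ESSENTIAL_GENE_IDS) -> MarkerCensus:
    """Count unique markers and total hits per bin.

    Parameters
    ----------
    hits : DataFrame with at least ``scaffold`` and ``marker_id`` columns.
    membership : mapping scaffold -> bin label. Hits on scaffolds without a
        membership are ignored (their count is logged and reported).
    reference : the active marker id set; hits outside it raise ``ValueError``.
    """
    refset = set(reference)
    bad = set(hits["marker_id"]) - refset
    if bad:
        raise ValueError(f"marker ids outside the reference set: {sorted(bad)[:5]}")

    bins = sorted({b for b in membership.values()}, key=str)
    counts: dict = {b: Counter() for b in bins}
    unassigned = 0
    for scaf, marker in zip(hits["scaffold"], hits["marker_id"]):
        b = membership.get(scaf)
        if b is None:
            unassigned += 1
            continue
        counts[b][marker] += 1
    if unassigned:
        logger.info("census: %d hits on scaffolds without bin membership", unassigned)

    table = pd.DataFrame(
        {
            "unique_markers": [len(counts[b]) for b in bins],
            "total_hits": [sum(counts[b].values()) for b in bins],
            "reference_size": len(reference),
        },
        index=pd.Index(bins, name="bin"),
    )
    return MarkerCensus(table=table, marker_counts=counts, unassigned_hits=unassigned)


def completeness(unique: int, reference_size: int = 105) -> int:
    """Integer completeness percent, rounded half-up."""
    if not 0 <= unique <= reference_size:
        raise ValueError(f"unique={unique} outside [0, {reference_size}]")
    return int(round_half_up_ratio(unique, reference_size, 0))


def duplication_level(marker_counts: Counter) -> tuple[int, float]:
    """(number of markers seen >= 2 times, total hits / unique markers).

    The ratio is 1.0 for a clean single-copy bin and 0.0 when the bin has no
    markers at all (undefined, reported as 0 by convention).
    """
    unique = len(marker_counts)
    if unique == 0:
        return 0, 0.0
    total = sum(marker_counts.values())
    duplicated = sum(1 for n in marker_counts.values() if n >= 2)
    return duplicated, total / unique


def census_report(c: MarkerCensus) -> pd.DataFrame:
    """Census table augmented with completeness and duplication columns."""
    rows = []
    for b, row in c.table.iterrows():
        dup_n, dup_ratio = duplication_level(c.marker_counts[b])
        rows.append({
            "bin": b,
            "unique_markers": int(row["unique_markers"]),
            "total_hits": int(row["total_hits"]),
            "reference_size": int(row["reference_size"]),
            "completeness_percent": completeness(
                int(row["unique_markers"]), int(row["reference_size"])
            ),
            "duplicated_markers": dup_n,
            "duplication_ratio": round(dup_ratio, 4),
        })
    return pd.DataFrame(rows).set_index("bin")


def read_hits_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = {"scaffold", "marker_id"} - set(df.columns)
    if missing:
        raise ValueError(f"hit table {path} missing columns {sorted(missing)}")
    return df


def read_hmmer_tblout(path: str | Path,
                      orf_to_scaffold: Callable[[str], str] | None = None) -> pd.DataFrame:
    """Adapter for HMMER3 ``--tblout`` files.

    The target name column holds the ORF id; ``orf_to_scaffold`` maps it to
    its scaffold (default: strip the final ``_<n>`` suffix, the common
    gene-caller convention).
    """
    if orf_to_scaffold is None:
        orf_to_scaffold = lambda orf: orf.rsplit("_", 1)[0]
    rows = []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            parts = line.split()
            if len(parts) < 6:
                continue
            rows.append({
                "scaffold": orf_to_scaffold(parts[0]),
                "marker_id": parts[2],
                "start": 0,
                "end": 0,
                "score": float(parts[5]),
            })
    return pd.DataFrame(rows, columns=list(HIT_COLUMNS))
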