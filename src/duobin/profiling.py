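"""Rank-level relative-abundance profiles and two-condition comparison.

Community profilers emit clade tables: one row per lineage string
(``k__Bacteria;p__Proteobacteria;...``) per sample, with either read counts
or pre-normalized percentages. Both are treated the same here — abundances
are summed within each clade at the requested rank and renormalized to 100
per sample — so count tables and percentage tables flow through one rollup.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .taxonomy import RANKS, parse_lineage

#: Pseudocount (in percent) substituted for zeros when forming abundance ratios.
RATIO_PSEUDOCOUNT = 1e-4


@dataclass
class RankProfile:
    """Relative abundances at one taxonomic rank.

    ``table`` is clades x samples; each sample column sums to 100 (within
    float tolerance) whenever the sample has any nonzero clade.
    """

    rank: str
    table: pd.DataFrame


def read_clade_table(path: str | Path) -> pd.DataFrame:
    """Read a wide clade table (lineage column + one column per sample) into
    tidy form (lineage, sample, abundance)."""
    wide = pd.read_csv(path, sep="\t", comment="#")
    lineage_col = wide.columns[0]
    tidy = wide.melt(id_vars=[lineage_col], var_name="sample", value_name="abundance")
    tidy = tidy.rename(columns={lineage_col: "lineage"})
    return tidy


def rollup(table: pd.DataFrame, rank: str) -> RankProfile:
    """Sum abundances within each clade at ``rank`` and normalize to 100%.

    ``table`` is tidy: columns ``lineage``, ``sample``, ``abundance``. Rows
    whose lineage does not reach the rank raise a row-level error (the rank
    must be present, per the profiler's output contract).
    """
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    clades = []
    for i, lineage in enumerate(table["lineage"]):
        try:
            named = parse_lineage(lineage)
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
        if rank not in named:
            raise ValueError(f"row {i}: lineage {lineage!r} has no {rank} field")
        clades.append(named[rank])
    if (table["abundance"] < 0).any():
        bad = int(np.argmax(table["abundance"].to_numpy() < 0))
        raise ValueError(f"row {bad}: negative abundance")

    df = table.assign(clade=clades)
    agg = df.pivot_table(index="clade", columns="sample", values="abundance",
                         aggfunc="sum", fill_value=0.0)
    agg.columns.name = None
    totals = agg.sum(axis=0)
    norm = agg.copy()
    for col in norm.columns:
        if totals[col] > 0:
            norm[col] = 100.0 * norm[col] / totals[col]
    return RankProfile(rank=rank, table=norm.sort_index())


def compare(profile: RankProfile, sample_a: str, sample_b: str,
            pseudocount: float = RATIO_PSEUDOCOUNT) -> pd.DataFrame:
    """Per-clade presence pattern, difference and ratio between two samples.

    Clades are classified ``shared`` / ``a_only`` / ``b_only`` / ``absent``
    on strict nonzero presence; the ratio uses ``pseudocount`` (percent) in
    place of zeros so it stays finite.
    """
    t = profile.table
    for s in (sample_a, sample_b):
        if s not in t.columns:
            raise ValueError(f"sample {s!r} not in profile (has {list(t.columns)})")
    a, b = t[sample_a], t[sample_b]
    pattern = np.select(
        [(a > 0) & (b > 0), (a > 0), (b > 0)],
        ["shared", "a_only", "b_only"],
        default="absent",
    )
    ratio = np.maximum(a, pseudocount) / np.maximum(b, pseudocount)
    return pd.DataFrame({
        sample_a: a, sample_b: b, "pattern": pattern,
        "difference": a - b, "ratio": ratio,
    })


def compare_profiles(profile_a: RankProfile, profile_b: RankProfile,
                     pseudocount: float = RATIO_PSEUDOCOUNT) -> pd.DataFrame:
    """Compare two single-sample profiles of the same rank."""
    if profile_a.rank != profile_b.rank:
        raise ValueError(
            f"rank mismatch: {profile_a.rank!r} vs {profile_b.rank!r}"
        )
    a = profile_a.table.iloc[:, 0]
    b = profile_b.table.iloc[:, 0]
    merged = pd.concat({"A": a, "B": b}, axis=1).fillna(0.0)
    prof = RankProfile(profile_a.rank, merged)
    return compare(prof, "A", "B", pseudocount=pseudocount)
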