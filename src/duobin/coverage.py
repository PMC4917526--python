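"""Per-scaffold coverage from per-base depth tables, cross-sample
normalization, and coverage-weighted functional-category abundance.

Coverage of a scaffold in a sample is its mean per-base read depth. With two
samples sequenced at different depths, raw coverages are made comparable by
scaling each sample by ``min(aligned reads) / aligned reads``, so the sample
with fewer aligned reads is the reference and keeps its raw values — the
convention the downstream differential-coverage binner assumes.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd


class DepthTable:
    """Dense per-base depth for a set of scaffolds in one sample.

    The on-disk dialect is the 3-column BED-style table ``(scaffold,
    0-based position, depth)``; positions omitted from the file count as
    depth zero (the sparse genomecov convention).
    """

    def __init__(self, depths: Mapping[str, np.ndarray]):
        self.depths = {k: np.asarray(v, dtype=np.int64) for k, v in depths.items()}
        for name, arr in self.depths.items():
            if (arr < 0).any():
                raise ValueError(f"negative depth on scaffold {name!r}")

    def __iter__(self) -> Iterator[str]:
        return iter(self.depths)

    def mean(self) -> pd.Series:
        return pd.Series(
            {k: (v.mean() if v.size else 0.0) for k, v in self.depths.items()},
            name="coverage",
        )

    def total_bases(self) -> int:
        """Total sequenced bases represented (sum of all depths)."""
        return int(sum(int(v.sum()) for v in self.depths.values()))

    @classmethod
    def from_records(cls, records: pd.DataFrame, lengths: Mapping[str, int]) -> "DepthTable":
        """Build from sparse (scaffold, position, depth) rows.

        Scaffolds present in ``lengths`` but absent from the records get
        all-zero depth. Positions at or beyond the scaffold length are a
        validation error.
        """
        depths = {name: np.zeros(int(L), dtype=np.int64) for name, L in lengths.items()}
        for scaf, grp in records.groupby("scaffold", sort=False):
            if scaf not in depths:
                raise ValueError(f"depth records for unknown scaffold {scaf!r}")
            pos = grp["position"].to_numpy(dtype=np.int64)
            if pos.size and (pos.max() >= len(depths[scaf]) or pos.min() < 0):
                raise ValueError(
                    f"position out of range for scaffold {scaf!r} "
                    f"(length {len(depths[scaf])})"
                )
            depths[scaf][pos] = grp["depth"].to_numpy(dtype=np.int64)
        return cls(depths)

    @classmethod
    def read_tsv(cls, path: str | Path, lengths: Mapping[str, int]) -> "DepthTable":
        records = pd.read_csv(
            path, sep="\t", comment="#",
            names=["scaffold", "position", "depth"], header=None,
            dtype={"scaffold": str, "position": np.int64, "depth": np.int64},
        )
        return cls.from_records(records, lengths)

    def to_tsv(self, path: str | Path, sparse: bool = True) -> None:
        """Write 3-column depth rows; ``sparse`` omits zero-depth positions."""
        with open(path, "w") as fh:
            fh.write("# scaffold\tposition\tdepth (0-based; omitted positions = 0)\n")
            for name in self.depths:
                arr = self.depths[name]
                pos = np.nonzero(arr)[0] if sparse else np.arange(arr.size)
                col = arr[pos]
                block = pd.DataFrame({"s": name, "p": pos, "d": col})
                block.to_csv(fh, sep="\t", header=False, index=False)


def mean_coverage(depth: DepthTable | pd.DataFrame, lengths: Mapping[str, int]) -> pd.Series:
    """Mean per-base depth per scaffold: (sum of depths) / length.

    Accepts a dense :class:`DepthTable` or sparse records; scaffolds with no
    depth rows get coverage 0. Every scaffold in the depth input must have a
    known length.
    """
    if isinstance(depth, pd.DataFrame):
        depth = DepthTable.from_records(depth, lengths)
    missing = set(depth.depths) - set(lengths)
    if missing:
        raise ValueError(f"scaffolds without known length: {sorted(missing)[:5]}")
    out = {}
    for name, L in lengths.items():
        arr = depth.depths.get(name)
        if arr is None:
            out[name] = 0.0
            continue
        if arr.size != int(L):
            raise ValueError(
                f"depth array length {arr.size} != scaffold length {L} for {name!r}"
            )
        out[name] = float(arr.sum()) / float(L)
    return pd.Series(out, name="coverage")


@dataclass
class CoverageMatrix:
    """Per-scaffold coverage in each sample, raw and (optionally) normalized."""

    raw: pd.DataFrame  # scaffolds x samples
    aligned_reads: dict[str, int]
    normalized: pd.DataFrame | None = None

    @property
    def samples(self) -> list[str]:
        return list(self.raw.columns)

    def require_normalized(self) -> pd.DataFrame:
        if self.normalized is None:
            raise ValueError("coverage matrix is not normalized; call normalize()")
        return self.normalized


def normalize(cov: CoverageMatrix) -> CoverageMatrix:
    """Scale each sample by min(aligned reads)/aligned reads.

    The sample with the fewest aligned reads is the reference (factor 1);
    deeper samples are scaled down, making coverages comparable across
    samples. Idempotent when aligned read counts are equal.
    """
    for s in cov.samples:
        if cov.aligned_reads.get(s, 0) <= 0:
            raise ValueError(f"sample {s!r}: aligned read count must be positive")
    ref = min(cov.aligned_reads[s] for s in cov.samples)
    factors = {s: ref / cov.aligned_reads[s] for s in cov.samples}
    norm = cov.raw.mul(pd.Series(factors), axis=1)
    return replace(cov, normalized=norm)


def functional_abundance(genes: pd.DataFrame, cov: CoverageMatrix, sample: str,
                         use: str = "normalized") -> pd.DataFrame:
    """Coverage-weighted abundance of functional categories in one sample.

    ``genes`` has columns ``gene``, ``scaffold``, ``categories`` (a string of
    ``;``-separated labels or a list). A gene contributes its host scaffold's
    coverage to every category it carries; gene counts weight every gene
    equally. Returns rows (category, gene_count, abundance, mean_coverage).
    """
    table = cov.require_normalized() if use == "normalized" else cov.raw
    if sample not in table.columns:
        raise ValueError(f"unknown sample {sample!r}")
    covs = table[sample]
    unknown = set(genes["scaffold"]) - set(covs.index)
    if unknown:
        raise ValueError(f"genes on unknown scaffolds: {sorted(unknown)[:5]}")

    acc: dict[str, list[float]] = {}
    for scaf, cats in zip(genes["scaffold"], genes["categories"]):
        labels = cats if isinstance(cats, (list, tuple)) else str(cats).split(";")
        c = float(covs[scaf])
        for label in labels:
            label = label.strip()
            if label:
                acc.setdefault(label, []).append(c)
    rows = [
        {
            "category": label,
            "gene_count": len(vals),
            "abundance": float(np.sum(vals)),
            "mean_coverage": float(np.mean(vals)),
        }
        for label, vals in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=["category", "gene_count", "abundance", "mean_coverage"])
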