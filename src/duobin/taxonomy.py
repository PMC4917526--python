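"""Taxonomic assignment of genome bins from marker-gene identity evidence.

Rank is assigned from the mean nucleotide identity of a bin's essential
genes to their database best hits: >=95% supports a species-level call,
>=85% genus, >=75% phylum (thresholds inclusive). Bins below 75% fall back
to protein-level evidence and phylogenomic placement, combined by taking the
deepest rank at which the two lineages agree (placement is only trusted at
high or medium confidence); if they diverge, the call is made at their
deepest common ancestor.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, NamedTuple

import numpy as np
import pandas as pd

RANKS: tuple[str, ...] = (
    "kingdom", "phylum", "class", "order", "family", "genus", "species",
)
_PREFIXES = {"k": "kingdom", "p": "phylum", "c": "class", "o": "order",
             "f": "family", "g": "genus", "s": "species"}

SPECIES_THRESHOLD = 95.0
GENUS_THRESHOLD = 85.0
PHYLUM_THRESHOLD = 75.0

PLACEMENT_CONFIDENCES = ("high", "medium", "low", "incomplete")


class NoEvidenceError(ValueError):
    """Raised when a bin has no usable taxonomic evidence at all."""


def parse_lineage(lineage: str) -> dict[str, str]:
    """Parse ``k__X;p__Y;...`` into {rank: name}, skipping empty fields."""
    out: dict[str, str] = {}
    if not lineage:
        return out
    for field in lineage.split(";"):
        field = field.strip()
        if not field:
            continue
        if len(field) < 3 or field[1:3] != "__":
            raise ValueError(f"malformed lineage field {field!r} in {lineage!r}")
        rank = _PREFIXES.get(field[0].lower())
        if rank is None:
            raise ValueError(f"unknown rank prefix {field[0]!r} in {lineage!r}")
        name = field[3:]
        if name:
            out[rank] = name
    return out


def format_lineage(named: dict[str, str], depth: str | None = None) -> str:
    """Inverse of :func:`parse_lineage`, optionally truncated at ``depth``."""
    stop = RANKS.index(depth) if depth is not None else len(RANKS) - 1
    fields = []
    for rank in RANKS[: stop + 1]:
        if rank in named:
            fields.append(f"{rank[0]}__{named[rank]}")
    return ";".join(fields)


def lineage_depth(named: dict[str, str]) -> str | None:
    """Deepest rank present in a parsed lineage (None when empty)."""
    deepest = None
    for rank in RANKS:
        if rank in named:
            deepest = rank
    return deepest


def common_ancestor_rank(a: dict[str, str], b: dict[str, str]) -> str | None:
    """Deepest rank at which two lineages agree along the full path.

    Agreement must be consecutive from the kingdom down; the first rank where
    both are named but differ stops the walk.
    """
    deepest = None
    for rank in RANKS:
        na, nb = a.get(rank), b.get(rank)
        if na is None or nb is None:
            continue
        if na != nb:
            break
        deepest = rank
    return deepest


class MeanIdentity(NamedTuple):
    nt: float | None
    aa: float | None
    n_genes: int
    n_no_hit_nt: int
    n_no_hit_aa: int


def mean_identity(evidence: pd.DataFrame) -> MeanIdentity:
    """Arithmetic mean identity over essential genes with hits.

    ``evidence`` needs ``nt_identity`` and/or ``aa_identity`` columns; NaN
    marks a gene without a database hit and is excluded from the mean (the
    excluded count is reported rather than scored as zero, which would
    penalize database incompleteness).
    """
    if len(evidence) == 0:
        raise NoEvidenceError("empty evidence table")
    out = {}
    misses = {}
    for col in ("nt_identity", "aa_identity"):
        if col in evidence.columns:
            vals = pd.to_numeric(evidence[col], errors="coerce")
            ok = vals.dropna()
            out[col] = float(ok.mean()) if len(ok) else None
            misses[col] = int(vals.isna().sum())
        else:
            out[col] = None
            misses[col] = len(evidence)
    if out["nt_identity"] is None and out["aa_identity"] is None:
        raise NoEvidenceError("no identity values in evidence table")
    return MeanIdentity(out["nt_identity"], out["aa_identity"], len(evidence),
                        misses["nt_identity"], misses["aa_identity"])


def assign_rank(nt_identity: float) -> str | None:
    """Rank supported by a mean nucleotide identity; None below 75%."""
    if not 0.0 <= nt_identity <= 100.0:
        raise ValueError(f"identity {nt_identity} outside [0, 100]")
    if nt_identity >= SPECIES_THRESHOLD:
        return "species"
    if nt_identity >= GENUS_THRESHOLD:
        return "genus"
    if nt_identity >= PHYLUM_THRESHOLD:
        return "phylum"
    return None


@dataclass(frozen=True)
class TaxonAssignment:
    bin_id: object
    rank: str | None
    lineage: str
    method: str  # nucleotide | protein | placement | consensus
    nt_identity: float | None = None
    aa_identity: float | None = None


def consensus(bin_id, nt_identity: float | None = None, nt_lineage: str = "",
              aa_identity: float | None = None, protein_lineage: str = "",
              placement_lineage: str = "", placement_confidence: str | None = None,
              ) -> TaxonAssignment:
    """Combine nucleotide, protein and placement evidence into one call.

    The nucleotide rank is taken outright when it reaches genus or species.
    Otherwise protein and placement lineages decide: their deepest point of
    agreement (placement requires high/medium confidence). A phylum-level
    nucleotide call acts as a floor when the fallback cannot do better.
    """
    nt_rank = assign_rank(nt_identity) if nt_identity is not None else None
    nt_named = parse_lineage(nt_lineage)
    if nt_rank in ("species", "genus"):
        return TaxonAssignment(
            bin_id, nt_rank, format_lineage(nt_named, nt_rank), "nucleotide",
            nt_identity, aa_identity,
        )

    prot_named = parse_lineage(protein_lineage)
    placement_ok = (
        placement_confidence in ("high", "medium") and bool(placement_lineage)
    )
    place_named = parse_lineage(placement_lineage) if placement_ok else {}

    fallback_rank: str | None = None
    fallback_named: dict[str, str] = {}
    method = "nucleotide"
    if prot_named and place_named:
        fallback_rank = common_ancestor_rank(prot_named, place_named)
        fallback_named = prot_named
        method = "consensus"
    elif prot_named:
        fallback_rank = lineage_depth(prot_named)
        fallback_named = prot_named
        method = "protein"
    elif place_named:
        fallback_rank = lineage_depth(place_named)
        fallback_named = place_named
        method = "placement"

    def depth(r: str | None) -> int:
        return RANKS.index(r) if r is not None else -1

    if depth(fallback_rank) > depth(nt_rank):
        return TaxonAssignment(
            bin_id, fallback_rank, format_lineage(fallback_named, fallback_rank),
            method, nt_identity, aa_identity,
        )
    if nt_rank is not None:
        return TaxonAssignment(
            bin_id, nt_rank, format_lineage(nt_named, nt_rank), "nucleotide",
            nt_identity, aa_identity,
        )
    raise NoEvidenceError(f"bin {bin_id}: no usable taxonomic evidence")


def assign_bins(evidence: pd.DataFrame, bin_col: str = "bin") -> pd.DataFrame:
    """Run mean-identity + consensus per bin over a long evidence table.

    Expected columns: ``bin``, ``nt_identity``, ``aa_identity``, ``lineage``
    (subject lineage used for both nucleotide and protein evidence when
    separate columns are not given), optional ``placement_lineage`` and
    ``placement_confidence`` (constant within a bin).
    """
    rows = []
    for b, grp in evidence.groupby(bin_col, sort=True):
        mi = mean_identity(grp)
        lineage = grp["lineage"].mode().iat[0] if "lineage" in grp else ""
        placement = (
            grp["placement_lineage"].iloc[0]
            if "placement_lineage" in grp else ""
        )
        confidence = (
            grp["placement_confidence"].iloc[0]
            if "placement_confidence" in grp else None
        )
        ta = consensus(
            b, nt_identity=mi.nt, nt_lineage=lineage,
            aa_identity=mi.aa, protein_lineage=lineage,
            placement_lineage=placement, placement_confidence=confidence,
        )
        rows.append({
            "bin": b, "rank": ta.rank, "lineage": ta.lineage, "method": ta.method,
            "nt_identity": None if mi.nt is None else round(mi.nt, 2),
            "aa_identity": None if mi.aa is None else round(mi.aa, 2),
            "n_genes": mi.n_genes, "n_no_hit_nt": mi.n_no_hit_nt,
        })
    return pd.DataFrame(rows).set_index("bin")
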