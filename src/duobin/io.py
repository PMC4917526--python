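"""FASTA and TSV input/output helpers.

All on-disk formats are plain text: FASTA for scaffolds, tab-separated tables
for everything else. Sequence IO goes through Biopython.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord


def read_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered {id: sequence} mapping.

    Raises ``ValueError`` on duplicate ids (scaffold ids must be unique to
    serve as table keys downstream).
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seqs:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    records = (SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items())
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def seq_gc(seq: str) -> float:
    """GC fraction of a sequence, ignoring non-ACGT symbols."""
    s = seq.upper()
    gc = s.count("G") + s.count("C")
    acgt = gc + s.count("A") + s.count("T")
    return gc / acgt if acgt else 0.0


def scaffold_lengths(seqs: Mapping[str, str]) -> pd.Series:
    return pd.Series({k: len(v) for k, v in seqs.items()}, name="length")


def read_tsv(path: str | Path, **kwargs) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", **kwargs)


def write_tsv(df: pd.DataFrame, path: str | Path, header_comment: str | None = None,
              index: bool = False) -> None:
    with open(path, "w") as fh:
        if header_comment:
            for line in header_comment.splitlines():
                fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def read_lengths_tsv(path: str | Path) -> pd.Series:
    df = read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"length table {path} needs two columns (scaffold, length)")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="length")


def validate_fasta(path: str | Path) -> list[str]:
    """Line-level diagnostics for a FASTA file; empty list means clean."""
    diags: list[str] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            diags.append(f"duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        if len(rec.seq) == 0:
            diags.append(f"empty sequence for id {rec.id!r}")
        bad = set(str(rec.seq).upper()) - set("ACGTN")
        if bad:
            diags.append(f"non-ACGTN symbols {sorted(bad)} in {rec.id!r}")
    if not seen:
        diags.append("no sequences found")
    return diags


def validate_depth_tsv(path: str | Path, lengths: Mapping[str, int]) -> list[str]:
    """Check a 3-column per-base depth table against known scaffold lengths."""
    diags: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                diags.append(f"line {lineno}: expected 3 columns, got {len(parts)}")
                continue
            scaf, pos_s, depth_s = parts[0], parts[1], parts[2]
            try:
                pos, depth = int(pos_s), int(depth_s)
            except ValueError:
                diags.append(f"line {lineno}: non-integer position/depth")
                continue
            if depth < 0:
                diags.append(f"line {lineno}: negative depth {depth}")
            if scaf not in lengths:
                diags.append(f"line {lineno}: unknown scaffold {scaf!r}")
            elif pos >= lengths[scaf]:
                diags.append(
                    f"line {lineno}: position {pos} >= length {lengths[scaf]} of {scaf!r}"
                )
    return diags
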