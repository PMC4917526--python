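"""Synthetic two-sample metagenome community generator.

Produces everything the binning pipeline consumes — scaffold FASTA, per-base
depth tables for two samples, marker-gene hit tables, paired-end link graphs,
taxonomic identity evidence — together with a ground-truth table, so recovery
can be scored exactly.

Model
-----
Each genome is an order-k Markov chain (k >= 1, default 1) over {A,C,G,T}.
Transition rows are drawn per genome from a Dirichlet centred on the
GC-constrained base composition and then rescaled so that every row's
probability of emitting G or C equals the genome's GC target exactly; the
realized GC therefore lands within a fraction of a percentage point of the
target while the within-AT / within-GC structure varies genome to genome,
giving each genome a distinguishable tetranucleotide signature.

Scaffold lengths are lognormal (configurable mean and dispersion) truncated
at the 500 bp assembly convention; per-base depths are Poisson with the
genome's per-sample mean coverage as rate; markers are abstract interval
annotations on the genome's scaffolds; paired-end links connect consecutive
scaffolds of a genome.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from . import io
from .coverage import DepthTable
from .markers import ESSENTIAL_GENE_IDS

READ_LENGTH = 100  # bp, used to convert simulated depth into aligned-read counts
MIN_SCAFFOLD_LENGTH = 500

_DECODE = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class Fragmentation:
    """Lognormal scaffold-length model (mean in bp, lognormal sigma)."""

    mean_length: float
    sigma: float = 0.25


@dataclass
class GenomeSpec:
    """Parameters of one synthetic genome.

    ``abundance`` is the genome's mean per-base coverage in each sample, in
    the order of ``CommunitySpec.samples``.
    """

    name: str
    length: int
    gc_target: float
    abundance: tuple[float, float]
    fragmentation: Fragmentation
    markov_order: int = 1
    markov_concentration: float = 20.0
    n_markers_present: int = 0
    n_markers_duplicated: int = 0
    lineage: str = ""
    nt_identity: float | None = None
    aa_identity: float | None = None

    def validate(self, n_markers_reference: int = len(ESSENTIAL_GENE_IDS)) -> None:
        if self.length <= 0:
            raise ValueError(f"{self.name}: genome length must be positive")
        if not 0.0 < self.gc_target < 1.0:
            raise ValueError(f"{self.name}: gc_target must be in (0, 1)")
        if self.markov_order < 1:
            raise ValueError(f"{self.name}: markov_order must be >= 1")
        if any(a < 0 for a in self.abundance):
            raise ValueError(f"{self.name}: abundances must be >= 0")
        if self.length < 10 * self.fragmentation.mean_length:
            raise ValueError(
                f"{self.name}: length must be >= 10x mean scaffold length"
            )
        if self.n_markers_present > n_markers_reference:
            raise ValueError(
                f"{self.name}: {self.n_markers_present} markers requested but the "
                f"reference set has {n_markers_reference}"
            )
        if not 0 <= self.n_markers_duplicated <= self.n_markers_present:
            raise ValueError(f"{self.name}: duplicated markers exceed planted markers")


@dataclass
class CommunitySpec:
    """A two-sample synthetic community: genomes, sample names, global seed."""

    genomes: list[GenomeSpec]
    samples: tuple[str, str] = ("sample_1", "sample_2")
    seed: int = 0

    def validate(self) -> None:
        if len(self.samples) != 2:
            raise ValueError("exactly 2 samples are required")
        if len(self.genomes) < 2:
            raise ValueError("at least 2 genomes are required")
        names = [g.name for g in self.genomes]
        if len(set(names)) != len(names):
            raise ValueError("genome names must be unique")
        for g in self.genomes:
            g.validate()


def _transition_matrix(gc: float, order: int, concentration: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Per-context next-base probabilities with exact GC mass per row."""
    base = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    n_ctx = 4 ** order
    rows = rng.dirichlet(concentration * base + 1e-3, size=n_ctx)
    # rescale so P(next in {C,G}) == gc exactly in every row
    at = rows[:, [0, 3]].sum(axis=1)
    cg = rows[:, [1, 2]].sum(axis=1)
    rows[:, [0, 3]] *= ((1 - gc) / at)[:, None]
    rows[:, [1, 2]] *= (gc / cg)[:, None]
    return rows


def generate_genome(spec: GenomeSpec, rng: np.random.Generator) -> str:
    """Sample one genome sequence from the spec's Markov model."""
    spec.validate()
    order = spec.markov_order
    T = _transition_matrix(spec.gc_target, order, spec.markov_concentration, rng)
    cum = np.cumsum(T, axis=1)
    cum[:, -1] = 1.0
    cum_rows = cum.tolist()

    base = np.array([(1 - spec.gc_target) / 2, spec.gc_target / 2,
                     spec.gc_target / 2, (1 - spec.gc_target) / 2])
    out = np.empty(spec.length, dtype=np.uint8)
    head = rng.choice(4, size=min(order, spec.length), p=base)
    out[: head.size] = head
    if spec.length > order:
        ctx = 0
        for b in head:
            ctx = ctx * 4 + int(b)
        u = rng.random(spec.length).tolist()
        buf = out  # local alias; filled via a plain python loop (fast enough
        # at the few-Mb scale this generator targets)
        mod = 4 ** (order - 1)
        for i in range(order, spec.length):
            row = cum_rows[ctx]
            x = u[i]
            b = 0 if x < row[0] else 1 if x < row[1] else 2 if x < row[2] else 3
            buf[i] = b
            ctx = (ctx % mod) * 4 + b
    return _DECODE[out].tobytes().decode("ascii")


def fragment_genome(sequence: str, fragmentation: Fragmentation,
                    min_len: int = MIN_SCAFFOLD_LENGTH, name: str = "genome",
                    rng: np.random.Generator | None = None) -> dict[str, str]:
    """Cut a genome into scaffolds covering a prefix of the sequence.

    Lengths are lognormal with the requested mean, truncated below at
    ``min_len``; a trailing remainder shorter than ``min_len`` is dropped
    (scaffolds partition a prefix, never exceed the genome).
    """
    if min_len < 1:
        raise ValueError("min_len must be >= 1")
    if fragmentation.mean_length < min_len:
        raise ValueError(
            f"mean scaffold length {fragmentation.mean_length} below min_len {min_len}"
        )
    rng = rng or np.random.default_rng(0)
    sigma = fragmentation.sigma
    mu = np.log(fragmentation.mean_length) - sigma ** 2 / 2.0
    scaffolds: dict[str, str] = {}
    pos, i = 0, 1
    n = len(sequence)
    while n - pos >= min_len:
        L = int(max(min_len, round(float(rng.lognormal(mu, sigma)))))
        L = min(L, n - pos)
        if L < min_len:
            break
        scaffolds[f"{name}_s{i:04d}"] = sequence[pos: pos + L]
        pos += L
        i += 1
    return scaffolds


def simulate_depth(scaffold_lengths: Mapping[str, int],
                   scaffold_abundance: Mapping[str, float],
                   noise_model: str = "poisson",
                   rng: np.random.Generator | None = None) -> DepthTable:
    """Per-base depth for one sample.

    ``noise_model='poisson'`` draws independent Poisson depths with the
    scaffold's abundance as rate; ``'none'`` emits the (rounded) abundance at
    every base. Expected mean depth equals the abundance in both cases.
    """
    if noise_model not in ("poisson", "none"):
        raise ValueError(f"unknown noise model {noise_model!r}")
    rng = rng or np.random.default_rng(0)
    depths = {}
    for name, L in scaffold_lengths.items():
        ab = float(scaffold_abundance[name])
        if ab < 0:
            raise ValueError(f"negative abundance for scaffold {name!r}")
        if noise_model == "none":
            depths[name] = np.full(int(L), int(round(ab)), dtype=np.int64)
        else:
            depths[name] = rng.poisson(ab, size=int(L)).astype(np.int64)
    return DepthTable(depths)


def plant_markers(spec: GenomeSpec, scaffolds: Mapping[str, str],
                  rng: np.random.Generator,
                  marker_ids: Sequence[str] = ESSENTIAL_GENE_IDS) -> pd.DataFrame:
    """Place the spec's markers as interval annotations on its scaffolds.

    Exactly ``n_markers_present`` distinct marker ids are placed once each;
    the first ``n_markers_duplicated`` of them receive a second placement.
    Rows: (scaffold, marker_id, start, end, score).
    """
    spec.validate(n_markers_reference=len(marker_ids))
    names = list(scaffolds)
    if spec.n_markers_present and not names:
        raise ValueError(f"{spec.name}: markers requested but no scaffolds")
    chosen_idx = rng.choice(len(marker_ids), size=spec.n_markers_present, replace=False)
    chosen = [marker_ids[i] for i in sorted(chosen_idx)]
    dup_idx = rng.choice(len(chosen), size=spec.n_markers_duplicated, replace=False) \
        if spec.n_markers_duplicated else np.array([], dtype=int)
    placements = list(chosen) + [chosen[i] for i in sorted(dup_idx)]
    rows = []
    for marker in placements:
        scaf = names[int(rng.integers(len(names)))]
        L = len(scaffolds[scaf])
        glen = min(600, max(1, L - 2))
        start = int(rng.integers(0, max(1, L - glen)))
        rows.append({
            "scaffold": scaf, "marker_id": marker,
            "start": start, "end": start + glen,
            "score": float(np.round(rng.uniform(50, 300), 1)),
        })
    return pd.DataFrame(rows, columns=["scaffold", "marker_id", "start", "end", "score"])


@dataclass
class Community:
    """A realized synthetic community and all its derived tables."""

    spec: CommunitySpec
    scaffolds: dict[str, str]
    truth: pd.DataFrame             # scaffold, genome, order, length, gc
    depth: dict[str, DepthTable]    # per sample
    marker_hits: pd.DataFrame
    links: pd.DataFrame             # scaffold_a, scaffold_b, weight
    identity_evidence: pd.DataFrame
    aligned_reads: dict[str, int]

    def scaffold_lengths(self) -> pd.Series:
        return io.scaffold_lengths(self.scaffolds)

    def truth_membership(self) -> dict[str, str]:
        return dict(zip(self.truth["scaffold"], self.truth["genome"]))

    def write(self, outdir: str | Path, write_depth: bool = False) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        seed_note = f"seed={self.spec.seed}"
        io.write_fasta(self.scaffolds, outdir / "scaffolds.fasta")
        io.write_tsv(self.truth, outdir / "truth.tsv", header_comment=seed_note)
        io.write_tsv(self.marker_hits, outdir / "marker_hits.tsv", header_comment=seed_note)
        io.write_tsv(self.links, outdir / "links.tsv", header_comment=seed_note)
        io.write_tsv(self.identity_evidence, outdir / "identity_evidence.tsv",
                     header_comment=seed_note)
        pd.Series(self.aligned_reads, name="aligned_reads").rename_axis("sample") \
            .to_frame().to_csv(outdir / "aligned_reads.tsv", sep="\t")
        if write_depth:
            for sample, table in self.depth.items():
                table.to_tsv(outdir / f"depth_{sample}.tsv")
        (outdir / "community_spec.json").write_text(spec_to_json(self.spec))


def simulate_community(spec: CommunitySpec, noise_model: str = "poisson") -> Community:
    """Realize a full community: sequences, depths, markers, links, truth."""
    spec.validate()
    ss = np.random.SeedSequence(spec.seed)
    genome_seeds = ss.spawn(len(spec.genomes))
    sample_seeds = ss.spawn(len(spec.samples))
    link_seed = ss.spawn(1)[0]

    scaffolds: dict[str, str] = {}
    truth_rows = []
    marker_frames = []
    evidence_rows = []
    link_rows = []
    scaffold_abundance: dict[str, dict[str, float]] = {s: {} for s in spec.samples}

    link_rng = np.random.Generator(np.random.PCG64(link_seed))
    for g, gseed in zip(spec.genomes, genome_seeds):
        rng = np.random.Generator(np.random.PCG64(gseed))
        seq = generate_genome(g, rng)
        frags = fragment_genome(seq, g.fragmentation, name=g.name, rng=rng)
        names = list(frags)
        for order_i, (scaf, s) in enumerate(frags.items(), start=1):
            scaffolds[scaf] = s
            truth_rows.append({
                "scaffold": scaf, "genome": g.name, "order": order_i,
                "length": len(s), "gc": round(io.seq_gc(s), 4),
            })
            for sample, ab in zip(spec.samples, g.abundance):
                scaffold_abundance[sample][scaf] = ab
        hits = plant_markers(g, frags, rng)
        marker_frames.append(hits)
        if g.nt_identity is not None:
            for _, h in hits.iterrows():
                evidence_rows.append({
                    "scaffold": h["scaffold"], "gene": h["marker_id"],
                    "nt_identity": float(np.clip(rng.normal(g.nt_identity, 0.3), 0, 100)),
                    "aa_identity": float(np.clip(rng.normal(g.aa_identity, 0.3), 0, 100))
                    if g.aa_identity is not None else np.nan,
                    "lineage": g.lineage,
                })
        for a, b in zip(names[:-1], names[1:]):
            link_rows.append({
                "scaffold_a": a, "scaffold_b": b,
                "weight": int(1 + link_rng.poisson(9)),
            })

    lengths = {k: len(v) for k, v in scaffolds.items()}
    depth = {}
    aligned = {}
    for sample, sseed in zip(spec.samples, sample_seeds):
        srng = np.random.Generator(np.random.PCG64(sseed))
        table = simulate_depth(lengths, scaffold_abundance[sample], noise_model, srng)
        depth[sample] = table
        aligned[sample] = max(1, table.total_bases() // READ_LENGTH)

    return Community(
        spec=spec,
        scaffolds=scaffolds,
        truth=pd.DataFrame(truth_rows),
        depth=depth,
        marker_hits=pd.concat(marker_frames, ignore_index=True)
        if marker_frames else pd.DataFrame(columns=["scaffold", "marker_id", "start", "end", "score"]),
        links=pd.DataFrame(link_rows, columns=["scaffold_a", "scaffold_b", "weight"]),
        identity_evidence=pd.DataFrame(
            evidence_rows,
            columns=["scaffold", "gene", "nt_identity", "aa_identity", "lineage"],
        ),
        aligned_reads=aligned,
    )


def spec_to_json(spec: CommunitySpec) -> str:
    d = asdict(spec)
    return json.dumps(d, indent=2)


def spec_from_json(text: str) -> CommunitySpec:
    d = json.loads(text)
    genomes = []
    for g in d["genomes"]:
        g = dict(g)
        g["fragmentation"] = Fragmentation(**g["fragmentation"])
        g["abundance"] = tuple(g["abundance"])
        genomes.append(GenomeSpec(**g))
    return CommunitySpec(genomes=genomes, samples=tuple(d["samples"]), seed=d["seed"])
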