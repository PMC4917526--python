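"""End-to-end workflow: simulate -> coverage -> TNF -> bin -> markers ->
taxonomy -> profile, with a consolidated per-bin report.

The report mirrors the conventional draft-genome summary table: one row per
kept bin with its dominant dataset, taxonomy, scaffold count, total length,
GC%, essential-gene census, completeness, per-sample coverage and mean
protein/nucleotide identities.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import io
from .binning import (NOISE, DifferentialCoverageBinner, bin_stats,
                      evaluate_against_truth, filter_bins)
from .coverage import CoverageMatrix, mean_coverage, normalize
from .markers import census, census_report
from .profiling import RankProfile, compare, rollup
from .synthetic import Community, CommunitySpec, simulate_community, spec_from_json
from .taxonomy import assign_bins
from .tnf import TNFPCA, tnf_matrix

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    ``community`` is either a :class:`CommunitySpec` or a path to its JSON
    form. Stage parameters default to each module's documented defaults;
    ``min_bin_size`` should be scaled with the community's genome sizes.
    """

    community: CommunitySpec | str | Path
    outdir: str | Path = "duobin_out"
    seed: int | None = None         # overrides the community spec seed
    noise_model: str = "poisson"
    n_components: int = 3
    binner_params: dict[str, Any] = field(default_factory=dict)
    min_completeness: float = 20.0
    min_bin_size: int = 1_000_000
    profile_rank: str = "phylum"
    write_depth: bool = False

    def resolve_spec(self) -> CommunitySpec:
        if isinstance(self.community, CommunitySpec):
            spec = self.community
        else:
            spec = spec_from_json(Path(self.community).read_text())
        if self.seed is not None:
            spec.seed = self.seed
        return spec


@dataclass
class PipelineResult:
    community: Community
    coverage: CoverageMatrix
    labels: pd.Series
    census_table: pd.DataFrame
    taxonomy: pd.DataFrame
    bin_report: pd.DataFrame
    rejected: pd.DataFrame
    profile: RankProfile
    profile_comparison: pd.DataFrame
    evaluation: pd.DataFrame


def _stage(name: str):
    logger.info("stage %s: start", name)
    return time.perf_counter()


def _done(name: str, t0: float, **counts) -> None:
    info = " ".join(f"{k}={v}" for k, v in counts.items())
    logger.info("stage %s: done in %.2fs %s", name, time.perf_counter() - t0, info)


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Run every stage on a (simulated) community and write all artifacts."""
    spec = config.resolve_spec()
    spec.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    t0 = _stage("simulate")
    community = simulate_community(spec, noise_model=config.noise_model)
    community.write(outdir, write_depth=config.write_depth)
    _done("simulate", t0, scaffolds=len(community.scaffolds))

    t0 = _stage("coverage")
    lengths = community.scaffold_lengths()
    raw = pd.DataFrame({
        s: mean_coverage(community.depth[s], lengths.to_dict())
        for s in spec.samples
    })
    cov = normalize(CoverageMatrix(raw=raw, aligned_reads=community.aligned_reads))
    io.write_tsv(
        cov.normalized.rename(columns=lambda s: f"norm_{s}").join(
            cov.raw.rename(columns=lambda s: f"raw_{s}")
        ).rename_axis("scaffold").reset_index(),
        outdir / "coverage.tsv", header_comment=f"seed={spec.seed}",
    )
    _done("coverage", t0, scaffolds=len(raw))

    t0 = _stage("tnf")
    tnf, excluded = tnf_matrix(community.scaffolds)
    pca = TNFPCA(n_components=config.n_components).fit(tnf)
    scores = pca.transform(tnf)
    io.write_tsv(scores.rename_axis("scaffold").reset_index(), outdir / "tnf_pca.tsv",
                 header_comment=f"seed={spec.seed} "
                 f"explained_variance={pca.explained_variance_ratio_.round(4).tolist()}")
    _done("tnf", t0, scaffolds=len(tnf), excluded=len(excluded))

    t0 = _stage("bin")
    binner = DifferentialCoverageBinner(**config.binner_params)
    labels = binner.fit_predict(cov.normalized, lengths=lengths,
                                pca_scores=scores, links=community.links)
    io.write_tsv(labels.rename("bin").rename_axis("scaffold").reset_index(),
                 outdir / "membership.tsv", header_comment=f"seed={spec.seed}")
    _done("bin", t0, bins=binner.n_bins_,
          noise=int((labels == NOISE).sum()))

    t0 = _stage("markers")
    membership = {s: int(b) for s, b in labels.items() if b != NOISE}
    cens = census(community.marker_hits, membership)
    cens_table = census_report(cens)
    io.write_tsv(cens_table.reset_index(), outdir / "marker_census.tsv",
                 header_comment=f"seed={spec.seed}")
    _done("markers", t0, bins=len(cens_table))

    t0 = _stage("taxonomy")
    ev = community.identity_evidence
    if len(ev):
        ev = ev.assign(bin=[membership.get(s, NOISE) for s in ev["scaffold"]])
        ev = ev[ev["bin"] != NOISE]
        taxonomy = assign_bins(ev) if len(ev) else pd.DataFrame()
    else:
        taxonomy = pd.DataFrame()
    if len(taxonomy):
        io.write_tsv(taxonomy.reset_index(), outdir / "taxonomy.tsv",
                     header_comment=f"seed={spec.seed}")
    _done("taxonomy", t0, bins=len(taxonomy))

    t0 = _stage("report")
    gc = pd.Series({k: io.seq_gc(v) for k, v in community.scaffolds.items()})
    stats = bin_stats(labels, lengths, gc, cov)
    stats = stats.join(cens_table, how="left")
    stats[["unique_markers", "total_hits"]] = (
        stats[["unique_markers", "total_hits"]].fillna(0).astype(int)
    )
    stats["completeness_percent"] = stats["completeness_percent"].fillna(0).astype(int)
    kept, rejected = filter_bins(stats, min_completeness=config.min_completeness,
                                 min_size=config.min_bin_size)
    report = _bin_report(kept, taxonomy, spec.samples)
    io.write_tsv(report.reset_index(), outdir / "bin_report.tsv",
                 header_comment=f"seed={spec.seed}")
    report.reset_index().to_json(outdir / "bin_report.json", orient="records", indent=2)
    if len(rejected):
        io.write_tsv(rejected.reset_index(), outdir / "rejected_bins.tsv",
                     header_comment=f"seed={spec.seed}")
    _done("report", t0, kept=len(kept), rejected=len(rejected))

    t0 = _stage("profile")
    profile, comparison = _community_profile(community, cov, config.profile_rank)
    io.write_tsv(profile.table.rename_axis("clade").reset_index(),
                 outdir / f"profile_{config.profile_rank}.tsv",
                 header_comment=f"seed={spec.seed}")
    io.write_tsv(comparison.rename_axis("clade").reset_index(),
                 outdir / "profile_comparison.tsv", header_comment=f"seed={spec.seed}")
    _done("profile", t0, clades=len(profile.table))

    evaluation = evaluate_against_truth(labels, community.truth_membership(), lengths)
    io.write_tsv(evaluation.reset_index(), outdir / "evaluation.tsv",
                 header_comment=f"seed={spec.seed}")

    return PipelineResult(
        community=community, coverage=cov, labels=labels, census_table=cens_table,
        taxonomy=taxonomy, bin_report=report, rejected=rejected, profile=profile,
        profile_comparison=comparison, evaluation=evaluation,
    )


def _bin_report(kept: pd.DataFrame, taxonomy: pd.DataFrame,
                samples: tuple[str, str]) -> pd.DataFrame:
    """Assemble the consolidated per-bin table in conventional column order."""
    cov_cols = [f"coverage_{s}" for s in samples]
    report = kept.copy()
    report["dataset"] = report[cov_cols].idxmax(axis=1).str.replace("coverage_", "", regex=False)
    if len(taxonomy):
        report = report.join(taxonomy[["lineage", "rank", "nt_identity", "aa_identity"]],
                             how="left")
    else:
        report[["lineage", "rank", "nt_identity", "aa_identity"]] = None
    report["essential_genes"] = (
        report["unique_markers"].astype(str) + "/" + report["reference_size"]
        .fillna(0).astype(int).astype(str)
    )
    cols = (["dataset", "lineage", "rank", "n_scaffolds", "total_length_bp",
             "gc_percent", "essential_genes", "completeness_percent"]
            + cov_cols + ["aa_identity", "nt_identity", "duplicated_markers",
                          "duplication_ratio"])
    return report[cols]


def _community_profile(community: Community, cov: CoverageMatrix,
                       rank: str) -> tuple[RankProfile, pd.DataFrame]:
    """Clade abundances from genome lineages weighted by summed coverage*bp."""
    norm = cov.require_normalized()
    truth = community.truth.set_index("scaffold")
    lineage_of = {g.name: g.lineage for g in community.spec.genomes}
    rows = []
    for sample in cov.samples:
        weighted = norm[sample] * truth["length"]
        by_genome = weighted.groupby(truth["genome"]).sum()
        for genome, ab in by_genome.items():
            if lineage_of.get(genome):
                rows.append({"lineage": lineage_of[genome], "sample": sample,
                             "abundance": float(ab)})
    table = pd.DataFrame(rows)
    profile = rollup(table, rank)
    comparison = compare(profile, cov.samples[0], cov.samples[1])
    return profile, comparison


def validate_paths(fasta: str | Path | None = None,
                   depth: str | Path | None = None,
                   clades: str | Path | None = None) -> list[str]:
    """Dialect checks with line-level diagnostics; empty list means clean."""
    diags: list[str] = []
    lengths: dict[str, int] = {}
    if fasta is not None:
        diags += [f"{fasta}: {d}" for d in io.validate_fasta(fasta)]
        try:
            lengths = {k: len(v) for k, v in io.read_fasta(fasta).items()}
        except ValueError:
            pass
    if depth is not None:
        if not lengths:
            diags.append(f"{depth}: cannot validate depth without a readable FASTA")
        else:
            diags += [f"{depth}: {d}" for d in io.validate_depth_tsv(depth, lengths)]
    if clades is not None:
        df = pd.read_csv(clades, sep="\t", comment="#")
        from .taxonomy import parse_lineage
        for i, lineage in enumerate(df.iloc[:, 0]):
            try:
                parse_lineage(str(lineage))
            except ValueError as exc:
                diags.append(f"{clades}: row {i}: {exc}")
    return diags
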