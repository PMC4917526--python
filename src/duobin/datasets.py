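"""Packaged reference tables and the default synthetic community.

The package ships three small TSVs: the profile of the 13 dominant genome
bins from a two-condition withered-grape berry metagenome survey, and the
phylum- and class-level relative-abundance tables of the same two samples.
``reference_community`` turns the bin profile into a ready-to-simulate
:class:`~duobin.synthetic.CommunitySpec` whose genomes mirror the observed
scaffold counts, GC%, marker counts and cross-sample coverage skew.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .synthetic import CommunitySpec, Fragmentation, GenomeSpec

#: Genome lengths are scaled to 1/20 of the observed bins by default: the
#: statistical structure (coverage skew, GC spread, scaffold counts, marker
#: census) is preserved while a full simulate-to-report run stays desk-sized.
DEFAULT_SCALE = 0.05

SAMPLES = ("TW", "AW")  # traditional and accelerated withering


def _data_path(name: str):
    return resources.files("duobin").joinpath("data", name)


def load_bin_profiles() -> pd.DataFrame:
    return pd.read_csv(_data_path("bin_profiles.tsv"), sep="\t", comment="#")


def load_phylum_profiles() -> pd.DataFrame:
    """Wide table: lineage, TW, AW (percent)."""
    return pd.read_csv(_data_path("phylum_abundance.tsv"), sep="\t", comment="#")


def load_class_profiles() -> pd.DataFrame:
    return pd.read_csv(_data_path("class_abundance.tsv"), sep="\t", comment="#")


def reference_community(scale: float = DEFAULT_SCALE, seed: int = 1,
                        markov_order: int = 2) -> CommunitySpec:
    """The default 13-genome two-sample community.

    Per-sample coverages come from each bin's dominant-sample coverage and
    its cross-sample fold ratio; genome lengths and mean scaffold lengths are
    scaled by ``scale`` with scaffold counts held at the observed values.
    """
    if not 0 < scale <= 1:
        raise ValueError("scale must be in (0, 1]")
    profiles = load_bin_profiles()
    genomes = []
    for _, row in profiles.iterrows():
        length = int(round(row["total_length_bp"] * scale))
        mean_scaffold = max(520.0, length / row["n_scaffolds"])
        cov_major = float(row["coverage_major"])
        cov_minor = cov_major / float(row["fold_ratio"])
        if row["dataset"] == "TW":
            abundance = (cov_major, cov_minor)
        else:
            abundance = (cov_minor, cov_major)
        genomes.append(GenomeSpec(
            name=row["name"],
            length=length,
            gc_target=row["gc_percent"] / 100.0,
            abundance=abundance,
            fragmentation=Fragmentation(mean_length=mean_scaffold, sigma=0.25),
            markov_order=markov_order,
            n_markers_present=int(row["essential_found"]),
            n_markers_duplicated=int(row["essential_duplicated"]),
            lineage=row["lineage"],
            nt_identity=float(row["nt_identity"]),
            aa_identity=float(row["aa_identity"]),
        ))
    return CommunitySpec(genomes=genomes, samples=SAMPLES, seed=seed)
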