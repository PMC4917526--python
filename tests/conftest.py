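import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def reference_run(tmp_path_factory):
    """One full pipeline run on the default 13-genome community, shared by
    the pipeline and acceptance tests (simulation dominates the cost)."""
    from duobin.datasets import reference_community
    from duobin.pipeline import RunConfig, run_pipeline

    outdir = tmp_path_factory.mktemp("reference_run")
    config = RunConfig(
        community=reference_community(scale=0.05, seed=1),
        outdir=outdir,
        min_bin_size=50_000,  # scaled with the 1/20 genome lengths
    )
    return run_pipeline(config)


@pytest.fixture(scope="session")
def small_community():
    """A tiny 3-genome community for fast unit-level checks."""
    from duobin.synthetic import CommunitySpec, Fragmentation, GenomeSpec, simulate_community

    spec = CommunitySpec(
        genomes=[
            GenomeSpec("low_gc", 60_000, 0.30, (100.0, 5.0), Fragmentation(2_000),
                       markov_order=2, n_markers_present=30, n_markers_duplicated=2,
                       lineage="k__Bacteria;p__Firmicutes;c__Clostridia;g__Clostridium",
                       nt_identity=90.0, aa_identity=95.0),
            GenomeSpec("high_gc", 60_000, 0.64, (5.0, 100.0), Fragmentation(2_000),
                       markov_order=2, n_markers_present=50,
                       lineage="k__Bacteria;p__Actinobacteria;c__Actinobacteria",
                       nt_identity=76.0, aa_identity=82.0),
            GenomeSpec("mid_gc", 60_000, 0.45, (40.0, 40.0), Fragmentation(2_000),
                       markov_order=2, n_markers_present=10,
                       lineage="k__Bacteria;p__Proteobacteria;c__Gammaproteobacteria",
                       nt_identity=97.5, aa_identity=99.0),
        ],
        samples=("s1", "s2"),
        seed=7,
    )
    return simulate_community(spec)
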