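"""Differential-coverage seeding, TNF refinement, link recovery, filtering."""

import numpy as np
import pandas as pd
import pytest

from duobin.binning import (NOISE, DifferentialCoverageBinner, bin_stats,
                            evaluate_against_truth, filter_bins, recover_linked,
                            refine_bins, seed_bins)
from duobin.coverage import CoverageMatrix
from duobin.synthetic import Fragmentation, GenomeSpec, fragment_genome, generate_genome
from duobin.tnf import project, tnf_matrix


def _two_genome_cov(rng, n=50, cov_a=(100.0, 5.0), cov_b=(5.0, 100.0), L=5_000):
    """Poisson-noised scaffold coverages for two planted genomes."""
    rows, truth = {}, {}
    for i in range(n):
        rows[f"a{i:03d}"] = [rng.poisson(c * L) / L for c in cov_a]
        truth[f"a{i:03d}"] = "A"
    for i in range(n):
        rows[f"b{i:03d}"] = [rng.poisson(c * L) / L for c in cov_b]
        truth[f"b{i:03d}"] = "B"
    return pd.DataFrame(rows, index=["s1", "s2"]).T, truth


class TestSeedBins:
    def test_two_opposed_genomes_two_clean_clusters(self, rng):
        cov, truth = _two_genome_cov(rng)
        labels = seed_bins(cov)
        assert set(labels) == {0, 1}
        by_genome = labels.groupby(pd.Series(truth))
        assert all(grp.nunique() == 1 for _, grp in by_genome)

    def test_single_genome_single_cluster(self, rng):
        cov, _ = _two_genome_cov(rng, cov_b=(100.0, 5.0))  # same signature
        labels = seed_bins(cov)
        assert set(labels) == {0}

    def test_short_scaffolds_left_as_noise(self, rng):
        cov, _ = _two_genome_cov(rng, n=20)
        lengths = pd.Series(5_000, index=cov.index)
        lengths.iloc[0] = 400
        labels = seed_bins(cov, lengths=lengths, min_len=500)
        assert labels.iloc[0] == NOISE  # pandas keeps positional order here
        assert (labels.drop(labels.index[0]) != NOISE).all()

    def test_all_zero_coverage_warns_and_returns_noise(self, rng, caplog):
        cov = pd.DataFrame(0.0, index=[f"s{i}" for i in range(10)],
                           columns=["s1", "s2"])
        with caplog.at_level("WARNING"):
            labels = seed_bins(cov)
        assert (labels == NOISE).all()

    def test_row_order_does_not_change_labels(self, rng):
        cov, _ = _two_genome_cov(rng)
        labels = seed_bins(cov)
        shuffled = cov.sample(frac=1.0, random_state=9)
        labels2 = seed_bins(shuffled)
        pd.testing.assert_series_equal(labels.sort_index(), labels2.sort_index())

    def test_requires_two_samples(self, rng):
        with pytest.raises(ValueError):
            seed_bins(pd.DataFrame({"s1": [1.0, 2.0]}))


@pytest.fixture(scope="module")
def mixed_cluster():
    """Two genomes with identical coverage but GC 0.30 vs 0.64, seeded as
    one coverage cluster."""
    seqs = {}
    for i, gc in enumerate((0.30, 0.64)):
        spec = GenomeSpec(f"g{i}", 120_000, gc, (10.0, 10.0),
                          Fragmentation(4_000), markov_order=2)
        g = generate_genome(spec, np.random.default_rng(10 + i))
        seqs.update(fragment_genome(g, spec.fragmentation, name=spec.name,
                                    rng=np.random.default_rng(20 + i)))
    matrix, _ = tnf_matrix(seqs)
    scores, _ = project(matrix, n_components=3)
    labels = pd.Series(0, index=scores.index)
    return labels, scores


class TestRefineBins:
    def test_mixed_gc_cluster_splits_cleanly(self, mixed_cluster):
        labels, scores = mixed_cluster
        refined = refine_bins(labels, scores)
        assert refined.nunique() == 2
        for genome in ("g0", "g1"):
            members = refined[[s for s in refined.index if s.startswith(genome)]]
            assert members.nunique() == 1

    def test_unimodal_cluster_untouched(self, mixed_cluster):
        _, scores = mixed_cluster
        only_g0 = scores.loc[[s for s in scores.index if s.startswith("g0")]]
        labels = pd.Series(0, index=only_g0.index)
        refined = refine_bins(labels, only_g0)
        assert refined.nunique() == 1

    def test_never_crosses_seeded_clusters(self, mixed_cluster):
        labels, scores = mixed_cluster
        # two seeded clusters, split arbitrarily in half
        half = len(labels) // 2
        seeded = labels.copy()
        seeded.iloc[half:] = 1
        refined = refine_bins(seeded, scores)
        # scaffolds seeded apart never end up in the same refined bin
        for lab in set(refined):
            members = refined.index[refined == lab]
            assert seeded.loc[members].nunique() == 1

    def test_missing_projection_rejected(self, mixed_cluster):
        labels, scores = mixed_cluster
        with pytest.raises(ValueError):
            refine_bins(labels, scores.iloc[:3])


class TestRecoverLinked:
    def _links(self, rows):
        return pd.DataFrame(rows, columns=["scaffold_a", "scaffold_b", "weight"])

    def test_strong_unambiguous_link_joins(self):
        labels = pd.Series({"x": NOISE, "m1": 0, "m2": 1})
        links = self._links([("x", "m1", 5)])
        out = recover_linked(labels, links, min_weight=3)
        assert out["x"] == 0

    def test_tie_leaves_unassigned(self):
        labels = pd.Series({"x": NOISE, "m1": 0, "m2": 1})
        links = self._links([("x", "m1", 4), ("x", "m2", 4)])
        assert recover_linked(labels, links, min_weight=3)["x"] == NOISE

    def test_weak_link_ignored(self):
        labels = pd.Series({"x": NOISE, "m1": 0})
        links = self._links([("x", "m1", 2)])
        assert recover_linked(labels, links, min_weight=3)["x"] == NOISE

    def test_weights_sum_over_bin_members(self):
        labels = pd.Series({"x": NOISE, "m1": 0, "m2": 0})
        links = self._links([("x", "m1", 2), ("m2", "x", 2)])
        assert recover_linked(labels, links, min_weight=3)["x"] == 0

    def test_dropped_short_scaffolds_recovered_via_links(self, small_community):
        """Scaffolds excluded from seeding by a length cutoff rejoin their
        genome through paired-end links."""
        com = small_community
        lengths = com.scaffold_lengths()
        from duobin.coverage import mean_coverage, normalize
        raw = pd.DataFrame({
            s: mean_coverage(com.depth[s], lengths.to_dict())
            for s in com.spec.samples
        })
        cov = normalize(CoverageMatrix(raw=raw, aligned_reads=com.aligned_reads))
        cutoff = float(lengths.quantile(0.2))  # exclude the shortest fifth
        labels = seed_bins(cov.normalized, lengths=lengths, min_len=int(cutoff))
        dropped = labels.index[labels == NOISE]
        assert len(dropped) > 0
        recovered = recover_linked(labels, com.links, min_weight=3)
        truth = com.truth_membership()
        correct = 0
        rejoined = [s for s in dropped if recovered[s] != NOISE]
        for s in rejoined:
            bin_members = recovered.index[(recovered == recovered[s]) & (recovered.index != s)]
            majority = pd.Series([truth[m] for m in bin_members]).mode().iat[0]
            correct += truth[s] == majority
        assert len(rejoined) / len(dropped) >= 0.9
        assert correct / len(rejoined) >= 0.9


class TestFilterAndStats:
    def _stats(self, completeness, length):
        return pd.DataFrame({
            "completeness_percent": completeness,
            "total_length_bp": length,
        }, index=range(len(completeness)))

    def test_incomplete_but_large_bin_kept(self):
        kept, rejected = filter_bins(self._stats([13], [4_145_951]), min_size=1_000_000)
        assert len(kept) == 1 and len(rejected) == 0

    def test_incomplete_and_small_bin_rejected(self):
        kept, rejected = filter_bins(self._stats([15], [300_000]), min_size=1_000_000)
        assert len(kept) == 0 and len(rejected) == 1
        assert "completeness" in rejected["reason"].iat[0]

    def test_complete_bin_always_kept(self):
        kept, _ = filter_bins(self._stats([100], [10_000]), min_size=1_000_000)
        assert len(kept) == 1

    def test_gc_is_length_weighted(self):
        labels = pd.Series({"a": 0, "b": 0})
        lengths = pd.Series({"a": 1_000, "b": 3_000})
        gc = pd.Series({"a": 0.40, "b": 0.60})
        raw = pd.DataFrame({"s1": {"a": 2.0, "b": 2.0}, "s2": {"a": 1.0, "b": 1.0}})
        cov = CoverageMatrix(raw=raw, aligned_reads={"s1": 10, "s2": 10})
        cov.normalized = raw
        stats = bin_stats(labels, lengths, gc, cov)
        assert stats.loc[0, "gc_percent"] == pytest.approx(55.0)
        assert stats.loc[0, "total_length_bp"] == 4_000

    def test_single_scaffold_all_gc(self):
        labels = pd.Series({"a": 0})
        cov = CoverageMatrix(raw=pd.DataFrame({"s1": {"a": 1.0}, "s2": {"a": 1.0}}),
                             aligned_reads={"s1": 1, "s2": 1})
        cov.normalized = cov.raw
        stats = bin_stats(labels, pd.Series({"a": 1_000}), pd.Series({"a": 1.0}), cov)
        assert stats.loc[0, "gc_percent"] == 100.0


class TestEstimator:
    def test_fit_predict_partition_property(self, rng):
        cov, truth = _two_genome_cov(rng)
        binner = DifferentialCoverageBinner(refine=False)
        labels = binner.fit_predict(cov)
        # every scaffold has exactly one label; estimator exposes sklearn API
        assert labels.index.equals(cov.sort_index().index)
        assert binner.n_bins_ == 2
        params = binner.get_params()
        assert params["eps"] == 0.1

    def test_evaluation_scores_perfect_binning(self, rng):
        cov, truth = _two_genome_cov(rng)
        labels = DifferentialCoverageBinner(refine=False).fit_predict(cov)
        lengths = pd.Series(5_000, index=cov.index)
        ev = evaluate_against_truth(labels, truth, lengths)
        assert ev["recovered"].all()
        assert (ev["purity"] == 1.0).all()
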