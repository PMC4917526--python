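"""Synthetic community generator: determinism, GC control, fragmentation,
depth simulation and marker planting."""

import numpy as np
import pandas as pd
import pytest

from duobin.io import seq_gc
from duobin.synthetic import (CommunitySpec, Fragmentation, GenomeSpec, fragment_genome,
                              generate_genome, plant_markers, simulate_community,
                              simulate_depth, spec_from_json, spec_to_json)
from duobin.tnf import tnf_vector


def _spec(**kw):
    base = dict(name="g", length=100_000, gc_target=0.5, abundance=(10.0, 1.0),
                fragmentation=Fragmentation(2_000))
    base.update(kw)
    return GenomeSpec(**base)


class TestGenerateGenome:
    def test_gc_near_target_for_balanced_model(self, rng):
        seq = generate_genome(_spec(), rng)
        assert 0.48 <= seq_gc(seq) <= 0.52

    @pytest.mark.parametrize("gc", [0.29, 0.42, 0.64])
    def test_gc_within_two_points_across_range(self, gc, rng):
        seq = generate_genome(_spec(gc_target=gc), rng)
        assert abs(seq_gc(seq) - gc) <= 0.02

    def test_same_seed_same_sequence(self):
        a = generate_genome(_spec(), np.random.default_rng(42))
        b = generate_genome(_spec(), np.random.default_rng(42))
        assert a == b

    def test_invalid_specs_rejected(self, rng):
        with pytest.raises(ValueError):
            generate_genome(_spec(length=-5), rng)
        with pytest.raises(ValueError):
            generate_genome(_spec(gc_target=1.5), rng)
        with pytest.raises(ValueError):
            generate_genome(_spec(markov_order=0), rng)

    def test_distinct_gc_means_distinct_tnf(self, rng):
        """Between-genome TNF distance exceeds within-genome distance,
        checked against brute-force distances of generated scaffolds."""
        lo = generate_genome(_spec(name="lo", gc_target=0.30), np.random.default_rng(1))
        hi = generate_genome(_spec(name="hi", gc_target=0.64), np.random.default_rng(2))
        frag = Fragmentation(5_000)
        lo_vecs = [tnf_vector(s) for s in
                   fragment_genome(lo, frag, rng=np.random.default_rng(3)).values()]
        hi_vecs = [tnf_vector(s) for s in
                   fragment_genome(hi, frag, rng=np.random.default_rng(4)).values()]

        def mean_dist(A, B):
            return float(np.mean([np.linalg.norm(a - b) for a in A for b in B
                                  if a is not b]))

        within = (mean_dist(lo_vecs, lo_vecs) + mean_dist(hi_vecs, hi_vecs)) / 2
        between = mean_dist(lo_vecs, hi_vecs)
        assert between > within


class TestFragmentGenome:
    def test_all_lengths_at_least_min(self, rng):
        seq = "A" * 10_000
        frags = fragment_genome(seq, Fragmentation(2_000), min_len=500, rng=rng)
        assert all(len(s) >= 500 for s in frags.values())

    def test_degenerate_single_scaffold(self, rng):
        frags = fragment_genome("ACGT" * 250, Fragmentation(1_000), rng=rng)
        assert len(frags) == 1
        only = next(iter(frags.values()))
        assert 500 <= len(only) <= 1_000

    def test_prefix_partition_length_audit(self, rng):
        seq = "".join(rng.choice(list("ACGT"), size=50_000))
        frags = fragment_genome(seq, Fragmentation(1_500), name="g", rng=rng)
        total = sum(len(s) for s in frags.values())
        assert total <= len(seq)
        # scaffolds are a contiguous prefix partition in emitted order
        assert "".join(frags.values()) == seq[:total]

    def test_mean_below_min_rejected(self, rng):
        with pytest.raises(ValueError):
            fragment_genome("A" * 10_000, Fragmentation(300), min_len=500, rng=rng)


class TestSimulateDepth:
    lengths = {"a": 10_000, "b": 5_000}

    def test_zero_abundance_means_zero_depth(self, rng):
        table = simulate_depth(self.lengths, {"a": 0.0, "b": 0.0}, "poisson", rng)
        assert table.mean().eq(0).all()

    def test_noise_free_depth_is_exact(self, rng):
        table = simulate_depth(self.lengths, {"a": 10, "b": 3}, "none", rng)
        assert (table.depths["a"] == 10).all()
        assert table.mean()["b"] == 3.0

    def test_poisson_mean_within_three_se(self, rng):
        ab = 100.0
        table = simulate_depth({"a": 10_000}, {"a": ab}, "poisson", rng)
        se = np.sqrt(ab / 10_000)
        assert abs(table.mean()["a"] - ab) <= 3 * se

    def test_unknown_noise_model_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_depth(self.lengths, {"a": 1, "b": 1}, "gaussian", rng)


class TestPlantMarkers:
    def _frags(self, rng, n=20):
        return {f"g_s{i:04d}": "".join(rng.choice(list("ACGT"), size=1_000))
                for i in range(n)}

    def test_full_census_single_copy(self, rng):
        spec = _spec(n_markers_present=105)
        hits = plant_markers(spec, self._frags(rng), rng)
        assert hits["marker_id"].nunique() == 105
        assert len(hits) == 105

    def test_no_markers_empty_table(self, rng):
        hits = plant_markers(_spec(), self._frags(rng), rng)
        assert len(hits) == 0

    def test_duplication_adds_extra_hits(self, rng):
        spec = _spec(n_markers_present=72, n_markers_duplicated=3)
        hits = plant_markers(spec, self._frags(rng), rng)
        assert hits["marker_id"].nunique() == 72
        assert len(hits) == 75
        counts = hits["marker_id"].value_counts()
        assert (counts >= 2).sum() == 3

    def test_too_many_markers_rejected(self, rng):
        with pytest.raises(ValueError):
            plant_markers(_spec(n_markers_present=106), self._frags(rng), rng)

    def test_intervals_lie_on_their_scaffolds(self, rng):
        frags = self._frags(rng)
        hits = plant_markers(_spec(n_markers_present=40), frags, rng)
        for _, h in hits.iterrows():
            assert 0 <= h["start"] < h["end"] <= len(frags[h["scaffold"]])


class TestCommunity:
    def test_byte_identical_under_fixed_seed(self, tmp_path, small_community):
        com2 = simulate_community(small_community.spec)
        assert com2.scaffolds == small_community.scaffolds
        pd.testing.assert_frame_equal(com2.truth, small_community.truth)
        pd.testing.assert_frame_equal(com2.marker_hits, small_community.marker_hits)
        a, b = tmp_path / "a", tmp_path / "b"
        small_community.write(a, write_depth=True)
        com2.write(b, write_depth=True)
        for name in ("scaffolds.fasta", "truth.tsv", "marker_hits.tsv",
                     "links.tsv", "depth_s1.tsv"):
            assert (a / name).read_bytes() == (b / name).read_bytes()

    def test_every_scaffold_has_exactly_one_truth_entry(self, small_community):
        truth = small_community.truth
        assert sorted(truth["scaffold"]) == sorted(small_community.scaffolds)
        assert truth["scaffold"].is_unique
        # base conservation: truth lengths match the emitted sequences
        for _, row in truth.iterrows():
            assert row["length"] == len(small_community.scaffolds[row["scaffold"]])

    def test_validation_rejects_degenerate_specs(self):
        g = _spec()
        with pytest.raises(ValueError):
            CommunitySpec(genomes=[g], seed=0).validate()  # < 2 genomes
        with pytest.raises(ValueError):
            CommunitySpec(genomes=[g, g], samples=("a",), seed=0).validate()
        with pytest.raises(ValueError):
            CommunitySpec(genomes=[g, _spec(name="g")], seed=0).validate()

    def test_spec_json_roundtrip(self, small_community):
        spec = small_community.spec
        again = spec_from_json(spec_to_json(spec))
        assert again == spec
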