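"""Binning, ICE balancing, resolution analysis, summaries, triplet I/O."""

import inspect
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from hiclite import (
    ContactMatrix, GenomeBins, SyntheticSpec, bin_contacts, bin_coverage,
    build_probability_map, cis_trans_summary, delta_matrix, ice_normalize,
    map_resolution, read_triplets, sample_contacts, write_triplets,
    RESOLUTION_GRID,
)
from hiclite.pairs import ValidPairs


def _pairs(rows):
    df = pd.DataFrame(rows, columns=["read_id", "chrom1", "pos1", "strand1",
                                     "chrom2", "pos2", "strand2"])
    return ValidPairs(df)


class TestBinContacts:
    g = GenomeBins({"c1": 10_000}, 1000)

    def test_diagonal_pair_counts_once(self):
        vp = _pairs([("r1", "c1", 100, "+", "c1", 100, "-")])
        m = bin_contacts(vp, self.g)
        assert m.counts[0, 0] == 1
        assert m.total == 1

    def test_symmetry_both_triangles(self):
        vp = _pairs([("r", "c1", 2500, "+", "c1", 7500, "-")] * 3)
        m = bin_contacts(vp, self.g)
        assert m.counts[2, 7] == 3 and m.counts[7, 2] == 3
        assert m.total == 3

    def test_conservation_on_random_pairs(self, rng):
        pos1 = rng.integers(1, 10_001, 10_000)
        pos2 = rng.integers(1, 10_001, 10_000)
        vp = _pairs([(f"r{k}", "c1", a, "+", "c1", b, "-")
                     for k, (a, b) in enumerate(zip(pos1, pos2))])
        m = bin_contacts(vp, self.g)
        assert m.total == 10_000
        np.testing.assert_allclose(m.counts, m.counts.T)

    def test_serialization_roundtrip_idempotent(self, tmp_path, rng):
        from hiclite.pairs import read_valid_pairs, write_valid_pairs
        pos = rng.integers(1, 10_001, (500, 2))
        vp = _pairs([(f"r{k}", "c1", a, "+", "c1", b, "-")
                     for k, (a, b) in enumerate(pos)])
        write_valid_pairs(vp, tmp_path / "p.tsv")
        vp2 = read_valid_pairs(tmp_path / "p.tsv", {"c1": 10_000})
        m1 = bin_contacts(vp, self.g)
        m2 = bin_contacts(vp2, self.g)
        np.testing.assert_array_equal(m1.counts, m2.counts)


class TestIce:
    def test_equal_row_sums_is_fixed_point(self):
        g = GenomeBins({"c": 5000}, 1000)
        T = np.full((5, 5), 2.0)  # constant matrix: already balanced
        m = ContactMatrix(g, T.copy())
        out = ice_normalize(m, low_pct=0.0, eps=0.1)
        np.testing.assert_allclose(out.counts, T)
        np.testing.assert_allclose(out.bias, np.ones(5))

    def test_constructed_bias_recovered(self):
        """O = diag(b) T diag(b) with doubly-balanced T: ICE recovers ~T."""
        rng = np.random.default_rng(7)
        # build a doubly-stochastic-like symmetric T by Sinkhorn iterations
        T = rng.uniform(0.5, 2.0, (5, 5))
        T = (T + T.T) / 2
        for _ in range(2000):
            s = T.sum(axis=1)
            T /= np.sqrt(np.outer(s, s))
        b = np.array([1.0, 2.0, 1.0, 0.5, 1.0])
        O = T * np.outer(b, b)
        g = GenomeBins({"c": 5000}, 1000)
        out = ice_normalize(ContactMatrix(g, O), low_pct=0.0, eps=1e-8,
                            max_iter=10_000)
        ratio = out.counts / T
        assert np.nanmax(np.abs(ratio / ratio.mean() - 1)) < 1e-6

    def test_defaults_match_standard_iced_parameters(self):
        sig = inspect.signature(ice_normalize)
        assert sig.parameters["max_iter"].default == 100
        assert sig.parameters["low_pct"].default == 0.02
        assert sig.parameters["high_pct"].default == 0.0
        assert sig.parameters["eps"].default == 0.1

    def test_all_zero_matrix_raises(self):
        g = GenomeBins({"c": 3000}, 1000)
        with pytest.raises(ValueError, match="nothing to balance"):
            ice_normalize(ContactMatrix(g, np.zeros((3, 3))))

    def test_row_sum_cv_decreases_monotonically(self, rng):
        """Row-sum CV over unmasked bins decreases across ICE sweeps."""
        n = 60
        W = rng.poisson(20.0, (n, n)).astype(float)
        W = W + W.T
        cvs = []
        for _ in range(8):
            s = W.sum(axis=1)
            cvs.append(s.std() / s.mean())
            rel = s / s.mean()
            W /= rel[:, None]
            W /= rel[None, :]
        assert all(b <= a + 1e-12 for a, b in zip(cvs, cvs[1:]))

    def test_low_coverage_bins_masked_with_nan_bias(self, rng):
        n = 100
        W = rng.poisson(50.0, (n, n)).astype(float)
        W = W + W.T
        W[0, :] = 0.0  # dead bin
        W[:, 0] = 0.0
        g = GenomeBins({"c": n * 1000}, 1000)
        out = ice_normalize(ContactMatrix(g, W))
        assert out.mask[0]
        assert np.isnan(out.bias[0])
        assert out.counts[0].sum() == 0


def _resolution_oracle(depths, percentile, threshold):
    srt = sorted(depths, reverse=True)
    pos = max(1, math.ceil(percentile * len(srt)))
    return srt[pos - 1] >= threshold


class TestMapResolution:
    def _pairs_with_depths(self, depths, bin_size=1000):
        """One chromosome; each bin k receives depths[k] pair *ends*."""
        rows = []
        rid = 0
        ends = []
        for k, d in enumerate(depths):
            ends.extend([k * bin_size + 1] * d)
        assert len(ends) % 2 == 0
        for a, b in zip(ends[::2], ends[1::2]):
            rows.append((f"r{rid}", "c", a, "+", "c", b, "-"))
            rid += 1
        return _pairs(rows), {"c": len(depths) * bin_size}

    def test_enumerated_example_position8_depth(self):
        depths = [2000] * 9 + [500]
        vp, sizes = self._pairs_with_depths(depths)
        rep = map_resolution(vp, sizes, candidate_sizes=(1000,))
        assert rep.per_size[1000]["depth_p80"] == 2000
        assert rep.achieved(1000)

    def test_threshold_boundary_is_geq(self):
        depths = [1000] * 10
        vp, sizes = self._pairs_with_depths(depths)
        rep = map_resolution(vp, sizes, candidate_sizes=(1000,))
        assert rep.achieved(1000)

    def test_defaults_are_the_standard_grid_and_threshold(self):
        sig = inspect.signature(map_resolution)
        assert tuple(sig.parameters["candidate_sizes"].default) == tuple(
            RESOLUTION_GRID)
        assert sig.parameters["depth_threshold"].default == 1000
        assert sig.parameters["percentile"].default == 0.80
        assert RESOLUTION_GRID == (1_000_000, 500_000, 200_000, 100_000,
                                   40_000, 20_000, 10_000, 5_000, 1_000)

    def test_empty_pairs_reports_nothing_achieved(self):
        vp = _pairs([])
        rep = map_resolution(vp, {"c": 10_000}, candidate_sizes=(1000,))
        assert rep.finest_achieved is None
        assert rep.per_size[1000]["depth_p80"] == 0

    def test_agrees_with_brute_force_on_random_depth_vectors(self, rng):
        """1,000 random depth vectors: percentile-position decision matches
        an independent sort-and-index oracle."""
        from hiclite.matrix import _percentile_depth
        for _ in range(1000):
            n = rng.integers(1, 400)
            depths = rng.integers(0, 3000, n)
            got = _percentile_depth(np.sort(depths)[::-1], 0.80) >= 1000
            assert got == _resolution_oracle(depths.tolist(), 0.80, 1000)


class TestCisTransSummary:
    def test_cis_always_stronger_with_default_trans_fraction(self):
        spec = SyntheticSpec({"chrA": 2_000_000, "chrB": 1_500_000}, 100_000,
                             total_pairs=200_000, trans_fraction=0.15)
        pm = build_probability_map(spec)
        vp = sample_contacts(pm, spec.total_pairs, 4)
        m = bin_contacts(vp, spec.genome)
        cis_means, trans_df = cis_trans_summary(m)
        assert min(cis_means.values()) > trans_df["mean_trans"].max()

    def test_planted_trans_boost_flags_exactly_that_pair(self):
        spec = SyntheticSpec(
            {"c1": 1_000_000, "c2": 1_000_000, "c3": 1_000_000,
             "c4": 1_000_000}, 100_000, total_pairs=300_000,
            trans_fraction=0.3, trans_boost={("c1", "c3"): 8.0})
        pm = build_probability_map(spec)
        vp = sample_contacts(pm, spec.total_pairs, 6)
        _, trans_df = cis_trans_summary(bin_contacts(vp, spec.genome))
        flagged = trans_df[trans_df["flagged"]]
        assert len(flagged) == 1
        assert {flagged.iloc[0]["chrom1"], flagged.iloc[0]["chrom2"]} == {
            "c1", "c3"}

    def test_uniform_matrix_has_no_flags(self):
        g = GenomeBins({"c1": 3000, "c2": 3000}, 1000)
        m = ContactMatrix(g, np.ones((6, 6)))
        _, trans_df = cis_trans_summary(m)
        assert not trans_df["flagged"].any()


class TestDeltaMatrix:
    g = GenomeBins({"c": 5000}, 1000)

    def _mat(self, arr):
        return ContactMatrix(self.g, np.asarray(arr, dtype=float))

    def test_identical_inputs_give_zero(self, rng):
        a = rng.poisson(10, (5, 5)).astype(float)
        a = a + a.T
        d = delta_matrix(self._mat(a), self._mat(a))
        np.testing.assert_allclose(d.counts, 0.0)

    def test_global_scaling_cancels(self, rng):
        a = rng.poisson(10, (5, 5)).astype(float) + 1
        a = a + a.T
        d = delta_matrix(self._mat(a), self._mat(2 * a))
        np.testing.assert_allclose(d.counts, 0.0, atol=1e-9)

    def test_shape_mismatch_raises(self):
        other = ContactMatrix(GenomeBins({"c": 3000}, 1000), np.ones((3, 3)))
        with pytest.raises(ValueError):
            delta_matrix(self._mat(np.ones((5, 5))), other)

    def test_planted_group_effect_dominates_delta(self, tmp_path):
        from hiclite import GroupEffect, make_cohort, read_chromsizes
        from hiclite.pairs import read_valid_pairs
        spec = SyntheticSpec({"chrA": 4_000_000}, 100_000,
                             total_pairs=400_000, trans_fraction=0.0)
        eff = GroupEffect("chrA", 10, 14, 4.0)
        sheet, _ = make_cohort(spec, 1, tmp_path, group_effect=eff, seed=3)
        sizes = read_chromsizes(tmp_path / "genome.chrom.sizes")
        g = GenomeBins(sizes, 100_000)
        mats = {row["group"]: bin_contacts(
            read_valid_pairs(row["path"], sizes), g)
            for _, row in sheet.iterrows()}
        d = delta_matrix(mats["case"], mats["ctrl"]).counts
        # exclude the diagonal's shot noise; largest |delta| must sit in locus
        np.fill_diagonal(d, 0.0)
        i, j = np.unravel_index(np.nanargmax(np.abs(d)), d.shape)
        assert 10 <= i <= 14 and 10 <= j <= 14


class TestTripletIO:
    def test_roundtrip_preserves_matrix(self, tmp_path, rng):
        g = GenomeBins({"c1": 5000, "c2": 3000}, 1000)
        a = rng.poisson(5, (8, 8)).astype(float)
        a = np.triu(a) + np.triu(a, 1).T
        m = ContactMatrix(g, a)
        write_triplets(m, tmp_path / "m.tsv", tmp_path / "bins.tsv")
        m2 = read_triplets(tmp_path / "m.tsv", g)
        np.testing.assert_array_equal(m.counts, m2.counts)
        bins = pd.read_csv(tmp_path / "bins.tsv", sep="\t", header=None)
        assert len(bins) == 8
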