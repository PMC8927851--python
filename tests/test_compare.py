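"""SCC reproducibility, joint loess normalization, exact-test differences."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import kstest

from hiclite import (
    ContactMatrix, GenomeBins, GroupEffect, SyntheticSpec, bin_contacts,
    build_probability_map, exact_test_diff, joint_normalize, sample_contacts,
    scc, smooth_mean_filter, thin_replicate,
)


class TestSmoothMeanFilter:
    def test_h0_is_identity(self, rng):
        x = rng.normal(size=(10, 10))
        np.testing.assert_array_equal(smooth_mean_filter(x, 0), x)

    def test_constant_matrix_unchanged_any_h(self):
        x = np.full((9, 9), 4.2)
        for h in (1, 2, 3):
            np.testing.assert_allclose(smooth_mean_filter(x, h), 4.2)

    def test_center_of_5x5_toy_is_mean_of_3x3_neighborhood(self):
        x = np.arange(25, dtype=float).reshape(5, 5)
        sm = smooth_mean_filter(x, 1)
        assert sm[2, 2] == pytest.approx(x[1:4, 1:4].mean())

    def test_edges_use_clipped_neighborhood(self):
        x = np.arange(25, dtype=float).reshape(5, 5)
        sm = smooth_mean_filter(x, 1)
        assert sm[0, 0] == pytest.approx(x[:2, :2].mean())


class TestScc:
    def _random_matrix(self, rng, nb=80, B=40_000):
        g = GenomeBins({"c": nb * B}, B)
        idx = np.arange(nb)
        lam = 50.0 / np.maximum(np.abs(idx[:, None] - idx[None, :]), 1)
        a = rng.poisson(lam).astype(float)
        return ContactMatrix(g, np.triu(a) + np.triu(a, 1).T)

    def test_self_correlation_is_exactly_one(self, rng):
        m = self._random_matrix(rng)
        res = scc(m, m)
        assert res.scc == pytest.approx(1.0, abs=1e-12)

    def test_symmetric_in_arguments(self, rng):
        a = self._random_matrix(rng)
        b = self._random_matrix(np.random.default_rng(1))
        assert scc(a, b).scc == pytest.approx(scc(b, a).scc)

    def test_invariant_to_positive_scaling(self, rng):
        a = self._random_matrix(rng)
        b = self._random_matrix(np.random.default_rng(2))
        r1 = scc(a, b).scc
        scaled = ContactMatrix(a.bins, a.counts * 13.7)
        assert scc(scaled, b).scc == pytest.approx(r1, abs=1e-12)

    def test_within_stratum_permutation_destroys_correlation(self):
        """Permuting one map's pixels within each stratum: |SCC| < 0.1
        averaged over 20 seeds."""
        rng = np.random.default_rng(3)
        a = self._random_matrix(rng)
        vals = []
        for seed in range(20):
            prng = np.random.default_rng(1000 + seed)
            nb = a.counts.shape[0]
            shuffled = a.counts.copy()
            for d in range(1, nb):
                diag = np.diagonal(a.counts, d).copy()
                prng.shuffle(diag)
                idx = np.arange(nb - d)
                shuffled[idx, idx + d] = diag
                shuffled[idx + d, idx] = diag
            b = ContactMatrix(a.bins, shuffled)
            # smoothing re-introduces local correlation; compare unsmoothed
            vals.append(scc(a, b, h=0).scc)
        assert abs(np.mean(vals)) < 0.1

    def test_thinned_replicates_highly_reproducible(self, tad_spec):
        """Two p=0.5 thinnings of one parent map: SCC >= 0.97 (replicate
        reproducibility analog at desk scale)."""
        pm = build_probability_map(tad_spec)
        parent = sample_contacts(pm, tad_spec.total_pairs, 51)
        g = tad_spec.genome
        m1 = bin_contacts(thin_replicate(parent, 0.5, 52), g)
        m2 = bin_contacts(thin_replicate(parent, 0.5, 53), g)
        assert scc(m1, m2, h=2, max_distance_bp=5e6).scc >= 0.97

    def test_no_usable_strata_raises(self):
        g = GenomeBins({"c": 3 * 40_000}, 40_000)
        m = ContactMatrix(g, np.ones((3, 3)))
        with pytest.raises(ValueError):
            scc(m, m)


def _null_cohort(n_samples, nb=60, B=40_000, depth=200_000, seed=0):
    spec = SyntheticSpec({"c": nb * B}, B, alpha=1.0, total_pairs=depth,
                         trans_fraction=0.0)
    pm = build_probability_map(spec)
    g = spec.genome
    rng = np.random.default_rng(seed)
    return [bin_contacts(sample_contacts(pm, depth,
                                         int(rng.integers(2**31 - 1))), g)
            for _ in range(n_samples)]


class TestJointNormalize:
    def test_identical_matrices_unchanged(self):
        mats = _null_cohort(1, seed=4) * 3  # same matrix three times
        normed = joint_normalize([m.copy() for m in mats])
        for m0, m1 in zip(mats, normed):
            np.testing.assert_allclose(m1.counts, m0.counts, rtol=1e-6,
                                       atol=1e-6)

    def test_distance_dependent_bias_removed(self):
        """A planted smooth bias g(D) on one sample: post-normalization mean
        M is within +-0.05 of zero across distance strata."""
        mats = _null_cohort(3, depth=400_000, seed=5)
        biased = mats[0].copy()
        nb = biased.counts.shape[0]
        idx = np.arange(nb)
        d = np.abs(idx[:, None] - idx[None, :])
        gbias = 1.0 + 0.6 * d / nb  # smooth multiplicative distance trend
        biased.counts *= gbias
        normed = joint_normalize([biased] + mats[1:])
        ref = np.mean([np.log2(m.counts + 0.5) for m in normed[1:]], axis=0)
        M = np.log2(normed[0].counts + 0.5) - ref
        for dlo in range(1, nb - 10, 10):
            sel = (d >= dlo) & (d < dlo + 10) & (np.triu(np.ones_like(d)) > 0)
            assert abs(np.mean(M[sel])) < 0.05

    def test_rank_order_preserved_within_stratum(self):
        mats = _null_cohort(2, seed=6)
        normed = joint_normalize([m.copy() for m in mats])
        nb = mats[0].counts.shape[0]
        d = 3
        idx = np.arange(nb - d)
        before = mats[0].counts[idx, idx + d]
        after = normed[0].counts[idx, idx + d]
        # monotone trend correction cannot reorder pixels within a stratum
        assert (np.argsort(before) == np.argsort(after)).all()

    def test_single_matrix_rejected(self):
        with pytest.raises(ValueError):
            joint_normalize(_null_cohort(1, seed=7))


class TestExactTestDiff:
    def test_identical_groups_give_p_one(self):
        mats = _null_cohort(1, seed=8)
        dt = exact_test_diff([mats[0]], [mats[0].copy()])
        assert (dt.table["p"] == 1.0).all()

    def test_null_type_one_error_controlled(self):
        """No true differences: fraction of pixels at q < 0.05 stays <= 0.05
        (averaged over 5 cohorts; the 20-seed version runs in acceptance)."""
        fracs = []
        for seed in range(5):
            mats = _null_cohort(4, nb=50, depth=150_000, seed=100 + seed)
            normed = joint_normalize(mats)
            dt = exact_test_diff(normed[:2], normed[2:])
            fracs.append((dt.table["q"] < 0.05).mean())
        assert np.mean(fracs) <= 0.05

    def test_null_pvalues_roughly_uniform(self):
        mats = _null_cohort(4, nb=50, depth=150_000, seed=200)
        normed = joint_normalize(mats)
        dt = exact_test_diff(normed[:2], normed[2:])
        # discrete exact p-values are conservative; check no liberal skew
        stat = kstest(dt.table["p"], "uniform", alternative="greater")
        assert stat.pvalue > 0.01

    def test_planted_effect_detected_with_enriched_m(self, tmp_path):
        from hiclite import make_cohort, read_chromsizes
        from hiclite.pairs import read_valid_pairs
        spec = SyntheticSpec({"c": 100 * 40_000}, 40_000, alpha=1.0,
                             total_pairs=500_000, trans_fraction=0.0)
        eff = GroupEffect("c", 40, 44, 3.0)
        sheet, _ = make_cohort(spec, 2, tmp_path, group_effect=eff, seed=11)
        sizes = read_chromsizes(tmp_path / "genome.chrom.sizes")
        g = GenomeBins(sizes, 40_000)
        mats = [bin_contacts(read_valid_pairs(r["path"], sizes), g)
                for _, r in sheet.iterrows()]
        dt = exact_test_diff(joint_normalize(mats)[:2],
                             joint_normalize(mats)[2:])
        tab = dt.table
        locus = ((tab["bin1"].between(40, 44)) & (tab["bin2"].between(40, 44)))
        assert (tab.loc[locus, "q"] < 0.05).mean() >= 0.8
        top = tab.assign(absM=tab["M"].abs()).nlargest(15, "absM")
        top_in_locus = (top["bin1"].between(40, 44)
                        & top["bin2"].between(40, 44)).mean()
        assert top_in_locus >= 0.8

    def test_empty_group_rejected(self):
        mats = _null_cohort(2, seed=9)
        with pytest.raises(ValueError):
            exact_test_diff(mats, [])
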