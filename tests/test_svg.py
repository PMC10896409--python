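from itertools import combinations

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import kstest

import sgft


def exact_ranksum_p(low, high):
    """Brute-force one-sided rank-sum p-value by enumerating all splits.

    Null: every assignment of the pooled values into a |low|-subset is
    equally likely; p = fraction of subsets whose rank sum is >= observed.
    """
    pooled = np.concatenate([low, high])
    ranks = np.argsort(np.argsort(pooled)) + 1.0
    n_low = len(low)
    observed = ranks[:n_low].sum()
    count = total = 0
    for idx in combinations(range(len(pooled)), n_low):
        total += 1
        if ranks[list(idx)].sum() >= observed - 1e-12:
            count += 1
    return count / total


class TestNormalizedFcs:
    def test_absolute_value_weights(self):
        np.testing.assert_allclose(
            sgft.normalized_fcs(np.array([0.0, 2.0, -2.0])), [0, 0.5, 0.5]
        )

    def test_one_hot_preserved(self):
        np.testing.assert_allclose(
            sgft.normalized_fcs(np.array([0.0, 0.0, 7.0])), [0, 0, 1]
        )

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            sgft.normalized_fcs(np.zeros(4))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_sums_to_one(self, seed):
        fcs = np.random.default_rng(seed).normal(size=17)
        assert abs(sgft.normalized_fcs(fcs).sum() - 1.0) <= 1e-12


class TestGftscore:
    def test_pure_mode_scores(self, path3):
        _, basis = path3
        s2 = sgft.gftscore(basis.eigenvalues, sgft.gft(basis, basis.modes[:, 1]))
        s3 = sgft.gftscore(basis.eigenvalues, sgft.gft(basis, basis.modes[:, 2]))
        assert abs(s2 - np.exp(-1)) <= 1e-10
        assert abs(s3 - np.exp(-3)) <= 1e-10
        assert s2 > s3  # lower frequency scores higher

    def test_scale_invariance(self, grid10):
        _, basis = grid10
        f = np.random.default_rng(0).normal(size=basis.n)
        fh = sgft.gft(basis, f)
        a = sgft.gftscore(basis.eigenvalues, fh)
        b = sgft.gftscore(basis.eigenvalues, 5.0 * fh)
        assert abs(a - b) <= 1e-12

    def test_monotone_in_mode_index(self, grid10):
        """One-hot coefficient vectors at increasing frequency score less."""
        _, basis = grid10
        scores = []
        for k in [1, 10, 50, 99]:
            fh = np.zeros(basis.n)
            fh[k] = 1.0
            scores.append(sgft.gftscore(basis.eigenvalues, fh))
        assert all(a > b for a, b in zip(scores, scores[1:]))


class TestScoreCutoff:
    def test_cliff_cutoff_between_groups(self):
        scores = np.array([10, 9.5, 9, 1.1, 1.0, 0.9, 0.85, 0.8])
        cut = sgft.score_cutoff(scores, sensitivity=1)
        assert 1.1 <= cut <= 9.0

    def test_equal_scores_fall_back(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="sgft"):
            cut = sgft.score_cutoff(np.full(10, 2.0))
        assert cut == 2.0
        assert any("no knee" in r.message for r in caplog.records)

    def test_cutoff_stable_under_subthreshold_additions(self):
        scores = np.concatenate([[10, 9.5, 9], np.linspace(1.1, 0.8, 17)])
        cut1 = sgft.score_cutoff(scores, sensitivity=1)
        more = np.concatenate([scores, np.linspace(0.5, 0.4, 10)])
        cut2 = sgft.score_cutoff(more, sensitivity=1)
        assert cut2 <= cut1  # knee stays at or above the original cliff
        assert cut2 >= 1.0


class TestBandTest:
    def test_extreme_separation_exact_p(self):
        # low = {5,6,7}, high = {1,2,3}: p = 1/C(6,3) = 0.05
        fcs = np.array([9.0, 5, 6, 7, 4, 1, 2, 3])
        p = sgft.band_test(fcs, n_low=3, n_high=3)
        assert abs(p - 0.05) <= 1e-12

    def test_reversed_separation_near_one(self):
        fcs = np.array([9.0, 1, 2, 3, 4, 5, 6, 7])
        assert sgft.band_test(fcs, 3, 3) >= 0.95

    def test_overlapping_bands_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            sgft.band_test(np.arange(6, dtype=float), 3, 3)

    @pytest.mark.parametrize("n_low, n_high", [(3, 3), (4, 5), (6, 6)])
    def test_matches_exact_enumeration(self, n_low, n_high):
        rng = np.random.default_rng(2)
        for _ in range(5):
            fcs = np.concatenate([[1.0], rng.normal(size=n_low + n_high)])
            p = sgft.band_test(fcs, n_low, n_high)
            low = np.abs(fcs[1 : 1 + n_low])
            high = np.abs(fcs[-n_high:])
            assert abs(p - exact_ranksum_p(low, high)) <= 1e-9

    def test_null_pvalues_uniform(self, grid15):
        """Rank-sum p-values are U(0,1) for i.i.d. Gaussian spot signals."""
        _, basis = grid15
        rng = np.random.default_rng(0)
        F = rng.normal(size=(10000, basis.n)) @ basis.modes
        p = sgft.band_test(F, basis.n_low, basis.n_high, skip=basis.n_zero)
        assert kstest(p, "uniform").pvalue > 0.01


class TestFdrAdjust:
    def test_bh_by_hand(self):
        np.testing.assert_allclose(
            sgft.fdr_adjust(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(sgft.fdr_adjust(np.array([0.2])), [0.2])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            sgft.fdr_adjust(np.array([0.5, 1.5]))

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_dominates_input_and_bounded(self, seed):
        p = np.random.default_rng(seed).uniform(size=25)
        q = sgft.fdr_adjust(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1.0)


class TestIdentifySvgs:
    def test_planted_patterns_recovered(self, grid15):
        """Planted spatial genes are called; spot-permuted copies score lower."""
        g, basis = grid15
        ds = sgft.make_benchmark(n_svg=20, n_null=180, grid=(15, 15), seed=7)
        expr = sgft.normalize(ds.raw)
        table = sgft.identify_svgs(expr, g, basis)
        truth = ds.truth_svg
        called = table["svg"].to_numpy()
        recall = (called & truth).sum() / truth.sum()
        fdp = (called & ~truth).sum() / max(1, called.sum())
        assert recall >= 0.8
        assert fdp <= 0.10

    def test_pure_noise_rarely_called(self, grid15):
        g, basis = grid15
        fractions = []
        for seed in range(5):
            ds = sgft.make_benchmark(n_svg=0, n_null=200, grid=(15, 15), seed=seed)
            expr = sgft.normalize(ds.raw)
            fractions.append(sgft.identify_svgs(expr, g, basis)["svg"].mean())
        assert np.mean(fractions) <= 0.07

    def test_permutation_destroys_score(self, grid15):
        g, basis = grid15
        wins = 0
        for seed in range(10):
            ds = sgft.make_benchmark(n_svg=1, n_null=50, grid=(15, 15), seed=seed)
            expr = sgft.normalize(ds.raw)
            perm = np.random.default_rng(seed).permutation(basis.n)
            fh = sgft.gft(basis, expr.values[0])
            fh_perm = sgft.gft(basis, expr.values[0][perm])
            s = sgft.gftscore(basis.eigenvalues, fh)
            s_perm = sgft.gftscore(basis.eigenvalues, fh_perm)
            wins += s > s_perm
        assert wins >= 9

    def test_deterministic(self, grid15):
        g, basis = grid15
        ds = sgft.make_benchmark(n_svg=10, n_null=90, grid=(15, 15), seed=3)
        expr = sgft.normalize(ds.raw)
        t1 = sgft.identify_svgs(expr, g, basis)
        t2 = sgft.identify_svgs(expr, g, basis)
        assert t1.equals(t2)

    def test_rank_is_permutation_sorted_by_score(self, grid15):
        g, basis = grid15
        ds = sgft.make_benchmark(n_svg=5, n_null=45, grid=(15, 15), seed=1)
        expr = sgft.normalize(ds.raw)
        t = sgft.identify_svgs(expr, g, basis)
        assert sorted(t["rank"]) == list(range(1, len(t) + 1))
        by_rank = t.sort_values("rank")["gftscore"].to_numpy()
        assert np.all(np.diff(by_rank) <= 1e-12)

    def test_spot_mismatch_rejected(self, grid15, grid10):
        g15, b15 = grid15
        _, b10 = grid10
        ds = sgft.make_benchmark(n_svg=2, n_null=8, grid=(15, 15), seed=0)
        expr = sgft.normalize(ds.raw)
        with pytest.raises(ValueError, match="spot mismatch"):
            sgft.identify_svgs(expr, g15, b10)
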