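import itertools
import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import rankdata

from semethyl.io import GenomicInterval
from semethyl.se_methylation import SuperEnhancer
from semethyl.stats import (
    ContingencyTable2x2,
    WindowRecord,
    assign_target,
    bh_fdr,
    classify_cpg,
    fisher_exact,
    linear_model_signal,
    loglinear_expression,
    rank_sum_test,
    spearman,
    window_stats,
)


class TestClassifyCpG:
    @pytest.mark.parametrize("lv,cls", [(0.10, "hypo"), (0.90, "hyper"),
                                        (0.50, "intermediate"),
                                        (0.33, "intermediate"),
                                        (0.66, "intermediate")])
    def test_thresholds(self, lv, cls):
        assert classify_cpg(lv) == cls

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            classify_cpg(1.2)


def fisher_enumeration_oracle(a, b, c, d):
    """Exact rational two-sided Fisher p by direct enumeration."""
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return Fraction(math.comb(c1, x) * math.comb(n - c1, r1 - x),
                        math.comb(n, r1))

    p_obs = prob(a)
    total = Fraction(0)
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        if prob(x) <= p_obs:
            total += prob(x)
    return float(total)


class TestFisherExact:
    def test_no_association(self):
        oratio, p = fisher_exact(ContingencyTable2x2(10, 10, 10, 10))
        assert oratio == 1.0
        assert p == pytest.approx(1.0)

    def test_oracle_agreement(self):
        oratio, p = fisher_exact(ContingencyTable2x2(8, 2, 2, 8))
        assert oratio == pytest.approx(16.0)
        assert p == pytest.approx(fisher_enumeration_oracle(8, 2, 2, 8), abs=1e-12)

    def test_haldane_correction(self):
        oratio, _ = fisher_exact(ContingencyTable2x2(5, 0, 5, 5))
        assert oratio == pytest.approx(11.0)

    def test_zero_margin(self):
        oratio, p = fisher_exact(ContingencyTable2x2(0, 0, 5, 5))
        assert math.isnan(oratio)
        assert p == 1.0

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12),
           st.integers(0, 12))
    @settings(max_examples=60, deadline=None)
    def test_enumeration_property(self, a, b, c, d):
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        _, p = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert p == pytest.approx(fisher_enumeration_oracle(a, b, c, d),
                                  rel=1e-9, abs=1e-12)

    def test_row_swap_inverts_or(self):
        or1, p1 = fisher_exact(ContingencyTable2x2(8, 2, 3, 7))
        or2, p2 = fisher_exact(ContingencyTable2x2(3, 7, 8, 2))
        assert or2 == pytest.approx(1 / or1)
        assert p2 == pytest.approx(p1, rel=1e-9)

    def test_double_swap_invariant(self):
        or1, p1 = fisher_exact(ContingencyTable2x2(8, 2, 3, 7))
        or2, p2 = fisher_exact(ContingencyTable2x2(7, 3, 2, 8))
        assert or2 == pytest.approx(or1)
        assert p2 == pytest.approx(p1, rel=1e-9)


class TestWindowStats:
    def region(self, length):
        return GenomicInterval("chr1", 0, length)

    def tracks(self, length, signal=2.0):
        pos = np.arange(length)
        return pos, np.full(length, signal)

    def test_exact_tiling(self):
        sp, sv = self.tracks(200)
        recs = window_stats(sp, sv, np.array([25]), np.array([0.1]),
                            self.region(200))
        assert len(recs) == 4
        assert not any(w.is_remainder for w in recs)

    def test_remainder_window(self):
        sp, sv = self.tracks(230)
        recs = window_stats(sp, sv, np.array([25]), np.array([0.1]),
                            self.region(230))
        assert len(recs) == 5
        assert recs[-1].is_remainder
        assert len(recs[-1].interval) == 30

    def test_constant_signal(self):
        sp, sv = self.tracks(200, signal=2.0)
        recs = window_stats(sp, sv, np.array([25]), np.array([0.1]),
                            self.region(200))
        assert all(w.mean_signal == pytest.approx(2.0) for w in recs)

    def test_no_cpg_window_flagged(self):
        sp, sv = self.tracks(100)
        recs = window_stats(sp, sv, np.array([75]), np.array([0.9]),
                            self.region(100))
        assert math.isnan(recs[0].mean_meth) and recs[0].meth_class is None
        assert recs[1].meth_class == "hyper"


def ranksum_enumeration_oracle(x, y):
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    n1 = len(x)
    w = ranks[:n1].sum()
    lower = upper = total = 0
    for comb in itertools.combinations(range(len(pooled)), n1):
        ws = ranks[list(comb)].sum()
        total += 1
        lower += ws <= w + 1e-9
        upper += ws >= w - 1e-9
    return w, min(1.0, 2 * min(lower / total, upper / total))


class TestRankSum:
    def test_extreme_exact(self):
        w, p = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert w == 6.0
        assert p == pytest.approx(0.1)  # 2 * 1/20

    def test_identical_groups(self):
        _, p = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert p == pytest.approx(1.0)

    def test_symmetry(self):
        _, p1 = rank_sum_test([1, 5, 3], [2, 8, 9])
        _, p2 = rank_sum_test([2, 8, 9], [1, 5, 3])
        assert p1 == pytest.approx(p2)

    def test_all_identical(self):
        _, p = rank_sum_test([2, 2], [2, 2, 2])
        assert p == 1.0

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_exact_matches_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 6, size=5).astype(float)
        y = rng.integers(0, 6, size=6).astype(float)
        if np.allclose(np.concatenate([x, y]), x[0]):
            return
        w, p = rank_sum_test(x, y)
        w0, p0 = ranksum_enumeration_oracle(x, y)
        assert w == pytest.approx(w0)
        assert p == pytest.approx(p0)

    def test_large_sample_normal_approx(self, rng):
        x = rng.normal(0, 1, size=40)
        y = rng.normal(1.2, 1, size=40)
        _, p = rank_sum_test(x, y)
        assert p < 1e-4


class TestLinearModelSignal:
    def window(self, signal, cls, density=0.02, start=0):
        return WindowRecord(GenomicInterval("chr1", start, start + 50),
                            signal, 0.1 if cls == "hypo" else 0.9, density, cls)

    def test_noiseless_fit(self):
        wins = [self.window(3.0 - 2.0 * (i % 2), "hyper" if i % 2 else "hypo",
                            density=0.01 + 0.001 * (i % 5), start=i * 50)
                for i in range(12)]
        out = linear_model_signal(wins)
        assert out["status"] == pytest.approx(-2.0, abs=1e-10)

    def test_single_status_error(self):
        wins = [self.window(1.0, "hypo", start=i * 50) for i in range(5)]
        with pytest.raises(ValueError):
            linear_model_signal(wins)

    def test_matches_normal_equation_oracle(self, rng):
        wins = []
        for i in range(40):
            cls = "hyper" if rng.random() < 0.5 else "hypo"
            dens = rng.uniform(0.005, 0.05)
            sig = rng.normal(2.0, 0.3)
            wins.append(self.window(sig, cls, density=dens, start=i * 50))
        out = linear_model_signal(wins)
        X = np.column_stack([
            np.ones(len(wins)),
            [1.0 if w.meth_class == "hyper" else 0.0 for w in wins],
            [w.cpg_density for w in wins]])
        yv = np.array([w.mean_signal for w in wins])
        beta = np.linalg.solve(X.T @ X, X.T @ yv)
        assert out["intercept"] == pytest.approx(beta[0], abs=1e-8)
        assert out["status"] == pytest.approx(beta[1], abs=1e-8)
        assert out["density"] == pytest.approx(beta[2], abs=1e-8)


def spearman_permutation_oracle(x, y):
    rx = rankdata(x)
    ry = rankdata(y)
    rho = np.corrcoef(rx, ry)[0, 1]
    count = total = 0
    for perm in itertools.permutations(ry):
        r = np.corrcoef(rx, perm)[0, 1]
        total += 1
        count += abs(r) >= abs(rho) - 1e-12
    return rho, count / total


class TestSpearman:
    def test_increasing(self):
        r = spearman([1, 2, 3, 4, 5], [10, 20, 30, 40, 50])
        assert r.rho == pytest.approx(1.0)

    def test_decreasing(self):
        r = spearman([1, 2, 3, 4], [9, 7, 5, 3])
        assert r.rho == pytest.approx(-1.0)

    def test_ties_against_permutation_oracle(self):
        x = [1.0, 2.0, 2.0, 3.0, 4.0]
        y = [5.0, 5.0, 7.0, 8.0, 6.0]
        res = spearman(x, y)
        rho0, p0 = spearman_permutation_oracle(x, y)
        assert res.rho == pytest.approx(rho0, abs=1e-12)
        assert res.p == pytest.approx(p0, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        r1 = spearman(x, y)
        r2 = spearman(np.exp(x), y ** 3)
        assert r1.rho == pytest.approx(r2.rho, abs=1e-12)
        assert r1.p == pytest.approx(r2.p, abs=1e-12)

    def test_zero_variance_flagged(self):
        res = spearman([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert math.isnan(res.rho)


class TestAssignTarget:
    def se(self, start=10_000, end=20_000):
        return SuperEnhancer(GenomicInterval("chr1", start, end, "SE1"),
                             se_id="SE1")

    def test_tss_inside(self):
        tss = [("G1", "chr1", 15_000), ("G2", "chr1", 50_000)]
        assert assign_target(self.se(), tss) == "G1"

    def test_beyond_one_mb_none(self):
        tss = [("G1", "chr1", 20_000 + 1_000_000)]
        assert assign_target(self.se(), tss) is None

    def test_at_one_mb_kept(self):
        tss = [("G1", "chr1", 10_000 - 1_000_000)]
        assert assign_target(self.se(), tss) == "G1"

    def test_tie_break_smaller_coordinate(self):
        tss = [("GR", "chr1", 25_000), ("GL", "chr1", 5_000)]
        # left at 5000: distance 5000; right at 25000: distance 5001 (end-exclusive)
        assert assign_target(self.se(), tss) == "GL"

    def test_other_chrom_ignored(self):
        assert assign_target(self.se(), [("G1", "chr2", 15_000)]) is None


class TestLoglinearExpression:
    def test_noiseless_slope(self):
        # expr = exp(2 - 3*meth) - 1 stays non-negative for meth <= 2/3
        meth = np.linspace(0.05, 0.65, 10)
        expr = np.exp(2 - 3 * meth) - 1
        slope, p = loglinear_expression(expr, meth)
        assert slope == pytest.approx(-3.0, abs=1e-10)
        assert p < 1e-10

    def test_constant_meth_error(self):
        with pytest.raises(ValueError):
            loglinear_expression([1.0, 2.0, 3.0], [0.5, 0.5, 0.5])

    def test_matches_normal_equation_oracle(self, rng):
        meth = rng.uniform(0, 1, size=25)
        expr = np.exp(1.5 - 2 * meth + rng.normal(0, 0.2, size=25))
        slope, _ = loglinear_expression(expr, meth)
        X = np.column_stack([np.ones(25), meth])
        beta = np.linalg.solve(X.T @ X, X.T @ np.log1p(expr))
        assert slope == pytest.approx(beta[1], abs=1e-8)


class TestBHFDR:
    def test_hand_computed_stepup(self):
        # p*n/i = [.04,.04,.04,.04]; cummin from the top keeps .04
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), 0.04)

    def test_single_p_unchanged(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_bounds_property(self, ps):
        adj = bh_fdr(ps)
        assert np.all(adj >= np.asarray(ps) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)

    def test_monotone_after_sorting(self, rng):
        ps = rng.uniform(0, 1, size=20)
        adj = bh_fdr(ps)
        order = np.argsort(ps)
        assert np.all(np.diff(adj[order]) >= -1e-12)
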