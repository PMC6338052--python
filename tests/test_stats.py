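"""m/M estimator, roar value, exact Fisher testing, pooled per-gene stats."""

import math
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from apadiff.annotation import ApaSegmentation, PolyASite
from apadiff.quant import RegionCounts
from apadiff.stats import (
    all_pairings_pvalues,
    fisher_pre_post,
    m_over_M,
    pooled_gene_stat,
    roar_value,
)


def exact_two_sided_fisher(a, b, c, d):
    """Independent oracle: exhaustive hypergeometric enumeration in rationals."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    denom = math.comb(n, c1)
    obs = Fraction(math.comb(r1, a) * math.comb(r2, c1 - a), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)
        if pk <= obs:
            total += pk
    return total


class TestFisher:
    def test_identical_proportions_give_one(self):
        assert fisher_pre_post(10, 10, 10, 10) == 1.0

    def test_disjoint_table_matches_enumeration(self):
        assert fisher_pre_post(5, 0, 0, 5) == pytest.approx(2 / 252, abs=1e-15)

    def test_empty_margins_undefined(self):
        assert math.isnan(fisher_pre_post(0, 0, 0, 0))
        assert math.isnan(fisher_pre_post(0, 0, 3, 4))
        assert math.isnan(fisher_pre_post(0, 3, 0, 4))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            fisher_pre_post(-1, 2, 3, 4)

    @given(
        st.integers(0, 40), st.integers(0, 40), st.integers(0, 40), st.integers(0, 40)
    )
    def test_matches_rational_enumeration_oracle(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        assert fisher_pre_post(a, b, c, d) == pytest.approx(
            float(exact_two_sided_fisher(a, b, c, d)), abs=1e-12
        )

    @given(
        st.integers(0, 60), st.integers(0, 60), st.integers(0, 60), st.integers(0, 60)
    )
    def test_matches_scipy_cross_check(self, a, b, c, d):
        from scipy.stats import fisher_exact

        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        ours = fisher_pre_post(a, b, c, d)
        assert ours == pytest.approx(fisher_exact([[a, b], [c, d]])[1], abs=1e-9)
        assert 0.0 <= ours <= 1.0

    @given(st.integers(0, 30), st.integers(0, 30), st.integers(0, 30), st.integers(0, 30))
    def test_row_and_column_swap_invariance(self, a, b, c, d):
        if (a + b) == 0 or (c + d) == 0 or (a + c) == 0 or (b + d) == 0:
            return
        p = fisher_pre_post(a, b, c, d)
        assert fisher_pre_post(c, d, a, b) == pytest.approx(p, abs=1e-12)
        assert fisher_pre_post(b, a, d, c) == pytest.approx(p, abs=1e-12)


class TestMoverM:
    @pytest.mark.parametrize(
        "pre,post,prelen,postlen,expected",
        [(100, 50, 1000, 500, 0.0), (300, 50, 1000, 500, 2.0), (50, 100, 1000, 500, -0.75)],
    )
    def test_formula(self, pre, post, prelen, postlen, expected):
        assert m_over_M(pre, post, prelen, postlen) == pytest.approx(expected)

    def test_zero_post_is_undefined(self):
        assert m_over_M(10, 0, 1000, 500) is None

    def test_bad_lengths_rejected(self):
        with pytest.raises(ValueError):
            m_over_M(1, 1, 0, 500)

    def test_recovers_molar_mixture_within_five_percent(self):
        # 2:1 short:long mixture, i.e. true m/M = 2: short molecules cover only
        # PRE, long ones cover PRE and POST uniformly per-base
        rng = np.random.default_rng(42)
        pre_len, post_len = 1000, 500
        short, long_ = 2, 1
        w_pre = (short + long_) * pre_len
        w_post = long_ * post_len
        n = 100_000
        pre = rng.binomial(n, w_pre / (w_pre + w_post))
        est = m_over_M(pre, n - pre, pre_len, post_len)
        assert est == pytest.approx(2.0, rel=0.05)

    @pytest.mark.parametrize("true_r", [0.25, 1.0, 4.0])
    def test_estimator_consistency(self, true_r):
        rng = np.random.default_rng(int(true_r * 100))
        pre_len, post_len = 1000, 500
        f = 1.0 / (1.0 + true_r)  # long molar fraction
        w_pre, w_post = pre_len, f * post_len
        n = 100_000
        pre = rng.binomial(n, w_pre / (w_pre + w_post))
        est = m_over_M(pre, n - pre, pre_len, post_len)
        assert est == pytest.approx(true_r, rel=0.10)


class TestRoar:
    def test_identity(self):
        assert roar_value(1.0, 1.0) == 1.0

    def test_shortening_direction(self):
        assert roar_value(0.5, 2.0) == pytest.approx(4.0)

    def test_undefined_cases(self):
        assert roar_value(0.0, 2.0) is None
        assert roar_value(None, 2.0) is None
        assert roar_value(2.0, None) is None


def _rc(sample_id, cond, counts, lib=10_000):
    return RegionCounts(sample_id, cond, counts, lib)


SEG = ApaSegmentation(
    gene_id="g1",
    chrom="chr1",
    strand="+",
    pre_intervals=((0, 1000),),
    post_intervals=((1000, 1500),),
    proximal_site=PolyASite("chr1", 1000, "+", "s"),
    canonical_end=1500,
)


class TestPairings:
    def test_three_by_three_gives_nine(self):
        base = [_rc(f"b{i}", "T0", {"g1": (10, 5)}) for i in range(3)]
        con = [_rc(f"c{i}", "T1", {"g1": (10, 5)}) for i in range(3)]
        ps = all_pairings_pvalues(base, con, "g1")
        assert len(ps) == 9
        assert all(p == 1.0 for p in ps)

    def test_single_pair_reduces_to_fisher(self):
        base = [_rc("b", "T0", {"g1": (12, 3)})]
        con = [_rc("c", "T1", {"g1": (4, 9)})]
        assert all_pairings_pvalues(base, con, "g1") == [fisher_pre_post(12, 3, 4, 9)]

    def test_missing_gene_raises_mismatch(self):
        base = [_rc("b", "T0", {"g1": (1, 1)})]
        con = [_rc("c", "T1", {"g2": (1, 1)})]
        with pytest.raises(ValueError, match="gene/sample mismatch"):
            all_pairings_pvalues(base, con, "g1")


class TestPooledStat:
    def test_null_identity(self):
        base = [_rc(f"b{i}", "T0", {"g1": (300, 50)}) for i in range(3)]
        con = [_rc(f"c{i}", "T1", {"g1": (300, 50)}) for i in range(3)]
        stat = pooled_gene_stat(base, con, SEG, "g1")
        assert stat.roar == pytest.approx(1.0)
        assert all(p == 1.0 for p in stat.pairwise_pvalues)
        assert stat.flag == "ok"

    def test_zero_post_flagged(self):
        base = [_rc("b", "T0", {"g1": (100, 0)})]
        con = [_rc("c", "T1", {"g1": (100, 50)})]
        stat = pooled_gene_stat(base, con, SEG, "g1")
        assert stat.flag == "zero_post"
        assert stat.roar is None

    def test_negative_mM_flagged(self):
        base = [_rc("b", "T0", {"g1": (10, 100)})]
        con = [_rc("c", "T1", {"g1": (100, 50)})]
        assert pooled_gene_stat(base, con, SEG, "g1").flag == "negative_mM"

    def test_fpkm_uses_pooled_common_region(self):
        base = [_rc("b1", "T0", {"g1": (100, 50)}, lib=10**6),
                _rc("b2", "T0", {"g1": (300, 150)}, lib=10**6)]
        con = [_rc("c", "T1", {"g1": (100, 50)}, lib=2 * 10**6)]
        stat = pooled_gene_stat(base, con, SEG, "g1")
        # pooled pre 400 over 1 kb and 2M reads -> 200; contrast 100 over 2M -> 50
        assert stat.fpkm_baseline == pytest.approx(200.0)
        assert stat.fpkm_contrast == pytest.approx(50.0)

    def test_roar_scale_invariance(self):
        base = [_rc("b", "T0", {"g1": (120, 30)})]
        con = [_rc("c", "T1", {"g1": (80, 60)})]
        r1 = pooled_gene_stat(base, con, SEG, "g1").roar
        scaled = [_rc("c", "T1", {"g1": (80 * 7, 60 * 7)}, lib=70_000)]
        r2 = pooled_gene_stat(base, scaled, SEG, "g1").roar
        assert r1 == pytest.approx(r2)

    def test_detects_planted_shortening(self, small_genome):
        """A 0.2 -> 0.8 short-fraction shift at depth 300 is significant."""
        from apadiff.synthetic import simulate_counts

        genome, segs = small_genome
        # build a single-gene truth with a strong shortening shift
        import dataclasses

        from apadiff.synthetic import SyntheticTruth

        gid = sorted(genome.truth.genes)[0]
        t = dataclasses.replace(
            genome.truth.genes[gid], long_fraction={"T0": 0.8, "T1": 0.2},
            expression_level=1.0,
        )
        truth = SyntheticTruth(("T0", "T1"), {gid: t})
        samples = simulate_counts(truth, n_replicates=3, mean_depth=300, dispersion=0.1, seed=55)
        base = [s for s in samples if s.condition == "T0"]
        con = [s for s in samples if s.condition == "T1"]
        stat = pooled_gene_stat(base, con, segs[gid], gid)
        assert stat.roar is not None and stat.roar > 1
        assert len(stat.pairwise_pvalues) == 9
        assert all(p < 0.05 for p in stat.pairwise_pvalues)
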