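import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given, settings
from hypothesis import strategies as st

from cyclodose import (
    delivered_expected_ratio,
    mann_whitney,
    median_range,
    spearman,
    wilcoxon_signed_rank,
)


def _u_bruteforce(x, y):
    """Independent oracle: count of (x_i > y_j) pairs, ties counted half."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


class TestMannWhitney:
    def test_tiny_exact_example(self):
        res = mann_whitney([1, 2], [3, 4], method="exact_enumeration")
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(2.0 / 6.0, rel=1e-12)

    def test_identical_samples_null(self):
        res = mann_whitney([5, 5, 5], [5, 5, 5])
        assert res.statistic == 4.5  # n1*n2/2 from midranks
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney([], [1, 2])

    def test_exact_enumeration_size_cap(self):
        with pytest.raises(ValueError, match="<= 20"):
            mann_whitney(list(range(11)), list(range(10)), "exact_enumeration")

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError, match="method"):
            mann_whitney([1], [2], method="bootstrap")

    def test_fixture_cycle4_delivered_vs_expected(self, cohort):
        res = [delivered_expected_ratio(c, "tumour", 4) for c in cohort]
        delivered = [r.ad_delivered_gy for r in res]
        expected = [r.ad_expected_gy for r in res]
        cc = mann_whitney(delivered, expected)
        assert cc.statistic == 2.0
        assert cc.statistic == _u_bruteforce(delivered, expected)
        assert round(cc.p_value, 3) == 0.013
        exact = mann_whitney(delivered, expected, "exact_enumeration")
        assert exact.statistic == 2.0
        assert round(exact.p_value, 3) == 0.009  # route the paper did not use

    @given(
        x=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
        y=st.lists(st.floats(-50, 50), min_size=1, max_size=8),
    )
    def test_u_complementarity(self, x, y):
        u1 = mann_whitney(x, y).statistic
        u2 = mann_whitney(y, x).statistic
        assert u1 + u2 == pytest.approx(len(x) * len(y), abs=1e-9)

    @given(
        x=st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=2, max_size=7
        ),
        y=st.lists(
            st.floats(-10, 10, allow_nan=False), min_size=2, max_size=7
        ),
    )
    @settings(max_examples=50)
    def test_u_matches_bruteforce_pair_count(self, x, y):
        assert mann_whitney(x, y).statistic == pytest.approx(
            _u_bruteforce(x, y), abs=1e-9
        )

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(7)
        for _ in range(50):
            x = rng.normal(0, 1, rng.integers(3, 9))
            y = rng.normal(0.5, 1.2, rng.integers(3, 9))
            ours = mann_whitney(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
            assert ours.statistic == pytest.approx(float(ref.statistic), abs=1e-9)
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_exact_agrees_with_scipy_exact(self):
        rng = np.random.default_rng(11)
        for _ in range(20):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.8, 1, 6)
            ours = mann_whitney(x, y, "exact_enumeration")
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)

    def test_calibration_exact_vs_normal_cc(self):
        # exact and continuity-corrected p agree within 0.03 at n1 = n2 = 6
        rng = np.random.default_rng(0)
        worst = 0.0
        for _ in range(200):
            x = rng.normal(0, 1, 6)
            y = rng.normal(rng.uniform(-2, 2), 1, 6)
            pe = mann_whitney(x, y, "exact_enumeration").p_value
            pc = mann_whitney(x, y, "normal_cc").p_value
            worst = max(worst, abs(pe - pc))
        assert worst <= 0.03

    @pytest.mark.parametrize(
        "n1, n2", [(n1, n2) for n1 in range(1, 5) for n2 in range(n1, 5)]
    )
    def test_decision_agreement_exhaustive_small_n(self, n1, n2):
        # on rank-distinct data, normal_cc never flips the alpha = 0.10
        # decision versus exact enumeration, for all rank assignments
        n = n1 + n2
        alpha = 0.10
        for combo in itertools.combinations(range(1, n + 1), n1):
            x = list(combo)
            y = [r for r in range(1, n + 1) if r not in combo]
            pe = mann_whitney(x, y, "exact_enumeration").p_value
            pc = mann_whitney(x, y, "normal_cc").p_value
            assert (pe <= alpha) == (pc <= alpha), (x, y, pe, pc)


class TestSpearman:
    def test_perfect_increasing(self):
        res = spearman([(1, 10), (2, 20), (3, 25), (4, 90)])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == 0.0

    def test_perfect_decreasing(self):
        res = spearman([(1, 9), (2, 5), (3, 1)])
        assert res.statistic == pytest.approx(-1.0)

    def test_constant_margin_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            spearman([(1, 5), (2, 5), (3, 5)])

    def test_too_few_pairs(self):
        with pytest.raises(ValueError):
            spearman([(1, 2), (3, 4)])

    def test_fixture_tumour_vs_kidney_ad_per_aa(self, cohort):
        pairs = [
            (c.ad_per_aa("tumour"), c.ad_per_aa("kidney"))
            for course in cohort
            for c in course.cycles
        ]
        assert len(pairs) == 24
        res = spearman(pairs)
        assert res.statistic == pytest.approx(-0.25, abs=0.02)

        # brute-force sum-of-squared-rank-differences oracle (no ties here)
        a = [p[0] for p in pairs]
        b = [p[1] for p in pairs]
        ra = [sorted(a).index(v) + 1 for v in a]
        rb = [sorted(b).index(v) + 1 for v in b]
        d2 = sum((x - y) ** 2 for x, y in zip(ra, rb))
        n = len(pairs)
        rho_oracle = 1 - 6 * d2 / (n * (n**2 - 1))
        assert res.statistic == pytest.approx(rho_oracle, rel=1e-12)

    def test_symmetry_under_margin_swap(self):
        pairs = [(1.0, 4.0), (2.0, 1.0), (5.0, 3.0), (7.0, 2.0)]
        swapped = [(b, a) for a, b in pairs]
        assert spearman(pairs).statistic == pytest.approx(
            spearman(swapped).statistic, rel=1e-12
        )

    @given(
        data=st.lists(
            st.tuples(st.integers(-1000, 1000), st.integers(-1000, 1000)),
            min_size=4,
            max_size=10,
            unique_by=(lambda p: p[0], lambda p: p[1]),
        ),
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-5, 5),
    )
    @settings(max_examples=50)
    def test_invariant_under_monotone_transform(self, data, scale, shift):
        # affine map on well-separated values: strictly increasing and
        # injective in floating point, so ranks are preserved exactly
        transformed = [(scale * a + shift, b) for a, b in data]
        assert spearman(data).statistic == pytest.approx(
            spearman(transformed).statistic, abs=1e-9
        )

    def test_agrees_with_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(25):
            pairs = list(zip(rng.normal(size=8), rng.normal(size=8)))
            ours = spearman(pairs)
            ref = sps.spearmanr([p[0] for p in pairs], [p[1] for p in pairs])
            assert ours.statistic == pytest.approx(float(ref.statistic), abs=1e-12)
            assert ours.p_value == pytest.approx(float(ref.pvalue), abs=1e-9)


class TestMedianRange:
    def test_cycle1_tumour_values(self):
        med, lo, hi = median_range([8.12, 11.8, 13.5, 17.7, 21.3, 26.4])
        assert (med, lo, hi) == (15.6, 8.12, 26.4)

    def test_singleton(self):
        assert median_range([5.0]) == (5.0, 5.0, 5.0)

    def test_even_midpoint(self):
        assert median_range([1, 2, 3, 4]) == (2.5, 1.0, 4.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            median_range([])


def test_signed_rank_alternative_exposed(cohort):
    res = [delivered_expected_ratio(c, "tumour", 4) for c in cohort]
    out = wilcoxon_signed_rank(
        [r.ad_delivered_gy for r in res], [r.ad_expected_gy for r in res]
    )
    assert out.method == "signed_rank"
    assert 0.0 <= out.p_value <= 1.0
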