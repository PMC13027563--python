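"""Rank tests, letter displays and regressions against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from dendromorph import (
    ValidationError,
    fit_linear_regression,
    mann_whitney,
    pairwise_letter_display,
)
from dendromorph.stats import RankTestMethod


class TestMannWhitney:
    def test_fully_separated_small_samples(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0
        assert res.method is RankTestMethod.EXACT_ENUMERATION
        # 2 of the C(6,3)=20 labelings are as extreme
        assert res.p_two_sided == pytest.approx(0.1)

    def test_identical_samples(self):
        res = mann_whitney([1, 2, 3], [1, 2, 3])
        assert res.u_statistic == pytest.approx(4.5)  # n1*n2/2
        assert res.z_statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_all_values_tied(self):
        res = mann_whitney([2.0] * 5, [2.0] * 7)
        assert res.z_statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_maximum_z_for_balanced_33(self):
        # two fully separated tie-free samples of 33: |Z| attains the
        # design's theoretical maximum 544.5/sqrt(6080.25)
        a = np.arange(33, dtype=float)
        b = np.arange(100, 133, dtype=float)
        res = mann_whitney(a, b)
        assert abs(res.z_statistic) == pytest.approx(544.5 / math.sqrt(6080.25), abs=1e-6)
        assert abs(res.z_statistic) == pytest.approx(6.982, abs=1e-3)
        assert res.method is RankTestMethod.NORMAL_APPROX

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney([], [1.0])

    def test_exact_p_matches_scipy_enumeration(self):
        # independent oracle: scipy's exact method on tie-free samples
        rng = np.random.default_rng(42)
        for _ in range(40):
            n1 = int(rng.integers(2, 6))
            n2 = int(rng.integers(2, 9 - n1))
            pooled = rng.permutation(np.arange(20.0))[: n1 + n2]
            a, b = pooled[:n1], pooled[n1:]
            ours = mann_whitney(a, b)
            ref = sps.mannwhitneyu(a, b, alternative="two-sided", method="exact")
            assert ours.method is RankTestMethod.EXACT_ENUMERATION
            assert ours.p_two_sided == pytest.approx(ref.pvalue, abs=1e-12)

    def test_u_statistics_sum_to_n1_n2(self):
        rng = np.random.default_rng(7)
        for _ in range(30):
            n1 = int(rng.integers(1, 12))
            n2 = int(rng.integers(1, 12))
            a = rng.integers(0, 6, size=n1).astype(float)  # many ties
            b = rng.integers(0, 6, size=n2).astype(float)
            res = mann_whitney(a, b)
            assert res.u_statistic + res.u_other == pytest.approx(n1 * n2)

    def test_invariance_under_monotone_transform(self):
        rng = np.random.default_rng(3)
        a = rng.normal(0, 1, 15)
        b = rng.normal(0.8, 1, 12)
        base = mann_whitney(a, b)
        for transform in (np.exp, lambda x: x**3, lambda x: np.arctan(x)):
            res = mann_whitney(transform(a), transform(b))
            assert res.u_statistic == pytest.approx(base.u_statistic)
            assert res.p_two_sided == pytest.approx(base.p_two_sided)

    def test_exact_close_to_normal_for_six_vs_six(self):
        # tie-free spot grid: without continuity correction the two-sided
        # normal p can sit up to ~0.07 below the exact mid-range p (the
        # worst case over all C(12,6) splits is 0.0694)
        rng = np.random.default_rng(11)
        for _ in range(20):
            pooled = rng.permutation(np.arange(40.0))[:12]
            a, b = pooled[:6], pooled[6:]
            exact = mann_whitney(a, b, exact_threshold=12)
            approx = mann_whitney(a, b, exact_threshold=0)
            assert approx.method is RankTestMethod.NORMAL_APPROX
            assert abs(exact.p_two_sided - approx.p_two_sided) < 0.07


class TestLetterDisplay:
    def test_three_separated_groups_get_distinct_letters(self):
        groups = {
            "sibiricus": list(np.linspace(10, 11, 20)),
            "pini": list(np.linspace(1, 2, 20)),
            "hybrid": list(np.linspace(5, 6, 20)),
        }
        display = pairwise_letter_display(groups, alpha=0.01)
        assert sorted(display.letters.values()) == ["a", "b", "c"]

    def test_one_group_apart_two_together(self):
        # first group differs from both; the other two indistinguishable
        rng = np.random.default_rng(4)
        groups = {
            "sibiricus": list(rng.normal(10, 0.5, 25)),
            "pini": list(rng.normal(1, 0.5, 25)),
            "hybrid": list(rng.normal(1.05, 0.5, 25)),
        }
        display = pairwise_letter_display(groups, alpha=0.01)
        assert display.letters["sibiricus"] == "a"
        assert display.letters["pini"] == display.letters["hybrid"] == "b"

    def test_identical_groups_share_one_letter(self):
        sample = [1.0, 2.0, 3.0, 4.0]
        display = pairwise_letter_display({"a": sample, "b": sample, "c": sample})
        assert set(display.letters.values()) == {"a"}

    def test_empty_group_rejected(self):
        with pytest.raises(ValidationError):
            pairwise_letter_display({"a": [1.0], "b": []})


class TestLinearRegression:
    def test_perfect_line(self):
        fit = fit_linear_regression([0, 1, 2], [0, 1, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(0.0)
        assert fit.r_squared == pytest.approx(1.0)

    def test_hand_computed_three_points(self):
        fit = fit_linear_regression([0, 1, 2], [0, 2, 2])
        assert fit.slope == pytest.approx(1.0)
        assert fit.intercept == pytest.approx(1 / 3)
        assert fit.r_squared == pytest.approx(0.75)

    def test_constant_predictor_rejected(self):
        with pytest.raises(ValidationError, match="degenerate"):
            fit_linear_regression([1.0, 1.0, 1.0], [1, 2, 3])

    def test_published_line_passes_through_grand_means(self):
        # the published pooled harpe-on-valva line evaluated at the
        # 33/33/4-weighted grand valva mean recovers the weighted grand
        # harpe mean of the per-taxon structure means
        grand_valva = (33 * 2.002 + 33 * 1.356 + 4 * 1.609) / 70
        grand_harpe = (33 * 1.312 + 33 * 0.339 + 4 * 0.608) / 70
        predicted = 1.286 * grand_valva - 1.341
        assert predicted == pytest.approx(grand_harpe, abs=0.005)

    def test_r_squared_equals_squared_correlation(self):
        rng = np.random.default_rng(19)
        x = rng.normal(0, 1, 40)
        y = 2 * x + rng.normal(0, 1, 40)
        fit = fit_linear_regression(x, y)
        assert fit.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2)

    def test_line_passes_through_mean_point(self):
        rng = np.random.default_rng(23)
        x = rng.uniform(0, 5, 25)
        y = rng.uniform(0, 5, 25)
        fit = fit_linear_regression(x, y)
        assert fit.predict(float(x.mean())) == pytest.approx(float(y.mean()), abs=1e-9)
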