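import itertools
import math

import numpy as np
import pytest

from darkdiv import (
    MembershipMatrix,
    ValidationError,
    compare_methods,
    hypergeom_overlap_p,
    major_axis_fit,
    overlap_coefficient,
    overlap_summary,
)
from darkdiv.compare import OverlapTest

from conftest import random_occurrence


def hypergeom_enumerate(N, x1, x2, overlap):
    """Oracle: enumerate all C(N, x1) equally likely draws, count overlap >= k."""
    marked = set(range(x2))
    hits = total = 0
    for draw in itertools.combinations(range(N), x1):
        total += 1
        if len(marked.intersection(draw)) >= overlap:
            hits += 1
    return hits / total


class TestOverlapCoefficient:
    def test_subset_gives_one(self):
        assert overlap_coefficient({"a", "b"}, {"a", "b", "c"}) == pytest.approx(1.0)

    def test_disjoint_gives_zero(self):
        assert overlap_coefficient({"a"}, {"b"}) == pytest.approx(0.0)

    def test_forced_arithmetic(self):
        # |A| = 4, |B| = 6, |A & B| = 3 -> 3/4
        assert overlap_coefficient({1, 2, 3, 4}, {2, 3, 4, 5, 6, 7}) == pytest.approx(0.75)

    def test_empty_set_missing(self):
        assert math.isnan(overlap_coefficient(set(), {"a"}))

    def test_symmetry(self):
        a, b = {1, 2, 3}, {2, 3, 4, 5}
        assert overlap_coefficient(a, b) == overlap_coefficient(b, a)


class TestHypergeom:
    def test_overlap_zero_is_one(self):
        assert hypergeom_overlap_p(12, 5, 4, 0) == pytest.approx(1.0)

    def test_degenerate_full_draw(self):
        assert hypergeom_overlap_p(10, 10, 4, 4) == pytest.approx(1.0)

    def test_worked_example(self):
        # 3 of the C(5,2)=10 draws contain both marked species
        assert hypergeom_overlap_p(5, 2, 3, 2) == pytest.approx(0.3)

    def test_bound_violation_named(self):
        with pytest.raises(ValidationError, match="overlap"):
            hypergeom_overlap_p(5, 2, 3, 3)
        with pytest.raises(ValidationError, match="x1"):
            hypergeom_overlap_p(5, 6, 3, 2)

    def test_matches_enumeration_small(self):
        for N in (4, 6, 8):
            for x1 in range(N + 1):
                for x2 in range(N + 1):
                    lo, hi = max(0, x1 + x2 - N), min(x1, x2)
                    for ov in range(lo, hi + 1):
                        p = hypergeom_overlap_p(N, x1, x2, ov)
                        assert p == pytest.approx(
                            hypergeom_enumerate(N, x1, x2, ov), abs=1e-12
                        )

    def test_tail_monotone_in_overlap(self):
        N, x1, x2 = 20, 8, 10
        ps = [hypergeom_overlap_p(N, x1, x2, ov) for ov in range(0, 9)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestOverlapSummary:
    def _tests(self, pvals):
        return [OverlapTest(f"s{i}", 10, 3, 3, 1, 0.5, p) for i, p in enumerate(pvals)]

    def test_uniform_small_p(self):
        mean, med, frac = overlap_summary(self._tests([0.01] * 4), alpha=0.05)
        assert (mean, med, frac) == (pytest.approx(0.01), pytest.approx(0.01), 0.0)

    def test_two_values(self):
        mean, med, frac = overlap_summary(self._tests([0.01, 0.5]), alpha=0.05)
        assert mean == pytest.approx(0.255)
        assert med == pytest.approx(0.255)
        assert frac == pytest.approx(0.5)

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            overlap_summary([], alpha=0.05)

    def test_nan_p_ignored(self):
        tests = self._tests([0.2, 0.4]) + [OverlapTest("x", 0, 0, 0, 0, float("nan"),
                                                       float("nan"))]
        mean, _, _ = overlap_summary(tests, alpha=0.05)
        assert mean == pytest.approx(0.3)


class TestMajorAxis:
    def test_perfect_line_slope_two(self):
        x = np.linspace(0, 5, 20)
        fit = major_axis_fit(x, 2 * x)
        assert fit.slope == pytest.approx(2.0)
        assert fit.r2 == pytest.approx(1.0)
        assert fit.slope_ci_low == pytest.approx(2.0)
        assert fit.slope_ci_high == pytest.approx(2.0)
        assert not fit.includes_one

    def test_axis_swap_reciprocal(self):
        rng = np.random.default_rng(12)
        x = rng.normal(size=100)
        y = 1.4 * x + rng.normal(scale=0.4, size=100)
        fwd = major_axis_fit(x, y)
        rev = major_axis_fit(y, x)
        assert rev.slope == pytest.approx(1.0 / fwd.slope, abs=1e-9)

    def test_eigenvector_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=200)
            y = 0.8 * x + rng.normal(scale=0.5, size=200)
            fit = major_axis_fit(x, y)
            cov = np.cov(x, y, ddof=1)
            vals, vecs = np.linalg.eigh(cov)
            lead = vecs[:, np.argmax(vals)]
            assert fit.slope == pytest.approx(lead[1] / lead[0], abs=1e-9)

    def test_isotropic_slope_one_ci_contains_one(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1.0, 0.6], [0.6, 1.0]], size=200)
        fit = major_axis_fit(z[:, 0], z[:, 1])
        assert fit.slope_ci_low <= 1.0 <= fit.slope_ci_high
        assert fit.includes_one

    def test_translation_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=80)
        y = 1.2 * x + rng.normal(scale=0.3, size=80)
        a = major_axis_fit(x, y)
        b = major_axis_fit(x + 100.0, y - 42.0)
        assert b.slope == pytest.approx(a.slope)
        assert b.r2 == pytest.approx(a.r2)

    def test_common_scaling_equivariance(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=80)
        y = 0.7 * x + rng.normal(scale=0.3, size=80)
        a = major_axis_fit(x, y)
        b = major_axis_fit(3.5 * x, 3.5 * y)
        assert b.slope == pytest.approx(a.slope)

    def test_zero_covariance_rejected(self):
        x = np.array([-1.0, 0.0, 1.0, -1.0, 0.0, 1.0])
        y = np.array([1.0, -2.0, 1.0, 1.0, -2.0, 1.0])
        assert np.cov(x, y, ddof=1)[0, 1] == pytest.approx(0.0)
        with pytest.raises(ValidationError, match="covariance"):
            major_axis_fit(x, y)

    def test_constant_input_rejected(self):
        with pytest.raises(ValidationError):
            major_axis_fit([1.0, 1.0, 1.0], [0.0, 1.0, 2.0])

    def test_sma_variant(self):
        rng = np.random.default_rng(8)
        x = rng.normal(size=100)
        y = 2.0 * x + rng.normal(scale=0.5, size=100)
        fit = major_axis_fit(x, y, method="sma")
        assert fit.slope == pytest.approx(np.sign(np.cov(x, y)[0, 1])
                                          * np.std(y, ddof=1) / np.std(x, ddof=1))
        assert fit.slope_ci_low <= fit.slope <= fit.slope_ci_high


class TestCompareMethods:
    def _memberships(self, seed, identical=False):
        occ = random_occurrence(30, 15, seed=seed, density=0.4)
        rng = np.random.default_rng(seed + 500)
        absent = occ.values == 0
        a = absent & (rng.random(absent.shape) < 0.5)
        b = a.copy() if identical else absent & (rng.random(absent.shape) < 0.5)
        return (occ,
                MembershipMatrix(occ.sites, occ.species, a, "sco"),
                MembershipMatrix(occ.sites, occ.species, b, "sdm"))

    def test_identical_methods(self):
        occ, a, b = self._memberships(1, identical=True)
        report = compare_methods(a, b, occ)
        coefs = [t.overlap_coefficient for t in report.tests
                 if not math.isnan(t.overlap_coefficient)]
        assert all(c == pytest.approx(1.0) for c in coefs)
        assert report.type2.slope == pytest.approx(1.0)
        assert report.type2.r2 == pytest.approx(1.0)

    def test_independent_random_null(self):
        # independent memberships: the hypergeometric null holds, p not small
        medians = []
        for seed in range(5):
            occ, a, b = self._memberships(seed + 10)
            report = compare_methods(a, b, occ)
            medians.append(report.median_p)
        assert np.mean(medians) > 0.2

    def test_universe_bounds_hold(self):
        occ, a, b = self._memberships(3)
        report = compare_methods(a, b, occ)
        for t in report.tests:
            assert max(0, t.x1 + t.x2 - t.N) <= t.overlap <= min(t.x1, t.x2)
            assert 0 < t.p_value <= 1

    def test_too_few_sites_skips_regression(self):
        occ, a, b = self._memberships(4)
        empty = np.zeros_like(a.values)
        empty[0, occ.values[0] == 0] = True  # a single site with dark species
        a2 = MembershipMatrix(a.sites, a.species, empty, "sco")
        report = compare_methods(a2, b, occ)
        assert report.type2 is None
        assert report.median_p is not None

    def test_eligibility_restricts_universe(self):
        occ, a, b = self._memberships(5)
        full = compare_methods(a, b, occ)
        elig = np.zeros_like(occ.values, dtype=bool)
        elig[:, :8] = True
        limited = compare_methods(a, b, occ, eligibility=elig)
        assert all(tl.N <= tf.N for tl, tf in zip(limited.tests, full.tests))
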