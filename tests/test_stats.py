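"""Oracles and simulation checks for the two-sample testing machinery."""

import itertools

import numpy as np
import pytest
from scipy.stats import brunnermunzel as scipy_bm

from lysopos import stats
from lysopos.exceptions import (
    DegenerateSampleError,
    ParameterError,
    SampleSizeError,
)


def brute_force_phat(a, b):
    """P(a < b) + 0.5 P(a = b) by enumerating all pairs."""
    pairs = [(x < y) + 0.5 * (x == y) for x in a for y in b]
    return float(np.mean(pairs))


class TestDagostinoPearson:
    def test_small_sample_rejected(self):
        with pytest.raises(SampleSizeError):
            stats.dagostino_pearson([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_type_one_error_near_alpha(self, rng):
        rejections = sum(
            stats.dagostino_pearson(rng.normal(size=100)).p_value < 0.05
            for _ in range(500)
        )
        assert 0.02 <= rejections / 500 <= 0.09

    def test_power_against_exponential(self, rng):
        rejections = sum(
            stats.dagostino_pearson(rng.exponential(size=100)).p_value < 0.05
            for _ in range(200)
        )
        assert rejections / 200 >= 0.9


class TestFTest:
    def test_identical_samples(self):
        res = stats.f_test_variances([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(1.0)
        assert res.p_value == pytest.approx(1.0)

    def test_type_one_and_power(self, rng):
        null = sum(
            stats.f_test_variances(rng.normal(size=50), rng.normal(size=50)).p_value
            < 0.05
            for _ in range(400)
        )
        assert 0.02 <= null / 400 <= 0.09
        power = sum(
            stats.f_test_variances(
                rng.normal(size=50), rng.normal(scale=3.0, size=50)
            ).p_value
            < 0.05
            for _ in range(100)
        )
        assert power / 100 >= 0.99

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateSampleError):
            stats.f_test_variances([2.0, 2.0], [3.0, 3.0])


class TestTTests:
    def test_identical_samples(self):
        res = stats.two_sample_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)
        assert res.df == 4.0

    def test_clear_separation(self):
        res = stats.two_sample_t([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert res.p_value < 0.01
        assert res.estimate == pytest.approx(-10.0)

    def test_welch_degrees_of_freedom_differ(self, rng):
        a, b = rng.normal(size=20), rng.normal(scale=4.0, size=10)
        assert stats.two_sample_t(a, b, welch=True).df < stats.two_sample_t(a, b).df

    def test_type_one_error(self, rng):
        rej = sum(
            stats.two_sample_t(rng.normal(size=20), rng.normal(size=20)).p_value < 0.05
            for _ in range(500)
        )
        assert 0.025 <= rej / 500 <= 0.08


class TestMannWhitney:
    def test_complete_separation_u_zero(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        assert res.estimate == pytest.approx(1.0)  # every a below every b

    def test_identical_samples_phat_half(self):
        res = stats.mann_whitney([1.0, 2.0, 3.0, 4.0], [1.0, 2.0, 3.0, 4.0])
        assert res.estimate == pytest.approx(0.5)

    def test_exact_p_equals_permutation_enumeration(self, rng):
        """For tie-free n=4 vs 4, the exact p equals full enumeration of the
        70 group relabelings of the pooled sample."""
        for _ in range(20):
            pooled = rng.normal(size=8)
            a, b = pooled[:4], pooled[4:]
            res = stats.mann_whitney(a, b)

            def u_of(ix):
                aa = pooled[list(ix)]
                bb = pooled[[i for i in range(8) if i not in ix]]
                return sum(x > y for x in aa for y in bb)

            observed = u_of(range(4))
            us = [u_of(ix) for ix in itertools.combinations(range(8), 4)]
            p_perm = np.mean([abs(u - 8) >= abs(observed - 8) for u in us])
            assert res.p_value == pytest.approx(p_perm, abs=1e-12)

    def test_phat_matches_brute_force_with_ties(self, rng):
        for _ in range(50):
            a = rng.integers(0, 5, size=rng.integers(2, 10)).astype(float)
            b = rng.integers(0, 5, size=rng.integers(2, 10)).astype(float)
            assert stats.mann_whitney(a, b).estimate == pytest.approx(
                brute_force_phat(a, b), abs=1e-12
            )


class TestBrunnerMunzel:
    def test_identical_samples(self):
        res = stats.brunner_munzel(np.arange(12.0), np.arange(12.0))
        assert res.estimate == pytest.approx(0.5)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)

    def test_worked_example(self):
        res = stats.brunner_munzel([1, 2, 4], [3, 5, 6], min_n_warn=0)
        assert res.estimate == pytest.approx(8 / 9, abs=1e-12)

    def test_phat_matches_pairwise_enumeration(self, rng):
        """200 random small instances: p-hat equals the brute-force pairwise
        count exactly; the p-value matches the reference implementation."""
        checked = 0
        while checked < 200:
            a = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            b = rng.integers(0, 6, size=rng.integers(3, 12)).astype(float)
            try:
                res = stats.brunner_munzel(a, b, min_n_warn=0)
            except DegenerateSampleError:
                continue
            assert res.estimate == pytest.approx(brute_force_phat(a, b), abs=1e-12)
            ref = scipy_bm(a, b)
            if np.isfinite(ref.pvalue):
                assert res.p_value == pytest.approx(ref.pvalue, abs=1e-10)
            checked += 1

    def test_degenerate_tied_separation(self):
        with pytest.raises(DegenerateSampleError) as err:
            stats.brunner_munzel([1.0, 1.0, 1.0], [2.0, 2.0, 2.0], min_n_warn=0)
        assert err.value.p_hat == 1.0

    def test_variance_robust_type_one_error(self, rng):
        rej = sum(
            stats.brunner_munzel(
                rng.normal(size=30), rng.normal(scale=2.0, size=30)
            ).p_value
            < 0.05
            for _ in range(500)
        )
        assert 0.025 <= rej / 500 <= 0.08

    def test_small_sample_warns(self):
        with pytest.warns(UserWarning):
            stats.brunner_munzel([1.0, 2.0, 3.0], [2.0, 3.0, 4.0])


@pytest.fixture(scope="module")
def samples():
    rng = np.random.default_rng(7)
    return rng.normal(size=25), rng.normal(0.5, 1.5, size=30)


class TestInvariances:

    def test_swap_negates_statistic_preserves_p(self, samples):
        a, b = samples
        for test in (
            lambda x, y: stats.two_sample_t(x, y),
            lambda x, y: stats.brunner_munzel(x, y),
        ):
            fwd, rev = test(a, b), test(b, a)
            assert fwd.statistic == pytest.approx(-rev.statistic)
            assert fwd.p_value == pytest.approx(rev.p_value)
        assert stats.mann_whitney(a, b).p_value == pytest.approx(
            stats.mann_whitney(b, a).p_value
        )

    def test_shift_invariance(self, samples):
        a, b = samples
        for test in (stats.two_sample_t, stats.mann_whitney, stats.brunner_munzel):
            assert test(a, b).p_value == pytest.approx(
                test(a + 100.0, b + 100.0).p_value
            )

    def test_positive_scaling_leaves_rank_tests_unchanged(self, samples):
        a, b = samples
        for test in (stats.mann_whitney, stats.brunner_munzel):
            r1, r2 = test(a, b), test(3.7 * a, 3.7 * b)
            assert r1.p_value == pytest.approx(r2.p_value)
            assert r1.estimate == pytest.approx(r2.estimate)


class TestDispatcher:
    def test_forced_methods(self, rng):
        a, b = rng.normal(size=15), rng.normal(size=15)
        for method, name in [
            ("t", "student_t"), ("welch", "welch_t"),
            ("mwu", "mann_whitney"), ("bm", "brunner_munzel"),
        ]:
            assert stats.compare_groups(a, b, method=method).chosen_method == name
        with pytest.raises(ParameterError):
            stats.compare_groups(a, b, method="anova")

    def test_small_samples_take_t_branch(self, rng):
        trace = stats.compare_groups(rng.normal(size=5), rng.normal(size=5))
        assert trace.chosen_method in ("student_t", "welch_t")
        assert trace.normality_p is None
        assert any("normality untestable" in w for w in trace.warnings)

    def test_normal_data_route_to_student_t(self, rng):
        chosen = [
            stats.compare_groups(rng.normal(size=50), rng.normal(size=50)).chosen_method
            for _ in range(300)
        ]
        assert chosen.count("student_t") / 300 >= 0.8

    def test_unequal_variances_route_to_welch(self, rng):
        chosen = [
            stats.compare_groups(
                rng.normal(size=50), rng.normal(scale=3.0, size=50)
            ).chosen_method
            for _ in range(100)
        ]
        t_like = [c for c in chosen if c in ("student_t", "welch_t")]
        assert t_like and t_like.count("welch_t") / len(t_like) >= 0.9

    def test_heavy_tails_route_to_mann_whitney(self, rng):
        chosen = [
            stats.compare_groups(
                rng.standard_cauchy(size=50), rng.standard_cauchy(size=50)
            ).chosen_method
            for _ in range(100)
        ]
        assert chosen.count("mann_whitney") / 100 >= 0.9


def test_significance_stars():
    assert [stats.significance_stars(p) for p in (0.2, 0.04, 0.004, 0.0004)] == [
        "ns", "*", "**", "***",
    ]


def test_holm_correction_orders_and_bounds():
    adj = stats.holm_correction([0.01, 0.04, 0.03, 0.5])
    assert (adj >= [0.01, 0.04, 0.03, 0.5]).all()
    assert (adj <= 1).all()
    assert adj[0] == pytest.approx(0.04)
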