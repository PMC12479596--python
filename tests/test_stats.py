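"""Inferential-layer contracts: effect-size conversions, Li-Ji/Sidak,
TANOVA permutation behavior, FDR, bootstrap CIs."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_

import mstates as ms
from mstates.exceptions import InvalidArgumentError, UndefinedCorrelationError


class TestStudentT:
    def test_equal_means_zero(self):
        res = ms.student_t_summary(5.0, 1.0, 10, 5.0, 2.0, 10)
        assert res.statistic == pytest.approx(0.0)
        assert res.effect == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_df_is_pooled(self):
        res = ms.student_t_summary(1.0, 1.0, 18, 0.0, 1.0, 18)
        assert res.df == 34

    def test_nonpositive_sd_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ms.student_t_summary(1.0, 0.0, 10, 0.0, 1.0, 10)


class TestMannWhitney:
    def test_complete_separation_delta_one(self):
        res = ms.mann_whitney([10.0, 11, 12], [1.0, 2, 3])
        assert res.effect == pytest.approx(1.0)

    def test_identical_multisets_delta_zero(self):
        res = ms.mann_whitney([1.0, 2, 3, 4], [1.0, 2, 3, 4])
        assert res.effect == pytest.approx(0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(
        x=st_.lists(st_.floats(-50, 50), min_size=2, max_size=12),
        y=st_.lists(st_.floats(-50, 50), min_size=2, max_size=12),
    )
    def test_delta_equals_pairwise_dominance(self, x, y):
        """delta from U equals the brute-force dominance count
        (#{x_i > y_j} - #{x_i < y_j}) / (n1 n2)."""
        x, y = np.asarray(x), np.asarray(y)
        res = ms.mann_whitney(x, y)
        gt = sum((xi > y).sum() for xi in x)
        lt = sum((xi < y).sum() for xi in x)
        brute = (gt - lt) / (x.size * y.size)
        assert res.effect == pytest.approx(brute, abs=1e-12)


class TestCliffsDelta:
    @pytest.mark.parametrize(
        "u,expected", [(46, -0.72), (100, -0.38), (254, 0.57), (126, -0.22)]
    )
    def test_u_conversion(self, u, expected):
        assert round(ms.cliffs_delta_from_u(u, 18, 18), 2) == expected

    def test_midpoint_is_zero(self):
        assert ms.cliffs_delta_from_u(18 * 18 / 2, 18, 18) == pytest.approx(0.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(InvalidArgumentError):
            ms.cliffs_delta_from_u(400, 18, 18)


class TestLiJiSidak:
    def test_independent_variables_meff_equals_count(self):
        rng = np.random.default_rng(0)
        # large n so the sample correlation matrix is near identity
        X = rng.standard_normal((4000, 5))
        res = ms.li_ji_meff(X)
        assert res.m_eff == pytest.approx(5.0, abs=0.15)

    def test_duplicated_pair_collapses_to_one(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(100)
        res = ms.li_ji_meff(np.column_stack([x, x]))
        assert res.m_eff == pytest.approx(1.0)
        assert res.alpha_adjusted == pytest.approx(0.05)

    def test_meff_six_gives_point_oh_oh_nine_threshold(self):
        assert ms.sidak_alpha(0.05, 6.0) == pytest.approx(0.0085, abs=2e-4)

    def test_sidak_identity_and_monotonicity(self):
        assert ms.sidak_alpha(0.05, 1.0) == pytest.approx(0.05)
        vals = [ms.sidak_alpha(0.05, m) for m in (1, 2, 4, 8)]
        assert np.all(np.diff(vals) < 0)

    def test_constant_variable_rejected(self):
        X = np.column_stack([np.ones(10), np.arange(10.0)])
        with pytest.raises(UndefinedCorrelationError):
            ms.li_ji_meff(X)


class TestTanova:
    def test_identical_groups_null(self):
        rng = np.random.default_rng(2)
        maps = rng.standard_normal((5, 16))
        res = ms.tanova(maps, maps, n_perm=200, seed=0)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_orthogonal_templates_minimal_p(self):
        rng = np.random.default_rng(3)
        u = rng.standard_normal(32)
        v = rng.standard_normal(32)
        v -= (v @ u) / (u @ u) * u
        a = u + 0.01 * rng.standard_normal((10, 32))
        b = v + 0.01 * rng.standard_normal((10, 32))
        res = ms.tanova(a, b, n_perm=200, seed=1)
        assert res.p <= 1.0 / 201 + 1e-12

    def test_p_never_zero(self):
        rng = np.random.default_rng(4)
        a = rng.standard_normal((3, 8)) + 10 * rng.standard_normal(8)
        b = rng.standard_normal((3, 8))
        res = ms.tanova(a, b, n_perm=100, seed=2)
        assert res.p >= 1.0 / 101


class TestFdrAndBootstrap:
    def test_single_p_unchanged(self):
        adj, rej = ms.bh_fdr([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_stepup_enumeration(self):
        adj, rej = ms.bh_fdr([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert rej.all()

    def test_all_ones_rejected_none(self):
        _, rej = ms.bh_fdr([1.0, 1.0, 1.0])
        assert not rej.any()

    def test_perfect_correlation_ci(self):
        x = np.arange(20.0)
        res = ms.correlate_bootstrap(x, x, n_boot=200, seed=0)
        assert res.statistic == pytest.approx(1.0)
        assert res.ci[1] == pytest.approx(1.0)

    def test_deterministic_under_seed(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal(25), rng.standard_normal(25)
        a = ms.correlate_bootstrap(x, y, n_boot=300, seed=7)
        b = ms.correlate_bootstrap(x, y, n_boot=300, seed=7)
        assert a.ci == b.ci

    def test_spearman_monotone_association(self):
        rng = np.random.default_rng(6)
        x = rng.standard_normal(30)
        y = np.exp(x) + 0.1 * rng.standard_normal(30)
        res = ms.correlate_bootstrap(x, y, method="spearman", n_boot=300, seed=8)
        assert res.statistic > 0.8
        assert res.ci[0] > 0
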