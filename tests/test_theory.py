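"""Closed forms vs recurrences vs exhaustive enumeration.

The pure-birth expectations have three independent routes: the Stirling /
harmonic closed forms, the one-step recurrences, and (for small step
counts) exhaustive enumeration over all equally-likely division-choice
sequences.  These tests pin each route against the others.
"""

import math
from fractions import Fraction

import numpy as np
import pytest

from mutburden import theory as th


from _oracles import enumerate_pure_birth_dd  # noqa: E402


class TestStirling:
    def test_boundary_and_small_values(self):
        assert th.stirling(1, 1) == 1
        assert th.stirling(3, 2) == 3  # 2*[2 2] + [2 1]
        assert th.stirling(4, 2) == 11
        assert th.stirling(5, 1) == 24  # (i-1)!
        assert th.stirling(6, 6) == 1

    def test_zero_outside_triangle(self):
        assert th.stirling(3, 0) == 0
        assert th.stirling(3, 4) == 0

    def test_invalid_indices_raise(self):
        with pytest.raises(ValueError):
            th.stirling(0, 1)
        with pytest.raises(ValueError):
            th.stirling(3, -1)

    def test_row_identity_exact_to_30(self):
        """sum_l [i l] 2^l = (i+1)! -- forced by DD mass conservation."""
        for i in range(1, 31):
            total = sum(th.stirling(i, ell) * 2**ell for ell in range(1, i + 1))
            assert total == math.factorial(i + 1)

    def test_log_row_matches_exact_integers(self):
        from mutburden.theory import _log_int

        for i in (5, 50, 200):
            row = th.StirlingTable.log_row(i)  # recurrence route, not exact
            for ell in range(1, i + 1, max(1, i // 7)):
                assert row[ell] == pytest.approx(
                    _log_int(th.stirling(i, ell)), rel=1e-12
                )

    def test_log_row_beyond_exact_limit_conserves_mass(self):
        """In log space the i=2000 row still satisfies the 2^l identity."""
        i = 2000
        row = th.StirlingTable.log_row(i)
        ell = np.arange(i + 1)
        from scipy.special import gammaln, logsumexp
        lhs = logsumexp(row[1:] + ell[1:] * math.log(2.0))
        assert lhs == pytest.approx(gammaln(i + 2), rel=1e-10)


class TestPureBirthDD:
    def test_one_step(self):
        assert th.expected_dd_pure_birth(1, 1) == pytest.approx(2.0)

    def test_two_steps_exhaustive(self):
        assert th.expected_dd_pure_birth(2, 1) == pytest.approx(1.0)
        assert th.expected_dd_pure_birth(2, 2) == pytest.approx(2.0)

    @pytest.mark.parametrize("i", [1, 2, 3, 4, 5, 6])
    def test_closed_form_matches_exhaustive_enumeration(self, i):
        oracle = enumerate_pure_birth_dd(i)
        # closed form as exact rationals: [i l] 2^l / i!
        for ell in range(1, i + 1):
            exact = Fraction(th.stirling(i, ell) * 2**ell, math.factorial(i))
            assert oracle.get(ell, Fraction(0)) == exact

    def test_recurrence_equals_closed_form_to_200(self):
        curves = th.iterate_dd_recurrence(200)
        for i in range(1, 201):
            rec = curves[i].values
            closed = th.dd_curve_pure_birth(i).values
            np.testing.assert_allclose(rec, closed, rtol=1e-10, atol=1e-300)

    def test_mass_conservation(self):
        for i in (1, 10, 100, 999):
            curve = th.dd_curve_pure_birth(i)
            assert curve.total == pytest.approx(i + 1, rel=1e-10)


class TestPureBirthSFS:
    def test_closed_form_values(self):
        assert th.expected_sfs_pure_birth(2.0, 4, 1) == pytest.approx(10.0)
        assert th.expected_sfs_pure_birth(0.0, 10, 3) == 0.0
        # j = 1 solves the recurrence linearly: 2 mu (i+1) / 2 = mu (i+1)
        for i in range(1, 8):
            assert th.expected_sfs_pure_birth(1.5, i, 1) == pytest.approx(
                1.5 * (i + 1)
            )

    def test_recurrence_matches_closed_form_inside_triangle(self):
        """Exactness region: closed form is exact for 1 <= j <= i <= 200."""
        mu = 1.7
        curves = th.iterate_sfs_recurrence(mu, 200)
        for i in (1, 2, 3, 5, 20, 100, 200):
            rec = curves[i]
            for j in range(1, i + 1):
                assert rec[j] == pytest.approx(
                    th.expected_sfs_pure_birth(mu, i, j), rel=1e-10
                )

    def test_recurrence_is_zero_beyond_the_triangle(self):
        """No mutation can be j-abundant after fewer than j divisions."""
        curves = th.iterate_sfs_recurrence(2.0, 12)
        for i in range(0, 12):
            for j in range(i + 2, 13):
                assert curves[i][j] == 0.0
            # ... while the closed form stays positive there
            assert th.expected_sfs_pure_birth(2.0, i, i + 2) > 0

    def test_two_step_shared_mutations(self):
        # E[S_{2,2}] = E[S_{1,1}]/2 = mu; closed form 2 mu * 3 / 6 agrees
        mu = 0.9
        assert th.iterate_sfs_recurrence(mu, 2)[2][2] == pytest.approx(mu)

    def test_starts_all_zero(self):
        assert np.all(th.iterate_sfs_recurrence(3.0, 0)[0].values == 0)


class TestBirthDeath:
    def test_sfs_series_reduces_to_pure_birth_at_zero_death(self):
        mu, i = 2.0, 50
        bd = th.expected_sfs_birth_death(mu, 1.0, 0.0, i=i, j_max=20)
        for j in range(1, 21):
            assert bd[j] == pytest.approx(
                th.expected_sfs_pure_birth(mu, i, j), rel=1e-12
            )

    def test_sfs_series_terms_are_positive_and_bounded(self):
        loose = th.expected_sfs_birth_death(1.0, 0.6, 0.4, i=30, tol=1e-3)
        tight = th.expected_sfs_birth_death(1.0, 0.6, 0.4, i=30, tol=1e-14)
        assert np.all(loose.values <= tight.values + 1e-12)
        r = 0.4 / 0.6
        # geometric tail bound on the j=1 series
        assert tight[1] <= loose[1] + loose.params["expected_n"] * r**2 / (1 - r)

    def test_dd_partition_reduces_to_pure_birth_at_zero_death(self):
        with pytest.raises(ValueError):
            th.expected_dd_birth_death(10, 0.5, 0.5)
        bd = th.expected_dd_birth_death(40, 1.0, 0.0)
        closed = th.dd_curve_pure_birth(40)
        np.testing.assert_allclose(bd.values, closed.values, rtol=1e-10)

    def test_dd_fractions_sum_to_population(self):
        for beta in (0.9, 2 / 3):
            curve = th.expected_dd_birth_death(60, beta, 1 - beta)
            assert curve.total == pytest.approx(
                curve.params["expected_n"], rel=1e-10
            )

    def test_refuses_shrinking_populations(self):
        with pytest.raises(ValueError):
            th.expected_sfs_birth_death(1.0, 0.4, 0.6, i=5)


class TestConditionedPopulation:
    def test_pure_birth_is_linear(self):
        curve = th.expected_population_conditioned(1.0, 0.0, 20)
        np.testing.assert_allclose(curve.values, np.arange(1, 22))

    def test_first_surviving_step_must_be_a_birth(self):
        for beta in (0.6, 2 / 3, 0.9):
            curve = th.expected_population_conditioned(beta, 1 - beta, 1)
            assert curve.values[1] == pytest.approx(2.0)

    def test_approaches_linear_slope_for_large_i(self):
        beta = 2 / 3
        curve = th.expected_population_conditioned(beta, 1 / 3, 600)
        linear = curve.params["linear"]
        rel_gap = np.abs(curve.values[1:] - linear[1:]) / linear[1:]
        # the relative gap to (beta-delta) i + 1 shrinks with i
        assert rel_gap[599] < rel_gap[60] < rel_gap[6]
        slope = (curve.values[600] - curve.values[500]) / 100
        assert slope == pytest.approx(beta - 1 / 3, rel=0.05)

    def test_cap_too_small_is_detected(self):
        with pytest.raises(ValueError):
            th.expected_population_conditioned(0.9, 0.1, 400, cap=40)


class TestMeanBurden:
    def test_small_cases_match_occurrence_recurrence(self):
        # E[T_i]: 0, 2, 5, 26/3 -> means over N = i+1: 0, 1, 5/3, 13/6
        t = th.iterate_occurrences_recurrence(3)
        np.testing.assert_allclose(t, [0.0, 2.0, 5.0, 26.0 / 3.0])
        for mu in (1.0, 2.5):
            assert th.expected_mean_burden(mu, 1) == pytest.approx(mu)
            assert th.expected_mean_burden(mu, 2) == pytest.approx(mu * 5 / 3)
            assert th.expected_mean_burden(mu, 3) == pytest.approx(mu * 13 / 6)

    def test_harmonic_rescaling_matches_recurrence_for_many_steps(self):
        t = th.iterate_occurrences_recurrence(500)
        for i in (1, 5, 50, 500):
            assert th.expected_mean_divisions(i) == pytest.approx(
                t[i] / (i + 1), rel=1e-12
            )

    def test_refuses_death(self):
        with pytest.raises(ValueError):
            th.expected_mean_burden(1.0, 10, delta=0.1)


class TestPureBirthMBD:
    def test_single_step_value(self):
        # only the l=1 term contributes: [1 1] 2 e^{-mu}
        assert th.expected_mbd_pure_birth(2.0, 1, 0) == pytest.approx(
            2.0 * math.exp(-2.0)
        )

    def test_mu_zero_concentrates_mass(self):
        curve = th.expected_mbd_pure_birth(0.0, 9)
        assert curve[0] == pytest.approx(10.0)
        assert curve.total == pytest.approx(10.0)

    @pytest.mark.parametrize("i,mu", [(9, 1.0), (99, 2.0), (299, 10.0)])
    def test_mass_and_mean(self, i, mu):
        curve = th.expected_mbd_pure_birth(mu, i)
        assert curve.total == pytest.approx(i + 1, abs=1e-8 * (i + 1))
        # mean of the MBD is mu times the DD mean: 2 mu (H_{i+1} - 1)
        assert curve.mean() == pytest.approx(
            th.expected_mean_burden(mu, i), rel=1e-8
        )

    def test_matches_direct_mixture_of_dd(self):
        from mutburden import dd_to_mbd

        i, mu = 30, 3.0
        via_theory = th.expected_mbd_pure_birth(mu, i)
        via_transform = dd_to_mbd(th.dd_curve_pure_birth(i), mu)
        n = min(len(via_theory.values), len(via_transform.values))
        np.testing.assert_allclose(
            via_theory.values[:n], via_transform.values[:n], rtol=1e-10
        )
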