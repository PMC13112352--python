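import math

import numpy as np
import pytest
from scipy.special import expit

from idpcr import (
    PhysicalParams,
    SequenceSpec,
    field_rhs,
    fixed_conformation_solve,
    ideal_ionization,
    mean_charge,
    quenched_solve,
    residual_x,
    self_consistent_solve,
    solve_x,
)
from idpcr.core_model import LN10
from idpcr.solver import BracketingError, SolverOptions


class TestResidualX:
    def test_ideal_chain_residual(self, polyacid30, polyacid_params):
        """With no interactions the equation reduces to N(1/x − 1)."""
        p = polyacid_params(pH=7.0)
        q = np.zeros(30)
        assert residual_x(1.0, q, polyacid30, p) == 0.0
        assert residual_x(2.0, q, polyacid30, p) == pytest.approx(-15.0)

    def test_sign_change_for_charged_polyacid(self, polyacid30):
        p = PhysicalParams(pH=7.0, bjerrum=7.1, kuhn=5.8, kappa=0.0328)
        q = -np.ones(30)
        lo = residual_x(1.0, q, polyacid30, p)
        hi = residual_x(1e3, q, polyacid30, p)
        assert lo > 0 > hi  # repulsion swells the chain: root above x = 1

    def test_domain_error(self, polyacid30, polyacid_params):
        with pytest.raises(ValueError):
            residual_x(0.0, np.zeros(30), polyacid30, polyacid_params(7.0))


class TestSolveX:
    def test_neutral_ideal_chain_is_exactly_one(self, polyacid_params):
        seq = SequenceSpec.from_string("G" * 20)
        assert solve_x(np.zeros(20), seq, polyacid_params(7.0)) == 1.0

    def test_excluded_volume_swells(self, polyacid_params):
        seq = SequenceSpec.from_string("G" * 20, omega=1.0)
        assert solve_x(np.zeros(20), seq, polyacid_params(7.0)) > 1.0

    def test_alternating_quenched_polyampholyte_contracts(self, polyacid_params):
        seq = SequenceSpec.from_string("EK" * 15)
        q = np.array([-1.0, 1.0] * 15)
        p = polyacid_params(pH=7.0, salt=1e-3)
        # attractive cross-correlations dominate: electrostatic term negative
        assert residual_x(1.0, q, seq, p) < 0
        assert solve_x(q, seq, p) < 1.0

    def test_charged_polyacid_swelling_shrinks_with_screening(self, polyacid30):
        xs = []
        for kl in (0.01, 0.1, 1.0, 10.0):
            p = PhysicalParams(pH=7.0, bjerrum=7.1, kuhn=5.8, kappa=kl / 5.8)
            xs.append(quenched_solve(-np.ones(30), polyacid30, p))
        assert all(a > b for a, b in zip(xs, xs[1:]))
        assert all(x > 1.0 for x in xs)

    def test_bracketing_error_is_diagnosed(self, polyacid_params):
        # a strongly attractive quenched diblock with no excluded volume has
        # no root: complete collapse beyond the two-body theory
        seq = SequenceSpec.from_string("E" * 25 + "K" * 25)
        q = np.concatenate((-np.ones(25), np.ones(25)))
        with pytest.raises(BracketingError):
            solve_x(q, seq, polyacid_params(7.0, salt=1e-3))


class TestMeanCharge:
    def test_midpoint_and_saturation(self):
        assert mean_charge(0.0, "acid") == pytest.approx(-0.5)
        assert mean_charge(0.0, "base") == pytest.approx(0.5)
        assert mean_charge(50.0, "acid") == pytest.approx(-1.0)
        assert mean_charge(50.0, "base") == pytest.approx(0.0)
        assert mean_charge(-50.0, "acid") == pytest.approx(0.0)
        assert mean_charge(-50.0, "base") == pytest.approx(1.0)


class TestFieldRhs:
    def test_uncharged_environment_gives_ideal_field(self, polyacid30, polyacid_params):
        p = polyacid_params(pH=6.0)
        got = field_rhs(5, np.zeros(30), 1.0, polyacid30, p)
        assert got == pytest.approx(LN10 * (6.0 - 4.0))

    def test_strong_screening_gives_ideal_field(self, polyacid30):
        p = PhysicalParams(pH=6.0, bjerrum=7.1, kuhn=5.8, kappa=1e6)
        got = field_rhs(5, -np.ones(30), 1.0, polyacid30, p)
        assert got == pytest.approx(LN10 * (6.0 - 4.0), abs=1e-9)

    def test_neutral_residue_rejected(self, polyacid_params):
        seq = SequenceSpec.from_string("EGE")
        with pytest.raises(ValueError):
            field_rhs(2, np.zeros(3), 1.0, seq, polyacid_params(7.0))

    def test_like_charge_neighbour_suppresses_ionization(self, polyacid_params):
        """A negatively charged neighbour lowers an acid's field (negative
        electrostatic pKA shift)."""
        seq = SequenceSpec.from_string("EE")
        p = polyacid_params(pH=4.4)
        q = np.array([-0.5, -0.5])
        shift = field_rhs(1, q, 1.0, seq, p) - LN10 * (p.pH - 4.4)
        assert shift < 0


class TestSelfConsistentSolve:
    def test_state_satisfies_both_equations(self, polyacid30, polyacid_params):
        p = polyacid_params(pH=4.0)
        st = self_consistent_solve(polyacid30, p)
        assert st.converged
        # conformation equation residual at the solution
        assert abs(residual_x(st.x, st.mean_q, polyacid30, p)) < 1e-6
        # field equations: re-evaluating the rhs reproduces phi
        for i in (1, 15, 30):
            assert field_rhs(i, st.mean_q, st.x, polyacid30, p) == pytest.approx(
                st.phi[i - 1], abs=1e-8
            )
        # charge law consistency
        np.testing.assert_allclose(st.mean_q, -expit(st.phi), atol=1e-12)

    def test_neutral_sequence_short_circuits(self, polyacid_params):
        seq = SequenceSpec.from_string("G" * 10)
        st = self_consistent_solve(seq, polyacid_params(7.0))
        assert st.converged and st.x == 1.0
        np.testing.assert_array_equal(st.mean_q, 0.0)

    def test_strong_screening_recovers_henderson_hasselbalch(self, polyacid30):
        p = PhysicalParams(pH=4.0, bjerrum=7.1, kuhn=5.8, kappa=1e4 / 5.8)
        st = self_consistent_solve(polyacid30, p)
        hh = ideal_ionization(4.0, 4.0, "acid")
        assert np.max(np.abs(np.abs(st.mean_q) - hh)) < 1e-6
        assert st.x == pytest.approx(1.0, abs=1e-6)

    def test_henderson_hasselbalch_deviation_scales_as_inverse_kl_squared(
        self, polyacid30
    ):
        hh = ideal_ionization(4.0, 4.0, "acid")
        devs = []
        for kl in (1e3, 1e4):
            p = PhysicalParams(pH=4.0, bjerrum=7.1, kuhn=5.8, kappa=kl / 5.8)
            st = self_consistent_solve(polyacid30, p)
            devs.append(np.max(np.abs(np.abs(st.mean_q) - hh)))
        assert devs[0] / devs[1] == pytest.approx(100.0, rel=0.05)

    def test_extreme_ph_matches_quenched_strong_polyelectrolyte(
        self, polyacid30, polyacid_params
    ):
        p = polyacid_params(pH=16.0)
        st = self_consistent_solve(polyacid30, p)
        xq = quenched_solve(-np.ones(30), polyacid30, p)
        assert abs(st.x - xq) < 1e-8
        assert np.max(np.abs(st.mean_q + 1.0)) < 1e-8

    def test_polyelectrolyte_effect_and_salt_ordering(self, polyacid30, polyacid_params):
        """Ionization never exceeds the ideal curve, and the gap shrinks
        with added salt."""
        gaps = []
        for salt in (1e-3, 1e-2, 1e-1):
            total = 0.0
            for pH in (3.0, 4.0, 5.0, 6.0):
                st = self_consistent_solve(polyacid30, polyacid_params(pH, salt=salt))
                theta = np.abs(st.mean_q)
                hh = ideal_ionization(pH, 4.0, "acid")
                assert np.all(theta <= hh + 1e-10)
                total += float(np.mean(hh - theta))
            gaps.append(total)
        assert gaps[0] > gaps[1] > gaps[2]

    def test_unconverged_state_is_flagged(self, polyacid30, polyacid_params):
        opts = SolverOptions(max_iterations=3)
        st = self_consistent_solve(polyacid30, polyacid_params(4.0), opts)
        assert not st.converged
        assert st.iterations == 3
        assert st.residual > 0


class TestFixedConformationSolve:
    def test_fixed_point_of_full_solution(self, polyacid30, polyacid_params):
        p = polyacid_params(pH=4.5)
        full = self_consistent_solve(polyacid30, p)
        frozen = fixed_conformation_solve(polyacid30, p, full.x)
        np.testing.assert_allclose(frozen.mean_q, full.mean_q, atol=1e-9)
        np.testing.assert_allclose(frozen.phi, full.phi, atol=1e-8)

    def test_two_acid_chain_against_hand_iteration(self, polyacid_params):
        """Brute-force fixed point of the two coupled scalar equations."""
        seq = SequenceSpec.from_string("EE", pka={"E": 4.0})
        p = polyacid_params(pH=4.5)
        from idpcr.kernels import coupling_J_profile

        x_fixed = 1.0
        c = 2.0 * p.bjerrum / (math.pi * p.kuhn) * coupling_J_profile(
            np.array([1.0]), x_fixed, p.kl
        )[0]
        base = LN10 * (p.pH - 4.0)
        phi1 = phi2 = base
        for _ in range(100_000):
            q1, q2 = -expit(phi1), -expit(phi2)
            phi1_new, phi2_new = base + c * q2, base + c * q1
            if max(abs(phi1_new - phi1), abs(phi2_new - phi2)) < 1e-14:
                break
            phi1, phi2 = phi1_new, phi2_new

        st = fixed_conformation_solve(seq, p, x_fixed)
        np.testing.assert_allclose(st.phi, [phi1, phi2], atol=1e-9)

    def test_rejects_non_positive_x(self, polyacid30, polyacid_params):
        with pytest.raises(ValueError):
            fixed_conformation_solve(polyacid30, polyacid_params(4.0), 0.0)


class TestSolverOptions:
    def test_validation(self):
        with pytest.raises(ValueError):
            SolverOptions(mixing=0.0)
        with pytest.raises(ValueError):
            SolverOptions(mixing=1.5)
        with pytest.raises(ValueError):
            SolverOptions(tolerance=0.0)
        with pytest.raises(ValueError):
            SolverOptions(x_bracket=(1.0, 0.5))
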