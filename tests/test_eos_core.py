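"""Cubic-EOS engine: roots, mixing rules, and fugacity coefficients."""

import math

import numpy as np
import pytest
from scipy.integrate import quad

import scfsol as s
from scfsol.eos_core import (_lnphi_from_Z, critical_point_coefficients,
                             lnphi_solute_binary)
from scfsol.errors import ConfigError, NonphysicalStateError
from scfsol.properties import R_CM3_BAR
from conftest import random_binary_state

SQRT2 = math.sqrt(2.0)


class TestRegistry:
    def test_named_families_resolve(self):
        for name in ("srk", "pr", "sv", "dptg"):
            eos = s.get_eos(name)
            assert eos.delta1 >= eos.delta2

    def test_unknown_family_rejected(self):
        with pytest.raises(ConfigError):
            s.get_eos("van-der-waals-iii")

    def test_critical_constraints_reproduce_canonical_constants(self):
        """The generic critical-point solver must land on the literature
        Omega values for the SRK and PR denominator pairs."""
        oa, ob, zc = critical_point_coefficients(1.0, 0.0)
        assert oa == pytest.approx(0.42748, abs=2e-5)
        assert ob == pytest.approx(0.08664, abs=2e-5)
        assert zc == pytest.approx(1.0 / 3.0, rel=1e-12)
        oa, ob, zc = critical_point_coefficients(1 + SQRT2, 1 - SQRT2)
        assert oa == pytest.approx(0.45724, abs=2e-5)
        assert ob == pytest.approx(0.07780, abs=2e-5)
        assert zc == pytest.approx(0.30740, abs=2e-5)


class TestAlphaAndPureParams:
    def test_alpha_is_one_at_Tc(self, co2):
        for name in ("srk", "pr"):
            assert s.alpha(co2.Tc, co2, s.get_eos(name)) == pytest.approx(1.0)

    def test_pr_alpha_hand_value(self, pr):
        c = s.Component(name="x", M=44.0, Tc=300.0, Pc=70.0, omega=0.225)
        # [1 + m(1 - sqrt(0.9))]^2 with m = 0.37464+1.54226w-0.26992w^2
        assert s.alpha(270.0, c, pr) == pytest.approx(1.0739827574638565,
                                                      rel=1e-12)

    def test_sv_with_zero_kappa1_uses_kappa0_only(self):
        sv = s.get_eos("sv")
        c = s.Component(name="x", M=44.0, Tc=300.0, Pc=70.0, omega=0.3,
                        kappa1=0.0)
        k0 = (0.378893 + 1.4897153 * 0.3 - 0.17131848 * 0.3 ** 2
              + 0.0196554 * 0.3 ** 3)
        tr = 0.7
        expect = (1 + k0 * (1 - math.sqrt(tr))) ** 2
        assert s.alpha(tr * 300.0, c, sv) == pytest.approx(expect, rel=1e-12)

    def test_pure_params_closed_form_co2(self, co2, pr):
        a, b = s.pure_params(co2, 313.15, pr)
        assert a == pytest.approx(3881227.084641336, rel=1e-10)
        assert b == pytest.approx(26.661706239815718, rel=1e-10)

    def test_a_at_Tc_is_critical_value_and_b_constant(self, co2):
        for name in ("srk", "pr"):
            eos = s.get_eos(name)
            a_tc, b1 = s.pure_params(co2, co2.Tc, eos)
            assert a_tc == pytest.approx(
                eos.Omega_a * (R_CM3_BAR * co2.Tc) ** 2 / co2.Pc, rel=1e-12)
            _, b2 = s.pure_params(co2, 500.0, eos)
            assert b1 == b2


class TestMixParams:
    def test_pure_limit(self):
        rule = s.MixingRuleSpec("vdw2", kij=0.2, lij=0.1)
        am, bm = s.mix_params([1.0, 0.0], [2e6, 5e6], [25.0, 80.0], rule)
        assert am == pytest.approx(2e6) and bm == pytest.approx(25.0)

    def test_identical_components_identity(self):
        rule = s.MixingRuleSpec("vdw1", kij=0.0)
        am, bm = s.mix_params([0.3, 0.7], [4e6, 4e6], [30.0, 30.0], rule)
        assert am == pytest.approx(4e6) and bm == pytest.approx(30.0)

    def test_against_double_loop_oracle(self):
        x = np.array([0.9, 0.1])
        a = np.array([3.2e6, 4.1e7])
        b = np.array([26.0, 310.0])
        rule = s.MixingRuleSpec("vdw2", kij=0.1, lij=0.05)
        k = np.array([[0, 0.1], [0.1, 0]])
        l = np.array([[0, 0.05], [0.05, 0]])
        am_o = sum(x[i] * x[j] * math.sqrt(a[i] * a[j]) * (1 - k[i, j])
                   for i in range(2) for j in range(2))
        bm_o = sum(x[i] * x[j] * (1 - l[i, j]) * (b[i] + b[j]) / 2
                   for i in range(2) for j in range(2))
        am, bm = s.mix_params(x, a, b, rule)
        assert am == pytest.approx(am_o, rel=1e-14)
        assert bm == pytest.approx(bm_o, rel=1e-14)
        # vdW1 co-volume is the linear rule
        am1, bm1 = s.mix_params(x, a, b, s.MixingRuleSpec("vdw1", kij=0.1))
        assert am1 == pytest.approx(am_o, rel=1e-14)
        assert bm1 == pytest.approx(float(x @ b), rel=1e-14)

    def test_exchange_symmetry(self):
        rule = s.MixingRuleSpec("vdw2", kij=0.13, lij=-0.07)
        am, bm = s.mix_params([0.25, 0.75], [3e6, 4e7], [26.0, 310.0], rule)
        am2, bm2 = s.mix_params([0.75, 0.25], [4e7, 3e6], [310.0, 26.0], rule)
        assert am == pytest.approx(am2) and bm == pytest.approx(bm2)

    def test_vdw1_rejects_lij(self):
        with pytest.raises(ConfigError):
            s.MixingRuleSpec("vdw1", kij=0.1, lij=0.2)


class TestSolveZ:
    def test_ideal_gas_limits(self, pr):
        roots, z = s.solve_Z(313.15, 50.0, 0.0, 0.0, pr)
        assert z == pytest.approx(1.0, abs=1e-12)
        a, b = s.pure_params(s.carbon_dioxide(), 313.15, pr)
        _, z = s.solve_Z(313.15, 1e-6, a, b, pr)
        assert z == pytest.approx(1.0, abs=1e-4)

    def test_against_polynomial_root_oracle(self, co2):
        for name in ("srk", "pr", "sv", "dptg"):
            eos = s.get_eos(name)
            a, b = s.pure_params(co2, 313.15, eos)
            T, P = 313.15, 155.0
            RT = R_CM3_BAR * T
            A, B = a * P / RT ** 2, b * P / RT
            sgm, pr_ = eos.delta1 + eos.delta2, eos.delta1 * eos.delta2
            poly = [1.0,
                    (sgm - 1) * B - 1,
                    (pr_ - sgm) * B ** 2 - sgm * B + A,
                    -(pr_ * B ** 3 + pr_ * B ** 2 + A * B)]
            oracle = sorted(r.real for r in np.roots(poly)
                            if abs(r.imag) < 1e-12 and r.real > B)
            got, _ = s.solve_Z(T, P, a, b, eos)
            assert len(got) == len(oracle)
            for g, o in zip(sorted(got), oracle):
                assert g == pytest.approx(o, abs=1e-10)

    def test_all_returned_roots_physical_in_extreme_state(self, pr):
        # dense, strongly attracting state: every root must satisfy v > b
        T, P, a, b = 100.0, 500.0, 1e9, 5000.0
        roots, z = s.solve_Z(T, P, a, b, pr)
        B = b * P / (R_CM3_BAR * T)
        assert all(r > B for r in roots)
        assert z == max(roots)


class TestLnphiPure:
    def test_near_ideal_bound(self, co2, pr):
        assert abs(s.lnphi_pure(co2, 313.15, 1.0, pr)) < 0.01

    @pytest.mark.parametrize("name", ["srk", "pr", "sv", "dptg"])
    def test_against_quadrature_oracle(self, co2, name):
        """ln phi = Z - 1 - ln Z + (1/RT) * int_v^inf (P - RT/v') dv'."""
        eos = s.get_eos(name)
        T, P = 313.15, 155.0
        a, b = s.pure_params(co2, T, eos)
        RT = R_CM3_BAR * T
        _, Z = s.solve_Z(T, P, a, b, eos)
        v = Z * RT / P

        def integrand(vp):
            p_eos = RT / (vp - b) - a / ((vp + eos.delta1 * b)
                                         * (vp + eos.delta2 * b))
            return p_eos - RT / vp

        tail, _ = quad(integrand, v, np.inf, limit=200)
        oracle = Z - 1 - math.log(Z) + tail / RT
        assert s.lnphi_pure(co2, T, P, eos) == pytest.approx(oracle, abs=1e-8)


def mixture_lnphi(T, P, x, comps, eos, rule):
    """Mixture ln phi via the mixture closed form only (no per-component
    derivative algebra) — the base quantity for the finite-difference oracle."""
    ab = [s.pure_params(c, T, eos) for c in comps]
    a = [p[0] for p in ab]
    b = [p[1] for p in ab]
    am, bm = s.mix_params(np.asarray(x) / np.sum(x), a, b, rule)
    RT = R_CM3_BAR * T
    A, B = am * P / RT ** 2, bm * P / RT
    _, Z = s.solve_Z(T, P, am, bm, eos)
    return _lnphi_from_Z(Z, A, B, eos)


def fd_lnphi_hat(i, T, P, x, comps, eos, rule, h=1e-6):
    """Central finite difference of n * ln phi_mix with respect to n_i."""
    def n_lnphi(n):
        return np.sum(n) * mixture_lnphi(T, P, n, comps, eos, rule)
    up = np.array(x); up[i] += h
    dn = np.array(x); dn[i] -= h
    return (n_lnphi(up) - n_lnphi(dn)) / (2 * h)


class TestLnphiComponents:
    def test_pure_limit_matches_lnphi_pure(self, co2, retinol, pr):
        rule = s.MixingRuleSpec("vdw2", kij=0.3, lij=0.2)
        st = s.lnphi_components(313.15, 155.0, (0.0, 1.0),
                                (retinol, co2), pr, rule)
        assert st.lnphi[1] == pytest.approx(
            s.lnphi_pure(co2, 313.15, 155.0, pr), abs=1e-12)

    def test_state_invariants(self, co2, retinol, pr):
        rule = s.MixingRuleSpec("vdw1", kij=0.1)
        st = s.lnphi_components(313.15, 155.0, (1e-4, 1 - 1e-4),
                                (retinol, co2), pr, rule)
        assert st.v > st.b_mix
        assert st.P * st.v == pytest.approx(st.Z * R_CM3_BAR * st.T,
                                            rel=1e-10)

    def test_exchange_symmetry(self, co2, retinol, pr):
        rule = s.MixingRuleSpec("vdw2", kij=0.2, lij=0.1)
        st1 = s.lnphi_components(313.15, 155.0, (1e-3, 1 - 1e-3),
                                 (retinol, co2), pr, rule)
        st2 = s.lnphi_components(313.15, 155.0, (1 - 1e-3, 1e-3),
                                 (co2, retinol), pr, rule)
        assert st1.lnphi[0] == pytest.approx(st2.lnphi[1], rel=1e-12)
        assert st1.lnphi[1] == pytest.approx(st2.lnphi[0], rel=1e-12)

    def test_finite_difference_oracle_spot_checks(self, co2, retinol):
        rng = np.random.default_rng(7)
        for _ in range(25):
            T, P, x, eos, rule = random_binary_state(rng, retinol, co2)
            try:
                st = s.lnphi_components(T, P, x, (retinol, co2), eos, rule)
            except NonphysicalStateError:
                continue
            for i in range(2):
                fd = fd_lnphi_hat(i, T, P, x, (retinol, co2), eos, rule)
                assert st.lnphi[i] == pytest.approx(fd, abs=1e-6)

    def test_euler_consistency_spot_checks(self, co2, retinol):
        rng = np.random.default_rng(8)
        for _ in range(50):
            T, P, x, eos, rule = random_binary_state(rng, retinol, co2)
            try:
                st = s.lnphi_components(T, P, x, (retinol, co2), eos, rule)
            except NonphysicalStateError:
                continue
            assert st.lnphi_mix == pytest.approx(
                mixture_lnphi(T, P, x, (retinol, co2), eos, rule), abs=1e-10)

    def test_scalar_binary_path_matches_general_path(self, co2, retinol):
        rng = np.random.default_rng(9)
        for _ in range(50):
            T, P, x, eos, rule = random_binary_state(rng, retinol, co2)
            aA, bA = s.pure_params(retinol, T, eos)
            aC, bC = s.pure_params(co2, T, eos)
            try:
                fast = lnphi_solute_binary(T, P, x[0], aA, bA, aC, bC,
                                           eos, rule)
            except NonphysicalStateError:
                continue
            st = s.lnphi_components(T, P, x, (retinol, co2), eos, rule)
            assert fast == pytest.approx(st.lnphi[0], rel=1e-12, abs=1e-12)


class TestGenericEngineCrossCheck:
    def test_generic_srk_matches_hardcoded_reference(self, co2):
        """delta = (1, 0) with SRK Omegas must reproduce an independently
        coded textbook SRK ln phi to near machine precision."""
        T, P = 313.15, 120.0
        m = 0.480 + 1.574 * co2.omega - 0.176 * co2.omega ** 2
        al = (1 + m * (1 - math.sqrt(T / co2.Tc))) ** 2
        a = 0.42748 * (R_CM3_BAR * co2.Tc) ** 2 / co2.Pc * al
        b = 0.08664 * R_CM3_BAR * co2.Tc / co2.Pc
        RT = R_CM3_BAR * T
        A, B = a * P / RT ** 2, b * P / RT
        zs = sorted(r.real for r in np.roots(
            [1, -1, A - B - B * B, -A * B]) if abs(r.imag) < 1e-13)
        Z = max(z for z in zs if z > B)
        reference = Z - 1 - math.log(Z - B) - A / B * math.log(1 + B / Z)
        assert s.lnphi_pure(co2, T, P, s.get_eos("srk")) == pytest.approx(
            reference, abs=1e-12)
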