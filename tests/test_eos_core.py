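"""Equation-of-state core: Soave term, mixing rules, association, volumes.

The SRK reference expressions and the closed-form site-fraction solutions
used here are written out independently of the implementation so they act
as genuine oracles.
"""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cpaeos.constants import R
from cpaeos import eos
from cpaeos.eos import (
    Mixture,
    association_strength,
    closed_form_site_fraction,
    cross_association_parameters,
    fugacity_coefficients,
    mix_ab,
    pressure,
    radial_distribution,
    reduced_residual_helmholtz,
    soave_a,
    solve_site_fractions,
    solve_volume,
    volume_roots,
)
from cpaeos.parameters import BinaryInteraction, PureComponent, get_binary, get_component


class TestSoave:
    def test_alpha_is_one_at_critical_temperature(self, co2, methanol):
        assert soave_a(co2, 304.2) == pytest.approx(3.5079, abs=1e-12)
        assert soave_a(methanol, 512.6) == pytest.approx(4.0531, abs=1e-12)

    def test_subcritical_evaluation(self, co2):
        expected = 3.5079 * (1 + 0.7602 * (1 - math.sqrt(273.15 / 304.2))) ** 2
        assert soave_a(co2, 273.15) == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(3.793, abs=5e-4)

    def test_supercritical_uses_same_expression(self, co2):
        expected = 3.5079 * (1 + 0.7602 * (1 - math.sqrt(350.0 / 304.2))) ** 2
        assert soave_a(co2, 350.0) == pytest.approx(expected, rel=1e-14)

    def test_nonpositive_temperature_rejected(self, co2):
        with pytest.raises(ValueError):
            soave_a(co2, 0.0)


class TestMixingRules:
    def test_pure_limit(self, co2_methanol):
        a, b, _ = mix_ab(co2_methanol, [1.0, 0.0], 304.2)
        assert a == pytest.approx(3.5079, abs=1e-12)
        assert b == pytest.approx(0.0272, abs=1e-15)

    def test_equimolar_hand_evaluation(self, co2_methanol):
        # hand-evaluated one-fluid rule at the temperature where both pure
        # a values are their a0 (alpha = 1 is not available jointly, so use
        # the actual Soave values in the oracle)
        T = 313.15
        a1 = soave_a(get_component("CO2"), T)
        a2 = soave_a(get_component("methanol"), T)
        kij = 0.0479
        expected = 0.25 * (a1 + a2) + 0.5 * math.sqrt(a1 * a2) * (1 - kij)
        a, b, bij = mix_ab(co2_methanol, [0.5, 0.5], T)
        assert a == pytest.approx(expected, rel=1e-14)
        assert b == pytest.approx(0.5 * (0.0272 + 0.0310), rel=1e-14)
        assert bij[0, 1] == pytest.approx(0.5 * (0.0272 + 0.0310), rel=1e-14)

    def test_kij_of_one_annihilates_cross_term(self):
        mix = Mixture(
            ["CO2", "methanol"],
            [BinaryInteraction(pair=("CO2", "methanol"), kij=1.0)],
        )
        T = 320.0
        a1 = soave_a(get_component("CO2"), T)
        a2 = soave_a(get_component("methanol"), T)
        a, _, _ = mix_ab(mix, [0.5, 0.5], T)
        assert a == pytest.approx((a1 + a2) / 4.0, rel=1e-14)


class TestRadialDistribution:
    @pytest.mark.parametrize(
        "eta,g,deriv",
        [
            (0.0, 1.0, 0.0),
            (0.25, 1.0 / 0.525, 1.9 * 0.25 / 0.525),
            (0.1, 1.0 / 0.81, 0.19 / 0.81),
        ],
    )
    def test_values(self, eta, g, deriv):
        gv, dv = radial_distribution(eta)
        assert gv == pytest.approx(g, rel=1e-14)
        assert dv == pytest.approx(deriv, rel=1e-14)

    def test_pole_rejected(self):
        with pytest.raises(ValueError):
            radial_distribution(1.0 / 1.9)


class TestCrossAssociation:
    def test_cr1_arithmetic_energy_geometric_volume(self, glycerol, methanol):
        inter = get_binary("glycerol", "methanol")
        eps, beta = cross_association_parameters(inter, glycerol, methanol)
        assert eps == pytest.approx((207.85 + 245.91) / 2, rel=1e-14)
        assert beta == pytest.approx(math.sqrt(0.0133 * 0.0161), rel=1e-12)

    def test_mcr1_half_energy_stored_volume(self, co2, glycerol):
        inter = get_binary("CO2", "glycerol", variant="one_site")
        eps, beta = cross_association_parameters(inter, co2, glycerol)
        assert eps == pytest.approx(207.85 / 2, rel=1e-14)
        assert beta == 0.0979

    def test_explicit_values_passed_through(self, co2, methanol):
        inter = get_binary("CO2", "methanol")
        eps, beta = cross_association_parameters(inter, co2, methanol)
        assert (eps, beta) == (123.8, 0.0196)

    def test_cr1_requires_two_self_associating_partners(self, co2, methanol):
        bad = BinaryInteraction(pair=("CO2", "methanol"), kij=0.0, cross_rule="CR1")
        with pytest.raises(ValueError, match="self-associating"):
            cross_association_parameters(bad, co2, methanol)


class TestAssociationStrength:
    def test_zero_volume_or_energy_gives_zero(self):
        assert association_strength(100.0, 0.0, 300.0, 1.3, 0.05) == 0.0
        assert association_strength(0.0, 0.02, 300.0, 1.3, 0.05) == 0.0

    def test_glycerol_self_pair_value(self):
        # Delta = g (exp(eps/RT) - 1) b beta with the glycerol parameters
        expected = 1.2 * math.expm1(207.85 / (R * 400.0)) * 0.0696 * 0.0133
        got = association_strength(207.85, 0.0133, 400.0, 1.2, 0.0696)
        assert got == pytest.approx(expected, rel=1e-14)
        assert expected == pytest.approx(0.574, abs=5e-4)


def _pure_scheme_mixture(scheme: str, eps: float = 150.0, beta: float = 0.02):
    comp = PureComponent(
        name=f"model_{scheme}", mw=100.0, tc=700.0, a0=10.0, b=0.08,
        c1=1.0, eps_assoc=eps, beta_assoc=beta, scheme=scheme,
    )
    return Mixture([comp]), comp


class TestSiteFractions:
    def test_all_inactive_gives_unity(self, srk_binary):
        X = solve_site_fractions(srk_binary, 350.0, 5.0, [0.5, 0.5])
        assert np.all(X == 1.0)

    @pytest.mark.parametrize("scheme,n", [("1A", 1), ("2B", 1), ("4C", 2), ("3x2B", 3)])
    def test_solver_matches_closed_form_over_wide_strength_range(self, scheme, n):
        # sweep the dimensionless bonding strength rho*Delta over [0, 1e3]
        mix, comp = _pure_scheme_mixture(scheme)
        T = 350.0
        rho = 8.0
        eta = comp.b * rho / 4.0
        g = 1.0 / (1.0 - 1.9 * eta)
        delta_unit = g * math.expm1(comp.eps_assoc / (R * T)) * comp.b
        for rd_target in np.geomspace(1e-6, 1e3, 200):
            beta = rd_target / (rho * delta_unit)
            mix2, _ = _pure_scheme_mixture(scheme, beta=beta)
            X = solve_site_fractions(mix2, T, rho, [1.0])
            expected = closed_form_site_fraction(scheme, rd_target)
            assert X == pytest.approx(expected, abs=1e-10)

    def test_closed_form_reference_points(self):
        assert closed_form_site_fraction("2B", 0.0) == 1.0
        assert closed_form_site_fraction("2B", 1.0) == pytest.approx(
            (-1 + math.sqrt(5)) / 2, rel=1e-14
        )
        assert closed_form_site_fraction("2B", 2.0) == pytest.approx(0.5, rel=1e-14)
        assert closed_form_site_fraction("4C", 1.0) == pytest.approx(0.5, rel=1e-14)
        assert closed_form_site_fraction("3x2B", 1.0) == pytest.approx(
            (-1 + math.sqrt(13)) / 6, rel=1e-14
        )
        with pytest.raises(ValueError):
            closed_form_site_fraction("5D", 1.0)

    def test_donor_acceptor_symmetry(self, glycerol):
        mix = Mixture([glycerol])
        X = solve_site_fractions(mix, 360.0, 11.0, [1.0])
        assert X[0] == pytest.approx(X[1], abs=1e-12)

    @given(
        rho=st.floats(0.5, 8.0),
        scale=st.floats(1.1, 2.5),
    )
    @settings(max_examples=25, deadline=None)
    def test_bonded_fraction_grows_with_density_and_volume(self, rho, scale):
        mix, _ = _pure_scheme_mixture("4C", beta=0.02)
        mix2, _ = _pure_scheme_mixture("4C", beta=0.02 * scale)
        X1 = solve_site_fractions(mix, 350.0, rho, [1.0])[0]
        X2 = solve_site_fractions(mix, 350.0, rho * scale, [1.0])[0]
        X3 = solve_site_fractions(mix2, 350.0, rho, [1.0])[0]
        assert X2 <= X1 + 1e-12  # denser fluid: more bonding
        assert X3 <= X1 + 1e-12  # larger association volume: more bonding


# ---------------------------------------------------------------------------
# SRK reduction oracle


def _srk_reference(mix, T, Vm, x):
    """Independent SRK closed forms: P, reduced residual Helmholtz, lnphi."""
    x = np.asarray(x, float)
    ai = np.array([soave_a(c, T) for c in mix.components])
    bi = np.array([c.b for c in mix.components])
    aij = np.sqrt(np.outer(ai, ai)) * (1.0 - mix.kij)
    a = x @ aij @ x
    b = x @ bi
    P = R * T / (Vm - b) - a / (Vm * (Vm + b))
    ares = -math.log(1 - b / Vm) - a / (b * R * T) * math.log(1 + b / Vm)
    lnphi = None
    if P > 0:
        Z = P * Vm / (R * T)
        Bs = b * P / (R * T)
        As = a * P / (R * T) ** 2
        lnphi = (
            bi / b * (Z - 1)
            - math.log(Z - Bs)
            - As / Bs * (2 * (aij @ x) / a - bi / b) * math.log(1 + Bs / Z)
        )
    return P, ares, lnphi


class TestSrkReduction:
    def test_matches_srk_closed_forms_on_grid(self, srk_binary):
        mix = srk_binary
        for T in np.linspace(310, 430, 10):
            for frac in np.linspace(0.05, 0.95, 5):
                x = np.array([frac, 1 - frac])
                b = float(x @ mix.b)
                for Vm in np.geomspace(b * 1.3, 50.0, 10):
                    P_ref, ares_ref, lnphi_ref = _srk_reference(mix, T, Vm, x)
                    assert pressure(mix, T, Vm, x) == pytest.approx(P_ref, rel=1e-12, abs=1e-12)
                    assert reduced_residual_helmholtz(mix, T, Vm, x) == pytest.approx(
                        ares_ref, rel=1e-12, abs=1e-14
                    )
                    if lnphi_ref is not None:
                        ctx = mix.context(T, x)
                        lnphi, _, _, _ = eos._lnphi_ctx(ctx, Vm)
                        assert np.allclose(lnphi, lnphi_ref, rtol=1e-12, atol=1e-12)


class TestPressure:
    def test_ideal_gas_limit(self, co2_methanol):
        T = 400.0
        Vm = 1e6
        P = pressure(co2_methanol, T, Vm, [0.5, 0.5])
        assert P * Vm / (R * T) == pytest.approx(1.0, rel=1e-4)

    def test_volume_below_covolume_rejected(self, co2_methanol):
        with pytest.raises(ValueError):
            pressure(co2_methanol, 300.0, 0.01, [0.5, 0.5])

    def test_pure_glycerol_term_by_term_oracle(self, glycerol):
        # rebuild every term of the pressure equation independently
        mix = Mixture([glycerol])
        T, Vm = 400.0, 0.09
        rho = 1.0 / Vm
        a = soave_a(glycerol, T)
        b = glycerol.b
        eta = b * rho / 4.0
        g = 1.0 / (1.0 - 1.9 * eta)
        delta = g * math.expm1(glycerol.eps_assoc / (R * T)) * b * glycerol.beta_assoc
        X = closed_form_site_fraction("3x2B", rho * delta)
        h = 6.0 * (1.0 - X)  # 3 donors + 3 acceptors per molecule
        P_expected = (
            R * T / (Vm - b)
            - a / (Vm * (Vm + b))
            - 0.5 * (R * T / Vm) * (1.0 + 1.9 * eta / (1.0 - 1.9 * eta)) * h
        )
        assert pressure(mix, T, Vm, [1.0]) == pytest.approx(P_expected, rel=1e-10)


class TestThermodynamicConsistency:
    def _three_component_mix(self):
        return Mixture(
            ["CO2", "methanol", "glycerol"],
            [
                get_binary("CO2", "methanol"),
                get_binary("CO2", "glycerol"),
                get_binary("glycerol", "methanol"),
            ],
        )

    def test_pressure_is_volume_derivative_of_helmholtz(self, rng):
        mix = self._three_component_mix()
        for _ in range(12):
            T = rng.uniform(300, 420)
            x = rng.dirichlet([2, 2, 2])
            b = float(x @ mix.b)
            Vm = rng.uniform(1.4 * b, 40 * b)
            h = Vm * 1e-4
            f = lambda V: reduced_residual_helmholtz(mix, T, V, x)
            dnum = (-f(Vm + 2 * h) + 8 * f(Vm + h) - 8 * f(Vm - h) + f(Vm - 2 * h)) / (12 * h)
            P_num = -R * T * dnum + R * T / Vm
            P_ana = pressure(mix, T, Vm, x)
            assert P_num == pytest.approx(P_ana, rel=1e-9)

    def test_lnphi_matches_numerical_composition_derivative(self, rng):
        mix = self._three_component_mix()
        checked = 0
        while checked < 10:
            T = rng.uniform(300, 420)
            x = rng.dirichlet([3, 3, 3])
            P = rng.uniform(5.0, 250.0)
            V = solve_volume(mix, T, P, x, "liquid")
            ctx = mix.context(T, x)
            lnphi, Pc, Z, _ = eos._lnphi_ctx(ctx, V)

            def n_ares(n):
                n = np.asarray(n)
                ntot = n.sum()
                return ntot * reduced_residual_helmholtz(mix, T, V / ntot, n / ntot)

            for i in range(3):
                dn = 1e-6
                hi = x.copy(); hi[i] += dn
                lo = x.copy(); lo[i] -= dn
                num = (n_ares(hi) - n_ares(lo)) / (2 * dn) - math.log(Z)
                assert num == pytest.approx(lnphi[i], rel=1e-6, abs=1e-8)
            checked += 1

    def test_gibbs_duhem_along_composition_path(self, co2_methanol):
        # sum_i x_i d(ln phi_i) ~ 0 at constant T, P
        T, P = 313.15, 60.0
        zs = np.linspace(0.2, 0.4, 21)
        lnphis = np.array(
            [fugacity_coefficients(co2_methanol, T, P, [z, 1 - z], "liquid") for z in zs]
        )
        mid = 0.5 * (np.array([zs, 1 - zs]).T[1:] + np.array([zs, 1 - zs]).T[:-1])
        dln = np.diff(lnphis, axis=0)
        gd = (mid * dln).sum(axis=1)
        assert np.max(np.abs(gd)) < 5e-6  # discretization error only


class TestVolumeRoots:
    def test_ideal_gas_regime(self, srk_binary):
        V = solve_volume(srk_binary, 600.0, 0.5, [0.5, 0.5], "vapor")
        assert V == pytest.approx(R * 600.0 / 0.5, rel=0.01)

    def test_root_satisfies_pressure_equation(self, co2_glycerol_one_site):
        mix = co2_glycerol_one_site
        for P in [1.0, 50.0, 300.0]:
            for hint in ("liquid", "vapor"):
                V = solve_volume(mix, 330.0, P, [0.1, 0.9], hint)
                assert pressure(mix, 330.0, V, [0.1, 0.9]) == pytest.approx(P, rel=1e-10)

    def test_no_hint_returns_lowest_gibbs_root(self, co2):
        # subcritical CO2 with two roots: compare against explicit Gibbs
        mix = Mixture([co2])
        T, P = 273.15, 20.0
        roots = volume_roots(mix, T, P, [1.0])
        assert len(roots) == 2

        def gibbs(V):
            ares = reduced_residual_helmholtz(mix, T, V, [1.0])
            Z = P * V / (R * T)
            return ares + Z - 1 - math.log(Z)

        chosen = solve_volume(mix, T, P, [1.0])
        g = [gibbs(V) for V in roots]
        assert chosen == pytest.approx(roots[int(np.argmin(g))], rel=1e-12)

    def test_dense_scan_confirms_root_census(self, co2):
        mix = Mixture([co2])
        T, P = 273.15, 20.0
        roots = volume_roots(mix, T, P, [1.0])
        Vs = np.geomspace(0.0272 * 1.001, 3.0, 4000)
        f = np.array([pressure(mix, T, V, [1.0]) for V in Vs]) - P
        crossings = np.where(np.sign(f[:-1]) != np.sign(f[1:]))[0]
        stable = [k for k in crossings if f[k] > 0 > f[k + 1]]
        assert len(stable) == len(roots)
        for k, V in zip(stable, roots):
            assert Vs[k] <= V <= Vs[k + 1]
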