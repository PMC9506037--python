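"""Phase-equilibrium solvers: saturation, bubble/dew, flash, isotherms."""

import math

import numpy as np
import pytest
from scipy.integrate import quad
from scipy.optimize import brentq

from cpaeos.constants import R
from cpaeos.eos import Mixture, pressure, volume_roots
from cpaeos.equilibrium import (
    ConvergenceError,
    SupercriticalError,
    binary_xy_at_tp,
    bubble_pressure,
    dew_pressure,
    pt_flash,
    pure_saturation,
    trace_isotherm,
    vapor_composition_minimum,
)
from cpaeos.parameters import get_binary, get_component
from cpaeos.synthetic import ternary_fixture


class TestPureSaturation:
    def test_equal_fugacity_contract(self, co2, glycerol):
        from cpaeos.eos import fugacity_coefficients

        for comp, T in [(co2, 260.0), (glycerol, 500.0)]:
            mix = Mixture([comp])
            psat, vl, vv = pure_saturation(comp, T)
            lnL = fugacity_coefficients(mix, T, psat, [1.0], "liquid")
            lnV = fugacity_coefficients(mix, T, psat, [1.0], "vapor")
            assert abs(lnL[0] - lnV[0]) <= 1e-10
            assert vl < vv

    def test_co2_matches_maxwell_equal_area_construction(self, co2):
        # independent oracle: the saturation pressure also makes the areas
        # between the isotherm and the horizontal P = Psat line cancel
        mix = Mixture([co2])
        T = 273.15

        def area(P):
            roots = volume_roots(mix, T, P, [1.0])
            vl, vv = roots[0], roots[-1]
            integral, _ = quad(lambda V: pressure(mix, T, V, [1.0]), vl, vv, limit=200)
            return integral - P * (vv - vl)

        P_area = brentq(area, 20.0, 45.0, xtol=1e-10)
        psat, _, _ = pure_saturation(co2, T)
        assert psat == pytest.approx(P_area, rel=1e-8)

    def test_monotone_in_temperature(self, co2):
        ps = [pure_saturation(co2, T)[0] for T in np.linspace(216.0, 300.0, 15)]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_supercritical_rejected(self, co2):
        with pytest.raises(SupercriticalError):
            pure_saturation(co2, 330.0)


class TestBubblePressure:
    def test_pure_limit_recovers_saturation(self, co2_methanol, methanol):
        T = 330.0
        res = bubble_pressure(co2_methanol, T, [0.0, 1.0])
        psat, _, _ = pure_saturation(methanol, T)
        assert res.P == pytest.approx(psat, rel=1e-8)

    def test_fugacity_equality_at_convergence(self, co2_glycerol_one_site):
        res = bubble_pressure(co2_glycerol_one_site, 333.15, [0.04, 0.96])
        assert res.converged
        assert res.residual <= 1e-8
        assert res.fugacity_residual(co2_glycerol_one_site) <= 1e-8
        assert res.x.sum() == pytest.approx(1.0, abs=1e-12)
        assert res.y.sum() == pytest.approx(1.0, abs=1e-12)

    def test_flash_round_trip(self, co2_methanol):
        # compositions produced by a flash at known (T, P) feed back into
        # bubble_pressure and recover that pressure
        T = 313.15
        base = bubble_pressure(co2_methanol, T, [0.3, 0.7])
        fl = pt_flash(co2_methanol, T, base.P * 0.9, [0.3, 0.7])
        assert 0 < fl.vapor_fraction < 1
        back = bubble_pressure(co2_methanol, T, fl.x)
        assert back.P == pytest.approx(base.P * 0.9, rel=1e-6)


class TestDewPressure:
    def test_pure_limit(self, co2_methanol, methanol):
        T = 330.0
        res = dew_pressure(co2_methanol, T, [0.0, 1.0])
        psat, _, _ = pure_saturation(methanol, T)
        assert res.P == pytest.approx(psat, rel=1e-8)

    def test_bubble_dew_closure(self, co2_methanol):
        T = 313.15
        bub = bubble_pressure(co2_methanol, T, [0.25, 0.75])
        dew = dew_pressure(co2_methanol, T, bub.y, P0=bub.P, K0=bub.K)
        assert dew.P == pytest.approx(bub.P, rel=1e-6)
        assert np.allclose(dew.x, bub.x, atol=1e-6)

    def test_ternary_closure_on_upper_branch(self):
        mix, feeds = ternary_fixture(["CO2", "glycerol", "methanol"])
        bub = bubble_pressure(mix, 333.15, feeds["mixture_2"])
        dew = dew_pressure(mix, 333.15, bub.y, P0=bub.P, K0=bub.K)
        assert dew.P == pytest.approx(bub.P, rel=1e-6)

    def test_zero_component_stays_absent(self, co2_methanol):
        res = dew_pressure(co2_methanol, 313.15, [1.0, 0.0])
        assert res.x[1] <= 1e-12


class TestFlash:
    def test_above_bubble_pressure_is_single_liquid(self, co2_methanol):
        T = 313.15
        bub = bubble_pressure(co2_methanol, T, [0.3, 0.7])
        fl = pt_flash(co2_methanol, T, bub.P * 1.05, [0.3, 0.7])
        assert fl.vapor_fraction == 0.0
        assert np.allclose(fl.x, [0.3, 0.7])

    def test_material_balance(self, co2_methanol):
        T, P = 313.15, 40.0
        z = np.array([0.45, 0.55])
        fl = pt_flash(co2_methanol, T, P, z)
        beta = fl.vapor_fraction
        assert 0 < beta < 1
        recon = beta * fl.y + (1 - beta) * fl.x
        assert np.max(np.abs(recon - z)) <= 1e-10
        assert fl.residual <= 1e-8

    def test_brackets_bubble_point_continuously(self, co2_methanol):
        T = 313.15
        z = np.array([0.3, 0.7])
        bub = bubble_pressure(co2_methanol, T, z)
        below = pt_flash(co2_methanol, T, bub.P * (1 - 1e-4), z)
        above = pt_flash(co2_methanol, T, bub.P * (1 + 1e-4), z)
        assert above.vapor_fraction == 0.0
        assert 0 < below.vapor_fraction < 5e-3
        assert np.allclose(below.x, z, atol=1e-3)


class TestIsotherm:
    def test_pressure_monotone_on_dilute_branch(self, co2_peg200):
        grid = np.linspace(0.05, 0.45, 9)
        results = trace_isotherm(co2_peg200, 313.15, grid)
        assert all(r.converged for r in results)
        ps = [r.P for r in results]
        assert all(a < b for a, b in zip(ps, ps[1:]))

    def test_empty_grid(self, co2_peg200):
        assert trace_isotherm(co2_peg200, 313.15, []) == []

    def test_grid_self_convergence(self, co2_peg200):
        # halving the step changes interpolated pressures by well under 0.1%
        T = 313.15
        coarse_x = np.linspace(0.1, 0.4, 16)
        fine_x = np.linspace(0.1, 0.4, 31)
        coarse = trace_isotherm(co2_peg200, T, coarse_x)
        fine = trace_isotherm(co2_peg200, T, fine_x)
        interp = np.interp(fine_x, coarse_x, [r.P for r in coarse])
        rel = np.abs(interp - [r.P for r in fine]) / [r.P for r in fine]
        assert rel.max() < 1e-3

    def test_requires_binary(self):
        mix, _ = ternary_fixture(["CO2", "glycerol", "methanol"])
        with pytest.raises(ValueError):
            trace_isotherm(mix, 313.15, [0.1])


class TestBinaryStateAtTP:
    def test_consistent_with_bubble_curve(self, co2_peg200):
        T = 313.15
        direct = bubble_pressure(co2_peg200, T, [0.25, 0.75])
        res = binary_xy_at_tp(co2_peg200, T, direct.P, x1_guess=0.2)
        assert res.x[0] == pytest.approx(0.25, abs=1e-8)
        assert np.allclose(res.y, direct.y, atol=1e-8)

    def test_unreachable_pressure_rejected(self, co2_methanol):
        # the CO2-methanol two-phase region at 313 K ends near the mixture
        # critical point, far below 500 bar
        with pytest.raises(ConvergenceError):
            binary_xy_at_tp(co2_methanol, 313.15, 500.0, x1_guess=0.2)


class TestVaporCompositionMinimum:
    def test_glycerol_isotherm_has_interior_minimum(self, co2_glycerol_one_site):
        P_min, y_min, interior = vapor_composition_minimum(
            co2_glycerol_one_site, 323.15, (10.0, 350.0), n_scan=16
        )
        assert interior
        assert 10.0 < P_min < 350.0
        assert 0 < y_min < 1e-4

    def test_minimum_confirmed_by_dense_scan(self, co2_glycerol_one_site):
        mix = co2_glycerol_one_site
        T = 323.15
        P_min, y_min, interior = vapor_composition_minimum(mix, T, (10.0, 80.0), n_scan=12)
        assert interior
        Ps = np.linspace(10.0, 80.0, 60)
        guess = 0.01
        ys = []
        for P in Ps:
            r = binary_xy_at_tp(mix, T, float(P), x1_guess=guess)
            guess = float(r.x[0])
            ys.append(float(r.y[1]))
        k = int(np.argmin(ys))
        assert abs(Ps[k] - P_min) <= (Ps[1] - Ps[0]) * 1.5
        assert y_min <= min(ys) + 1e-12

    def test_monotone_stretch_returns_boundary(self, co2_glycerol_one_site):
        # on the rising branch well above the minimum there is no interior
        # minimizer: the lower boundary comes back flagged
        P_min, _, interior = vapor_composition_minimum(
            co2_glycerol_one_site, 323.15, (150.0, 300.0), n_scan=8
        )
        assert not interior
        assert P_min == 150.0
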