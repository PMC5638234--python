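"""Closed-form stomatal models, Weibull curves and the Farquhar model."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from stomatafit.exceptions import InvalidInputError
from stomatafit.farquhar import FarquharParams, arrhenius, farquhar_a
from stomatafit.models import (WeibullCurve, bbl_gs, bblh_gs, medlyn_gs, plc,
                               tuzet_gs, weibull_from_p50_p88,
                               weibull_survival)


class TestStomatalModels:
    @pytest.mark.parametrize("A,Cs,D,g1,expected", [
        (10.0, 400.0, 1.0, 4.0, 0.2),
        (0.0, 400.0, 1.0, 4.0, 0.0),
        (10.0, 400.0, 4.0, 4.0, 0.12),
    ])
    def test_medlyn_hand_values(self, A, Cs, D, g1, expected):
        assert medlyn_gs(A, Cs, D, g1) == pytest.approx(expected)

    @pytest.mark.parametrize("A,D,d1,expected", [
        (10.0, 1.0, 1.0, 0.125),   # 100 / (400 * 2)
        (10.0, 0.0, 1.0, 0.25),    # VPD term = 1
        (0.0, 1.0, 1.0, 0.0),
    ])
    def test_bbl_hand_values(self, A, D, d1, expected):
        assert bbl_gs(A, 440.0, D, alpha=10.0, d1=d1, gamma_star=40.0) == \
            pytest.approx(expected)

    def test_tuzet_hand_values(self):
        base = tuzet_gs(10.0, 440.0, 0.0, alpha=10.0, b=2.0, c=2.0,
                        gamma_star=40.0)
        assert base == pytest.approx(0.25)  # Weibull factor 1 at psi=0
        at_c = tuzet_gs(10.0, 440.0, -2.0, alpha=10.0, b=2.0, c=2.0,
                        gamma_star=40.0)
        assert at_c == pytest.approx(0.25 * math.exp(-1.0))
        assert at_c == pytest.approx(0.0920, abs=5e-5)

    def test_bblh_hand_value(self):
        out = bblh_gs(10.0, 440.0, 1.0, -2.0, alpha=10.0, d1=1.0, b=2.0,
                      c=2.0, gamma_star=40.0)
        assert out == pytest.approx(0.125 * math.exp(-1.0))
        assert out == pytest.approx(0.0460, abs=5e-5)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            medlyn_gs(10.0, -1.0, 1.0, 4.0)
        with pytest.raises(InvalidInputError):
            bbl_gs(10.0, 40.0, 1.0, alpha=10.0, d1=1.0, gamma_star=40.0)
        with pytest.raises(InvalidInputError):
            tuzet_gs(10.0, 440.0, 0.5, alpha=10.0, b=2.0, c=2.0,
                     gamma_star=40.0)  # psi > 0

    def test_medlyn_vpd_floor(self):
        # below the floor the singular 1/sqrt(D) term is clamped
        assert medlyn_gs(10.0, 400.0, 0.0, 4.0) == \
            medlyn_gs(10.0, 400.0, 0.05, 4.0)

    @given(A=st.floats(0.1, 30), Cs=st.floats(200, 800),
           D=st.floats(0.06, 6), psi=st.floats(-8, 0),
           alpha=st.floats(1, 40), d1=st.floats(0.1, 8),
           b=st.floats(0.5, 8), c=st.floats(0.3, 8))
    @settings(max_examples=200, deadline=None)
    def test_reduction_identities(self, A, Cs, D, psi, alpha, d1, b, c):
        """BBL.H collapses exactly to BBL at psi=0 and to Tuzet at D=0."""
        at0 = bblh_gs(A, Cs, D, 0.0, alpha, d1, b, c)
        assert at0 == pytest.approx(bbl_gs(A, Cs, D, alpha, d1), abs=1e-12)
        noD = bblh_gs(A, Cs, 0.0, psi, alpha, d1, b, c)
        assert noD == pytest.approx(tuzet_gs(A, Cs, psi, alpha, b, c),
                                    abs=1e-12)

    @given(A=st.floats(0.5, 30), D=st.floats(0.1, 5.5),
           psi=st.floats(-7.5, -0.01))
    @settings(max_examples=100, deadline=None)
    def test_monotone_in_drivers(self, A, D, psi):
        """gs falls with atmospheric dryness and with water stress, and is
        linear in assimilation."""
        assert medlyn_gs(A, 400, D + 0.3, 4.0) < medlyn_gs(A, 400, D, 4.0)
        assert bbl_gs(A, 400, D + 0.3, 9.0, 1.2) < bbl_gs(A, 400, D, 9.0, 1.2)
        assert tuzet_gs(A, 400, psi - 0.2, 9.0, 2.0, 2.0) < \
            tuzet_gs(A, 400, psi, 9.0, 2.0, 2.0)
        assert bblh_gs(2 * A, 400, D, psi, 9.0, 1.2, 2.0, 2.0) == \
            pytest.approx(2 * bblh_gs(A, 400, D, psi, 9.0, 1.2, 2.0, 2.0))


class TestWeibull:
    def test_survival_anchors(self):
        cur = WeibullCurve(b=2.5, c=1.8)
        assert weibull_survival(0.0, cur) == 1.0
        assert weibull_survival(-cur.c, cur) == pytest.approx(math.exp(-1))

    def test_large_shape_is_step_like(self):
        cur = WeibullCurve(b=80.0, c=2.0)
        assert weibull_survival(-1.8, cur) > 0.999
        assert weibull_survival(-2.2, cur) < 0.001

    def test_from_p50_p88_roundtrip_and_closed_form(self):
        cur = weibull_from_p50_p88(-3.0, -4.5)
        assert plc(-3.0, cur) == pytest.approx(50.0, abs=1e-6)
        assert plc(-4.5, cur) == pytest.approx(88.0, abs=1e-6)
        # independent numeric solve of the two defining constraints
        b_num = brentq(
            lambda b: (4.5 / (3.0 / math.log(2) ** (1 / b))) ** b
            - math.log(1 / 0.12), 0.1, 50.0)
        assert cur.b == pytest.approx(b_num, rel=1e-9)
        assert cur.b == pytest.approx(2.76, abs=0.01)
        assert cur.c == pytest.approx(3.43, abs=0.01)

    def test_wider_spread_gives_shallower_curve(self):
        assert weibull_from_p50_p88(-3.0, -6.0).b < \
            weibull_from_p50_p88(-3.0, -4.5).b

    def test_invalid_p50_p88(self):
        with pytest.raises(InvalidInputError):
            weibull_from_p50_p88(-3.0, -2.5)
        with pytest.raises(InvalidInputError):
            weibull_from_p50_p88(3.0, -4.5)

    def test_plc_anchors(self):
        cur = weibull_from_p50_p88(-2.0, -3.1)
        assert plc(0.0, cur) == 0.0
        assert plc(-2.0, cur) == pytest.approx(50.0, abs=1e-9)

    def test_psi_at_half_closed_form(self):
        cur = WeibullCurve(b=3.0, c=2.0)
        assert weibull_survival(cur.psi_at_half, cur) == pytest.approx(0.5)


class TestFarquhar:
    def test_compensation_point_gives_minus_rd(self):
        p = FarquharParams()
        gstar = arrhenius(p.gamma_star25, p.Ea_gamma_star, 25.0)
        rd = arrhenius(p.Rd25, p.Ea_Rd, 25.0)
        assert farquhar_a(gstar, 25.0, 1500.0, p) == pytest.approx(-rd)

    def test_dark_gives_minus_rd(self):
        p = FarquharParams()
        assert farquhar_a(300.0, 25.0, 0.0, p) == pytest.approx(-p.Rd25)

    def test_rubisco_limit_hand_formula(self):
        # saturating light, Ci far above Gamma*: A equals the Rubisco-limited
        # expression evaluated independently
        p = FarquharParams(Jmax25=400.0)  # light never limiting here
        ci, T = 300.0, 25.0
        kc = p.Kc25 * (1 + p.O / p.Ko25)
        expect = p.Vcmax25 * (ci - p.gamma_star25) / (ci + kc) - p.Rd25
        assert farquhar_a(ci, T, 5000.0, p) == pytest.approx(expect, rel=1e-6)

    def test_monotone_in_ci_and_par(self):
        p = FarquharParams()
        ci = np.linspace(60.0, 1500.0, 200)
        a = farquhar_a(ci, 25.0, 1200.0, p)
        assert np.all(np.diff(a) >= -1e-9)
        par = np.linspace(0.0, 2500.0, 150)
        a2 = farquhar_a(300.0 * np.ones_like(par), 25.0, par, p)
        assert np.all(np.diff(a2) >= -1e-9)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            farquhar_a(-5.0, 25.0, 1000.0)
        with pytest.raises(InvalidInputError):
            FarquharParams(Vcmax25=-1.0)
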