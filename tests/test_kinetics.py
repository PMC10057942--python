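"""Rate laws, porosity-diffusivity relation and Arrhenius scaling."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from polyerode.kinetics import (
    ArrheniusLaw,
    KineticParameters,
    arrhenius_evaluate,
    arrhenius_preexponential,
    arrhenius_transfer,
    ester_reaction_rate,
    monomer_diffusivity,
    monomer_production_rate,
    porosity,
)
from polyerode.units import GAS_CONSTANT


class TestRates:
    def test_noncatalytic_rate_at_zero_monomer(self, plga):
        # pure non-catalytic limit: -k1 * Ce exactly
        assert ester_reaction_rate(17300.0, 0.0, plga) == pytest.approx(-34.6)
        assert ester_reaction_rate(123.0, 0.0, plga) == pytest.approx(-plga.k1 * 123.0)

    def test_zero_substrate_gives_zero_rate(self, plga):
        assert ester_reaction_rate(0.0, 500.0, plga) == 0.0
        assert monomer_production_rate(0.0, 500.0, plga) == 0.0

    def test_autocatalytic_contribution(self):
        p = KineticParameters(k1=0.002, k2=0.002, d0=1e-12, ce0=17300.0)
        # k1*Ce + k2*Ce*sqrt(Cm) = 34.6 + 0.002*17300*10
        assert monomer_production_rate(17300.0, 100.0, p) == pytest.approx(380.6)

    @given(
        ce=st.floats(0.0, 2e4),
        cm=st.floats(0.0, 2e4),
    )
    def test_reaction_conserves_molar_substance(self, ce, cm):
        p = KineticParameters(k1=0.002, k2=1.2e-7, d0=6.5e-12, ce0=17300.0)
        assert ester_reaction_rate(ce, cm, p) + monomer_production_rate(ce, cm, p) == 0.0
        assert ester_reaction_rate(ce, cm, p) <= 0.0

    @given(ce=st.floats(1.0, 2e4), cm=st.floats(0.0, 1e4), dcm=st.floats(0.0, 1e4))
    def test_autocatalysis_monotone_in_monomer(self, ce, cm, dcm):
        p = KineticParameters(k1=0.002, k2=1.2e-7, d0=6.5e-12, ce0=17300.0)
        assert ester_reaction_rate(ce, cm + dcm, p) <= ester_reaction_rate(ce, cm, p)

    def test_negative_concentration_rejected(self, plga):
        with pytest.raises(ValueError):
            ester_reaction_rate(-1.0, 0.0, plga)
        with pytest.raises(ValueError):
            monomer_production_rate(10.0, -1e-9, plga)

    def test_vectorised_evaluation(self, plga):
        ce = np.array([17300.0, 0.0, 100.0])
        out = ester_reaction_rate(ce, np.zeros(3), plga)
        assert out.shape == (3,)
        assert out[1] == 0.0


class TestPorosityDiffusivity:
    def test_porosity_endpoints(self):
        assert porosity(17300.0, 0.0, 17300.0) == 0.0
        assert porosity(0.0, 0.0, 17300.0) == 1.0
        assert porosity(0.5 * 17300, 0.2 * 17300, 17300.0) == pytest.approx(0.3)

    def test_porosity_clamped(self):
        assert porosity(17300.0, 5000.0, 17300.0) == 0.0  # transient overshoot

    def test_porosity_requires_positive_reference(self):
        with pytest.raises(ValueError):
            porosity(1.0, 1.0, 0.0)

    def test_diffusivity_band(self, plla):
        assert monomer_diffusivity(plla.ce0, 0.0, plla) == pytest.approx(plla.d0)
        assert monomer_diffusivity(0.0, 0.0, plla) == pytest.approx(5.5 * plla.d0)
        d = monomer_diffusivity(0.6 * plla.ce0, 0.1 * plla.ce0, plla)
        assert d == pytest.approx(6.5e-12 * (1 + 4.5 * 0.3))  # 1.5275e-11

    @given(
        frac_e=st.floats(0.0, 1.0),
        frac_m=st.floats(0.0, 1.0),
    )
    def test_diffusivity_always_within_physical_band(self, frac_e, frac_m, plla):
        d = monomer_diffusivity(frac_e * plla.ce0, frac_m * plla.ce0, plla)
        assert plla.d0 <= d <= plla.d0 * (1 + plla.alpha) + 1e-25


class TestArrhenius:
    def test_zero_activation_energy_is_temperature_independent(self):
        law = ArrheniusLaw(ea=0.0, a=3.14)
        for t in (273.15, 310.15, 350.0):
            assert arrhenius_evaluate(law, t) == pytest.approx(3.14)

    def test_preexponential_closed_form(self):
        law = arrhenius_preexponential(6.5e-12, 323.15, 50000.0)
        assert law.a == pytest.approx(6.5e-12 * np.exp(50000.0 / (GAS_CONSTANT * 323.15)))

    def test_transfer_between_temperatures_closed_form(self):
        # k(T_ref) = 2e-3/day at 50 C with Ea = 80 kJ/mol, evaluated at 37 C
        law = arrhenius_preexponential(2e-3, 323.15, 80000.0)
        expect = 2e-3 * np.exp(-(80000.0 / GAS_CONSTANT) * (1 / 310.15 - 1 / 323.15))
        assert arrhenius_evaluate(law, 310.15) == pytest.approx(expect, rel=1e-12)

    @given(
        value=st.floats(1e-15, 1e3),
        t_ref=st.floats(250.0, 400.0),
        ea=st.floats(0.0, 2e5),
    )
    def test_roundtrip_identity_at_reference(self, value, t_ref, ea):
        law = arrhenius_preexponential(value, t_ref, ea)
        assert arrhenius_evaluate(law, t_ref) == pytest.approx(value, rel=1e-12)

    def test_monotone_increasing_in_temperature(self):
        law = arrhenius_preexponential(1e-3, 323.15, 80000.0)
        temps = np.linspace(280.0, 360.0, 10)
        vals = [arrhenius_evaluate(law, t) for t in temps]
        assert np.all(np.diff(vals) > 0)

    def test_invalid_inputs_rejected(self):
        law = ArrheniusLaw(ea=1e4, a=1.0)
        with pytest.raises(ValueError):
            arrhenius_evaluate(law, -10.0)
        with pytest.raises(ValueError):
            arrhenius_preexponential(-1.0, 300.0, 1e4)
        with pytest.raises(ValueError):
            ArrheniusLaw(ea=-1.0, a=1.0)

    def test_transfer_requires_all_activation_energies(self, plla):
        with pytest.raises(KeyError):
            arrhenius_transfer(plla, {"k1": 8e4, "k2": 8e4}, 310.15)


class TestParameterValidation:
    def test_defaults(self):
        p = KineticParameters(k1=1e-3, k2=1e-7, d0=1e-12, ce0=1e4)
        assert p.beta == 0.5 and p.alpha == 4.5

    @pytest.mark.parametrize(
        "bad",
        [
            {"k1": 0.0},
            {"ce0": -1.0},
            {"beta": 0.0},
            {"beta": 1.5},
            {"alpha": -0.1},
            {"temperature": 0.0},
            {"k2": -1e-9},
            {"d0": -1e-15},
        ],
    )
    def test_invalid_parameters_rejected(self, bad):
        base = dict(k1=1e-3, k2=1e-7, d0=1e-12, ce0=1e4)
        base.update(bad)
        with pytest.raises(ValueError):
            KineticParameters(**base)

    def test_analytic_limits_allowed(self):
        KineticParameters(k1=1e-3, k2=0.0, d0=0.0, ce0=1e4)
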