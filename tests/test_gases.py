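"""Henry partitioning, total gas pressure, hydrostatic pressure, saturation."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from merolake import constants as C
from merolake.gases import (
    HeadspaceFlask,
    concentration_from_partial_pressure,
    headspace_from_dissolved,
    henry_constant,
    hydrostatic_pressure,
    partition_flask,
    saturation_ratio,
    total_gas_pressure,
)
from merolake.profile import GasRecord


def oracle_equilibrium_pressure(n_total, gas, flask):
    """Independent two-phase balance: root-find P with the ideal-gas headspace
    and Henry liquid terms summed explicitly."""
    rt = C.R_L_ATM * (flask.temp_C + C.T0_K)
    kh = henry_constant(gas, flask.temp_C)

    def imbalance(p):
        return p * flask.headspace_volume_L / rt + kh * p * flask.water_volume_L - n_total

    upper = n_total / (flask.headspace_volume_L / rt) + 1.0
    return brentq(imbalance, 0.0, upper, xtol=1e-18, rtol=1e-15)


class TestHenry:
    def test_reference_solubilities_at_25C(self):
        assert henry_constant("CO2", 25.0) == pytest.approx(0.034, rel=0.03)
        assert henry_constant("CH4", 25.0) == pytest.approx(0.0014, rel=0.03)

    def test_solubility_ordering(self):
        kh = {g: henry_constant(g, 25.0) for g in C.GAS_SPECIES}
        assert kh["CO2"] > kh["CH4"] > kh["He"]

    @pytest.mark.parametrize("gas", C.GAS_SPECIES)
    def test_cold_water_dissolves_more(self, gas):
        assert henry_constant(gas, 10.0) > henry_constant(gas, 25.0)

    def test_unknown_gas_and_range(self):
        with pytest.raises(KeyError):
            henry_constant("Xe", 25.0)
        with pytest.raises(ValueError):
            henry_constant("CO2", 45.0)


class TestPartition:
    def test_pure_co2_flask_against_oracle(self):
        # field protocol: 250 mL vial, three-fourths water, pure CO2 headspace
        flask = HeadspaceFlask(0.250, 0.1875, 20.0, 1.0, {"CO2": 1.0})
        part = partition_flask(flask)["CO2"]
        p = oracle_equilibrium_pressure(part.n_total_mol, "CO2", flask)
        assert p == pytest.approx(1.0, rel=1e-6)
        rt = C.R_L_ATM * (20.0 + C.T0_K)
        assert part.n_headspace_mol == pytest.approx(p * flask.headspace_volume_L / rt, rel=1e-6)

    def test_empty_headspace_gives_zero(self):
        flask = HeadspaceFlask(mole_fractions={"CO2": 0.0, "CH4": 0.0})
        for part in partition_flask(flask).values():
            assert part.n_total_mol == 0.0
            assert part.partial_pressure_insitu_atm == 0.0

    def test_insoluble_gas_limit(self):
        # He is the least soluble gas: its liquid share is a few percent,
        # far below the CO2 share in the same flask geometry
        flask = HeadspaceFlask(mole_fractions={"He": 0.5, "CO2": 0.5})
        parts = partition_flask(flask)
        he_share = parts["He"].n_liquid_mol / parts["He"].n_total_mol
        co2_share = parts["CO2"].n_liquid_mol / parts["CO2"].n_total_mol
        assert he_share < 0.05 < co2_share

    @settings(deadline=None, max_examples=60)
    @given(
        water_frac=st.floats(0.1, 0.9),
        temp=st.floats(5.0, 35.0),
        pressure=st.floats(0.1, 3.0),
        y_co2=st.floats(0.0, 0.5),
        y_ch4=st.floats(0.0, 0.5),
    )
    def test_mole_conservation_property(self, water_frac, temp, pressure, y_co2, y_ch4):
        flask = HeadspaceFlask(0.25, 0.25 * water_frac, temp, pressure,
                               {"CO2": y_co2, "CH4": y_ch4})
        for gas, part in partition_flask(flask).items():
            assert part.n_liquid_mol + part.n_headspace_mol == part.n_total_mol
            if part.n_total_mol > 0:
                p = oracle_equilibrium_pressure(part.n_total_mol, gas, flask)
                y = flask.mole_fractions[gas]
                assert p == pytest.approx(y * pressure, rel=1e-9)

    @settings(deadline=None, max_examples=40)
    @given(
        c_co2=st.floats(1e-8, 0.05),
        c_ch4=st.floats(1e-8, 0.01),
        temp=st.floats(5.0, 35.0),
    )
    def test_dissolved_headspace_round_trip(self, c_co2, c_ch4, temp):
        base = HeadspaceFlask(0.25, 0.1875, temp)
        flask = headspace_from_dissolved({"CO2": c_co2, "CH4": c_ch4}, base)
        parts = partition_flask(flask)
        assert parts["CO2"].concentration_mol_L == pytest.approx(c_co2, rel=1e-9)
        assert parts["CH4"].concentration_mol_L == pytest.approx(c_ch4, rel=1e-9)

    def test_zero_headspace_rejected(self):
        with pytest.raises(ValueError):
            HeadspaceFlask(0.25, 0.25, 20.0)


class TestConcentration:
    def test_zero_pressure(self):
        assert concentration_from_partial_pressure(0.0, "CO2", 10.0) == (0.0, 0.0)

    def test_bottom_methane_load(self):
        # 0.64 atm CH4 at 10.8 C in ~1002 kg/m^3 water
        _, g_kg = concentration_from_partial_pressure(0.64, "CH4", 10.8, 1002.0)
        assert g_kg == pytest.approx(0.019, rel=0.05)

    def test_linearity(self):
        one = concentration_from_partial_pressure(0.3, "CH4", 15.0)
        two = concentration_from_partial_pressure(0.6, "CH4", 15.0)
        assert two[0] == pytest.approx(2 * one[0])
        assert two[1] == pytest.approx(2 * one[1])


class TestTotalGasPressure:
    def test_bottom_total(self, averno_gas):
        assert total_gas_pressure(averno_gas[-1]) == pytest.approx(1.33, rel=0.01)

    def test_atmospheric_gas_cap_in_epilimnion(self, averno_gas):
        top = max(
            g.partial_pressure("N2") + g.partial_pressure("O2") + g.partial_pressure("Ar")
            for g in averno_gas if g.depth_m <= 12
        )
        assert top == pytest.approx(0.90, rel=0.015)

    def test_row_sums_match_reported(self, averno_gas):
        # The printed 18 m and 20 m totals are internally inconsistent with
        # their own row entries (sums 0.579 and 0.612) and are excluded.
        for g in averno_gas:
            if math.isnan(g.pTOT_atm) or g.depth_m in (18.0, 20.0):
                continue
            assert total_gas_pressure(g) == pytest.approx(g.pTOT_atm, rel=0.015)

    def test_all_missing_is_zero(self):
        assert total_gas_pressure(GasRecord(depth_m=0.0)) == 0.0


class TestHydrostatic:
    def test_surface(self):
        assert hydrostatic_pressure(0.0, 1000.0) == pytest.approx(1.0)

    def test_bottom_constant_density(self):
        expected = 1.0 + 1000.0 * 9.80665 * 34.0 / 101325.0
        assert hydrostatic_pressure(34.0, 1000.0) == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(4.29, abs=0.01)

    def test_affine_in_depth(self):
        p10 = hydrostatic_pressure(10.0, 1000.0)
        p20 = hydrostatic_pressure(20.0, 1000.0)
        p30 = hydrostatic_pressure(30.0, 1000.0)
        assert p20 - p10 == pytest.approx(p30 - p20, rel=1e-12)

    def test_profile_density_integration(self):
        zs = [0.0, 10.0, 34.0]
        rhos = [998.0, 1000.0, 1002.0]
        p = hydrostatic_pressure(34.0, (zs, rhos))
        assert 4.2 < p < 4.4
        with pytest.raises(ValueError):
            hydrostatic_pressure(50.0, (zs, rhos))


class TestSaturation:
    def test_baseline_never_oversaturated(self, averno):
        points = saturation_ratio(averno)
        assert all(s.ratio < 1.0 for s in points)
        assert max(s.ratio for s in points) == pytest.approx(0.91, abs=0.02)

    def test_zero_gas_profile(self, averno):
        empty = [(c, GasRecord(depth_m=g.depth_m)) for c, g in averno.records]
        from merolake.profile import LakeProfile
        prof = LakeProfile(empty, dict(averno.metadata))
        assert all(s.ratio == 0.0 for s in saturation_ratio(prof))
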