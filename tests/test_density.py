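"""Density model (pure water + salinity + dissolved gas) and stability."""

import math
from dataclasses import replace

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from merolake.density import (
    ScenarioSpec,
    apply_scenario,
    assess_stability,
    density_profile,
    density_ts,
    density_with_gas,
    lambda_coefficients,
    pure_water_density,
    solution_density_pmv,
    specific_conductance_25,
    tep_instability_threshold,
)
from merolake.gases import total_gas_pressure
from merolake.profile import ChemistryRecord, GasRecord, LakeProfile
from merolake.synthetic import SyntheticParams, generate_profile


def record(temp=25.0, **solutes):
    return ChemistryRecord(depth_m=0, temp_C=temp, pH=7.0, alk_mgL=math.nan,
                           **solutes)


class TestPureWater:
    def test_density_maximum_near_4C(self):
        assert pure_water_density(3.983) == pytest.approx(999.975, abs=0.001)
        assert pure_water_density(3.983) > pure_water_density(3.5)
        assert pure_water_density(3.983) > pure_water_density(4.5)

    def test_reference_point_25C(self):
        assert pure_water_density(25.0) == pytest.approx(997.047, abs=0.001)

    def test_monotone_above_maximum(self):
        assert pure_water_density(10.0) > pure_water_density(26.6)

    def test_range_guard(self):
        with pytest.raises(ValueError):
            pure_water_density(-2.0)


class TestConductance:
    def test_pure_water_is_zero(self):
        assert specific_conductance_25(record()) == 0.0

    def test_kcl_calibration_point(self):
        kcl = record(K_mgL=0.01 * 39.098 * 1000, Cl_mgL=0.01 * 35.453 * 1000)
        assert specific_conductance_25(kcl) == pytest.approx(1.413, rel=0.03)

    def test_surface_lake_water_plausible(self, averno_chemistry):
        k25 = specific_conductance_25(averno_chemistry[0])
        assert 2.0 < k25 < 4.0

    def test_strictly_increasing_in_concentration(self, averno_chemistry):
        base = averno_chemistry[0]
        richer = replace(base, Na_mgL=base.Na_mgL * 1.2,
                         below_detection=dict(base.below_detection))
        assert specific_conductance_25(richer) > specific_conductance_25(base)


class TestMolalVolumeDensity:
    def test_zero_solutes_reduce_to_pure_water(self):
        for t in (5.0, 15.0, 25.0):
            assert solution_density_pmv(record(t), t) == pure_water_density(t)

    def test_surface_water_increment_band(self, averno_chemistry):
        incr = (solution_density_pmv(averno_chemistry[0], 25.0)
                - pure_water_density(25.0))
        assert 1.0 < incr < 1.6

    def test_single_salt_additivity(self):
        nacl = record(Na_mgL=230.0, Cl_mgL=355.0)
        kcl = record(K_mgL=391.0, Cl_mgL=355.0)
        both = record(Na_mgL=230.0, K_mgL=391.0, Cl_mgL=710.0)
        rho_w = pure_water_density(25.0)
        incr = lambda r: solution_density_pmv(r, 25.0) - rho_w
        assert incr(both) == pytest.approx(incr(nacl) + incr(kcl), rel=1e-6)


class TestLambdaChain:
    def test_equations_reproduce_molal_volume_density(self, averno_chemistry):
        # the conductivity form is anchored at 25 C and in-situ T by construction
        for c in averno_chemistry:
            k25 = specific_conductance_25(c)
            lam0, lam1 = lambda_coefficients(c, c.temp_C)
            assert lam0 > 0
            assert density_ts(c.temp_C, k25, lam0, lam1) == pytest.approx(
                solution_density_pmv(c, c.temp_C), rel=1e-9
            )
            assert density_ts(25.0, k25, lam0, lam1) == pytest.approx(
                solution_density_pmv(c, 25.0), rel=1e-9
            )

    def test_lambda1_removable_singularity_at_25C(self, averno_chemistry):
        c = averno_chemistry[0]
        _, lam1_at_25 = lambda_coefficients(c, 25.0)
        _, lam1_near = lambda_coefficients(c, 25.001)
        assert lam1_at_25 == pytest.approx(lam1_near, rel=0.05)

    def test_no_salinity_term_collapses_to_pure_water(self):
        assert density_ts(12.0, 0.0, 0.5, 0.1) == pure_water_density(12.0)

    def test_zero_excess_gives_zero_lambda0(self):
        assert density_ts(25.0, 3.0, 0.4, 99.0) == pytest.approx(
            pure_water_density(25.0) + 3.0 * 0.4
        )


class TestGasContraction:
    @pytest.mark.parametrize("c_co2,c_ch4,expected", [
        (0.0, 0.0, 1000.0),
        (1.0, 0.0, 1000.284),
        (0.0, 1.0, 998.75),
    ])
    def test_direct_evaluation(self, c_co2, c_ch4, expected):
        assert density_with_gas(1000.0, c_co2, c_ch4) == pytest.approx(expected)

    @settings(deadline=None, max_examples=40)
    @given(rho=st.floats(995.0, 1005.0), c=st.floats(0.0, 1.0),
           dc=st.floats(0.01, 0.5))
    def test_signs_of_contraction(self, rho, c, dc):
        assert density_with_gas(rho, c + dc, 0.0) > density_with_gas(rho, c, 0.0)
        assert density_with_gas(rho, 0.0, c + dc) < density_with_gas(rho, 0.0, c)


class TestDensityProfile:
    def test_baseline_is_stably_stratified(self, averno):
        dens = density_profile(averno)
        assert assess_stability(dens).stable

    def test_density_band(self, averno):
        for d in density_profile(averno):
            assert 996.0 < d.rho < 1005.0

    def test_zeroed_solutes_give_pure_water(self, averno):
        stripped = [
            (ChemistryRecord(depth_m=c.depth_m, temp_C=c.temp_C, pH=c.pH,
                             alk_mgL=math.nan),
             GasRecord(depth_m=g.depth_m))
            for c, g in averno.records
        ]
        prof = LakeProfile(stripped, dict(averno.metadata))
        for d in density_profile(prof):
            assert d.rho == pure_water_density(d.temp_C)


class TestScenarios:
    def test_identity_scenario(self, averno):
        out = apply_scenario(averno, ScenarioSpec("noop"))
        assert out.records == averno.records

    def test_baseline_never_mutated(self, averno):
        before = [g.PCH4_atm for g in averno.gas]
        apply_scenario(averno, ScenarioSpec("x", tep_override_C=10.0,
                                            multipliers={"CH4": 20.0}))
        assert [g.PCH4_atm for g in averno.gas] == before

    def test_methane_surge_total_pressure(self, averno):
        pert = apply_scenario(averno, ScenarioSpec("ch4x20", multipliers={"CH4": 20.0}))
        assert max(total_gas_pressure(g) for g in pert.gas) == pytest.approx(13.0, rel=0.10)

    def test_methane_surge_density_drop(self, averno):
        base = density_profile(averno)
        pert = density_profile(
            apply_scenario(averno, ScenarioSpec("ch4x20", multipliers={"CH4": 20.0}))
        )
        drop = max(a.rho - b.rho for a, b in zip(base, pert))
        assert drop == pytest.approx(0.5, rel=0.25)

    def test_increasing_methane_monotonically_destabilizes(self, averno):
        bottoms = []
        for mult in (1.0, 5.0, 10.0, 20.0):
            dens = density_profile(
                apply_scenario(averno, ScenarioSpec("m", multipliers={"CH4": mult}))
            )
            bottoms.append(dens[-1].rho)
        assert all(b < a for a, b in zip(bottoms, bottoms[1:]))


class TestStability:
    def test_strictly_increasing_is_stable(self, averno):
        dens = density_profile(averno)
        assert assess_stability(dens).stable

    def test_too_few_depths_rejected(self, averno):
        with pytest.raises(ValueError):
            assess_stability(density_profile(averno)[:1])

    def test_cooled_epilimnion_inverts_column(self, averno):
        dens = density_profile(
            apply_scenario(averno, ScenarioSpec("tep10", tep_override_C=10.0))
        )
        report = assess_stability(dens)
        assert not report.stable
        # the inversion sits at the base of the cooled epilimnion
        assert any(upper <= 8.0 < lower for upper, lower in report.inversions)


class TestTepThreshold:
    def test_fixture_threshold_near_10C(self, averno):
        tep = tep_instability_threshold(averno, 5.0, 15.0, 1.0)
        assert tep is not None
        assert abs(tep - 10.0) <= 1.0

    def test_boundary_returns_scan_top(self, averno):
        assert tep_instability_threshold(averno, 4.0, 6.0, 1.0) == 6.0

    def test_homogeneous_column_has_no_threshold(self):
        prof = generate_profile(SyntheticParams(
            t_epilimnion_C=11.0, t_hypolimnion_C=11.0,
            tds_surface_mgL=1800.0, tds_bottom_mgL=1800.0,
            ph_surface=7.5, ph_bottom=7.5,
            gas_bottom_atm={"N2": 0.6}, gas_efold_m={"N2": 1e9},
        ))
        assert tep_instability_threshold(prof, 12.0, 15.0, 1.0) is None

    def test_parameter_recovery_within_one_step(self, averno):
        # fine scan as oracle for the instability onset temperature
        fine = tep_instability_threshold(averno, 5.0, 15.0, 0.05)
        coarse = tep_instability_threshold(averno, 5.0, 15.0, 0.5)
        assert abs(coarse - fine) <= 0.5

    def test_invalid_scan(self, averno):
        with pytest.raises(ValueError):
            tep_instability_threshold(averno, 15.0, 5.0, 1.0)
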