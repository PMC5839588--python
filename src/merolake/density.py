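"""Water-density model and stratification-stability analysis.

The density of a lake water parcel is decomposed as

    rho = rho(T, S) * (1 + beta_CO2 * C_CO2 + beta_CH4 * C_CH4)

where the salinity/temperature part follows the conductivity
parameterization

    rho(T, S) = rhoW(T) + K25 * [lambda0 + lambda1 * (T - 25 C)]

rhoW(T) is Tanaka's air-free pure-water density, K25 the specific
conductance at 25 C derived from the ionic composition, and lambda0/lambda1
are fixed by requiring the expression to reproduce the partial-molal-volume
solution density at 25 C and at the in-situ temperature.  C_CO2 and C_CH4
are dissolved-gas mass concentrations in g/kg; their contraction
coefficients have opposite sign, so CO2 stabilizes and CH4 destabilizes a
stratified column.

Scenario tools perturb a measured profile (epilimnion cooling, per-gas
partial-pressure multipliers) and assess whether the resulting density
profile still increases monotonically with depth — the criterion separating
a stable meromictic stratification from one primed for rollover.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from . import constants as C
from .carbonate import davies_gamma
from .gases import concentration_from_partial_pressure, total_gas_pressure
from .profile import GAS_PRESSURE_FIELDS, ChemistryRecord, LakeProfile

# Density differences below this (kg/m^3) are treated as neutral when
# classifying inversions.  The tabulated survey rounds T to 0.1 C and solute
# concentrations to 2-3 digits, which propagates to ~0.03 kg/m^3 of spurious
# wiggle between adjacent layers; 0.05 kg/m^3 suppresses that noise while
# real inversions (epilimnion cooling scenarios) exceed it by an order of
# magnitude.
DEFAULT_STABILITY_TOL = 0.05


def pure_water_density(temp_C: float) -> float:
    """Density of air-free pure water, kg/m^3 (Tanaka et al. 2001), 0-40 C."""
    if not (0.0 <= temp_C <= 40.0):
        raise ValueError(f"temperature {temp_C} C outside 0-40 C")
    a = C.TANAKA
    t = temp_C
    return a["a5"] * (
        1.0 - (t + a["a1"]) ** 2 * (t + a["a2"]) / (a["a3"] * (t + a["a4"]))
    )


def specific_conductance_25(record: ChemistryRecord) -> float:
    """Specific conductance at 25 C, mS/cm, from the ionic composition.

    Sum of limiting equivalent conductances damped for ionic-strength
    interactions with the PHREEQC-style attenuation lambda_i = lambda0_i *
    gamma_i^alpha (alpha = 0.6/sqrt(|z|) for I < 0.36 |z|, else sqrt(I)/|z|),
    gamma from the Davies equation.  Reproduces the 0.01 mol/L KCl
    calibration point (1.413 mS/cm) to ~1%.
    """
    molarities = record.ion_molarities(include_carbonate=True)
    ionic = 0.5 * sum(c * C.ION_CHARGE[k] ** 2 for k, c in molarities.items())
    total_mS_cm = 0.0
    for ion, mol_L in molarities.items():
        z = abs(C.ION_CHARGE[ion])
        gamma = davies_gamma(z, ionic)
        alpha = 0.6 / math.sqrt(z) if ionic < 0.36 * z else math.sqrt(ionic) / z
        eq_L = mol_L * z
        # (S cm^2/eq) * (eq/L) = S cm^2 / (1000 cm^3) = mS/cm
        total_mS_cm += C.EQUIV_CONDUCTANCE_25[ion] * gamma**alpha * eq_L
    return total_mS_cm


def solution_density_pmv(record: ChemistryRecord, temp_C: float) -> float:
    """Solution density, kg/m^3, from conventional partial molal volumes.

    rho = rhoW(T) + sum_i c_i (M_i - rhoW V_i(T)) / 1000 with c in mol/L,
    M in g/mol and V in cm^3/mol (25 C values plus a linear T slope).
    Solute increments are additive by construction.
    """
    rho_w = pure_water_density(temp_C)
    incr = 0.0
    for ion, mol_L in record.ion_molarities(include_carbonate=True).items():
        v_molal = C.MOLAL_VOLUME_25[ion] + C.MOLAL_VOLUME_DVDT[ion] * (temp_C - 25.0)
        incr += mol_L * (C.ION_MASS_G_MOL[ion] - rho_w / 1000.0 * v_molal)
    return rho_w + incr


def lambda_coefficients(
    record: ChemistryRecord, temp_C: float
) -> tuple[float, float]:
    """(lambda0, lambda1) tying the conductivity form to the molal-volume density.

    lambda0 = [rho(25 C, K25) - rhoW(25 C)] / K25 and lambda1 the matching
    linear-in-T slope, so that rho(T,S) reproduces the partial-molal-volume
    density exactly at 25 C and at ``temp_C``.  At the removable singularity
    T = 25 C, lambda1 is taken as the symmetric finite difference over
    +/- 0.5 C.
    """
    k25 = specific_conductance_25(record)
    if k25 <= 0:
        raise ValueError("K25 must be positive")

    def excess(t: float) -> float:
        return (solution_density_pmv(record, t) - pure_water_density(t)) / k25

    lam0 = excess(25.0)
    if abs(temp_C - 25.0) < 1e-9:
        lam1 = (excess(25.5) - excess(24.5)) / 1.0
    else:
        lam1 = (excess(temp_C) - lam0) / (temp_C - 25.0)
    return lam0, lam1


def density_ts(
    temp_C: float, k25_mS_cm: float, lambda0: float, lambda1: float
) -> float:
    """rho(T, S) = rhoW(T) + K25 [lambda0 + lambda1 (T - 25 C)], kg/m^3."""
    return pure_water_density(temp_C) + k25_mS_cm * (
        lambda0 + lambda1 * (temp_C - 25.0)
    )


def density_with_gas(rho_ts: float, c_co2_g_kg: float, c_ch4_g_kg: float) -> float:
    """Apply the dissolved-gas contraction terms to the T/S density."""
    if c_co2_g_kg < 0 or c_ch4_g_kg < 0:
        raise ValueError("gas concentrations must be >= 0")
    return rho_ts * (1.0 + C.BETA_CO2 * c_co2_g_kg + C.BETA_CH4 * c_ch4_g_kg)


@dataclass
class DensityRecord:
    """Per-depth decomposition of the modelled water density."""

    depth_m: float
    temp_C: float
    rho_pure: float
    k25_mS_cm: float
    lambda0: float
    lambda1: float
    rho_ts: float
    c_co2_g_kg: float
    c_ch4_g_kg: float
    rho: float


def density_profile(profile: LakeProfile) -> list[DensityRecord]:
    """Evaluate the full density chain at every depth of an aligned profile."""
    out = []
    for chem, gas in profile.records:
        t = chem.temp_C
        k25 = specific_conductance_25(chem)
        if k25 > 0:
            lam0, lam1 = lambda_coefficients(chem, t)
        else:  # solute-free water: the salinity term vanishes
            lam0 = lam1 = 0.0
        rho_ts = density_ts(t, k25, lam0, lam1)
        _, c_co2 = concentration_from_partial_pressure(
            gas.partial_pressure("CO2"), "CO2", t, rho_ts
        )
        _, c_ch4 = concentration_from_partial_pressure(
            gas.partial_pressure("CH4"), "CH4", t, rho_ts
        )
        out.append(
            DensityRecord(
                chem.depth_m, t, pure_water_density(t), k25, lam0, lam1,
                rho_ts, c_co2, c_ch4, density_with_gas(rho_ts, c_co2, c_ch4),
            )
        )
    return out


@dataclass
class ScenarioSpec:
    """A perturbation of a measured profile.

    ``tep_override_C`` replaces the temperature of every layer at or above
    ``z_epi_m`` (the epilimnion, 0-8 m by default); ``multipliers`` scales
    the partial pressure of individual gases everywhere in the column.
    """

    label: str = "scenario"
    tep_override_C: float | None = None
    z_epi_m: float = 8.0
    multipliers: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.tep_override_C is not None and not (0.0 < self.tep_override_C < 40.0):
            raise ValueError("epilimnion override outside (0, 40) C")
        if any(m < 0 for m in self.multipliers.values()):
            raise ValueError("multipliers must be >= 0")


def apply_scenario(profile: LakeProfile, spec: ScenarioSpec) -> LakeProfile:
    """Return a perturbed copy of ``profile``; the input is never mutated."""
    result = profile.copy()
    inv_fields = {gas: fname for fname, gas in GAS_PRESSURE_FIELDS.items()}
    new_records = []
    for chem, gas in result.records:
        if spec.tep_override_C is not None and chem.depth_m <= spec.z_epi_m:
            chem = replace(chem, temp_C=spec.tep_override_C)
        updates = {}
        for species, mult in spec.multipliers.items():
            fname = inv_fields[species]
            v = getattr(gas, fname)
            if not math.isnan(v):
                updates[fname] = v * mult
        if updates:
            gas = replace(gas, **updates)
        new_records.append((chem, gas))
    return LakeProfile(new_records, result.metadata, result.unmatched_depths)


@dataclass
class StabilityReport:
    """Verdict on a density profile: stable iff no density inversion."""

    densities: list[DensityRecord]
    tolerance_kg_m3: float
    inversions: list[tuple[float, float]]  # (upper depth, lower depth) pairs

    @property
    def stable(self) -> bool:
        return not self.inversions


def assess_stability(
    densities: list[DensityRecord],
    tolerance_kg_m3: float = DEFAULT_STABILITY_TOL,
) -> StabilityReport:
    """Flag every adjacent pair where density drops with depth beyond tolerance."""
    if len(densities) < 2:
        raise ValueError("need at least 2 depths to assess stability")
    inversions = [
        (a.depth_m, b.depth_m)
        for a, b in zip(densities, densities[1:])
        if b.rho < a.rho - tolerance_kg_m3
    ]
    return StabilityReport(densities, tolerance_kg_m3, inversions)


def tep_instability_threshold(
    profile: LakeProfile,
    t_low_C: float,
    t_high_C: float,
    step_C: float = 1.0,
    z_epi_m: float = 8.0,
    deep_band_m: tuple[float, float] = (8.0, 26.0),
) -> float | None:
    """Highest epilimnion temperature that destabilizes the stratification.

    For each candidate override temperature (scanned from ``t_high_C`` down
    to ``t_low_C`` in ``step_C`` increments) the epilimnion (depths <=
    ``z_epi_m``) is cooled to that value and the column is declared unstable
    when the minimum epilimnetic density exceeds the maximum density over the
    layers strictly below the epilimnion and above the deep chemocline
    (``deep_band_m``, exclusive bounds).  Returns the highest qualifying
    temperature, or None if no scanned value destabilizes the column.
    """
    if t_low_C >= t_high_C:
        raise ValueError("need t_low < t_high")
    if step_C <= 0:
        raise ValueError("step must be positive")
    lo, hi = deep_band_m
    n = int(round((t_high_C - t_low_C) / step_C))
    candidates = [t_high_C - i * step_C for i in range(n + 1)]
    for t_ep in candidates:
        scenario = ScenarioSpec("tep-scan", tep_override_C=t_ep, z_epi_m=z_epi_m)
        dens = density_profile(apply_scenario(profile, scenario))
        epi = [d.rho for d in dens if d.depth_m <= z_epi_m]
        deep = [d.rho for d in dens if lo < d.depth_m < hi]
        if not epi or not deep:
            raise ValueError("empty epilimnion or comparison band")
        if min(epi) > max(deep):
            return t_ep
    return None
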