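"""Carbonate speciation, equilibrium PCO2 and carbon-isotope corrections.

Given titrated alkalinity, electrode pH and temperature, the carbonate system
is solved for CO2(aq), HCO3- and CO32-, and the CO2 partial pressure a water
parcel would exhibit at equilibrium with its alkalinity (PCO2calc) follows
from the Henry solubility of CO2.  Comparing PCO2calc with the measured
dissolved CO2 pressure quantifies how far a layer sits from carbonate
equilibrium — in productive lakes the measured values fall well below
equilibrium because photosynthesis and high-pH dissolution strip CO2.

Equilibrium constants are the freshwater parameterization of Plummer &
Busenberg (1982).  The default speciation composes the measured pH and the
equivalent alkalinity concentration directly with those constants, without
single-ion activity corrections: at the ionic strengths of dilute volcanic
lakes (I < 0.06 mol/L) the correction is comparable to the electrode and
titration uncertainty, and the equilibrium-PCO2 column of the packaged Averno
survey is reproduced on this convention.  Davies-equation corrections are
available via ``activity_model="davies"`` for sensitivity checks.

Isotopes: headspace delta13C of CO2 is corrected to the dissolved phase with
the linear gas-water enrichment factor eps1(T) = 0.0049 T - 1.31 (T in C),
and the delta13C of total dissolved inorganic carbon (TDIC) is the
species-abundance-weighted sum using equilibrium fractionation factors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from . import constants as C
from .profile import ChemistryRecord


def ionic_strength(record: ChemistryRecord) -> float:
    """I = 1/2 sum(c_i z_i^2) in mol/L over the charged major species.

    Alkalinity enters as HCO3- and reduced sulfur as HS-; trace elements are
    negligible at these concentrations and are ignored.
    """
    total = 0.0
    for ion, molarity in record.ion_molarities(include_carbonate=True).items():
        total += molarity * C.ION_CHARGE[ion] ** 2
    return 0.5 * total


def debye_huckel_A(temp_C: float) -> float:
    """Debye-Huckel limiting-law coefficient (kg/mol)^1/2, 0-40 C fit."""
    return 0.4918 + 6.614e-4 * temp_C + 1.9e-6 * temp_C**2


def davies_gamma(charge: int, I: float, temp_C: float = 25.0) -> float:
    """Single-ion activity coefficient from the Davies equation (I in mol/L)."""
    if I < 0:
        raise ValueError("ionic strength must be >= 0")
    if I == 0:
        return 1.0
    sqrt_i = math.sqrt(I)
    f = sqrt_i / (1.0 + sqrt_i) - 0.3 * I
    return 10.0 ** (-debye_huckel_A(temp_C) * charge**2 * f)


def _log10_poly(coeffs: tuple, t_K: float) -> float:
    a1, a2, a3, a4, a5 = coeffs
    return a1 + a2 * t_K + a3 / t_K + a4 * math.log10(t_K) + a5 / t_K**2


@dataclass(frozen=True)
class EquilibriumConstants:
    """Temperature-dependent carbonate equilibrium constants (freshwater)."""

    temp_C: float
    K1: float  # carbonic acid, first dissociation
    K2: float  # second dissociation
    KH_CO2: float  # CO2 solubility, mol/(L atm)
    Kw: float  # water ion product

    @property
    def pK1(self) -> float:
        return -math.log10(self.K1)

    @property
    def pK2(self) -> float:
        return -math.log10(self.K2)


def equilibrium_constants(temp_C: float) -> EquilibriumConstants:
    if not (0.0 <= temp_C <= 40.0):
        raise ValueError(f"temperature {temp_C} C outside 0-40 C")
    t_K = temp_C + C.T0_K
    k1 = 10.0 ** _log10_poly(C.PB82_K1, t_K)
    k2 = 10.0 ** _log10_poly(C.PB82_K2, t_K)
    kh = 10.0 ** _log10_poly(C.PB82_KH_CO2, t_K)
    a1, a3, a4 = C.MILLERO_KW
    kw = math.exp(a1 + a3 / t_K + a4 * math.log(t_K))
    return EquilibriumConstants(temp_C, k1, k2, kh, kw)


@dataclass
class CarbonateSystem:
    """Solved carbonate state for one water parcel (concentrations in mol/L)."""

    alkalinity_eq_L: float
    pH: float
    temp_C: float
    ionic_strength_mol_L: float
    co2_mol_L: float
    hco3_mol_L: float
    co3_mol_L: float
    pco2calc_atm: float
    activity_model: str = "none"

    @property
    def tdic_mol_L(self) -> float:
        return self.co2_mol_L + self.hco3_mol_L + self.co3_mol_L

    def mole_fractions(self) -> tuple[float, float, float]:
        t = self.tdic_mol_L
        return self.co2_mol_L / t, self.hco3_mol_L / t, self.co3_mol_L / t


def speciate(
    alk_mgL: float,
    pH: float,
    temp_C: float,
    record: ChemistryRecord | None = None,
    activity_model: str = "none",
) -> CarbonateSystem:
    """Solve the carbonate system from alkalinity (mg/L as HCO3-), pH and T.

    Total alkalinity is treated as carbonate alkalinity after the small
    hydroxide/proton correction; contributions from HS-, NH3 and borate
    (< 3% at these compositions) are ignored.  pH is hydrogen-ion activity
    (NBS electrode scale).
    """
    if alk_mgL <= 0:
        raise ValueError("alkalinity must be positive")
    if not (4.0 < pH < 11.0):
        raise ValueError(f"pH {pH} outside supported range (4, 11)")
    if activity_model not in ("none", "davies"):
        raise ValueError(f"unknown activity model {activity_model!r}")

    ks = equilibrium_constants(temp_C)
    ionic = ionic_strength(record) if record is not None else 0.0
    if activity_model == "davies":
        g1 = davies_gamma(1, ionic, temp_C)
        g2 = davies_gamma(2, ionic, temp_C)
    else:
        g1 = g2 = 1.0

    a_h = 10.0 ** (-pH)
    total_alk = alk_mgL / C.ION_MASS_G_MOL["HCO3"] / 1000.0  # eq/L
    carb_alk = total_alk - ks.Kw / a_h / g1 + a_h / g1
    if carb_alk <= 0:
        raise ValueError("non-positive carbonate alkalinity after OH-/H+ correction")

    ratio = (ks.K2 / a_h) * (g1 / g2)  # [CO3]/[HCO3]
    hco3 = carb_alk / (1.0 + 2.0 * ratio)
    co3 = ratio * hco3
    co2 = a_h * g1 * hco3 / ks.K1
    return CarbonateSystem(
        total_alk, pH, temp_C, ionic, co2, hco3, co3, co2 / ks.KH_CO2,
        activity_model,
    )


def pco2_from_alkalinity(
    alk_mgL: float,
    pH: float,
    temp_C: float,
    record: ChemistryRecord | None = None,
    activity_model: str = "none",
) -> float:
    """Equilibrium CO2 partial pressure (atm) for the given water chemistry."""
    return speciate(alk_mgL, pH, temp_C, record, activity_model).pco2calc_atm


# ---------------------------------------------------------------------------
# Carbon isotopes
# ---------------------------------------------------------------------------


def epsilon1(temp_C: float) -> float:
    """Gas-water enrichment factor for CO2, per mil: eps1 = 0.0049 T - 1.31."""
    if not (0.0 <= temp_C <= 40.0):
        raise ValueError(f"temperature {temp_C} C outside validated 0-40 C range")
    return 0.0049 * temp_C - 1.31


def correct_delta13c_co2(delta_measured: float, temp_C: float) -> float:
    """delta13C of dissolved CO2 from the measured headspace value, per mil."""
    return delta_measured + epsilon1(temp_C)


def tdic_delta13c_equilibrium(
    system: CarbonateSystem,
    delta13c_co2: float,
    temp_C: float | None = None,
) -> float:
    """Species-abundance-weighted delta13C of TDIC, per mil V-PDB.

    Uses the additive per-mil approximation with equilibrium enrichment of
    HCO3- and CO32- over CO2(aq); adequate to ~0.1 per mil at these
    fractionations.
    """
    t_K = (temp_C if temp_C is not None else system.temp_C) + C.T0_K
    a, b = C.EPS_HCO3_CO2AQ
    eps_b = a / t_K + b
    eps_c = eps_b + C.EPS_CO3_OFFSET
    x_co2, x_hco3, x_co3 = system.mole_fractions()
    return (
        x_co2 * delta13c_co2
        + x_hco3 * (delta13c_co2 + eps_b)
        + x_co3 * (delta13c_co2 + eps_c)
    )
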