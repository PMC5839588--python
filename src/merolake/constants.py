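"""Frozen physical-chemistry constants used across the package.

All tables here come from standard public compilations (cited per table) and
are deliberately kept as plain Python literals so that every number is
reviewable in one place.  Functions that consume them accept override
arguments, so alternative parameterizations can be swapped in without editing
this module.
"""

from __future__ import annotations

# ---------------------------------------------------------------------------
# Universal constants
# ---------------------------------------------------------------------------

R_L_ATM = 0.082057366  # gas constant, L atm / (mol K)
G_M_S2 = 9.80665  # standard gravity, m/s^2
ATM_PA = 101325.0  # 1 atm in Pa
T0_K = 273.15

# ---------------------------------------------------------------------------
# Henry's-law solubilities (Sander 2015, Atmos. Chem. Phys. compilation).
# kh25: mol/(L atm) at 298.15 K; van't Hoff coefficient c in
#   KH(T) = kh25 * exp(c * (1/T - 1/298.15)), T in kelvin.
# ---------------------------------------------------------------------------

HENRY_KH25 = {
    "CO2": 3.34e-2,
    "CH4": 1.41e-3,
    "N2": 6.42e-4,
    "O2": 1.27e-3,
    "Ar": 1.40e-3,
    "H2": 7.80e-4,
    "He": 3.76e-4,
}

HENRY_VANT_HOFF_K = {
    "CO2": 2400.0,
    "CH4": 1750.0,
    "N2": 1300.0,
    "O2": 1500.0,
    "Ar": 1300.0,
    "H2": 500.0,
    "He": 230.0,
}

MOLAR_MASS_G_MOL = {
    "CO2": 44.009,
    "CH4": 16.043,
    "N2": 28.014,
    "O2": 31.998,
    "Ar": 39.948,
    "H2": 2.016,
    "He": 4.0026,
}

GAS_SPECIES = tuple(HENRY_KH25)

# ---------------------------------------------------------------------------
# Solute properties for the major dissolved ions.
# charge: signed ionic charge; mass in g/mol.
# Reduced sulfur (sigma S2-) is treated as HS-, its dominant form at the
# near-neutral pH of the deep water column.
# ---------------------------------------------------------------------------

ION_CHARGE = {
    "F": -1, "Cl": -1, "Br": -1, "NO3": -1, "SO4": -2,
    "Ca": 2, "Mg": 2, "Na": 1, "K": 1, "NH4": 1, "Li": 1,
    "HCO3": -1, "CO3": -2, "HS": -1,
}

ION_MASS_G_MOL = {
    "F": 18.998, "Cl": 35.453, "Br": 79.904, "NO3": 62.004, "SO4": 96.06,
    "Ca": 40.078, "Mg": 24.305, "Na": 22.990, "K": 39.098, "NH4": 18.039,
    "Li": 6.941, "HCO3": 61.016, "CO3": 60.008, "HS": 33.073,
}

# ---------------------------------------------------------------------------
# Limiting equivalent conductances at 25 C, S cm^2 / equivalent
# (CRC Handbook / Robinson & Stokes).  Used for the composition-derived
# specific conductance K25.
# ---------------------------------------------------------------------------

EQUIV_CONDUCTANCE_25 = {
    "F": 55.4, "Cl": 76.35, "Br": 78.1, "NO3": 71.44, "SO4": 80.0,
    "Ca": 59.5, "Mg": 53.06, "Na": 50.11, "K": 73.5, "NH4": 73.5,
    "Li": 38.66, "HCO3": 44.5, "CO3": 69.3, "HS": 65.0,
}

# ---------------------------------------------------------------------------
# Conventional single-ion partial molal volumes at 25 C, cm^3/mol
# (Millero 1971, Chem. Rev., conventional scale with V(H+) = 0) and an
# approximate linear temperature slope d(V)/dT in cm^3/(mol K), adequate for
# the 10-27 C range of temperate lakes.
# ---------------------------------------------------------------------------

MOLAL_VOLUME_25 = {
    "F": -1.16, "Cl": 17.83, "Br": 24.71, "NO3": 29.00, "SO4": 13.98,
    "Ca": -17.85, "Mg": -21.17, "Na": -1.21, "K": 9.02, "NH4": 17.86,
    "Li": -0.88, "HCO3": 24.29, "CO3": -3.90, "HS": 20.20,
}

MOLAL_VOLUME_DVDT = {
    "F": 0.09, "Cl": 0.09, "Br": 0.09, "NO3": 0.10, "SO4": 0.20,
    "Ca": 0.18, "Mg": 0.18, "Na": 0.11, "K": 0.09, "NH4": 0.09,
    "Li": 0.11, "HCO3": 0.12, "CO3": 0.25, "HS": 0.10,
}

# ---------------------------------------------------------------------------
# Density contraction coefficients for dissolved gases (kg solution / g gas),
# McGinnis et al. 2006 convention: rho = rho_TS * (1 + b_CO2*C_CO2 + b_CH4*C_CH4)
# with C in g/kg.  CO2 densifies, CH4 lightens.
# ---------------------------------------------------------------------------

BETA_CO2 = 2.84e-4
BETA_CH4 = -1.25e-3

# ---------------------------------------------------------------------------
# Tanaka et al. 2001 (Metrologia 38, 301) air-free pure-water density,
# valid 0-40 C:  rho = a5 * [1 - (t+a1)^2 (t+a2) / (a3 (t+a4))]
# ---------------------------------------------------------------------------

TANAKA = {
    "a1": -3.983035,
    "a2": 301.797,
    "a3": 522528.9,
    "a4": 69.34881,
    "a5": 999.974950,
}

# ---------------------------------------------------------------------------
# Carbonate system, freshwater scale (Plummer & Busenberg 1982, GCA 46).
# log10 K as f(T[K]):  A1 + A2*T + A3/T + A4*log10(T) + A5/T^2
# ---------------------------------------------------------------------------

PB82_K1 = (-356.3094, -0.06091964, 21834.37, 126.8339, -1684915.0)
PB82_K2 = (-107.8871, -0.03252849, 5151.79, 38.92561, -563713.9)
PB82_KH_CO2 = (108.3865, 0.01985076, -6919.53, -40.45154, 669365.0)
# Millero (1995) pure-water ion product, ln Kw = A1 + A3/T + A4*ln(T) form.
MILLERO_KW = (148.9802, -13847.26, -23.6521)

# ---------------------------------------------------------------------------
# Carbon isotope equilibrium enrichment factors (Mook et al. 1974; Zhang et
# al. 1995), expressed relative to dissolved CO2(aq) in per mil:
#   eps(HCO3- minus CO2aq) = 9866/T - 24.12
#   eps(CO32- minus CO2aq) = eps(HCO3) - 0.52  (near-constant offset 10-30 C)
# ---------------------------------------------------------------------------

EPS_HCO3_CO2AQ = (9866.0, -24.12)
EPS_CO3_OFFSET = -0.52
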