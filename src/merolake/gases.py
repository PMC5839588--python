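"""Henry's-law gas partitioning, total dissolved gas pressure and saturation.

Dissolved-gas samples are taken with pre-evacuated flasks partly filled with
lake water; at laboratory temperature the headspace equilibrates with the
liquid.  Given the headspace composition, the two-phase mole balance
(ideal-gas headspace + Henry's-law liquid) recovers the total moles of each
gas in the sample and hence its in-situ partial pressure and concentration.

The same Henry constants convert partial pressures to the mass concentrations
that enter the density model, and the hydrostatic-pressure routine supports
the oversaturation check (total dissolved gas pressure vs. local hydrostatic
pressure, the physical ceiling for a single-phase water column).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .profile import GasRecord, LakeProfile


def henry_constant(gas: str, temp_C: float) -> float:
    """Henry solubility KH in mol/(L atm) at ``temp_C`` (van't Hoff scaling).

    Valid for 0-40 C; KH decreases with temperature for every gas here.
    """
    if gas not in C.HENRY_KH25:
        raise KeyError(f"unknown gas {gas!r}")
    if not (0.0 <= temp_C <= 40.0):
        raise ValueError(f"temperature {temp_C} C outside 0-40 C")
    t_K = temp_C + C.T0_K
    return C.HENRY_KH25[gas] * math.exp(
        C.HENRY_VANT_HOFF_K[gas] * (1.0 / t_K - 1.0 / 298.15)
    )


@dataclass
class HeadspaceFlask:
    """Sampling-flask state after headspace/liquid equilibration.

    Defaults follow the field protocol: 250 mL pre-evacuated vial filled to
    about three fourths with water (187.5 mL).
    """

    flask_volume_L: float = 0.250
    water_volume_L: float = 0.1875
    temp_C: float = 20.0
    headspace_pressure_atm: float = 1.0
    mole_fractions: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 < self.water_volume_L < self.flask_volume_L):
            raise ValueError("need 0 < water volume < flask volume")
        if any(x < 0 for x in self.mole_fractions.values()):
            raise ValueError("mole fractions must be >= 0")
        if sum(self.mole_fractions.values()) > 1.0 + 1e-9:
            raise ValueError("mole fractions sum above 1")

    @property
    def headspace_volume_L(self) -> float:
        return self.flask_volume_L - self.water_volume_L


@dataclass
class GasPartition:
    """Per-gas result of the two-phase mole balance."""

    gas: str
    n_liquid_mol: float
    n_headspace_mol: float
    partial_pressure_insitu_atm: float
    concentration_mol_L: float
    concentration_g_kg: float

    @property
    def n_total_mol(self) -> float:
        return self.n_liquid_mol + self.n_headspace_mol


def partition_flask(
    flask: HeadspaceFlask,
    temp_insitu_C: float | None = None,
    water_density_kg_m3: float = 998.0,
) -> dict[str, GasPartition]:
    """Split each gas between headspace and liquid and reconstruct in-situ state.

    Headspace moles follow the ideal gas law at the equilibration temperature;
    liquid moles follow Henry's law at the same temperature.  The in-situ
    partial pressure re-expresses the total dissolved amount (referred to the
    water volume) through the Henry constant at the lake temperature.
    """
    if flask.headspace_volume_L <= 0:
        raise ValueError("zero headspace volume")
    t_eq = flask.temp_C
    t_situ = temp_insitu_C if temp_insitu_C is not None else t_eq
    rt = C.R_L_ATM * (t_eq + C.T0_K)
    out: dict[str, GasPartition] = {}
    for gas, y in flask.mole_fractions.items():
        p_i = y * flask.headspace_pressure_atm
        n_g = p_i * flask.headspace_volume_L / rt
        n_l = henry_constant(gas, t_eq) * p_i * flask.water_volume_L
        conc = (n_g + n_l) / flask.water_volume_L
        p_situ = conc / henry_constant(gas, t_situ)
        g_kg = conc * C.MOLAR_MASS_G_MOL[gas] * 1000.0 / water_density_kg_m3
        out[gas] = GasPartition(gas, n_l, n_g, p_situ, conc, g_kg)
    return out


def headspace_from_dissolved(
    concentrations_mol_L: dict[str, float],
    flask: HeadspaceFlask,
) -> HeadspaceFlask:
    """Equilibrate a known dissolved load into a flask (inverse of partitioning).

    Each gas's equilibrium headspace pressure solves the closed mole balance
    n_tot = P_i V_hs/(RT) + KH P_i V_w.  Returns a new flask carrying the
    resulting headspace pressure and mole fractions.
    """
    rt = C.R_L_ATM * (flask.temp_C + C.T0_K)
    pressures = {}
    for gas, conc in concentrations_mol_L.items():
        n_tot = conc * flask.water_volume_L
        denom = flask.headspace_volume_L / rt + henry_constant(gas, flask.temp_C) * flask.water_volume_L
        pressures[gas] = n_tot / denom
    p_hs = sum(pressures.values())
    fracs = {g: (p / p_hs if p_hs > 0 else 0.0) for g, p in pressures.items()}
    return HeadspaceFlask(
        flask.flask_volume_L, flask.water_volume_L, flask.temp_C,
        headspace_pressure_atm=p_hs, mole_fractions=fracs,
    )


def concentration_from_partial_pressure(
    pressure_atm: float,
    gas: str,
    temp_C: float,
    density_kg_m3: float = 998.0,
) -> tuple[float, float]:
    """(mol/L, g/kg) of dissolved gas in Henry equilibrium with ``pressure_atm``."""
    if pressure_atm < 0:
        raise ValueError("partial pressure must be >= 0")
    mol_L = henry_constant(gas, temp_C) * pressure_atm
    g_kg = mol_L * C.MOLAR_MASS_G_MOL[gas] * 1000.0 / density_kg_m3
    return mol_L, g_kg


def total_gas_pressure(record: GasRecord) -> float:
    """Sum of all present partial pressures, atm (missing species count 0)."""
    return sum(record.partial_pressure(g) for g in C.GAS_SPECIES)


def hydrostatic_pressure(
    depth_m: float,
    density,
    surface_pressure_atm: float = 1.0,
) -> float:
    """Absolute pressure at depth, atm: surface + g * integral of rho dz.

    ``density`` is either a constant in kg/m^3 or a pair of equal-length
    sequences ``(depths_m, rho_kg_m3)``; the integral uses the trapezoid rule
    on the piecewise-linear profile.  Depths beyond the profile are refused.
    """
    if depth_m < 0:
        raise ValueError("depth must be >= 0")
    if np.isscalar(density):
        integral = float(density) * depth_m  # kg/m^2
    else:
        zs, rhos = (np.asarray(a, dtype=float) for a in density)
        if zs[0] > 0 or depth_m > zs[-1]:
            raise ValueError("depth outside density profile; no extrapolation rule")
        grid = np.union1d(zs, [depth_m])
        grid = grid[grid <= depth_m]
        integral = float(np.trapezoid(np.interp(grid, zs, rhos), grid))
    return surface_pressure_atm + C.G_M_S2 * integral / C.ATM_PA


@dataclass
class SaturationPoint:
    depth_m: float
    ptot_atm: float
    hydrostatic_atm: float
    ratio: float
    oversaturated: bool


def saturation_ratio(
    profile: LakeProfile,
    densities=None,
) -> list[SaturationPoint]:
    """Total dissolved gas pressure vs hydrostatic pressure at each depth.

    A ratio >= 1 flags oversaturation (ebullition becomes possible).  With no
    density profile supplied, a constant 1000 kg/m^3 water column is assumed,
    which is accurate to ~0.3% for dilute lakes.
    """
    surface_p = profile.metadata.get("surface_pressure_atm", 1.0)
    if densities is None:
        densities = 1000.0
    out = []
    for _, gas in profile.records:
        ptot = total_gas_pressure(gas)
        ph = hydrostatic_pressure(gas.depth_m, densities, surface_p)
        out.append(SaturationPoint(gas.depth_m, ptot, ph, ptot / ph, ptot >= ph))
    return out
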