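"""Synthetic meromictic-lake profile generator.

Builds depth profiles with the structure the analysis assumes — a warm
epilimnion over a cold hypolimnion separated by a sigmoidal thermocline, one
or more haloclines, an oxic/anoxic boundary, and reduced-gas partial
pressures growing toward the bottom — so that every downstream stage
(conductance, carbonate, density, stability scans) can be exercised and
parameter-recovery tests are possible without external data.

The generator does not emulate measurement physics beyond optional Gaussian
noise: no sensor drift, no titration bias, no detection-limit censoring.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .profile import ChemistryRecord, GasRecord, LakeProfile, align_profiles

# Solute mass fractions of TDS for a Na-Cl-(HCO3) volcanic-lake water,
# matching the surface composition of the packaged Averno survey.
ION_TEMPLATE = {
    "alk_mgL": 0.2266, "F_mgL": 0.0060, "Cl_mgL": 0.3087, "Br_mgL": 0.00084,
    "NO3_mgL": 0.000135, "SO4_mgL": 0.1124, "Ca_mgL": 0.0101,
    "Mg_mgL": 0.0090, "Na_mgL": 0.2879, "K_mgL": 0.0365,
    "NH4_mgL": 0.0012, "Li_mgL": 0.0004,
}


@dataclass
class SyntheticParams:
    """Shape parameters of a generated meromictic profile."""

    max_depth_m: float = 34.0
    step_m: float = 2.0
    # thermal structure
    t_epilimnion_C: float = 26.5
    t_hypolimnion_C: float = 11.0
    thermocline_center_m: float = 5.0
    thermocline_width_m: float = 1.2
    # salinity structure: haloclines as (center_m, width_m, weight); weights
    # are normalized to split the surface-to-bottom TDS contrast
    tds_surface_mgL: float = 1780.0
    tds_bottom_mgL: float = 2800.0
    haloclines: tuple = ((26.0, 3.0, 0.75), (33.0, 1.0, 0.25))
    # pH follows the thermocline shape between these values
    ph_surface: float = 9.25
    ph_bottom: float = 6.8
    # gases: bottom partial pressure (atm) and e-folding depth (m)
    gas_bottom_atm: dict = field(default_factory=lambda: {
        "CO2": 0.093, "CH4": 0.64, "H2": 0.013, "He": 0.0001, "N2": 0.59,
    })
    gas_efold_m: dict = field(default_factory=lambda: {
        "CO2": 9.0, "CH4": 5.5, "H2": 6.0, "He": 10.0, "N2": 1e9,
    })
    oxic_boundary_m: float = 13.0
    o2_surface_atm: float = 0.15
    # measurement noise (1-sigma): absolute on T and pH, relative elsewhere
    noise_temp_C: float = 0.0
    noise_ph: float = 0.0
    noise_rel: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_depth_m <= 0 or self.step_m <= 0:
            raise ValueError("depth grid must be positive")
        if self.thermocline_width_m <= 0 or any(w <= 0 for _, w, _ in self.haloclines):
            raise ValueError("widths must be positive")
        if min(self.noise_temp_C, self.noise_ph, self.noise_rel) < 0:
            raise ValueError("noise levels must be >= 0")


def _pinned_sigmoid(z: np.ndarray, center: float, width: float, z_max: float) -> np.ndarray:
    """Logistic ramp rescaled to hit exactly 0 at the surface and 1 at z_max."""
    raw = 1.0 / (1.0 + np.exp(-(z - center) / width))
    lo = 1.0 / (1.0 + math.exp(center / width))
    hi = 1.0 / (1.0 + math.exp(-(z_max - center) / width))
    return (raw - lo) / (hi - lo)


def generate_profile(params: SyntheticParams) -> LakeProfile:
    """Generate an aligned chemistry+gas profile from ``params`` (seeded)."""
    p = params
    rng = np.random.default_rng(p.seed)
    z = np.arange(0.0, p.max_depth_m + p.step_m / 2, p.step_m)
    z_max = z[-1]

    ramp_t = _pinned_sigmoid(z, p.thermocline_center_m, p.thermocline_width_m, z_max)
    temp = p.t_epilimnion_C + (p.t_hypolimnion_C - p.t_epilimnion_C) * ramp_t
    ph = p.ph_surface + (p.ph_bottom - p.ph_surface) * ramp_t

    weights = np.array([w for _, _, w in p.haloclines], dtype=float)
    weights /= weights.sum()
    ramp_s = sum(
        w * _pinned_sigmoid(z, c, wd, z_max)
        for (c, wd, _), w in zip(p.haloclines, weights)
    )
    tds = p.tds_surface_mgL + (p.tds_bottom_mgL - p.tds_surface_mgL) * ramp_s

    if p.noise_temp_C:
        temp = temp + rng.normal(0.0, p.noise_temp_C, z.shape)
    if p.noise_ph:
        ph = ph + rng.normal(0.0, p.noise_ph, z.shape)
    if p.noise_rel:
        tds = np.maximum(tds * (1.0 + rng.normal(0.0, p.noise_rel, z.shape)), 0.0)

    chem_records = []
    gas_records = []
    for i, depth in enumerate(z):
        solutes = {k: f * tds[i] for k, f in ION_TEMPLATE.items()}
        rec = ChemistryRecord(
            depth_m=float(depth), temp_C=float(temp[i]), pH=float(ph[i]),
            **solutes,
        )
        rec.TDS_mgL = sum(solutes.values())
        chem_records.append(rec)

        pressures: dict[str, float] = {}
        for gas, bottom in p.gas_bottom_atm.items():
            val = bottom * math.exp(-(z_max - depth) / p.gas_efold_m[gas])
            if gas in ("CH4", "H2", "He") and depth < p.oxic_boundary_m:
                val = math.nan  # not detected above the oxic boundary
            if p.noise_rel and not math.isnan(val):
                val = max(val * (1.0 + rng.normal(0.0, p.noise_rel)), 0.0)
            pressures[gas] = val
        o2 = p.o2_surface_atm * max(1.0 - depth / p.oxic_boundary_m, 0.0)
        pressures["O2"] = o2 if o2 > 0 else math.nan
        gas_records.append(GasRecord(
            depth_m=float(depth),
            PCO2_atm=pressures.get("CO2", math.nan),
            PN2_atm=pressures.get("N2", math.nan),
            PCH4_atm=pressures.get("CH4", math.nan),
            PO2_atm=pressures.get("O2", math.nan),
            PH2_atm=pressures.get("H2", math.nan),
            PHe_atm=pressures.get("He", math.nan),
        ))

    profile = align_profiles(chem_records, gas_records,
                             metadata={"max_depth_m": float(z_max),
                                       "synthetic_seed": p.seed})
    return profile


PRESETS = {
    # bottom pTOT ~1.2-1.5 atm, bottom TDS ~2.6-3.0 g/L, bottom CH4 0.5-0.8 atm
    "averno2015": SyntheticParams(),
}


def make_fixture_like(preset: str = "averno2015", seed: int = 0) -> LakeProfile:
    """Generate a profile from a named preset (seeded, deterministic)."""
    if preset not in PRESETS:
        raise KeyError(f"unknown preset {preset!r}; available: {sorted(PRESETS)}")
    params = PRESETS[preset]
    params = SyntheticParams(**{**params.__dict__, "seed": seed})
    return generate_profile(params)


def estimate_thermocline_center(profile: LakeProfile) -> float:
    """Depth of max |dT/dz| (midpoint of the steepest grid interval)."""
    chem = profile.chemistry
    grads = [
        (abs(b.temp_C - a.temp_C) / (b.depth_m - a.depth_m), (a.depth_m + b.depth_m) / 2)
        for a, b in zip(chem, chem[1:])
    ]
    return max(grads)[1]
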