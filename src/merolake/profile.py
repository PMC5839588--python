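"""Depth-profile data model for meromictic-lake surveys.

A survey is two depth-indexed tables: water chemistry (temperature, pH,
alkalinity, major ions, reduced sulfur, trace elements, stable isotopes) and
dissolved-gas partial pressures.  This module reads/writes the CSV layout,
joins the two tables into a :class:`LakeProfile`, and provides the simple
derived metrics (TDS sums, redox ratios) used by the downstream carbonate and
density analyses.

Conventions: depths in metres, positive downward, surface = 0; concentrations
in mg/L; partial pressures in atm; "<x" cells mark below-detection values,
stored as 0 with the detection limit kept for round-tripping; blank cells are
missing (NaN) and contribute 0 to sums.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field, replace

import pandas as pd

# field name -> solute key used in constants tables
ION_FIELDS = {
    "F_mgL": "F", "Cl_mgL": "Cl", "Br_mgL": "Br", "NO3_mgL": "NO3",
    "SO4_mgL": "SO4", "Ca_mgL": "Ca", "Mg_mgL": "Mg", "Na_mgL": "Na",
    "K_mgL": "K", "NH4_mgL": "NH4", "Li_mgL": "Li",
}
TRACE_FIELDS = ("P_mgL", "Fe_mgL", "Mn_mgL", "Zn_mgL")

CHEM_COLUMNS = [
    "depth_m", "temp_C", "pH", "alk_mgL",
    "F_mgL", "Cl_mgL", "Br_mgL", "P_mgL", "NO3_mgL", "SO4_mgL",
    "Ca_mgL", "Mg_mgL", "Na_mgL", "K_mgL", "NH4_mgL", "Li_mgL",
    "S2_mgL", "Fe_mgL", "Mn_mgL", "Zn_mgL",
    "TDS_mgL", "d13C_TDIC_calc", "d13C_TDIC", "dD_H2O", "d18O_H2O",
]

GAS_PRESSURE_FIELDS = {
    "PCO2_atm": "CO2", "PN2_atm": "N2", "PAr_atm": "Ar", "PCH4_atm": "CH4",
    "PO2_atm": "O2", "PH2_atm": "H2", "PHe_atm": "He",
}

GAS_COLUMNS = [
    "depth_m", "PCO2_atm", "PN2_atm", "PAr_atm", "PCH4_atm", "PO2_atm",
    "PH2_atm", "PHe_atm", "pTOT_atm", "d13C_CO2", "d13C_CH4", "dD_CH4",
    "PCO2calc_atm",
]


class ProfileError(ValueError):
    """Raised for malformed profile tables."""


@dataclass
class ChemistryRecord:
    """One depth level of the water-chemistry table (mg/L basis).

    Alkalinity is carried in mg/L as bicarbonate (HCO3-) equivalent; on that
    basis the sum of alkalinity plus all solutes reproduces the reported TDS
    column of the packaged survey to better than 1%.
    """

    depth_m: float
    temp_C: float
    pH: float
    alk_mgL: float
    F_mgL: float = math.nan
    Cl_mgL: float = math.nan
    Br_mgL: float = math.nan
    P_mgL: float = math.nan
    NO3_mgL: float = math.nan
    SO4_mgL: float = math.nan
    Ca_mgL: float = math.nan
    Mg_mgL: float = math.nan
    Na_mgL: float = math.nan
    K_mgL: float = math.nan
    NH4_mgL: float = math.nan
    Li_mgL: float = math.nan
    S2_mgL: float = math.nan
    Fe_mgL: float = math.nan
    Mn_mgL: float = math.nan
    Zn_mgL: float = math.nan
    TDS_mgL: float = math.nan
    d13C_TDIC_calc: float = math.nan
    d13C_TDIC: float = math.nan
    dD_H2O: float = math.nan
    d18O_H2O: float = math.nan
    # field name -> detection limit for "<x" cells (value itself stored as 0)
    below_detection: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ProfileError(f"depth must be >= 0, got {self.depth_m}")
        if not (0.0 < self.pH < 14.0):
            raise ProfileError(f"pH out of (0, 14): {self.pH}")
        if not (-5.0 < self.temp_C < 50.0):
            raise ProfileError(f"temperature out of (-5, 50) C: {self.temp_C}")
        for name in (*ION_FIELDS, *TRACE_FIELDS, "S2_mgL", "alk_mgL"):
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ProfileError(f"negative concentration {name}={v}")

    def ion_molarities(self, include_carbonate: bool = True) -> dict[str, float]:
        """Major-ion concentrations in mol/L, keyed by solute symbol.

        Alkalinity enters as HCO3- and reduced sulfur as HS- when
        ``include_carbonate`` is set; missing values contribute nothing.
        """
        from .constants import ION_MASS_G_MOL

        # mg/L -> mol/L: divide by molar mass (g/mol) and by 1000 mg/g
        out = {
            key: getattr(self, fname) / ION_MASS_G_MOL[key] / 1000.0
            for fname, key in ION_FIELDS.items()
            if not math.isnan(getattr(self, fname))
        }
        if include_carbonate:
            if not math.isnan(self.alk_mgL):
                out["HCO3"] = self.alk_mgL / ION_MASS_G_MOL["HCO3"] / 1000.0
            if not math.isnan(self.S2_mgL):
                out["HS"] = self.S2_mgL / ION_MASS_G_MOL["HS"] / 1000.0
        return out


@dataclass
class GasRecord:
    """One depth level of the dissolved-gas table (partial pressures, atm)."""

    depth_m: float
    PCO2_atm: float = math.nan
    PN2_atm: float = math.nan
    PAr_atm: float = math.nan
    PCH4_atm: float = math.nan
    PO2_atm: float = math.nan
    PH2_atm: float = math.nan
    PHe_atm: float = math.nan
    pTOT_atm: float = math.nan
    d13C_CO2: float = math.nan
    d13C_CH4: float = math.nan
    dD_CH4: float = math.nan
    PCO2calc_atm: float = math.nan
    below_detection: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ProfileError(f"depth must be >= 0, got {self.depth_m}")
        for name in GAS_PRESSURE_FIELDS:
            v = getattr(self, name)
            if not math.isnan(v) and v < 0:
                raise ProfileError(f"negative partial pressure {name}={v}")

    def partial_pressure(self, gas: str) -> float:
        """Partial pressure of *gas* in atm; 0.0 when not detected."""
        for fname, key in GAS_PRESSURE_FIELDS.items():
            if key == gas:
                v = getattr(self, fname)
                return 0.0 if math.isnan(v) else v
        raise KeyError(f"unknown gas {gas!r}")


DEFAULT_METADATA = {
    # Lake Averno basin figures: elliptical surface ~0.54 km^2, volume ~6e6 m^3
    "max_depth_m": 34.0,
    "surface_area_m2": 0.54e6,
    "volume_m3": 6.0e6,
    "surface_pressure_atm": 1.0,
    "alkalinity_basis": "mg/L as HCO3-",
}


@dataclass
class LakeProfile:
    """Joined chemistry + gas records on a shared, strictly increasing depth grid."""

    records: list[tuple[ChemistryRecord, GasRecord]]
    metadata: dict = field(default_factory=lambda: dict(DEFAULT_METADATA))
    unmatched_depths: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        depths = [c.depth_m for c, _ in self.records]
        if any(b <= a for a, b in zip(depths, depths[1:])):
            raise ProfileError("depths must be strictly increasing")
        for c, g in self.records:
            if round(c.depth_m, 1) != round(g.depth_m, 1):
                raise ProfileError("chemistry/gas depth mismatch")

    @property
    def depths(self) -> list[float]:
        return [c.depth_m for c, _ in self.records]

    @property
    def chemistry(self) -> list[ChemistryRecord]:
        return [c for c, _ in self.records]

    @property
    def gas(self) -> list[GasRecord]:
        return [g for _, g in self.records]

    def __len__(self) -> int:
        return len(self.records)

    def copy(self) -> "LakeProfile":
        recs = [(replace(c, below_detection=dict(c.below_detection)),
                 replace(g, below_detection=dict(g.below_detection)))
                for c, g in self.records]
        return LakeProfile(recs, dict(self.metadata), self.unmatched_depths)


def _parse_cell(text: object) -> tuple[float, float | None]:
    """Parse one CSV cell -> (value, detection_limit or None)."""
    if text is None or (isinstance(text, float) and math.isnan(text)):
        return math.nan, None
    s = str(text).strip()
    if s == "" or s.lower() == "nan":
        return math.nan, None
    if s.startswith("<"):
        try:
            return 0.0, float(s[1:])
        except ValueError as exc:
            raise ProfileError(f"unparseable below-detection cell {s!r}") from exc
    try:
        return float(s), None
    except ValueError as exc:
        raise ProfileError(f"non-numeric cell {s!r}") from exc


def _read_table(source, columns: list[str], record_cls):
    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    df = pd.read_csv(source, dtype=str, skipinitialspace=True)
    if "depth_m" not in df.columns:
        raise ProfileError("missing depth column 'depth_m'")
    if len(df) == 0:
        raise ProfileError("no records")
    records = []
    for _, row in df.iterrows():
        kwargs: dict = {}
        flags: dict[str, float] = {}
        for col in columns:
            if col not in df.columns:
                continue
            value, limit = _parse_cell(row[col])
            kwargs[col] = value
            if limit is not None:
                flags[col] = limit
        if math.isnan(kwargs.get("depth_m", math.nan)):
            raise ProfileError("row with missing depth")
        records.append(record_cls(**kwargs, below_detection=flags))
    depths = [round(r.depth_m, 1) for r in records]
    if len(set(depths)) != len(depths):
        raise ProfileError("duplicate depths")
    records.sort(key=lambda r: r.depth_m)
    return records


def read_chemistry_table(source) -> list[ChemistryRecord]:
    """Read a water-chemistry CSV (path, file object or CSV text)."""
    return _read_table(source, CHEM_COLUMNS, ChemistryRecord)


def read_gas_table(source) -> list[GasRecord]:
    """Read a dissolved-gas CSV (path, file object or CSV text)."""
    return _read_table(source, GAS_COLUMNS, GasRecord)


def _format_cell(value: float, limit: float | None) -> str:
    if limit is not None:
        return f"<{limit:g}"
    if math.isnan(value):
        return ""
    return f"{value:g}"


def _write_table(records, columns: list[str], dest) -> None:
    rows = []
    for r in records:
        rows.append({
            col: _format_cell(getattr(r, col), r.below_detection.get(col))
            for col in columns
        })
    pd.DataFrame(rows, columns=columns).to_csv(dest, index=False)


def write_chemistry_table(records: list[ChemistryRecord], dest) -> None:
    _write_table(records, CHEM_COLUMNS, dest)


def write_gas_table(records: list[GasRecord], dest) -> None:
    _write_table(records, GAS_COLUMNS, dest)


def compute_tds(record: ChemistryRecord) -> float:
    """Total dissolved solids, mg/L: alkalinity (as HCO3-) + all solutes.

    Missing and below-detection entries contribute 0, which matches how the
    reported TDS column of the packaged survey was assembled.
    """
    total = 0.0
    for name in ("alk_mgL", *ION_FIELDS, "S2_mgL", *TRACE_FIELDS):
        v = getattr(record, name)
        if not math.isnan(v):
            total += v
    return total


def redox_ratios(record: ChemistryRecord) -> tuple[float | None, float | None]:
    """(NH4+/NO3-, sigmaS2-/SO42-) mass-concentration ratios.

    ``None`` marks an undefined ratio (denominator missing, zero or below
    detection).  These track the vertical redox zonation: both climb steeply
    below the oxycline.
    """
    def ratio(num: float, den: float, den_name: str) -> float | None:
        if math.isnan(num) or math.isnan(den):
            return None
        if den == 0.0 or den_name in record.below_detection:
            return None
        return num / den

    return (
        ratio(record.NH4_mgL, record.NO3_mgL, "NO3_mgL"),
        ratio(record.S2_mgL, record.SO4_mgL, "SO4_mgL"),
    )


def align_profiles(
    chem: list[ChemistryRecord],
    gas: list[GasRecord],
    metadata: dict | None = None,
) -> LakeProfile:
    """Inner-join chemistry and gas records on depth (matched at 0.1 m).

    Unmatched depths are kept on the returned profile for reporting; an empty
    intersection is an error.
    """
    gas_by_depth = {round(g.depth_m, 1): g for g in gas}
    pairs = []
    unmatched: list[float] = []
    for c in chem:
        key = round(c.depth_m, 1)
        if key in gas_by_depth:
            pairs.append((c, gas_by_depth.pop(key)))
        else:
            unmatched.append(c.depth_m)
    unmatched.extend(g.depth_m for g in gas_by_depth.values())
    if not pairs:
        raise ProfileError("empty intersection between chemistry and gas depths")
    meta = dict(DEFAULT_METADATA)
    if metadata:
        meta.update(metadata)
    return LakeProfile(pairs, meta, tuple(sorted(unmatched)))
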