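"""End-to-end orchestration: read -> join -> derive -> scenarios -> report.

One call runs the whole analysis a survey supports: TDS and redox metrics,
carbonate speciation with equilibrium PCO2 and isotope corrections, the
density chain, hydrostatic saturation ratios, scenario perturbations with
stability verdicts, and the epilimnion-cooling instability scan.  Results
are a per-depth table (CSV) plus a JSON report with headline metrics.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import pandas as pd
import yaml

from . import __version__ as _version
from . import data as packaged_data
from .carbonate import (
    correct_delta13c_co2,
    pco2_from_alkalinity,
    speciate,
    tdic_delta13c_equilibrium,
)
from .density import (
    DEFAULT_STABILITY_TOL,
    ScenarioSpec,
    apply_scenario,
    assess_stability,
    density_profile,
    tep_instability_threshold,
)
from .gases import hydrostatic_pressure, saturation_ratio, total_gas_pressure
from .profile import (
    LakeProfile,
    align_profiles,
    compute_tds,
    read_chemistry_table,
    read_gas_table,
    redox_ratios,
)
from .synthetic import make_fixture_like


@dataclass
class PipelineConfig:
    """Inputs and options for one pipeline run."""

    chem_path: str | None = None
    gas_path: str | None = None
    preset: str | None = None  # synthetic preset instead of CSV inputs
    scenarios: list[ScenarioSpec] = field(default_factory=list)
    stability_tol_kg_m3: float = DEFAULT_STABILITY_TOL
    activity_model: str = "none"
    tep_scan_C: tuple[float, float, float] = (5.0, 15.0, 1.0)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text())
        scenarios = [
            ScenarioSpec(
                label=s.get("label", f"scenario{i}"),
                tep_override_C=s.get("tep_override_C"),
                z_epi_m=s.get("z_epi_m", 8.0),
                multipliers=s.get("multipliers", {}) or {},
            )
            for i, s in enumerate(raw.pop("scenarios", []))
        ]
        return cls(scenarios=scenarios, **raw)

    def load_profile(self) -> LakeProfile:
        if self.preset is not None:
            return make_fixture_like(self.preset, seed=self.seed)
        if self.chem_path is None and self.gas_path is None:
            return packaged_data.load_averno_2015()
        if self.chem_path is None or self.gas_path is None:
            raise ValueError("need both chem_path and gas_path (or a preset)")
        for p in (self.chem_path, self.gas_path):
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return align_profiles(
            read_chemistry_table(self.chem_path),
            read_gas_table(self.gas_path),
        )


@dataclass
class RunReport:
    """Full output of one pipeline run."""

    table: pd.DataFrame
    scenarios: list[dict]
    headline: dict
    provenance: dict


def depth_table(profile: LakeProfile, activity_model: str = "none") -> pd.DataFrame:
    """Per-depth derived quantities for an aligned profile."""
    dens = density_profile(profile)
    zs = [d.depth_m for d in dens]
    rhos = [d.rho for d in dens]
    rows = []
    for (chem, gas), d in zip(profile.records, dens):
        nh4_no3, s2_so4 = redox_ratios(chem)
        system = speciate(chem.alk_mgL, chem.pH, chem.temp_C, chem, activity_model)
        d13c_corr = (
            correct_delta13c_co2(gas.d13C_CO2, chem.temp_C)
            if not math.isnan(gas.d13C_CO2) else math.nan
        )
        d13c_tdic = (
            tdic_delta13c_equilibrium(system, d13c_corr)
            if not math.isnan(d13c_corr) else math.nan
        )
        ptot = total_gas_pressure(gas)
        phydro = hydrostatic_pressure(
            chem.depth_m, (zs, rhos),
            profile.metadata.get("surface_pressure_atm", 1.0),
        )
        rows.append({
            "depth_m": chem.depth_m,
            "temp_C": chem.temp_C,
            "pH": chem.pH,
            "tds_mgL": compute_tds(chem),
            "nh4_no3": math.nan if nh4_no3 is None else nh4_no3,
            "s2_so4": math.nan if s2_so4 is None else s2_so4,
            "pco2calc_atm": system.pco2calc_atm,
            "d13C_CO2_dissolved": d13c_corr,
            "d13C_TDIC_calc": d13c_tdic,
            "K25_mScm": d.k25_mS_cm,
            "rho_pure": d.rho_pure,
            "rho_TS": d.rho_ts,
            "C_CO2_gkg": d.c_co2_g_kg,
            "C_CH4_gkg": d.c_ch4_g_kg,
            "rho_kgm3": d.rho,
            "ptot_atm": ptot,
            "phydro_atm": phydro,
            "saturation_ratio": ptot / phydro,
        })
    return pd.DataFrame(rows)


def _scenario_summary(
    profile: LakeProfile,
    spec: ScenarioSpec,
    baseline_rho: list[float],
    tolerance: float,
) -> dict:
    perturbed = apply_scenario(profile, spec)
    dens = density_profile(perturbed)
    report = assess_stability(dens, tolerance)
    sats = saturation_ratio(perturbed, ([d.depth_m for d in dens], [d.rho for d in dens]))
    oversat = [s.depth_m for s in sats if s.oversaturated]
    if not report.stable:
        verdict = "unstable"
    elif oversat:
        verdict = "stable-but-oversaturated"
    else:
        verdict = "stable"
    return {
        "label": spec.label,
        "verdict": verdict,
        "stable": report.stable,
        "inversions": report.inversions,
        "max_density_decrease_gL": max(
            (b - d.rho for b, d in zip(baseline_rho, dens)), default=0.0
        ),
        "max_ptot_atm": max(s.ptot_atm for s in sats),
        "max_saturation_ratio": max(s.ratio for s in sats),
        "oversaturated_depths_m": oversat,
    }


def run_pipeline(config: PipelineConfig) -> RunReport:
    """Execute the full analysis described by ``config`` (deterministic)."""
    profile = config.load_profile()
    table = depth_table(profile, config.activity_model)
    baseline_dens = density_profile(profile)
    baseline_rho = [d.rho for d in baseline_dens]
    baseline_stab = assess_stability(baseline_dens, config.stability_tol_kg_m3)

    scenario_rows = []
    for spec in config.scenarios:
        try:
            scenario_rows.append(
                _scenario_summary(profile, spec, baseline_rho, config.stability_tol_kg_m3)
            )
        except Exception as exc:  # one bad scenario must not sink the run
            scenario_rows.append({"label": spec.label, "error": str(exc)})

    lo, hi, step = config.tep_scan_C
    tep = tep_instability_threshold(profile, lo, hi, step)
    headline = {
        "n_depths": len(profile),
        "max_tds_mgL": float(table["tds_mgL"].max()),
        "max_ptot_atm": float(table["ptot_atm"].max()),
        "max_nh4_no3": float(table["nh4_no3"].max()),
        "max_s2_so4": float(table["s2_so4"].max()),
        "surface_pco2calc_atm": float(table["pco2calc_atm"].iloc[0]),
        "baseline_stable": baseline_stab.stable,
        "max_saturation_ratio": float(table["saturation_ratio"].max()),
        "tep_instability_threshold_C": tep,
        "max_scenario_density_decrease_gL": max(
            (s.get("max_density_decrease_gL", 0.0) for s in scenario_rows),
            default=0.0,
        ),
    }
    provenance = {
        "package_version": _version,
        "seed": config.seed,
        "activity_model": config.activity_model,
        "stability_tol_kg_m3": config.stability_tol_kg_m3,
        "inputs": config.preset or [config.chem_path, config.gas_path],
    }
    return RunReport(table, scenario_rows, headline, provenance)


def _round_sig(x, sig: int = 6):
    if isinstance(x, float):
        if math.isnan(x):
            return None
        return float(f"{x:.{sig}g}")
    if isinstance(x, dict):
        return {k: _round_sig(v, sig) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_round_sig(v, sig) for v in x]
    return x


def write_report(report: RunReport, directory, timestamp: bool = True) -> dict[str, Path]:
    """Write results.csv (full precision) and report.json (6 significant digits)."""
    if report.table.empty:
        raise ValueError("empty report")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    csv_path = directory / "results.csv"
    report.table.to_csv(csv_path, index=False)
    payload = {
        "headline": _round_sig(report.headline),
        "scenarios": _round_sig(report.scenarios),
        "provenance": dict(report.provenance),
    }
    if timestamp:
        payload["provenance"]["written_utc"] = datetime.now(timezone.utc).isoformat()
    json_path = directory / "report.json"
    json_path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return {"results_csv": csv_path, "report_json": json_path}
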