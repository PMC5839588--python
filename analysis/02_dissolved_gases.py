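#!/usr/bin/env python
"""Dissolved-gas pressures: reservoir structure and saturation state.

Sums the per-species partial pressures into total dissolved gas pressure,
compares it with the hydrostatic pressure from the modelled density
profile, and reports the saturation ratio — the fraction of the local
physical ceiling the gas reservoir has reached.  Writes
results/gas_saturation.csv.
"""

from pathlib import Path

import pandas as pd

from merolake.data import load_averno_2015
from merolake.density import density_profile
from merolake.gases import saturation_ratio, total_gas_pressure

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    profile = load_averno_2015()
    dens = density_profile(profile)
    points = saturation_ratio(profile, ([d.depth_m for d in dens],
                                        [d.rho for d in dens]))
    table = pd.DataFrame([{
        "depth_m": s.depth_m,
        "ptot_atm": s.ptot_atm,
        "phydro_atm": s.hydrostatic_atm,
        "saturation_ratio": s.ratio,
        "oversaturated": s.oversaturated,
    } for s in points])
    OUT.mkdir(exist_ok=True)
    table.to_csv(OUT / "gas_saturation.csv", index=False)

    epilimnion = [
        g.partial_pressure("N2") + g.partial_pressure("O2") + g.partial_pressure("Ar")
        for g in profile.gas if g.depth_m <= 12
    ]
    print(f"atmospheric gases dominate above 12 m: N2+O2+Ar up to "
          f"{max(epilimnion):.2f} atm")
    print(f"bottom total dissolved gas pressure "
          f"{total_gas_pressure(profile.gas[-1]):.2f} atm vs hydrostatic "
          f"{points[-1].hydrostatic_atm:.2f} atm")
    print(f"max saturation ratio {max(s.ratio for s in points):.2f} "
          f"-> the 2015 column is everywhere undersaturated")


if __name__ == "__main__":
    main()
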