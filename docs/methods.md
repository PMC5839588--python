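# Methods

This note documents the models implemented in `merolake`, the constants they
rest on, the choices made where the design was genuinely open, and what the
synthetic-data tests do and do not demonstrate about real surveys.

## Data model

A survey is a pair of depth-indexed CSV tables: water chemistry
(temperature, pH, alkalinity, eleven major ions, reduced sulfur ΣS²⁻, four
trace elements, water and TDIC stable isotopes) and dissolved-gas partial
pressures (CO2, N2, Ar, CH4, O2, H2, He, plus gas isotopes). Depths are in
metres, positive downward, surface = 0, and must be strictly increasing;
the two tables are inner-joined on depth rounded to 0.1 m. Below-detection
cells (`<x`) are stored as zero with the detection limit retained so that
write→read round-trips are exact; blank cells are missing and contribute
zero to sums. Alkalinity is carried in mg/L **as bicarbonate**: on that
basis the plain sum of alkalinity and all solutes reproduces the reported
TDS column of the packaged Averno table to <0.1% at every depth, which
fixes the otherwise unstated basis. ΣS²⁻ is included in TDS when measured
and is treated as HS⁻ (its dominant form at pH 6.7–7.5) wherever a charge
or molar mass is needed.

## Gas partitioning

Sampling flasks (250 mL, filled to about three fourths with water) come to
two-phase equilibrium at laboratory temperature: headspace moles follow the
ideal gas law, dissolved moles Henry's law, and their sum is exactly
conserved. Henry solubilities use the Sander compilation (KH at 25 °C with
a one-parameter van't Hoff temperature factor); ideality is assumed in the
headspace and salting-out is ignored (TDS < 3 g/L implies a < 2% effect).
In-situ partial pressures re-express the total dissolved amount through the
Henry constant at lake temperature, which makes the
dissolved→headspace→partition round trip the identity to 1e-9 relative —
the property the test suite checks against an independent root-finding
oracle of the same mole balance.

Total dissolved gas pressure is the sum of present partial pressures;
hydrostatic pressure integrates the modelled density profile (trapezoid
rule, g = 9.80665 m/s², 1 atm = 101325 Pa). Their ratio is the saturation
ratio; values ≥ 1 mean the column cannot hold its gas load in solution.

## Carbonate system and equilibrium PCO2

Speciation is solved from total alkalinity, electrode pH and temperature
with the Plummer & Busenberg (1982) freshwater constants (K1, K2, KH of
CO2) and the Millero water ion product. Total alkalinity is carbonate
alkalinity after the (small) OH⁻/H⁺ correction; HS⁻, NH3 and borate
contributions (< 3% here) are neglected. pH is hydrogen-ion activity (NBS
scale).

**Activity convention.** The default speciation composes the measured pH
and the equivalent alkalinity concentration directly with the thermodynamic
constants, i.e. no single-ion activity coefficients. This is a deliberate
choice, made on two grounds: (i) at the ionic strengths of these waters
(0.03–0.05 mol/L) the correction (~20% on PCO2calc) is comparable to the
combined electrode, titration and constants uncertainty; and (ii) the
equilibrium-PCO2 column shipped with the packaged survey is reproduced on
this convention (surface value within 7%, log-space correlation 0.999 over
three decades), while Davies-corrected values fall systematically ~20%
lower and would contradict the survey's own published column. The Davies
correction remains available (`activity_model="davies"`) for sensitivity
analysis. Computed deep-water values run ~25–30% below the shipped column
regardless of activity model — the constants behind that column are not
documented, so only the surface anchor is treated as tight; the deep
anchor is checked at ±35%.

**Isotopes.** Headspace δ¹³C-CO2 is corrected to the dissolved phase with
the linear enrichment factor ε₁(T) = 0.0049·T − 1.31 ‰ (T in °C, validated
0–40 °C). δ¹³C of TDIC is the mole-fraction-weighted sum over CO2(aq),
HCO3⁻ and CO3²⁻ using Mook-style equilibrium enrichments relative to
CO2(aq) (9866/T − 24.12 ‰ for HCO3⁻, a −0.52 ‰ offset for CO3²⁻) in the
additive per-mil approximation, adequate to ~0.1 ‰ at these fractionations.
The method behind the TDIC column of the packaged survey is not documented,
so agreement is only asserted loosely (±2 ‰ at the 6 m anchor) and the
implementation is not tuned to it.

## Density model

* **Pure water**: Tanaka et al. (2001) air-free density, 0–40 °C
  (maximum 999.975 kg/m³ at 3.983 °C).
* **Salinity term**: specific conductance at 25 °C is built from limiting
  equivalent conductances attenuated PHREEQC-style (λi = λ°i·γi^α with
  Davies γ and α = 0.6/√|z|), calibrated against the 0.01 mol/L KCl point
  (1.413 mS/cm, reproduced to 0.3%). The anchor densities ρ(25 °C, K25) and
  ρ(T, K25) come from conventional single-ion partial molal volumes
  (Millero compilation, 25 °C values with linear T slopes). λ0 and λ1 then
  follow from their definitions, which makes the conductivity form
  *algebraically identical* to the molal-volume density at the two anchor
  temperatures — tested to 1e-9 relative. At T = 25 °C the λ1 expression
  has a removable singularity, evaluated as a symmetric ±0.5 °C finite
  difference.
* **Gas term**: contraction coefficients β_CO2 = 2.84·10⁻⁴ kg/g and
  β_CH4 = −1.25·10⁻³ kg/g (McGinnis convention) applied to mass
  concentrations obtained from the partial pressures via Henry's law at
  in-situ temperature. Scenario multipliers act on partial pressures;
  Henry linearity keeps this proportional to multiplying concentrations.

**Stability.** A column is stable when density never decreases with depth
beyond a tolerance, default **0.05 kg/m³**. The tolerance is set by the
data, not the arithmetic: survey tables round temperature to 0.1 °C and
solutes to 2–3 digits, which propagates to ~0.03 kg/m³ of spurious
adjacent-layer wiggle (the packaged profile shows a 0.024 kg/m³ dip between
10 and 12 m that is rounding, not physics). Real scenario inversions exceed
0.1 kg/m³. A tighter tolerance (e.g. 1e-3 kg/m³, sufficient against pure
floating-point noise) misclassifies tabulated-but-stable profiles.

**Epilimnion-cooling scan.** The rollover-onset temperature is the highest
scanned override for which the *minimum* density over the cooled epilimnion
(depths ≤ 8 m) exceeds the *maximum* density over the layers strictly
between 8 m and the top of the deep chemocline at 26 m. Both band edges are
exclusive: 8 m belongs to the overridden epilimnion, and 26 m already sits
in the chemocline whose salinity excess no plausible cooling can overcome.
On the packaged survey a 1 °C scan from 15 to 5 °C returns 9 °C; widening
the band to include the 26 m layer gives 7 °C and narrowing it to 8–24 m
gives 10 °C, so ±1 °C is the honest resolution of this construction given
that the survey's conductance is derived from composition rather than
measured in situ.

## Synthetic profiles

The generator emulates the structure the analysis assumes: a sigmoidal
thermocline between a warm epilimnion and a ~11 °C hypolimnion (ramps are
rescaled to hit the end temperatures exactly), TDS interpolated through one
or more logistic haloclines with the solute proportions of a Na-Cl-HCO3
volcanic-lake template, exponential build-up of CO2/CH4/H2/He toward the
bottom with CH4/H2/He absent above the oxic boundary, and O2 present only
above it. Noise is optional, Gaussian, truncated at zero, and fully
seeded. The `averno2015` preset lands in the observed bands (bottom TDS
2.6–3.0 g/L, bottom total gas pressure 1.2–1.5 atm, bottom CH4 0.5–0.8
atm). What the generator does **not** emulate: sensor response/drift,
detection-limit censoring, double-diffusive microstructure, or any temporal
dynamics — so passing tests demonstrate correctness of the computational
chain on structurally realistic columns, not robustness to real-world
measurement pathology.

## Numerical and interface choices

* Constants are frozen Python tables (`constants.py`) with literature
  citations; functions accept overrides rather than reading config files.
* All randomness flows through a single integer seed
  (`numpy.random.default_rng`); pipeline outputs are deterministic given
  config and seed, and `report.json` rounds to 6 significant digits while
  `results.csv` keeps full precision.
* Degenerate inputs: solute-free water short-circuits the salinity term
  (K25 = 0 would otherwise make λ0 undefined); empty tables, duplicate or
  non-increasing depths, negative pressures and non-numeric cells are
  rejected with specific errors; an undefined redox ratio (zero or
  below-detection denominator) is `None`, never infinity.

## Known limitations

* No Pitzer or ion-pairing activity model; no mineral saturation indices.
* Single van't Hoff coefficients misfit the CO2 solubility curvature by up
  to ~8% at 5 °C relative to the carbonate module's dedicated
  parameterization (they agree to 2% at 25 °C); the density-model impact is
  < 0.01 kg/m³.
* The conductance model is a documented stand-in for a full speciated
  conductivity code; it is calibrated at one KCl point and inherits ~3%
  uncertainty, which is the main contributor to the ±1 °C slack on the
  rollover-onset temperature.
* No bubble nucleation/growth, double-diffusive convection, internal-wave
  or gas-flux modelling: the stability analysis is hydrostatic.
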