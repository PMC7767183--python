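# Methods

## System and model

A 0.5–2.5% w/w aqueous solution of AMPD (2-amino-2-methyl-1,3-propanediol,
M = 105.14 g/mol, pKa of the conjugate acid 8.76 at 25 °C) is applied
(~3 cm³, treated as 3 g at unit density) over a ~20 mm column of model
skin sebum in a 16 mm diameter tube.  The sebum is a defined lipid mixture
— triglycerides 34%, stearic acid 24%, lanolin 26%, squalene 12%,
cholesterol 4% — with density 0.842 mg/mm³.  The alcoholamine neutralises
the stearic acid 1:1 in moles to an amine soap, etching into the column
while the water-binding soap layer rises above the initial level.

Two independent estimates of the reacted sebum volume are computed:

1. **Optical**: layer heights below (penetration) and above (increase) the
   initial sebum level, converted through V = πr²h.  Heights come either
   from height tables or from grayscale tube images via column-wise
   boundary detection (see below).
2. **Stoichiometric (pH)**: the weak-base relation
   pH = pKw − ½(pKb − log₁₀Cb) is inverted to track the undissociated base
   concentration; the drop since t₀, scaled through the molar masses
   (284.48 g/mol for stearic acid), the 24% stearic fraction and the sebum
   density, yields the reacted volume.  The pH at t₀ defines the unreacted
   baseline rather than the nominal prepared concentration, since both
   endpoints come from the same electrode.

Assumptions shared by both: ionic strength and activity corrections are
ignored (the equilibrium is bookkeeping for a complex mixture, not a
speciation model); hydrolysis of the formed soap is negligible on the 4 h
horizon — consistent with the hydrolysis equilibrium itself, which gives
K_h = K_w/(K_a·K_b) ≈ 8.91×10⁻⁵ and a near-neutral salt-solution pH of
½(pKw + pKa − pKb) = 6.775 for the stearate; temperature is fixed (pKw =
14, constants at 25 °C; water density 0.997 g/cm³ at 20 °C in the
pycnometer formula).

Two pKb values for AMPD coexist in the literature on this system: 5.24
(from the 25 °C conjugate-acid pKa of 8.76) and ≈5.200 (from
K_b = 6.309×10⁻⁶ as used in the hydrolysis treatment).  Both ship as named
constants; the pH method defaults to 5.24 with a config override, and the
hydrolysis operations take explicit constants so the two are never mixed
silently.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| `molar_mass` (AMPD) | 105.14 | g/mol | converts moles to mass |
| `pKb` | 5.24 | — | weak-base equilibrium; 5.200 alternative available |
| `stearic_molar_mass` | 284.48 | g/mol | 1:1 neutralisation stoichiometry |
| `stearic_fraction` | 0.24 | — | scales acid mass to sebum mass |
| `density_mg_per_mm3` | 0.842 | mg/mm³ | sebum mass → volume |
| `Vr_cm3` | 3.0 | cm³ | applied solution volume; mass ≈ volume at density 1 |
| `radius_mm` | 8.0 | mm | tube cross section for V = πr²h |
| `pixels_per_mm` | 50.0 | px/mm | 0.02 mm measurement resolution |
| `reference_time_min` | 216 | min | comparison time of the packaged table |
| `ph_accuracy` | 0.01 | pH | instrument accuracy propagated to the pH-method SD |

`eq8_direction` selects the molar-mass ratio in the acid-mass step.  The
default `physical` direction m_kp = m_zp·284.48/105.14 follows from the
1:1 stoichiometry; the transposed `as_printed` reading is retained for
audit only.  The discriminating check is mass balance: a 2.0% w/w, 3 g
application contains 60 mg of AMPD, and at the observed 216-min reacted
volume (164.88 mm³) the physical direction implies ~12 mg of reacted
amine while the transposed reading implies ~90 mg — more than was applied.

Negative reacted masses (a pH rise between samples, e.g. an electrode
transient during particle flotation) clamp to zero with a logged flag by
default; `raw` mode preserves them for diagnostics.  The SD reported by
the pH method is the half-spread of the chain evaluated at pHₙ ± 0.01,
the only defensible error model for a single electrode trace; replicate
optical series aggregate as mean ± sample SD (n − 1).

## Optical boundary detection

Rendered or photographed columns present three vertically stacked
intensity zones: solution (mid intensity, ~128), reacted band (bright,
~220), intact sebum (dark, ~30).  Two fixed thresholds (dark < 60,
bright > 180) classify pixels; per column, the boundary is the first row
crossing the bright threshold scanning away from the known baseline row,
and the band must terminate in the correct zone (dark below, solution
above) or the measurement raises on non-monotone ordering.  The
per-column pixel counts aggregate by median with even-count ties broken
toward the baseline (the conservative, smaller height).  Conversion to mm
happens once, after aggregation.  Fixed thresholds keep the measurement
deterministic and testable; a histogram-valley automatic mode was
deliberately left out as it adds failure modes without a validation
dataset to justify them.

The initial sebum geometry carries a recorded ambiguity: a "2 cm³ piece"
versus a "2 cm thick" layer (≈4 cm³ in this tube).  The default geometry
uses a 20 mm column height with a config override; nothing downstream
depends on the choice because both methods measure changes relative to
the initial level.

## Pycnometer density

The standard pharmacopoeial water-displacement formula is implemented:
d = m₁·0.997/(w + m₁ − m₂) + 0.0012 g/cm³, with the air-buoyancy term as
an additive correction.  (The source formula as typeset is ambiguous
about bracketing; the reconstruction follows the standard method and the
stated symbol meanings.)  The shipped sebum density 0.842 mg/mm³ is a
constant, not recomputed — the underlying masses are unpublished.  The
synthetic inverse (`synth_pycnometer`) solves the formula for m₂ at a
target density and round-trips exactly, which is the module's main
correctness check.

## Synthetic-data generator

The generator defines the study conditions under which the pipeline is
validated.  Reacted amine mass follows a first-order approach to a
ceiling, m_zp(t) = f·m_z0·(1 − e^(−kt)), the simplest trajectory with the
observed fast-then-stabilising shape — it is a test harness, not a
kinetic claim, and no rate parameters are fitted to real curves.
Defaults: k = 0.025 /min (most of the reaction inside the first hour over
a 240 min observation at 1 min sampling), ceiling fraction f = 0.95
(reproducing the observed ~0.6–0.8 unit pH drops), multiplied by 0.4
above the 2.0% plug threshold to emulate the dense product layer.  From
m_zp(t) the truth container derives the clean pH (through the same
weak-base relation the pipeline inverts — forward mass→pH generation
versus backward pH→volume recovery), the true reacted volume, the
penetration height V_s/(πr²), and the increase height as
(water_binding_factor − 1)·h_pen plus a small saturating swell term
(factor 1.8, swell 0.2 mm).  Gaussian noise is added per time point: 0.01
pH (the instrument accuracy) and 0.05 mm on heights, across 4 replicate
height series.  Turbidity rises in time and scales inversely with
concentration, qualitatively matching the measured pattern; it is never
used quantitatively.  Each output stream draws from its own child of the
master seed, so runs are bit-for-bit reproducible and adding a stream
never perturbs the others.

What the generator does **not** emulate: diffusion-limited kinetics, the
meniscus and lighting artifacts of real photographs, electrode drift and
the flotation transients seen at intermediate concentrations, or any
coupling between turbidity and the mass balance.  Passing recovery tests
therefore demonstrates that the computational chain is self-consistent
and correctly inverted at the stated noise levels — not that the chain is
an accurate model of a real sebum column.

## Numerical choices and degenerate inputs

- log means log₁₀ throughout, per pH convention.
- Inverting a pH ≥ pKw is non-physical for the weak-base model; the value
  is computed but flagged with a warning.
- Unit conversions are named module constants (1 dm³ = 10⁶ mm³,
  1 mg = 10⁻³ g); masses in g, concentrations in mol/dm³, solution
  volumes in dm³, sebum volumes in mm³.
- CSV writers use `%.17g` floats and readers parse with round-trip
  precision, so write-then-read is lossless and outputs are byte-stable.
- Zero stearic fraction, zero density, non-positive concentrations and
  non-monotone time grids raise `ValueError` at construction.

## Known limitations and recorded inconsistencies

- The packaged 216-min comparison table carries an internal
  inconsistency at 2.5%: the printed difference (121.77 mm³) does not
  equal its own rows' subtraction (310.00 − 31.77 = 278.23 mm³), and the
  accompanying footnote speaks of a negative number.  The pipeline
  reproduces the subtraction and documents the discrepancy; the 2.5%
  column is excluded from exact-difference checks.
- The packaged turbidity table violates its own
  decreasing-in-concentration trend once, at hour 3 (1.0%: 0.269 vs
  1.5%: 0.294).  `turbidity_trend_check` reports exactly this violation;
  the suite asserts the faithful behaviour, and the blanket
  zero-violation expectation is left failing as a documented data
  inconsistency.
- SDs attached to single-run pH-derived volumes can only be
  device-accuracy propagation; the implementation adopts that
  interpretation explicitly and does not claim equivalence with how the
  published SDs were produced.
- Temperature dependence of the equilibrium constants, multiprotic
  equilibria, buffer mixtures, reaction kinetics fitting and
  diffusion–reaction modelling of the plug are out of scope.
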