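# Calibration log for the auxiliary constants

The three auxiliary constants of the osmolality and aggregate sub-models
(`k_osm`, `osm_ref`, `d_agg_init`) are not published; they are fixed once
by the deterministic grid search implemented in
`perfusion_twin.kinetics.calibrate_defaults` and committed as the
defaults of `KineticParameters`. All published kinetic constants stay
frozen at their exemplary values.

## Setup

- Objective: minimise |X(7 d) − 35 × 10⁹ cells/L| for the reference run
  (150 mL, 0.5 × 10⁶ cells/mL inoculation, published feed schedule,
  default integration settings).
- Grid (inclusive of both bounds, lexicographic tie-break):
  - `k_osm` ∈ [0, 2] mOsm·kg⁻¹·mM⁻¹, 9 points (step 0.25)
  - `osm_ref` ∈ [315, 340] mOsm/kg, 6 points (step 5)
  - `d_agg_init` ∈ [20, 80] μm, 7 points (step 10)
- 378 simulations.

Reproduce with:

```
perfusion-twin calibrate --target-density 35e6
```

## Result (committed defaults)

| constant | value |
|---|---|
| `k_osm` | 2.0 |
| `osm_ref` | 325.0 |
| `d_agg_init` | 80.0 |

Endpoint of the reference run at these values: X(7 d) = 3.511 × 10⁷
cells/mL (70.2-fold, relative residual 0.003 against the 35 × 10⁶
cells/mL target), day-7 mean aggregate diameter 233 μm, day-7 lactate
36 mM, day-7 osmolality ≈ 430 mOsm/kg.

Top of the grid ranking (|X₇ − target| ascending):

| k_osm | osm_ref | d_agg_init | X₇ [10⁶/mL] |
|---|---|---|---|
| 2.00 | 325 | 80 | 35.11 |
| 1.75 | 320 | 80 | 35.15 |
| 1.50 | 315 | 80 | 35.17 |
| 1.75 | 315 | 80 | 34.64 |
| 2.00 | 320 | 80 | 34.63 |

The endpoint is only weakly sensitive to trading `k_osm` against
`osm_ref` along a ridge; the committed point is the grid minimiser.
`k_osm = 2` matches the sodium-lactate stoichiometry of bicarbonate-
buffered pH control (each lactate ion plus its counter-ion from base
addition contributes ≈ 2 mOsm/kg per mM).
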