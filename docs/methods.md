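# Methods

`perfusion-twin` implements a Monod-kinetic digital twin of a perfused
stirred-tank expansion process for human pluripotent stem cells (hPSCs)
grown as free-floating aggregates, together with the surrounding process
toolkit: cell-specific rate estimation from sampled data, relative
prediction-error scoring, impeller-speed scale-up, and a synthetic-data
generator. This note records the model, its assumptions, the numerical
choices, and the places where the design was genuinely open.

## Growth model

The culture state is (X, Glc, Lac, Gln, Osm, d_agg, V): viable cell
density [cells/L], glucose, lactate and glutamine [mM], osmolality
[mOsm/kg], mean aggregate diameter [μm], and the constant working volume
[L]. The effective specific growth rate is the maximal rate scaled by
multiplicative Monod factors:

```
μ_eff = μ_max · Glc/(K_Glc+Glc) · Gln/(K_Gln+Gln)
              · K_Lac/(K_Lac+Lac)
              · K_Osm/(K_Osm + max(0, Osm − Osm_ref))
              · K_Agg/(K_Agg + d_agg/2)
```

Substrates limit saturably; lactate, osmolality and aggregate size
inhibit hyperbolically. Three sub-model choices deserve comment:

- **Osmolality acts through its excess over a reference** `Osm_ref`
  rather than absolutely. An absolute form K_Osm/(K_Osm+Osm) would
  impose a constitutive ≈0.61 factor already at the basal
  320 mOsm/kg of fresh medium, i.e. it would claim that perfectly fresh
  medium inhibits growth by 40% — dimensionally possible but
  biologically meaningless. The excess form is inactive in fresh medium
  and engages as lactate secretion and pH-control base addition drive
  osmolality up.
- **Aggregate size enters as the radius** d_agg/2 against a critical
  radius K_Agg = 175 μm (a 350 μm diameter spheroid), the scale at
  which diffusion limits nutrient supply to core cells.
- **Cells are fully retained.** The perfusion line runs through a
  retention filter, so the cell balance has no washout term and the
  working volume is constant. No death or lysis term is carried: the
  process this models sustains high viability throughout, and the state
  variable is viable density.

## Metabolite balances and the metabolic closure

Each metabolite combines cell-specific turnover with perfusion exchange
at dilution rate D = F/V against the feed composition c_f:

```
dX/dt   = μ_eff · X
dGlc/dt = −q_Glc_max · a · X + D·(Glc_f − Glc)
dGln/dt = −q_Gln_max · a · X + D·(Gln_f − Gln)
dLac/dt = +q_Lac_max · a · X + D·(Lac_f − Lac)
dOsm/dt = k_osm · q_Lac_max · a · X + D·(Osm_f − Osm)
```

with the **metabolic activity a = μ_eff/μ_max** (a Pirt-type
growth-associated closure with zero maintenance). This closure was a
real design decision, settled quantitatively:

- Scaling each uptake only by its own substrate factor (e.g. glucose
  consumption by f_Glc) keeps near-maximal specific rates while growth
  is already strongly inhibited. At the printed maximal rates the feed
  then cannot meet demand at high density — glucose demand at
  35 × 10⁶ cells/mL (≈ 516 mM/day) exceeds the entire day-7 feed supply
  (≈ 297 mM/day) — and steady lactate pins near 60 mM, capping the
  7-day endpoint at ≈ 28 × 10⁶ cells/mL for *every* admissible setting
  of the auxiliary constants. The documented process endpoint is then
  unreachable.
- Growth-associated metabolism lets specific uptake relax as the
  culture leaves exponential growth, which is also what the rate
  estimates on perfused culture data show. It preserves the glycolysis
  coupling (lactate production ceases when glucose is exhausted,
  because μ_eff contains f_Glc), reproduces the documented endpoint
  inside the calibration bounds, and selects a physically motivated
  osmolality yield (see below) instead of driving it to zero.

Osmolality has no published dynamic equation; the source term
`k_osm · q_Lac` lumps the lactate ion itself with the sodium counter-ion
added by bicarbonate-buffered pH control — stoichiometrically ≈2
mOsm·kg⁻¹ per mM lactate — and perfusion relaxes osmolality toward the
feed value.

Aggregates nucleate at t_agg = 1 day with mean diameter `d_agg_init`
and then obey d′ = (μ_eff/3)·d: if aggregate volume tracks cell number,
diameter grows with the cube root of density. The published
formation/nucleation coefficients (agg_f, agg_g) are carried in
`KineticParameters` and exposed through an optional initializer
`nucleation_diameter()` interpreting them as a formation fraction and a
nuclei-per-inoculated-cell count over close-packed spheres of
d_cell-sized cells; this interpretation is this package's, since no
published formula exists.

## Parameters

Published exemplary constants (frozen in calibration):

| parameter | value | unit | role |
|---|---|---|---|
| K_Glc | 1.5 | mM | glucose half-saturation |
| K_Lac | 50 | mM | lactate inhibition constant |
| K_Gln | 0.01 | mM | glutamine half-saturation |
| K_Agg | 175 | μm | critical aggregate radius |
| K_Osm | 500 | mOsm/kg | osmotic inhibition constant (on excess) |
| μ_max | 1.35 | 1/day | maximal specific growth rate |
| q_Glc_max | 1.474e−8 | mmol·cell⁻¹·d⁻¹ | maximal glucose uptake |
| q_Lac_max | 2.37e−8 | mmol·cell⁻¹·d⁻¹ | maximal lactate production |
| q_Gln_max | 1.856e−9 | mmol·cell⁻¹·d⁻¹ | maximal glutamine uptake |
| agg_f | 0.95 | – | aggregate formation fraction |
| agg_g | 0.25 | – | aggregate nucleation coefficient |

Auxiliary constants closing the osmolality/aggregate sub-models, fixed
once by the deterministic grid calibration documented in
`calibration_log.md` (k_osm = 2.0 mOsm·kg⁻¹·mM⁻¹, Osm_ref = 325
mOsm/kg, d_agg_init = 80 μm) and committed as defaults. The calibration
minimises the miss of the documented 7-day endpoint (35 × 10⁶ cells/mL)
over an inclusive grid (9 × 6 × 7 points); ties break toward the first
point in lexicographic order. A target missed by more than 25% raises a
calibration error reporting the best achieved value.

Media defaults: DMEM/F12-based E8 carries 17.5 mM basal glucose
(configurable) and 2.5 mM basal glutamine; feed I adds 16.65 mM glucose
(30 g per 10 L) and glutamine to 4.5 mM; feed II adds 24.98 mM glucose
(45 g per 10 L) and glutamine to 5.0 mM. Osmolalities are the midpoints
of the quality-control ranges (317.5 / 337.5 / 352.5 mOsm/kg). Perfusion
feed is fresh medium: feed lactate is 0 mM.

## Numerical integration

`scipy.integrate.solve_ivp` with LSODA (adaptive, stiffness-switching —
the glutamine balance has a fast boundary layer near K_Gln = 0.01 mM
that plain explicit Runge–Kutta resolves only at punitive step sizes),
relative tolerance 1e-8 and per-state absolute tolerances in each
state's own unit (1 cell/L for X, 1e-8 mM for metabolites, 1e-10 mM for
glutamine, 1e-6 for osmolality and diameter). Integration restarts at
every feed-schedule boundary and at the aggregation onset, so rate and
medium switches and nucleation are exact events rather than artifacts of
output resolution. Concentrations are clamped at zero from below
(consumption of an exhausted substrate vanishes with its Monod factor;
states below −1e-6 raise an internal-consistency error instead of being
hidden). Output lands on a uniform dt_out grid (default 0.05 d)
including both endpoints. The simulation is fully deterministic.

## Rate estimation

The estimators are strictly pairwise between consecutive samples, using
logarithmic means: μ̂ = ΔX/Δt / X̄_log (algebraically ln(X₂/X₁)/Δt),
and for metabolites ±[Δc/Δt + D·(c̄_log − c_f)]/X̄_log with the feed
term dropped on unfed intervals and the feed waste concentration taken
as zero (fresh medium). Conventions: consumption-positive for
substrates, production-positive for wastes; F over an interval comes
from the record opening it; intervals spanning the day-4 medium switch
use the feed composition in effect at interval start. A log mean of a
non-positive value (e.g. lactate 0 at inoculation on a perfused
interval) yields a null estimate with a reason code — never a silent
arithmetic-mean substitution — and the equal-value limit is handled
analytically at relative gap ≤ 1e-12.

Accuracy, measured against the simulator's own interval-averaged rates
on noise-free daily samples of the reference process: μ is recovered
exactly (identity); the metabolite rates carry a discretisation bias
that grows with the dilution number D·Δt, from <4% on the batch day to
≈20% on the 4-vvd interval, because a two-point log mean cannot
represent the strongly non-exponential intra-interval concentration
path. Substituting exact time averages for the log means recovers the
true rates to <1%, which isolates the log mean as the only error
source; the bias is therefore intrinsic to the pairwise estimators at
daily sampling cadence, not to this implementation. Under 5% CV
multiplicative counting noise the median relative error across days 1–5
and 50 seeds stays within 20%.

## Model evaluation

Per variable, each paired point contributes
e_i = |x_wl − x_m|/max(x_wl) × 100 — normalised by the series-wide
wet-lab maximum of that variable (the only dimensionally sensible
reading), not per point — summarised by the arithmetic mean and the
sample standard deviation (n−1). Pairing is nearest-in-time within a
tolerance (default 0.02 d, exposed as a flag); unpaired observations are
reported, not dropped.

## Scale-up and planning

Between geometrically similar vessels, constant power per volume:
N_o = (N_i³·(V_o/V_i)·D_i⁵/D_o⁵)^(1/3), so N³D⁵/V is invariant. Each
supported system also has a fitted law N = c·V^(1/3) (DASbox c = 150.5,
Bioblock c = 76.5; V in liters, N in rpm — the unit convention fixed by
back-solving the published 80 rpm setpoint at 0.15 L, which the law
gives as 79.97). The two routes disagree across systems (DASbox 0.15 L →
Bioblock 0.5 L gives 57.0 rpm by power-per-volume but 60.7 rpm by the
Bioblock law) because the two vessels are not geometrically similar;
both paths are provided and neither is "corrected". Operating speed
windows scale from the reference-volume bounds (50–120 rpm at 0.15 L for
the DASbox) by the same cube-root law. Planning arithmetic: inoculum =
V·density; feed volume over a window = V × Σ(rate × overlap), pro-rated
for partial days; headspace gassing = 6 reactor volumes per hour.

## Synthetic data generator

Emulates the daily sampling routine (automated trypan-blue counting,
supernatant metabolite and osmolality assays) by sampling a simulated
trajectory and applying multiplicative lognormal noise to cell density
(unit mean, CV default 5% — typical automated-counter repeatability)
and additive Gaussian noise to concentrations (defaults 0.3 mM
metabolites, 3 mOsm/kg, 10 μm; engineering defaults, not published
values), clamped at zero; density draws are strictly positive by
construction. Identical seed and inputs give an identical dataset.

What it does *not* emulate — and what passing tests therefore do not
show about real data: systematic assay bias, sampling dead-volume
effects, within-day dynamics between samples, aggregate size
*distributions* (only the mean diameter is modeled), cell-line
differences, and any model-structure mismatch between the twin and a
real culture. Tests against synthetic data validate the estimators and
the pipeline, not the biology.

## Known limitations

- pH and DO control loops are hardware concerns and are not simulated
  (setpoints pH 7.1, DO 40%); no oxygen-transfer (kLa) model.
- Growth-factor (FGF-2) thermal decay is not modeled.
- The twin describes expansion of pluripotent cells only, not
  differentiation.
- The aggregate model carries a mean diameter with a single nucleation
  event; polydispersity and breakage/agglomeration are out of scope.
- The headline endpoint is a calibration surface, not an independent
  prediction: the auxiliary constants were fixed against it (the
  published workflow is itself calibration-by-iteration). Independent
  checks are the closed-form, property and recovery suites.
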