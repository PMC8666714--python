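# perfusion-twin

A Monod-kinetic digital twin and process-analysis toolkit for
high-density expansion of human pluripotent stem cells (hPSCs) in
perfused stirred-tank bioreactors.

hPSCs grown as free-floating aggregates secrete lactate heavily, do not
re-consume it, and trigger pH-control base addition that drives
osmolality up — a tightly coupled metabolic spiral that perfusion
feeding (continuous medium exchange with cells retained) is designed to
break. This package is for bioprocess engineers and stem-cell groups
who run or design such processes: it simulates the culture, estimates
cell-specific rates from sampling data, scores model-vs-data agreement,
and computes impeller-speed and feed-volume settings for scale-up.

## The model

Specific growth rate as a product of Monod factors over the key process
variables — substrate limitation for glucose and glutamine, hyperbolic
inhibition for lactate, osmolality excess and aggregate radius:

    μ_eff = μ_max · Glc/(K_Glc+Glc) · Gln/(K_Gln+Gln)
                  · K_Lac/(K_Lac+Lac)
                  · K_Osm/(K_Osm + max(0, Osm − Osm_ref))
                  · K_Agg/(K_Agg + d_agg/2)

Mass balances couple growth-associated metabolite turnover
(q_i = q_i,max · μ_eff/μ_max) with perfusion exchange at dilution rate
F/V against the feed composition; cells are fully retained, so dX/dt =
μ_eff·X with no washout term. Aggregates nucleate on day 1 and grow
with the cube root of cell density. From sampled data, cell-specific
rates are estimated pairwise with logarithmic means, e.g.

    μ̂ = (X₂ − X₁)/Δt · 1/X̄,   X̄ = (X₂ − X₁)/(ln X₂ − ln X₁)

and model agreement is scored as relative prediction errors normalised
by the wet-lab series maximum. Impeller speeds scale between vessels at
constant power per volume (N³D⁵/V invariant), with fitted volume-to-
speed laws N = c·V^(1/3) for the two supported systems. See
`docs/methods.md` for the full model and the reasoning behind every
choice the published material leaves open.

## Worked example

```python
from perfusion_twin import PerfusionModel, NoiseModel, synthesize

model = PerfusionModel()          # 150 mL reference process, 0.5e6 cells/mL
traj = model.simulate()           # 7 days on the published feed schedule
print(f"day-7 density : {traj.X[-1]/1e3:.3g} cells/mL")
print(f"fold expansion: {traj.fold_expansion:.1f}")
print(f"aggregate d50 : {traj.d_agg[-1]:.0f} um")
```

```
day-7 density : 3.51e+07 cells/mL
fold expansion: 70.2
aggregate d50 : 233 um
```

The simulated run reaches 3.51 × 10⁷ cells/mL on day 7 — a 70.2-fold
expansion of the 0.5 × 10⁶ cells/mL inoculum, matching the documented
process outcome — with a mean aggregate diameter of 233 μm, inside the
expected 150–350 μm band. Rate estimation on a synthetic noisy sampled
dataset of the same run:

```python
series = synthesize(model.params, model.schedule, range(8), NoiseModel(seed=11))
print(model.estimate_rates(series).summary())
```

```
 t_start_d  t_end_d    regime  mu_per_d     q_glc     q_lac     q_gln reason
         0        1     batch     1.067 1.165e-08 1.781e-08 1.856e-09
         1        2 perfusion    0.6593 7.766e-09 1.126e-08 7.843e-10
         2        3 perfusion    0.5448 6.691e-09 1.039e-08 1.077e-09
         ...
```

The batch-day growth rate (1.07/d) sits near μ_max = 1.35/d and decays
as lactate, osmolality and aggregate size engage; the specific glucose
rate starts near its 1.47 × 10⁻⁸ mmol·cell⁻¹·d⁻¹ maximum and relaxes as
the culture leaves exponential growth.

The same operations are available from the shell:

```
perfusion-twin simulate --out traj.csv
perfusion-twin scale --system dasbox --volume 0.15   # -> 79.97 rpm (set 80 rpm)
perfusion-twin plan --volume 0.15 --days 1 4         # -> 0.825 L of feed I
perfusion-twin synthesize --out process.csv --seed 7
perfusion-twin estimate-rates --data process.csv --out rates.csv
perfusion-twin evaluate --data process.csv --out errors.csv
perfusion-twin calibrate --target-density 35e6
```

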