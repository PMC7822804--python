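# urbantree

Hourly simulation of the microclimate services of a single street tree:
evaporative **cooling** from transpiration, **shading** of the pavement
beneath the crown, and **ozone removal** by dry deposition — all driven by
one shared stomatal-conductance state that is down-regulated as the soil
dries out.

The package is aimed at urban-climate and urban-forestry researchers who
want a transparent, fully scriptable process model of a single tree (the
defaults describe a mature street-planted lime, *Tilia cordata*) rather
than a land-surface scheme. Everything runs from a plain CSV of hourly
weather — or from a built-in synthetic weather generator, so the whole
chain can be exercised and tested without any external data.

## Model in brief

For every forcing hour the simulator solves, in order:

1. **Leaf gas exchange.** Net photosynthesis *A* from a two-limitation
   Farquhar model with temperature-dependent kinetics, coupled to
   Ball–Berry stomatal conductance
   `gs = m·A·rh/Cs + gm`. The slope *m* is a piecewise-linear function of
   a soil drought index `DI = (θ − θwp)/(θfc − θwp)`: it plateaus at 3
   under drought (DI ≤ 0.3), at 10 when well watered (DI ≥ 0.5), and
   rises linearly in between. The A–gs–Ci fixed point is solved with a
   bracketed root find (the balance residual is monotone in Ci).
2. **Transpiration and cooling.** The water-vapor flux through the
   stomatal and aerodynamic resistances in series,
   `Tf = (C_leaf − C_air)/(1/gs + Ra)·3600/LAI`, capped by a
   Thornthwaite-type potential-ET demand and by extractable soil water.
   Cooling power is its latent-heat equivalent, `E = Tf·λ/3600`.
3. **Ozone deposition.** The classical series network
   `vd = 1/(Ra + Rb + Rc)`, where the canopy resistance Rc combines the
   stomatal+mesophyll path (using the *same* gs, scaled by the O₃/H₂O
   diffusivity ratio 1.66), a soil path, and a cuticular path in
   parallel. vd is masked during rain hours.
4. **Soil water.** A three-layer bucket with canopy interception
   (0.2 mm per unit LAI), a surface-sealing runoff fraction, downward
   redistribution, deep seepage, and ET extraction. The budget
   `P = T + I + E + R + S + ΔStorage` closes to < 10⁻⁶ mm over any run.
5. **Pavement energy balance.** Equilibrium surface temperature of a
   sunlit and a crown-shaded pavement patch (shortwave, sky and surface
   longwave, convection, conduction), solved by bisection to a residual
   below 0.1 W m⁻². The crown attenuates the direct beam by
   Beer–Lambert `exp(−k·LAI)`. The shading service is the sum of flux
   differences between the two patches; ΔTs is their temperature
   difference.

A full description of the equations, parameters, and numerical choices is
in [docs/methods.md](docs/methods.md).

## Worked example

Two site configurations are bundled: `bordeaux` (an open green square —
unsealed ground, more wind) and `pariser` (a sealed paved square — 40 %
runoff, a thinner soil column, calmer air). Run two weeks of synthetic
Munich-like summer weather over the open square:

```bash
$ urbantree run --config bordeaux --seed 7 --out results/demo
```

(The bundled preset simulates July–August; the run below was truncated to
1–14 July by copying the preset to a YAML file and editing
`forcing.synthetic.start/end`.) The command writes `hourly.csv` (one row
per hour: gs, A, Ra/Rb/Rc, vd, transpiration, cooling and shading power,
sunlit and shaded surface temperatures, the water-budget terms) plus
`summary.json`, and prints:

```
simulated hours:            336
midday cooling mean/max:    0.054 / 0.059 kW m-2
midday shading mean/max:    0.169 / 0.772 kW m-2
cooling share of total:     47.8 %
max surface-T reduction:    24.0 degC
mean Ra / Rb:               24.2 / 32.2 s m-1
mean gs:                    0.117 mol m-2 s-1
mean vd (dry hours):        0.190 cm s-1
water balance residual:     -7.11e-14 mm
```

Midday (12:00–15:00) shading delivers a few hundred W per m² of shaded
pavement while transpirational cooling contributes tens of W per m² of
crown projection; as the soil dries over a rain-free spell, gs, cooling,
and ozone uptake all decline together. The same pipeline is available as
a library:

```python
from urbantree import cli, simulator

cfg = cli.load_config("pariser")
forcing, run_cfg = cli.build_run(cfg, seed=7)
hourly, summary = simulator.run(forcing, run_cfg)
```

Synthetic weather on its own:

```bash
urbantree generate-forcing --preset heatwave --seed 3 --out heatwave.csv
```

## Layout

```
src/urbantree/
  forcing.py            weather I/O, solar geometry, derived meteorology, PET
  canopy_exchange.py    Farquhar + Ball-Berry leaf model, transpiration, cooling
  resistance_network.py Ra/Rb/Rc and the ozone deposition velocity
  soil_water.py         3-layer bucket, interception, runoff, drought index
  surface_energy.py     pavement energy balance, sun/shade step
  simulator.py          hourly coupling loop and run summaries
  synthetic_forcing.py  seeded synthetic weather generator
  cli.py                urbantree run / generate-forcing / report
  presets/              bordeaux.yaml, pariser.yaml site configs
```
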