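# Methods

This note documents the model equations, the parameter choices, the
synthetic weather generator, and the numerical decisions behind
`urbantree`. Units are SI unless stated; conductances are given in both
mol m⁻² s⁻¹ and m s⁻¹ (conversion factor RT/P).

## 1. Scope and assumptions

The model treats **one tree** as a single "big leaf" above a pavement
patch and resolves hourly:

- leaf gas exchange (photosynthesis + stomatal conductance),
- transpiration and its evaporative-cooling power,
- ozone dry-deposition velocity through a resistance network,
- a three-layer soil water bucket that feeds a drought index back into
  the stomatal model,
- the equilibrium surface temperature of a sunlit and a shaded pavement
  patch.

Key simplifications: no within-crown radiation profile (one sun/shade
leaf state), neutral atmospheric stability for the wind profile, no heat
storage in the canopy, no snow or frozen-soil processes, and a pavement
slab with a fixed deep-ground temperature. The model is intended for
mid-latitude summer conditions.

## 2. Forcing and derived meteorology (`forcing.py`)

Input is an hourly CSV with `timestamp, t_air, rh, pressure, wind,
rad_global, precip`. The reader also accepts a column-rename map,
detects RH given in percent, aggregates 15-minute data to hours (means;
precipitation summed), linearly fills gaps up to 3 h, and flags longer
gaps as `missing` (the simulator carries state through them and emits
NaN rows).

Derived quantities per hour:

- Saturation vapor pressure from the Magnus form
  `e_sat = 0.6108·exp(17.27·T/(T+237.3))` kPa; vapor *concentrations*
  (g m⁻³) at leaf (saturated at air temperature) and air via the ideal
  gas law.
- Solar elevation from standard declination/equation-of-time
  astronomy (no atmospheric refraction), evaluated at the half-hour to
  represent the hourly mean.
- Direct/diffuse partitioning of global radiation with the Spitters
  hourly clearness-index regressions.
- Friction velocity from a neutral logarithmic profile
  `u* = k·u / ln((z−d)/z₀)` with `d = 0.67·h`, `z₀ = 0.1·h`; wind is
  floored at 0.1 m s⁻¹ so calm hours stay defined.

**Potential ET** follows Thornthwaite with an effective temperature
`Tef = 0.36·(3·Tmax − Tmin)·N/(24 − N)` (N = daylength), constrained to
`Tmin ≤ Tef ≤ Tmax`; daily PET `= 16·(10·Tef/I)^a / 30` mm day⁻¹ with
the annual heat index *I* from monthly normal temperatures (months fully
covered by the forcing use their observed means). The constraint is what
keeps PET monotone in temperature and zero in freezing conditions; a
high-temperature parabolic variant was rejected because the daylength
factor can push `Tef` past its vertex and make PET *decrease* with
warming. Hourly atmospheric demand is PET/24 — a deliberate
simplification (no diurnal weighting) that only acts as a cap.

## 3. Leaf gas exchange (`canopy_exchange.py`)

Photosynthesis is the two-limitation Farquhar model: Rubisco-limited
`Ac = Vcmax·(Ci−Γ*)/(Ci + Kc·(1+O/Ko))` and RuBP-regeneration-limited
`Aj = J·(Ci−Γ*)/(4Ci+8Γ*)`, minus dark respiration `Rd = 0.015·Vcmax`.
Kinetic constants use Arrhenius temperature responses with activation
energies (J mol⁻¹): Kc 404.9 µmol mol⁻¹/79430, Ko 278.4 mmol mol⁻¹/36380,
Γ* 42.75 µmol mol⁻¹/37830, Vcmax 65330, Jmax 43540. Electron transport J
is the non-rectangular hyperbola in absorbed PAR (α = 0.3, θ = 0.9).
Defaults `Vcmax25 = 60`, `Jmax25 = 114` µmol m⁻² s⁻¹ are typical
broadleaf values. PAR at canopy top is `0.5 × 4.6` µmol J⁻¹ of global
radiation.

Stomatal conductance is Ball–Berry, `gs = m·A·rh/Cs + gm`, with A
clamped at zero (so a dark leaf rests at `gm = 0.02 mol m⁻² s⁻¹`) and
the slope *m* supplied by the drought response (§5).

**Coupling.** At equilibrium the biochemical rate equals the diffusive
supply, `A(Ci) = (Cs − Ci)·gs(A)/1.6`. The residual of this balance is
strictly increasing in Ci, so the inner problem is solved with a
bracketed Brent root find on Ci ∈ [0.5, 2·Ca] (xtol 10⁻⁶); a short outer
loop updates the leaf-surface CO₂ `Cs = Ca − 1.37·A/gb` until gs changes
by < 10⁻⁵ mol m⁻² s⁻¹, then re-solves once at the final Cs so the
reported (A, gs, Cs) triple is self-consistent. A plain fixed-point
iteration was tried first and oscillates between the Ac/Aj limitation
branches; the bracketed solve is unconditionally stable. If the bracket
degenerates (extreme respiration at very low light), the closed-stomata
limit is returned.

**Transpiration and cooling.** Per unit ground area under the crown,
`Tf = (C_leaf − C_air)/(1/gs + Ra)·3600/LAI` g m⁻² h⁻¹, clamped at zero
when the gradient inverts. Cooling power is `E = Tf·λ/3600` W m⁻² with
λ = 2450 J per **gram** of water. (λ is sometimes quoted as J kg⁻¹ in
the literature this model family derives from; with Tf in g m⁻² h⁻¹
only the J g⁻¹ reading yields physically sensible W m⁻², so that is the
convention adopted and documented here.)

## 4. Ozone deposition (`resistance_network.py`)

Series network `vd = 1/(Ra + Rb + Rc)` with:

- `Ra = u(z)/u*²`, capped at 2000 s m⁻¹ for calm hours;
- `Rb = 2·Sc^{2/3}·Pr^{−2/3}/(k·u*)` with Sc(O₃) = 1, Pr = 0.72;
- `1/Rc = 1/(rs + rm) + 1/r_soil + 1/r_cut`, where `rs = 1/gs(O₃)` uses
  the same stomatal conductance as transpiration scaled by the
  H₂O/O₃ diffusivity ratio 1.66, `rm = 10`, `r_soil = 2941`,
  `r_cut = 10000` s m⁻¹ (defaults for a broadleaf canopy over urban
  ground; all overridable).

vd is reported as undefined (NaN) during precipitation hours: wet
surfaces change the uptake pathways and the dry-deposition network does
not apply.

## 5. Soil water and drought feedback (`soil_water.py`)

Three layers (default thicknesses 0.2/0.3/0.5 m; field capacity 0.32,
wilting point 0.12, porosity 0.45 m³ m⁻³; saturated drainage rate
2 mm h⁻¹). Each hour:

1. **Interception**: the crown holds up to 0.2 mm × LAI; the store
   evaporates at potential rate before soil extraction.
2. **Runoff**: a fixed fraction of throughfall (0 for unsealed ground,
   0.4 for the sealed preset) is shed; infiltration above layer-1
   saturation is also rejected as runoff.
3. **Redistribution**: downward inter-layer flux proportional to the
   relative-water-content difference times `k_sat`, clipped so no layer
   over-drains; water above field capacity in the bottom layer drains as
   seepage, capped at `k_sat·dt`.
4. **ET extraction**: transpiration = min(atmospheric demand from the
   Ball–Berry/gradient flux, the water-use-efficiency demand A/WUE with
   0.0648 mm per mmol H₂O m⁻² s⁻¹·h, remaining PET, extractable water
   above wilting), drawn from layers proportionally to availability;
   residual PET drives soil evaporation from the top 0.3 m.

The cumulative budget `P − T − I − E − R − S − ΔStorage` is checked to
< 10⁻⁶ mm at the end of every run (it closes to rounding error, ~10⁻¹³).

**Drought index** `DI = (θ − θwp)/(θfc − θwp)` is thickness-weighted
over the column, and the Ball–Berry slope is

- `m = 3` for DI ≤ 0.3,
- `m = 3 + 35·(DI − 0.3)` for 0.3 < DI < 0.5,
- `m = 10` for DI ≥ 0.5,

continuous at both joints. The simulator evaluates DI from the
*previous* hour's soil state (lagged, explicit coupling); at an hourly
step the lag error is far below parameter uncertainty.

## 6. Pavement energy balance (`surface_energy.py`)

Equilibrium of `q_net = q_a + q_s − q_c − q_k − q_r` for each patch:

- absorbed shortwave `q_a = (1 − albedo)·R` (albedo 0.3);
- sky longwave `q_s = εa·σ·T_air⁴` with
  `εa = 0.77 − 0.28·10^(−0.074·Vp)` (vapor pressure in mmHg);
- surface emission `q_r = εb·σ·T_s⁴` with `εb = 1.24·(10·Vp/T_air)^{1/7}`;
- convection `q_c = h_c·(T_s − T_air)`,
  `h_c = 698.24·[0.00144·T_m^{0.3}·U^{0.7} + 0.00097·|T_s − T_air|^{0.3}]`
  (T_m the mean of surface and air in K, U the daily mean wind; the
  absolute value keeps the free-convection term defined for a surface
  colder than the air, e.g. at night);
- conduction `q_k = −k·(T_d − T_s)/d` into a slab (k = 1.65 W m⁻¹ K⁻¹,
  d = 2 m, deep temperature 8 °C).

The root is found by bisection on `[T_air − 50, T_air + 80]` °C to an
internal residual < 0.01 W m⁻² (reported tolerance 0.1 W m⁻²), verified
in tests against an exhaustive 0.01 K grid scan.

The shaded patch receives the direct beam attenuated by Beer–Lambert
`exp(−k_ext·LAI)` (k_ext = 0.7); diffuse radiation passes unattenuated
by default (an isolated street crown leaves most of the sky dome open),
switchable via `attenuate_diffuse`. The shading service is the sum of
absolute flux-term differences between the sunlit and shaded equilibria;
ΔTs is the temperature difference. The total microclimate service is
cooling + shading; midday statistics use 12:00–15:00 local standard time.

## 7. Synthetic weather generator (`synthetic_forcing.py`)

A seeded generator (numpy `default_rng`) produces statistically plausible
Central-European summer forcing: diurnal temperature sinusoid plus AR(1)
noise; clear-sky radiation from the site's solar geometry times a fixed
transmissivity times an AR(1) latent cloud factor (s.d. configurable via
`cloud_noise_sd`; 0 gives a steady sky) clipped to [0.15, 1] and forced
≤ 0.25 in rain hours; RH anti-correlated with the temperature anomaly
and ≥ 0.9 in rain; AR(1) wind about a site mean; rain as a marked
Poisson process with exponential depths spread over 1–3 h. Presets:
`munich_summer`, `heatwave`, `wet_cool`.

The series are **stand-ins, not observations**: tests that pass on them
demonstrate internal consistency (conservation, monotonicity, coupling
identities, solver accuracy) and directionally correct responses to
contrasting regimes — they do not validate the model against measured
fluxes, which would require real eddy-covariance/sap-flow data.

## 8. Site presets and the two-site experiment

`bordeaux` (open green square): unsealed (runoff 0), 1.0 m soil column,
windier (mean 0.9 m s⁻¹), LAI 2.41, tree height 15.1 m.
`pariser` (sealed paved square): runoff fraction 0.4, thinner 0.7 m
column, calmer (mean 0.5 m s⁻¹), LAI 2.54, height 16.8 m. Sensor height
20 m keeps the log profile defined above the displacement height.

Run under identical weather (same seed), the sealed site develops higher
Ra and Rb (calmer air), a lower drought index (thin column + runoff),
hence lower gs, transpiration, cooling, and ozone uptake, and a larger
sunlit-minus-shaded surface-temperature difference. These contrasts are
asserted in the test suite and reproduced by `scripts/acceptance.py`.

## 9. Limitations

- Big-leaf canopy: no sun/shade leaf split for photosynthesis, no
  within-crown microclimate.
- Neutral-stability aerodynamics only; Ra is crude in very calm or very
  unstable hours (hence the 2000 s m⁻¹ cap).
- PET is temperature-based (Thornthwaite); it ignores radiation and
  humidity anomalies and serves only as a demand cap.
- The pavement model is one-dimensional with a fixed deep temperature
  and no heat storage dynamics (equilibrium each hour).
- Ozone deposition uses a constant soil/cuticular resistance; surface
  wetness effects are handled only by masking rain hours.
- Parameters default to a mature street lime in a temperate summer;
  other species/climates require re-parameterization.
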