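"""Pavement surface energy balance and canopy shading.

The surface temperature of a (concrete) pavement is the equilibrium of

    q_net = q_a + q_s - q_c - q_k - q_r = 0

with absorbed shortwave q_a = (1 - a) R, absorbed atmospheric longwave
q_s = eps_a sigma T_air^4, convection q_c = h_c (T_s - T_air), conduction
into the ground q_k = -k (T_d - T_s)/d, and surface emission
q_r = eps_b sigma T_s^4. Under the tree crown the direct beam is
attenuated by Beer-Lambert extinction exp(-k LAI) while diffuse radiation
passes unattenuated (optionally attenuated too); the shading benefit is
the sum of the absolute flux-term differences between the sunlit and
shaded equilibria.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .forcing import DerivedMeteo, MeteoRecord
from .canopy_exchange import TreeTraits

STEFAN_BOLTZMANN = 5.68e-8  # W m-2 K-4 (value used by the surface model)


@dataclass(frozen=True)
class SurfaceParams:
    """Material and boundary constants of the pavement surface."""

    albedo: float = 0.3
    thermal_conductivity: float = 1.65  # W m-1 K-1
    damping_depth: float = 2.0          # m, depth of constant ground temperature
    t_deep: float = 8.0                 # degC at damping_depth
    attenuate_diffuse: bool = False     # also pass diffuse through the canopy filter

    def __post_init__(self) -> None:
        if not 0.0 <= self.albedo <= 1.0:
            raise ValueError("albedo must be in [0, 1]")
        if self.damping_depth <= 0:
            raise ValueError("damping depth must be positive")


@dataclass(frozen=True)
class EnergyFluxes:
    """All flux terms (W m-2) evaluated at a given surface temperature."""

    q_a: float
    q_s: float
    q_c: float
    q_k: float
    q_r: float
    q_net: float
    eps_a: float
    eps_b: float
    h_c: float
    t_surface: float  # degC at which the terms were evaluated


class SurfaceSolverError(RuntimeError):
    """The equilibrium bracket failed to contain a root."""


def atmospheric_emissivity(vp_mmhg: float) -> float:
    """Sky emissivity eps_a = 0.77 - 0.28 * 10^(-0.074 Vp), Vp in mmHg."""
    return 0.77 - 0.28 * 10.0 ** (-vp_mmhg * 0.074)


def surface_emissivity(vp_mmhg: float, t_air_k: float) -> float:
    """Emission coefficient eps_b = 1.24 (10 Vp / T_air)^(1/7), T_air in K."""
    return 1.24 * (10.0 * vp_mmhg / t_air_k) ** (1.0 / 7.0)


def convection_coefficient(t_s_k: float, t_air_k: float, wind_daily: float) -> float:
    """Surface heat-transfer coefficient h_c (W m-2 K-1).

    h_c = 698.24 [0.00144 T_m^0.3 U^0.7 + 0.00097 |T_s - T_air|^0.3] with
    T_m the surface/air mean temperature (K) and U the daily-mean wind
    speed; the temperature-difference term uses the absolute value so the
    expression stays defined for a surface cooler than the air.
    """
    t_m = 0.5 * (t_s_k + t_air_k)
    return 698.24 * (0.00144 * t_m ** 0.3 * max(wind_daily, 0.0) ** 0.7
                     + 0.00097 * abs(t_s_k - t_air_k) ** 0.3)


def flux_terms(t_s: float, rec: MeteoRecord, met: DerivedMeteo,
               rad_at_surface: float, params: SurfaceParams,
               wind_daily: float) -> EnergyFluxes:
    """Evaluate every energy-balance term at surface temperature ``t_s`` (degC).

    ``rad_at_surface`` is the shortwave irradiance actually reaching the
    surface (already canopy-filtered for a shaded surface).
    """
    if not rec.t_air - 51.0 <= t_s <= rec.t_air + 81.0:
        raise ValueError(f"surface temperature {t_s} degC outside physical range")
    t_s_k = t_s + 273.15
    t_air_k = rec.t_air + 273.15
    eps_a = atmospheric_emissivity(met.vp_mmhg)
    eps_b = surface_emissivity(met.vp_mmhg, t_air_k)
    h_c = convection_coefficient(t_s_k, t_air_k, wind_daily)
    q_a = (1.0 - params.albedo) * rad_at_surface
    q_s = eps_a * STEFAN_BOLTZMANN * t_air_k ** 4
    q_c = h_c * (t_s_k - t_air_k)
    q_k = -params.thermal_conductivity * (params.t_deep - t_s) / params.damping_depth
    q_r = eps_b * STEFAN_BOLTZMANN * t_s_k ** 4
    q_net = q_a + q_s - q_c - q_k - q_r
    return EnergyFluxes(q_a=q_a, q_s=q_s, q_c=q_c, q_k=q_k, q_r=q_r, q_net=q_net,
                        eps_a=eps_a, eps_b=eps_b, h_c=h_c, t_surface=t_s)


def solve_surface_temperature(rec: MeteoRecord, met: DerivedMeteo,
                              rad_at_surface: float, params: SurfaceParams,
                              wind_daily: float,
                              residual_tol: float = 0.01) -> EnergyFluxes:
    """Equilibrium surface temperature: root of q_net on [T_air-50, T_air+80].

    q_net is strictly decreasing in T_s over the bracket (emission,
    convection, and conduction all grow with T_s), so bisection converges
    to the unique root; iteration stops when |q_net| < ``residual_tol``
    W m-2.
    """
    lo, hi = rec.t_air - 50.0, rec.t_air + 80.0

    def residual(t_s: float) -> float:
        return flux_terms(t_s, rec, met, rad_at_surface, params, wind_daily).q_net

    f_lo, f_hi = residual(lo), residual(hi)
    if f_lo < 0.0 or f_hi > 0.0:
        raise SurfaceSolverError(
            f"no sign change in bracket [{lo:.1f}, {hi:.1f}] degC "
            f"(q_net: {f_lo:.1f}, {f_hi:.1f} W m-2)")
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        f_mid = residual(mid)
        if abs(f_mid) < residual_tol:
            return flux_terms(mid, rec, met, rad_at_surface, params, wind_daily)
        if f_mid > 0.0:
            lo = mid
        else:
            hi = mid
    raise SurfaceSolverError("bisection failed to reach the residual tolerance")


def canopy_transmitted_radiation(rad_direct: float, traits: TreeTraits) -> float:
    """Direct beam under the crown: Beer-Lambert R_in = R exp(-k LAI)."""
    if rad_direct < 0:
        raise ValueError("radiation must be nonnegative")
    return rad_direct * math.exp(-traits.k_ext * traits.lai)


def shaded_surface_radiation(met: DerivedMeteo, traits: TreeTraits,
                             params: SurfaceParams) -> float:
    """Total shortwave reaching the surface under the crown (W m-2)."""
    direct = canopy_transmitted_radiation(met.rad_direct, traits)
    diffuse = met.rad_diffuse
    if params.attenuate_diffuse:
        diffuse *= math.exp(-traits.k_ext * traits.lai)
    return direct + diffuse


def shading_energy(sun: EnergyFluxes, shade: EnergyFluxes) -> float:
    """Energy reduction by shading (W m-2): sum of |flux-term differences|.

    Each term is evaluated at its own equilibrium surface temperature.
    """
    return (abs(sun.q_a - shade.q_a) + abs(sun.q_s - shade.q_s)
            + abs(sun.q_c - shade.q_c) + abs(sun.q_k - shade.q_k)
            + abs(sun.q_r - shade.q_r))


def sun_shade_step(rec: MeteoRecord, met: DerivedMeteo, traits: TreeTraits,
                   params: SurfaceParams, wind_daily: float
                   ) -> tuple[EnergyFluxes, EnergyFluxes, float, float]:
    """Solve both equilibria for one hour.

    Returns (sunlit fluxes, shaded fluxes, shading energy W m-2,
    surface-temperature reduction degC).
    """
    rad_sun = met.rad_direct + met.rad_diffuse
    rad_shade = shaded_surface_radiation(met, traits, params)
    sun = solve_surface_temperature(rec, met, rad_sun, params, wind_daily)
    shade = solve_surface_temperature(rec, met, rad_shade, params, wind_daily)
    return sun, shade, shading_energy(sun, shade), sun.t_surface - shade.t_surface
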