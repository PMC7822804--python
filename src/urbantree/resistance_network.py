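"""Dry-deposition resistance network and ozone deposition velocity.

Ozone is removed along a series path of aerodynamic (Ra), quasi-laminar
boundary-layer (Rb), and canopy (Rc) resistances; the canopy resistance
itself combines stomatal+mesophyll, soil, and cuticular pathways in
parallel. The deposition velocity is the inverse of the series sum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .forcing import KARMAN, WIND_FLOOR

R_SOIL_DEFAULT = 2941.0   # s m-1, soil resistance to O3
SCHMIDT_O3 = 1.0          # Schmidt number used in the Rb formula
PRANDTL = 0.72            # Prandtl number
RA_CAP = 2000.0           # s m-1 ceiling for calm hours
DIFFUSIVITY_RATIO_O3 = 1.66  # D(H2O)/D(O3): converts gs(H2O) to gs(O3)


@dataclass(frozen=True)
class DepositionParams:
    """Non-stomatal resistance constants of the canopy pathway (s m-1)."""

    r_mesophyll: float = 10.0
    r_cuticular: float = 10000.0
    r_soil: float = R_SOIL_DEFAULT
    diffusivity_ratio: float = DIFFUSIVITY_RATIO_O3


@dataclass(frozen=True)
class ResistanceSet:
    """All resistances (s m-1) and the resulting deposition velocity (m s-1)."""

    r_a: float
    r_b: float
    r_c: float
    r_s: float
    r_m: float
    r_soil: float
    r_t: float
    vd: float


def aerodynamic_resistance(wind: float, u_star: float) -> float:
    """Aerodynamic resistance Ra = u(z)/u*^2 (s m-1), capped for calm hours."""
    if u_star <= 0:
        raise ValueError("friction velocity must be positive")
    return min(max(wind, WIND_FLOOR) / u_star ** 2, RA_CAP)


def boundary_layer_resistance(u_star: float) -> float:
    """Quasi-laminar boundary-layer resistance Rb = 2 Sc^(2/3) Pr^(-2/3) / (k u*)."""
    if u_star <= 0:
        raise ValueError("friction velocity must be positive")
    return 2.0 * SCHMIDT_O3 ** (2.0 / 3.0) * PRANDTL ** (-2.0 / 3.0) / (KARMAN * u_star)


def canopy_resistance(gs_ms_o3: float, params: DepositionParams = DepositionParams()) -> float:
    """Canopy resistance: 1/Rc = 1/(rs + rm) + 1/r_soil + 1/r_t (s m-1).

    ``gs_ms_o3`` is the stomatal conductance already converted to ozone
    (rs = 1/gs_o3); a value of 0 disables the stomatal path, and an infinite
    ``r_cuticular`` disables the cuticular path, leaving only soil uptake.
    """
    if gs_ms_o3 < 0:
        raise ValueError("stomatal conductance must be nonnegative")
    r_s = math.inf if gs_ms_o3 == 0.0 else 1.0 / gs_ms_o3
    conduct = 0.0
    if math.isfinite(r_s + params.r_mesophyll):
        conduct += 1.0 / (r_s + params.r_mesophyll)
    conduct += 1.0 / params.r_soil
    if math.isfinite(params.r_cuticular):
        conduct += 1.0 / params.r_cuticular
    return 1.0 / conduct


def deposition_velocity(r_a: float, r_b: float, r_c: float) -> float:
    """Deposition velocity vd = 1/(Ra + Rb + Rc) (m s-1)."""
    if min(r_a, r_b, r_c) <= 0 or not all(map(math.isfinite, (r_a, r_b, r_c))):
        raise ValueError("all component resistances must be finite and positive")
    return 1.0 / (r_a + r_b + r_c)


def build_resistances(wind: float, u_star: float, gs_ms_h2o: float,
                      params: DepositionParams = DepositionParams()) -> ResistanceSet:
    """Assemble the full resistance set for one hour from water-vapor gs."""
    r_a = aerodynamic_resistance(wind, u_star)
    r_b = boundary_layer_resistance(u_star)
    gs_o3 = gs_ms_h2o / params.diffusivity_ratio
    r_c = canopy_resistance(gs_o3, params)
    return ResistanceSet(
        r_a=r_a,
        r_b=r_b,
        r_c=r_c,
        r_s=1.0 / gs_o3,
        r_m=params.r_mesophyll,
        r_soil=params.r_soil,
        r_t=params.r_cuticular,
        vd=deposition_velocity(r_a, r_b, r_c),
    )
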