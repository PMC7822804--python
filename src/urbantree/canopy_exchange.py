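"""Leaf gas exchange: photosynthesis, stomatal conductance, transpiration.

The canopy is treated as a single big leaf. Net photosynthesis comes from a
two-limitation Farquhar model with Bernacchi temperature responses;
stomatal conductance follows the Ball-Berry relation

    gs = m * A * rh / Cs + gm

whose slope m is down-regulated by the soil drought index (see
:mod:`urbantree.soil_water`). Transpiration is a concentration-gradient
flux through the stomatal and aerodynamic resistances in series, and the
latent-heat equivalent of that flux is the evaporative cooling power.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from scipy.optimize import brentq

from .forcing import R_GAS, DerivedMeteo

log = logging.getLogger("urbantree")

O2_MMOL = 210.0          # mmol mol-1, atmospheric oxygen for the oxygenation term
LATENT_HEAT_VAP = 2450.0 # J g-1 latent heat of vaporization
PAR_PER_GLOBAL = 0.5 * 4.6  # umol photons J-1: PAR fraction x quantum conversion


@dataclass(frozen=True)
class TreeTraits:
    """Morphology and leaf physiology of the simulated tree.

    Defaults describe a mature street-planted *Tilia cordata*.
    """

    lai: float = 2.5           # leaf area index, m2 m-2
    canopy_cover: float = 70.0 # crown projected area, m2
    height: float = 15.0       # m
    dbh: float = 30.0          # cm
    m_max: float = 10.0        # unstressed Ball-Berry slope
    gm: float = 0.02           # minimum stomatal conductance, mol m-2 s-1
    wue: float = 3.0           # water-use efficiency, umol CO2 per mmol H2O
    k_ext: float = 0.7         # canopy extinction coefficient
    vcmax25: float = 60.0      # umol m-2 s-1
    jmax25: float = 114.0      # umol m-2 s-1 (~1.9 x vcmax25)

    def __post_init__(self) -> None:
        if self.lai < 0 or self.gm < 0:
            raise ValueError("lai and gm must be nonnegative")
        if not 0.0 < self.k_ext <= 1.0:
            raise ValueError("extinction coefficient must be in (0, 1]")


@dataclass(frozen=True)
class LeafGasExchange:
    """Converged leaf-level gas-exchange state for one hour."""

    a_net: float      # umol CO2 m-2 s-1 (>= 0 as used in the conductance model)
    gs_mol: float     # mol m-2 s-1, conductance to water vapor
    gs_ms: float      # m s-1, same conductance in velocity units
    cs: float         # umol mol-1, CO2 at the leaf surface
    m_eff: float      # drought-modified Ball-Berry slope
    converged: bool = True


# ---------------------------------------------------------------------------
# Farquhar photosynthesis
# ---------------------------------------------------------------------------

def _arrhenius(k25: float, ha: float, t_k: float) -> float:
    return k25 * math.exp(ha * (t_k - 298.15) / (298.15 * R_GAS * t_k))


def photosynthesis(par: float, t_air: float, ci: float, traits: TreeTraits) -> float:
    """Net photosynthesis (umol CO2 m-2 s-1) at intercellular CO2 ``ci``.

    Minimum of the Rubisco-limited and RuBP-regeneration-limited rates minus
    dark respiration Rd = 0.015 Vcmax. Kinetic constants and their
    activation energies follow Bernacchi; electron transport is a
    non-rectangular hyperbola in absorbed PAR.
    """
    if par < 0:
        raise ValueError("PAR must be nonnegative")
    t_k = t_air + 273.15
    kc = _arrhenius(404.9, 79430.0, t_k)          # umol mol-1
    ko = _arrhenius(278.4, 36380.0, t_k)          # mmol mol-1
    gamma_star = _arrhenius(42.75, 37830.0, t_k)  # umol mol-1
    vcmax = _arrhenius(traits.vcmax25, 65330.0, t_k)
    jmax = _arrhenius(traits.jmax25, 43540.0, t_k)

    # electron transport: theta J^2 - (alpha*PAR + Jmax) J + alpha*PAR*Jmax = 0
    alpha, theta = 0.3, 0.9
    b = alpha * par + jmax
    j = (b - math.sqrt(b * b - 4.0 * theta * alpha * par * jmax)) / (2.0 * theta)

    ci = max(ci, 0.1)
    ac = vcmax * (ci - gamma_star) / (ci + kc * (1.0 + O2_MMOL / ko))
    aj = j * (ci - gamma_star) / (4.0 * ci + 8.0 * gamma_star)
    rd = 0.015 * vcmax
    return min(ac, aj) - rd


# ---------------------------------------------------------------------------
# Ball-Berry conductance
# ---------------------------------------------------------------------------

def ball_berry(a_net: float, rh: float, cs: float, m_eff: float,
               traits: TreeTraits) -> float:
    """Stomatal conductance to water vapor (mol m-2 s-1).

    gs = m * A * rh / Cs + gm with A clamped at zero: a dark or stressed
    leaf falls back to the minimum (cuticular-free) conductance gm.
    """
    if cs <= 0:
        raise ValueError("leaf-surface CO2 must be positive")
    return m_eff * max(a_net, 0.0) * rh / cs + traits.gm


def gs_mol_to_ms(gs_mol: float, t_air: float, pressure_kpa: float) -> float:
    """Convert conductance from mol m-2 s-1 to m s-1 (ideal-gas factor RT/P)."""
    return gs_mol * R_GAS * (t_air + 273.15) / (pressure_kpa * 1000.0)


def couple_a_gs(par: float, t_air: float, rh: float, ca: float, m_eff: float,
                traits: TreeTraits, pressure_kpa: float = 96.0,
                r_b: float = 50.0) -> LeafGasExchange:
    """Solve the photosynthesis-conductance equilibrium for one hour.

    At equilibrium the biochemical rate A(Ci) equals the diffusive supply
    (Cs - Ci) gs(A)/1.6, with gs from the Ball-Berry relation. The residual
    of that balance is strictly increasing in Ci, so the inner problem is
    solved by a bracketed root find; a short outer loop then updates the
    leaf-surface CO2 Cs = Ca - 1.37 A/gb (gb from the quasi-laminar
    resistance ``r_b``) until the conductance changes by less than
    1e-5 mol m-2 s-1.
    """
    gb_mol = 1.0 / max(gs_mol_to_ms(1.0, t_air, pressure_kpa) * r_b, 1e-6)

    def solve_at(cs: float) -> tuple[float, float]:
        def residual(ci: float) -> float:
            a = photosynthesis(par, t_air, ci, traits)
            gs = ball_berry(a, rh, cs, m_eff, traits)
            return a - (cs - ci) * gs / 1.6

        lo, hi = 0.5, 2.0 * ca
        if residual(lo) > 0.0 or residual(hi) < 0.0:
            # degenerate bracket (extreme respiration): closed-stomata limit
            a = photosynthesis(par, t_air, cs, traits)
            return a, ball_berry(a, rh, cs, m_eff, traits)
        ci = brentq(residual, lo, hi, xtol=1e-6)
        a = photosynthesis(par, t_air, ci, traits)
        return a, ball_berry(a, rh, cs, m_eff, traits)

    cs = ca
    gs_prev = None
    converged = False
    a_net, gs = 0.0, traits.gm
    for _ in range(50):
        a_net, gs = solve_at(cs)
        cs = max(ca - 1.37 * max(a_net, 0.0) / gb_mol, 1.0)
        if gs_prev is not None and abs(gs - gs_prev) < 1e-5:
            converged = True
            break
        gs_prev = gs
    if not converged:
        log.warning("A-gs coupling did not converge; using last iterate gs=%.4f", gs)
    a_net, gs = solve_at(cs)  # re-solve at the final leaf-surface CO2

    a_eff = max(a_net, 0.0)
    return LeafGasExchange(
        a_net=a_eff,
        gs_mol=gs,
        gs_ms=gs_mol_to_ms(gs, t_air, pressure_kpa),
        cs=cs,
        m_eff=m_eff,
        converged=converged,
    )


# ---------------------------------------------------------------------------
# transpiration & cooling
# ---------------------------------------------------------------------------

def transpiration_flux(gs_ms: float, r_a: float, met: DerivedMeteo,
                       traits: TreeTraits) -> float:
    """Transpiration flux (g m-2 h-1, per unit ground area under canopy).

    T_f = (C_leaf - C_air) / (1/gs + R_a) * 3600 / LAI, clamped at zero when
    the gradient inverts (saturated air). A leafless tree transpires nothing.
    """
    if traits.lai == 0:
        return 0.0
    if gs_ms <= 0:
        raise ValueError("stomatal conductance must be positive")
    flux = (met.c_leaf - met.c_air) / (1.0 / gs_ms + r_a) * 3600.0 / traits.lai
    return max(flux, 0.0)


def cooling_energy(t_f: float) -> float:
    """Evaporative cooling power (W m-2) of a transpiration flux.

    E = T * Lv / 3600 with Lv = 2450 J per gram of water; the input is in
    g (= ml) of water per m2 per hour.
    """
    if t_f < 0:
        raise ValueError("transpiration flux must be nonnegative")
    return t_f * LATENT_HEAT_VAP / 3600.0


def par_from_global(rad_global: float) -> float:
    """Photosynthetically active radiation (umol m-2 s-1) at canopy top."""
    return rad_global * PAR_PER_GLOBAL
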