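"""Hourly soil water balance and the drought control on stomatal conductance.

A three-layer bucket model closes the budget P = T + I + E + R + S + dStorage
each hour: precipitation is first intercepted by the canopy (capacity
linear in LAI), a fixed fraction of throughfall runs off sealed surfaces,
the rest infiltrates the top layer; water moves between layers in
proportion to their relative-water-content difference, scaled by the
saturated conductivity; excess above field capacity in the bottom layer
leaves as seepage. Transpiration and soil evaporation draw the profile
down, never below the wilting point. The thickness-weighted root-zone
water content defines the drought index

    DI = (water content - wilting point) / (field capacity - wilting point)

which maps piecewise-linearly onto the Ball-Berry slope (3 when DI <= 0.3,
10 when DI >= 0.5, linear in between).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MM_PER_M = 1000.0
INTERCEPT_CAPACITY_PER_LAI = 0.2  # mm of canopy storage per unit LAI
#: 1 mmol H2O m-2 s-1 = 18 mg m-2 s-1 = 64.8 g m-2 h-1 = 0.0648 mm h-1
MM_PER_MMOL_H2O_HOUR = 0.0648


@dataclass(frozen=True)
class SoilProfile:
    """Hydraulic description of the three-layer soil column.

    Volumetric constants default to a loam-like soil; layer thicknesses and
    the runoff fraction are the main site-specific knobs (sealed squares:
    thinner layers, runoff_fraction 0.4).
    """

    layer_thickness: tuple[float, float, float] = (0.2, 0.3, 0.5)  # m
    field_capacity: tuple[float, float, float] = (0.32, 0.32, 0.32)
    wilting_point: tuple[float, float, float] = (0.12, 0.12, 0.12)
    porosity: tuple[float, float, float] = (0.45, 0.45, 0.45)
    k_sat: float = 2.0            # mm h-1
    runoff_fraction: float = 0.0  # fraction of throughfall shed
    evap_depth: float = 0.3       # m, soil evaporation supply depth

    def __post_init__(self) -> None:
        for wp, fc, po in zip(self.wilting_point, self.field_capacity, self.porosity):
            if not wp < fc < po:
                raise ValueError("require wilting_point < field_capacity < porosity")
        if not 0.0 <= self.runoff_fraction <= 1.0:
            raise ValueError("runoff_fraction must be in [0, 1]")

    # per-layer storages expressed in mm of water
    def water_at(self, theta: np.ndarray) -> np.ndarray:
        return theta * np.asarray(self.layer_thickness) * MM_PER_M

    @property
    def wp_mm(self) -> np.ndarray:
        return self.water_at(np.asarray(self.wilting_point))

    @property
    def fc_mm(self) -> np.ndarray:
        return self.water_at(np.asarray(self.field_capacity))

    @property
    def sat_mm(self) -> np.ndarray:
        return self.water_at(np.asarray(self.porosity))


@dataclass
class SoilState:
    """Evolving water storages (mm) and cumulative flux bookkeeping."""

    water_mm: np.ndarray            # per-layer stored water, mm
    intercept_store: float = 0.0    # canopy-retained water, mm
    cum: dict = field(default_factory=lambda: {
        "P": 0.0, "T": 0.0, "I": 0.0, "E": 0.0, "R": 0.0, "S": 0.0})

    @classmethod
    def initialize(cls, profile: SoilProfile, rwc: float = 1.0) -> "SoilState":
        """Start all layers at the given relative water content (1 = field capacity)."""
        rwc = float(rwc)
        water = profile.wp_mm + rwc * (profile.fc_mm - profile.wp_mm)
        return cls(water_mm=np.minimum(water, profile.sat_mm))

    def rwc(self, profile: SoilProfile) -> np.ndarray:
        """Per-layer relative water content on the (field capacity - wilting point) span."""
        return (self.water_mm - profile.wp_mm) / (profile.fc_mm - profile.wp_mm)

    def total_storage(self) -> float:
        return float(np.sum(self.water_mm)) + self.intercept_store

    def copy(self) -> "SoilState":
        return SoilState(water_mm=self.water_mm.copy(),
                         intercept_store=self.intercept_store,
                         cum=dict(self.cum))


@dataclass(frozen=True)
class DroughtResponse:
    di: float     # drought index, 0 at wilting point, 1 at field capacity
    m_eff: float  # effective Ball-Berry slope in [3, 10]


# ---------------------------------------------------------------------------
# flux operations (each mutates a copy-owned state in place)
# ---------------------------------------------------------------------------

def intercept_rain(precip: float, lai: float, state: SoilState) -> float:
    """Fill the canopy interception store; return throughfall (mm).

    Storage capacity is 0.2 mm per unit LAI; anything beyond the remaining
    capacity passes through.
    """
    if precip < 0:
        raise ValueError("precipitation must be nonnegative")
    capacity = INTERCEPT_CAPACITY_PER_LAI * lai
    room = max(capacity - state.intercept_store, 0.0)
    stored = min(precip, room)
    state.intercept_store += stored
    state.cum["P"] += precip
    return precip - stored


def evaporate_interception(demand: float, state: SoilState) -> float:
    """Evaporate canopy-retained water against the demand; return the flux I (mm)."""
    evap = min(max(demand, 0.0), state.intercept_store)
    state.intercept_store -= evap
    state.cum["I"] += evap
    return evap


def apply_runoff(throughfall: float, profile: SoilProfile,
                 state: SoilState) -> tuple[float, float]:
    """Split throughfall into (infiltration, runoff) and add water to layer 1.

    Infiltration beyond the top layer's saturation deficit is shed as
    additional runoff so the column never exceeds porosity.
    """
    runoff = profile.runoff_fraction * throughfall
    infiltration = throughfall - runoff
    deficit = float(profile.sat_mm[0] - state.water_mm[0])
    if infiltration > deficit:
        runoff += infiltration - deficit
        infiltration = deficit
    state.water_mm[0] += infiltration
    state.cum["R"] += runoff
    return infiltration, runoff


def redistribute_layers(state: SoilState, profile: SoilProfile, dt: float = 1.0) -> float:
    """Move water between adjacent layers and drain the bottom; return seepage (mm).

    The inter-layer flux is k_sat * (rwc_i - rwc_{i+1}) * dt, clipped so no
    layer drops below the wilting point or exceeds porosity. Water above
    field capacity in layer 3 percolates out as seepage at up to k_sat * dt.
    """
    rwc = state.rwc(profile)
    for i in range(2):
        q = profile.k_sat * (rwc[i] - rwc[i + 1]) * dt
        if q > 0:
            q = min(q, state.water_mm[i] - profile.wp_mm[i],
                    profile.sat_mm[i + 1] - state.water_mm[i + 1])
        else:
            q = -min(-q, state.water_mm[i + 1] - profile.wp_mm[i + 1],
                     profile.sat_mm[i] - state.water_mm[i])
        state.water_mm[i] -= q
        state.water_mm[i + 1] += q
    excess = max(state.water_mm[2] - profile.fc_mm[2], 0.0)
    seepage = min(excess, profile.k_sat * dt)
    state.water_mm[2] -= seepage
    state.cum["S"] += seepage
    return seepage


def plant_water_demand(a_net: float, wue: float) -> float:
    """Water demand (mm h-1) implied by photosynthesis at the given WUE.

    A umol CO2 m-2 s-1 at ``wue`` umol CO2 per mmol H2O costs A/wue mmol H2O
    m-2 s-1, i.e. A/wue * 0.0648 mm h-1 of ground-equivalent water.
    """
    if wue <= 0:
        raise ValueError("water-use efficiency must be positive")
    return max(a_net, 0.0) / wue * MM_PER_MMOL_H2O_HOUR


def extract_et(state: SoilState, demand_pot: float, transp_demand: float,
               profile: SoilProfile) -> tuple[float, float]:
    """Withdraw transpiration and soil evaporation; return (t_actual, e_soil) in mm.

    Transpiration is the minimum of the remaining potential-ET demand and the
    plant demand, drawn from the rooted layers in proportion to their
    extractable water; soil evaporation then takes the residual demand from
    water above the wilting point within ``evap_depth``. No draw takes a
    layer below its wilting point.
    """
    if demand_pot < 0 or transp_demand < 0:
        raise ValueError("demands must be nonnegative")
    avail = np.maximum(state.water_mm - profile.wp_mm, 0.0)
    total_avail = float(avail.sum())

    t_target = min(demand_pot, transp_demand)
    t_actual = min(t_target, total_avail)
    if t_actual > 0:
        draw = avail / total_avail * t_actual
        state.water_mm -= draw
        avail -= draw

    residual = max(demand_pot - t_actual, 0.0)
    # fraction of each layer lying within the evaporation supply depth
    depths = np.asarray(profile.layer_thickness)
    tops = np.concatenate(([0.0], np.cumsum(depths)[:-1]))
    frac = np.clip((profile.evap_depth - tops) / depths, 0.0, 1.0)
    evap_avail = avail * frac
    e_soil = min(residual, float(evap_avail.sum()))
    if e_soil > 0:
        draw = evap_avail / evap_avail.sum() * e_soil
        state.water_mm -= draw

    state.cum["T"] += t_actual
    state.cum["E"] += e_soil
    return t_actual, e_soil


# ---------------------------------------------------------------------------
# drought index
# ---------------------------------------------------------------------------

def ball_berry_slope(di: float) -> float:
    """Piecewise drought mapping of the Ball-Berry slope m.

    m = 3 for DI <= 0.3, m = 3 + 35 (DI - 0.3) for 0.3 < DI < 0.5, m = 10
    for DI >= 0.5.
    """
    if di <= 0.3:
        return 3.0
    if di >= 0.5:
        return 10.0
    return 3.0 + 35.0 * (di - 0.3)


def drought_index(state: SoilState, profile: SoilProfile) -> DroughtResponse:
    """Root-zone drought index and the resulting Ball-Berry slope.

    The water content entering DI is the thickness-weighted mean over all
    three layers.
    """
    depths = np.asarray(profile.layer_thickness)
    theta = state.water_mm / (depths * MM_PER_M)
    theta_bar = float(np.average(theta, weights=depths))
    wp_bar = float(np.average(profile.wilting_point, weights=depths))
    fc_bar = float(np.average(profile.field_capacity, weights=depths))
    di = (theta_bar - wp_bar) / (fc_bar - wp_bar)
    return DroughtResponse(di=di, m_eff=ball_berry_slope(di))


def balance_residual(state: SoilState, initial_storage: float) -> float:
    """P - (T + I + E + R + S) - dStorage over the run so far (mm); ~0 if closed."""
    c = state.cum
    outflux = c["T"] + c["I"] + c["E"] + c["R"] + c["S"]
    return c["P"] - outflux - (state.total_storage() - initial_storage)
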