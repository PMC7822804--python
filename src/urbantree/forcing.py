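"""Weather forcing: reading, validation, and derived hourly meteorology.

Turns a raw hourly (or 15-min) weather series into the quantities the
tree and pavement models consume each hour: vapor pressures and
concentrations, a direct/diffuse split of global radiation, friction
velocity from a neutral log wind profile, and the daily potential
evapotranspiration demand that drives the soil water balance.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from datetime import datetime, timedelta

import numpy as np
import pandas as pd

log = logging.getLogger("urbantree")

# physical constants
M_WATER = 18.0          # molecular weight of water, g mol-1
R_GAS = 8.314           # universal gas constant, J mol-1 K-1
KARMAN = 0.41           # von Karman constant
SOLAR_CONSTANT = 1370.0 # W m-2
KPA_TO_MMHG = 7.50062   # 1 kPa in mmHg
WIND_FLOOR = 0.1        # m s-1, prevents infinite resistances in calm hours

#: canonical forcing columns, in file order
FORCING_COLUMNS = ["timestamp", "t_air", "rh", "pressure", "wind", "rad_global", "precip"]


class SchemaError(ValueError):
    """A required forcing column is absent or unmappable."""


class ForcingFormatError(ValueError):
    """Timestamps are non-monotonic or irregular beyond repair."""


@dataclass(frozen=True)
class SiteGeometry:
    """Location and heights needed for solar geometry and the wind profile."""

    latitude: float          # deg, positive north
    longitude: float         # deg, positive east
    sensor_height: float     # m, height of the wind/temperature sensor
    tree_height: float       # m
    utc_offset: float = 1.0  # h, local standard time offset (CET = +1)

    def __post_init__(self) -> None:
        if not -90.0 <= self.latitude <= 90.0:
            raise ValueError(f"latitude out of range: {self.latitude}")
        if self.sensor_height <= 0:
            raise ValueError("sensor height must be positive")


@dataclass(frozen=True)
class MeteoRecord:
    """One validated hour of raw weather forcing."""

    timestamp: datetime
    t_air: float       # deg C
    rh: float          # fraction 0-1
    pressure: float    # kPa
    wind: float        # m s-1
    rad_global: float  # W m-2
    precip: float      # mm h-1
    missing: bool = False  # True when the hour was a gap too long to interpolate


@dataclass(frozen=True)
class DerivedMeteo:
    """Per-hour derived meteorological quantities."""

    e_sat: float        # kPa
    e_act: float        # kPa
    vpd: float          # kPa
    vp_mmhg: float      # actual vapor pressure, mmHg (for emissivity formulas)
    rad_direct: float   # W m-2
    rad_diffuse: float  # W m-2
    u_star: float       # m s-1
    c_air: float        # g m-3
    c_leaf: float       # g m-3


# ---------------------------------------------------------------------------
# reading & validation
# ---------------------------------------------------------------------------

def read_forcing(path, schema: dict[str, str] | None = None) -> pd.DataFrame:
    """Read a forcing CSV into a validated hourly DataFrame.

    Parameters
    ----------
    path:
        CSV file with columns ``timestamp,t_air,rh,pressure,wind,rad_global,precip``
        (ISO-8601 timestamps). 15-min data are aggregated to hours (mean;
        precipitation summed).
    schema:
        Optional mapping from canonical column name to the name used in the
        file, e.g. ``{"t_air": "Temp"}``.

    Returns
    -------
    DataFrame indexed 0..n-1 with the canonical columns plus a boolean
    ``missing`` flag. Gaps of up to 3 h are filled by linear interpolation;
    longer gaps are retained as rows flagged missing.
    """
    df = pd.read_csv(path)
    schema = schema or {}
    rename = {v: k for k, v in schema.items()}
    df = df.rename(columns=rename)
    for col in FORCING_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"forcing file is missing required column {col!r}")
    df = df[FORCING_COLUMNS].copy()
    df["timestamp"] = pd.to_datetime(df["timestamp"])
    if not df["timestamp"].is_monotonic_increasing or df["timestamp"].duplicated().any():
        raise ForcingFormatError("timestamps must be strictly increasing")

    # RH unit sniffing: values look like percent -> rescale to fraction
    if df["rh"].max() > 1.5:
        log.warning("relative humidity looks like percent (max %.1f); rescaling to fraction",
                    df["rh"].max())
        df["rh"] = df["rh"] / 100.0

    df = df.set_index("timestamp")
    step = df.index.to_series().diff().dropna().min()
    if step < pd.Timedelta(hours=1):
        # sub-hourly (e.g. 15-min): aggregate to hours
        agg = {c: "mean" for c in df.columns}
        agg["precip"] = "sum"
        df = df.resample("1h").agg(agg)
    else:
        df = df.resample("1h").asfreq()

    missing = df["t_air"].isna()
    if missing.any():
        # interpolate short gaps (<= 3 h); leave longer gaps flagged
        filled = df.interpolate(method="time", limit=3, limit_area="inside")
        gap_id = (~missing).cumsum()
        gap_len = missing.groupby(gap_id).transform("sum")
        short = missing & (gap_len <= 3) & ~filled["t_air"].isna()
        df[short] = filled[short]
        missing = df["t_air"].isna()
        if missing.any():
            log.warning("%d hours remain missing after interpolation", int(missing.sum()))
        df.loc[missing, "precip"] = df.loc[missing, "precip"].fillna(0.0)

    df = df.reset_index()
    df["missing"] = missing.to_numpy()
    _validate_ranges(df)
    return df


def _validate_ranges(df: pd.DataFrame) -> None:
    ok = df[~df["missing"]]
    for col, lo in (("rh", 0.0), ("rad_global", 0.0), ("precip", 0.0), ("wind", 0.0)):
        if (ok[col] < lo).any():
            raise ForcingFormatError(f"column {col!r} has values below {lo}")
    if (ok["rh"] > 1.0 + 1e-9).any():
        raise ForcingFormatError("relative humidity exceeds 1 after unit scaling")


def iter_records(df: pd.DataFrame):
    """Yield one :class:`MeteoRecord` per row of a validated forcing frame."""
    for row in df.itertuples(index=False):
        yield MeteoRecord(
            timestamp=row.timestamp.to_pydatetime(),
            t_air=float(row.t_air) if not row.missing else math.nan,
            rh=float(row.rh) if not row.missing else math.nan,
            pressure=float(row.pressure) if not row.missing else math.nan,
            wind=float(row.wind) if not row.missing else math.nan,
            rad_global=float(row.rad_global) if not row.missing else math.nan,
            precip=float(row.precip),
            missing=bool(row.missing),
        )


# ---------------------------------------------------------------------------
# vapor pressure and concentration
# ---------------------------------------------------------------------------

def saturation_vapor_pressure(t_air: float) -> float:
    """Saturation vapor pressure (kPa) from the Magnus formula.

    Uses the FAO-56 coefficients 0.6108 / 17.27 / 237.3.
    """
    if not -40.0 <= t_air <= 60.0:
        raise ValueError(f"air temperature {t_air} degC outside supported range [-40, 60]")
    return 0.6108 * math.exp(17.27 * t_air / (t_air + 237.3))


def vapor_concentrations(t_air: float, rh: float) -> tuple[float, float]:
    """Water vapor concentrations (g m-3) at leaf (saturation) and in air.

    c = M_w * e / (R * T) with e in Pa and T in K. The leaf is assumed to be
    at air temperature (no leaf energy balance), so c_leaf is the saturation
    concentration at ``t_air``.
    """
    if not 0.0 <= rh <= 1.0:
        raise ValueError(f"relative humidity {rh} outside [0, 1]")
    t_k = t_air + 273.15
    e_sat_pa = saturation_vapor_pressure(t_air) * 1000.0
    c_leaf = M_WATER * e_sat_pa / (R_GAS * t_k)
    c_air = c_leaf * rh
    return c_leaf, c_air


# ---------------------------------------------------------------------------
# solar geometry (standard astronomical formulas)
# ---------------------------------------------------------------------------

def solar_declination(day_of_year: int) -> float:
    """Solar declination (radians), Cooper's formula."""
    return math.radians(23.45) * math.sin(2.0 * math.pi * (284 + day_of_year) / 365.0)


def equation_of_time(day_of_year: int) -> float:
    """Equation of time (minutes), Spencer series."""
    b = 2.0 * math.pi * (day_of_year - 1) / 365.0
    return 229.18 * (0.000075 + 0.001868 * math.cos(b) - 0.032077 * math.sin(b)
                     - 0.014615 * math.cos(2 * b) - 0.04089 * math.sin(2 * b))


def solar_elevation(timestamp: datetime, site: SiteGeometry) -> float:
    """Sine of the solar elevation angle at ``timestamp`` (local standard time).

    Evaluated at the given instant; callers integrating over an hour should
    pass the mid-hour time.
    """
    doy = timestamp.timetuple().tm_yday
    decl = solar_declination(doy)
    hours = timestamp.hour + timestamp.minute / 60.0 + timestamp.second / 3600.0
    solar_time = hours + (site.longitude - 15.0 * site.utc_offset) / 15.0 \
        + equation_of_time(doy) / 60.0
    hour_angle = math.radians(15.0 * (solar_time - 12.0))
    lat = math.radians(site.latitude)
    sin_beta = (math.sin(lat) * math.sin(decl)
                + math.cos(lat) * math.cos(decl) * math.cos(hour_angle))
    return sin_beta


def daylength_hours(day_of_year: int, latitude: float) -> float:
    """Astronomical daylength (h) at the given latitude and day of year."""
    decl = solar_declination(day_of_year)
    lat = math.radians(latitude)
    x = -math.tan(lat) * math.tan(decl)
    x = min(1.0, max(-1.0, x))
    return 2.0 * math.degrees(math.acos(x)) / 15.0


# ---------------------------------------------------------------------------
# radiation partition (Spitters et al. 1986 hourly regressions)
# ---------------------------------------------------------------------------

def partition_radiation(rad_global: float, timestamp: datetime,
                        site: SiteGeometry) -> tuple[float, float]:
    """Split global shortwave into (direct, diffuse) components (W m-2).

    The diffuse fraction follows the hourly clearness-index regressions of
    Spitters, with the clearness index computed against extraterrestrial
    radiation on a horizontal plane at mid-hour solar elevation. Components
    always sum to ``rad_global``.
    """
    if rad_global < 0:
        raise ValueError("global radiation must be nonnegative")
    if rad_global == 0.0:
        return 0.0, 0.0
    sin_beta = solar_elevation(timestamp + timedelta(minutes=30), site)
    if sin_beta <= 0.0:
        if rad_global > 5.0:
            log.warning("%.0f W m-2 global radiation with sun below horizon at %s; "
                        "treating as all-diffuse", rad_global, timestamp)
        return 0.0, rad_global

    doy = timestamp.timetuple().tm_yday
    s0 = SOLAR_CONSTANT * (1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)) * sin_beta
    kt = min(rad_global / s0, 1.0)

    if kt <= 0.22:
        fd = 1.0
    elif kt <= 0.35:
        fd = 1.0 - 6.4 * (kt - 0.22) ** 2
    else:
        fd = 1.47 - 1.66 * kt
    # lower bound for very clear hours (circumsolar term)
    r = 0.847 - 1.61 * sin_beta + 1.04 * sin_beta ** 2
    fd = max(fd, r)
    fd = min(max(fd, 0.0), 1.0)

    rad_diffuse = fd * rad_global
    return rad_global - rad_diffuse, rad_diffuse


# ---------------------------------------------------------------------------
# friction velocity (neutral log profile)
# ---------------------------------------------------------------------------

def friction_velocity(wind: float, site: SiteGeometry) -> float:
    """Friction velocity (m s-1) from a neutral logarithmic wind profile.

    u* = k * u(z) / ln((z - d)/z0) with zero-plane displacement d = 0.67 h
    and roughness length z0 = 0.1 h (h = tree height). The wind speed is
    floored at 0.1 m s-1 so calm hours do not produce infinite resistances.
    """
    if wind < 0:
        raise ValueError("wind speed must be nonnegative")
    d = 0.67 * site.tree_height
    z0 = 0.1 * site.tree_height
    if site.sensor_height <= d + z0:
        raise ValueError(
            f"sensor height {site.sensor_height} m is below the displacement height "
            f"plus roughness length ({d + z0:.1f} m) of a {site.tree_height} m tree")
    u = max(wind, WIND_FLOOR)
    return KARMAN * u / math.log((site.sensor_height - d) / z0)


# ---------------------------------------------------------------------------
# derived-meteo assembly
# ---------------------------------------------------------------------------

def derive_meteo(rec: MeteoRecord, site: SiteGeometry) -> DerivedMeteo:
    """Compute the full set of per-hour derived quantities for one record."""
    e_sat = saturation_vapor_pressure(rec.t_air)
    e_act = e_sat * rec.rh
    c_leaf, c_air = vapor_concentrations(rec.t_air, rec.rh)
    rad_direct, rad_diffuse = partition_radiation(rec.rad_global, rec.timestamp, site)
    u_star = friction_velocity(rec.wind, site)
    return DerivedMeteo(
        e_sat=e_sat,
        e_act=e_act,
        vpd=e_sat - e_act,
        vp_mmhg=e_act * KPA_TO_MMHG,
        rad_direct=rad_direct,
        rad_diffuse=rad_diffuse,
        u_star=u_star,
        c_air=c_air,
        c_leaf=c_leaf,
    )


# ---------------------------------------------------------------------------
# potential evapotranspiration (Thornthwaite family)
# ---------------------------------------------------------------------------

#: Munich-like climatological monthly mean temperatures (degC), used as the
#: fallback when the simulated period does not span a full year.
DEFAULT_MONTHLY_NORMALS = [-0.4, 0.5, 4.6, 9.0, 13.6, 16.9, 19.0, 18.5,
                           14.2, 9.5, 4.0, 0.6]


def heat_index(monthly_means: list[float] | np.ndarray) -> float:
    """Thornthwaite annual heat index I = sum((T/5)^1.514) over T > 0."""
    t = np.asarray(monthly_means, dtype=float)
    t = t[t > 0.0]
    return float(np.sum((t / 5.0) ** 1.514))


def daily_potential_et(t_max: float, t_min: float, day_of_year: int,
                       site: SiteGeometry,
                       annual_heat_index: float | None = None) -> float:
    """Daily potential evapotranspiration (mm day-1), Thornthwaite family.

    The daily driver is the effective temperature of Camargo,
    Tef = 0.36 (3 Tmax - Tmin), corrected for photoperiod after Pereira and
    Pruitt by the factor N/(24 - N) (N = astronomical daylength) and
    constrained to the day's temperature range Tmin <= Tef <= Tmax; the
    correction embeds the latitude dependence, so no further daylength
    factor enters. The corrected temperature drives the Thornthwaite power
    law per 30-day month. The hourly demand used by the water balance is
    this value divided by 24.
    """
    if t_max < t_min:
        raise ValueError("t_max must be >= t_min")
    if annual_heat_index is None:
        annual_heat_index = heat_index(DEFAULT_MONTHLY_NORMALS)
    n_day = daylength_hours(day_of_year, site.latitude)
    tef = 0.36 * (3.0 * t_max - t_min) * n_day / (24.0 - n_day)
    tef = min(max(tef, t_min), t_max)
    if tef <= 0.0:
        return 0.0
    i = annual_heat_index
    a = 6.75e-7 * i ** 3 - 7.71e-5 * i ** 2 + 1.7912e-2 * i + 0.49239
    pet_month = 16.0 * (10.0 * tef / i) ** a
    return pet_month / 30.0
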