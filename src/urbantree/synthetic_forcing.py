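"""Synthetic hourly weather generator for tests and demonstrations.

Produces statistically plausible Central-European (Munich-like) summer
forcing so the whole simulator can be exercised without external data:
a sinusoidal diurnal temperature cycle with AR(1) noise, clear-sky solar
geometry modulated by stochastic cloud transmissivity, relative humidity
anti-correlated with the temperature anomaly, AR(1) wind around a
site-specific mean, and convective rain as a marked Poisson process with
exponential depths. Everything is reproducible from a seed. The generated
series are plausible stand-ins for measured city weather, not
observations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from datetime import date, datetime, timedelta

import numpy as np
import pandas as pd

from .forcing import FORCING_COLUMNS, SOLAR_CONSTANT, SiteGeometry, solar_elevation


@dataclass(frozen=True)
class ForcingSpec:
    """Statistical description of the weather regime to generate."""

    start: date = date(2015, 7, 1)
    end: date = date(2015, 8, 31)          # inclusive
    latitude: float = 48.13
    longitude: float = 11.58
    utc_offset: float = 1.0                 # local standard time (CET)
    t_mean: float = 20.0                    # degC, period-mean temperature
    t_amplitude: float = 6.0                # degC, half peak-to-trough diurnal swing
    t_seasonal_amplitude: float = 0.0       # degC, slow within-period drift amplitude
    t_noise_sd: float = 1.0                 # degC, AR(1) innovation s.d.
    t_persistence: float = 0.8              # AR(1) coefficient (hourly)
    rh_mean: float = 0.65                   # fraction, period mean
    rh_temp_slope: float = 0.03             # RH drop per degC of warm anomaly
    wind_mean: float = 0.9                  # m s-1
    wind_persistence: float = 0.9
    wind_noise_sd: float = 0.15             # m s-1
    pressure: float = 95.6                  # kPa (Munich altitude)
    clear_sky_transmissivity: float = 0.75
    cloud_persistence: float = 0.85
    cloud_noise_sd: float = 0.25            # s.d. of the latent cloud factor (0 = steady sky)
    clear_sky_fraction: float = 0.6         # mean of the cloud modulation factor
    rain_events_per_day: float = 0.15
    rain_mean_depth: float = 5.0            # mm per event
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_amplitude < 0 or self.rain_events_per_day < 0:
            raise ValueError("amplitudes and rates must be nonnegative")
        if not 0.0 <= self.t_persistence < 1.0:
            raise ValueError("persistence must be in [0, 1)")


#: named regimes used by the demos and tests
PRESETS: dict[str, dict] = {
    # hot, dry Central-European summer with sparse convective rain
    "munich_summer": dict(t_mean=21.0, t_amplitude=6.5, rh_mean=0.6,
                          rain_events_per_day=0.15, rain_mean_depth=5.0),
    # prolonged rain-free heat spell
    "heatwave": dict(t_mean=26.0, t_amplitude=7.0, rh_mean=0.45,
                     rain_events_per_day=0.0, clear_sky_fraction=0.85),
    # cool, wet, overcast spell
    "wet_cool": dict(t_mean=14.0, t_amplitude=4.0, rh_mean=0.85,
                     rain_events_per_day=1.0, rain_mean_depth=4.0,
                     clear_sky_fraction=0.3),
}


def spec_from_preset(name: str, **overrides) -> ForcingSpec:
    """Build a :class:`ForcingSpec` from a named preset with overrides."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(PRESETS)}")
    params = dict(PRESETS[name])
    params.update(overrides)
    return ForcingSpec(**params)


def generate(spec: ForcingSpec) -> pd.DataFrame:
    """Generate an hourly forcing DataFrame in the standard column layout.

    Deterministic for a given spec (including its seed); all records
    satisfy the forcing invariants (rh in [0.15, 1], nonnegative wind,
    radiation, and precipitation, zero radiation while the sun is down).
    """
    rng = np.random.default_rng(spec.seed)
    t0 = datetime(spec.start.year, spec.start.month, spec.start.day)
    n_hours = ((spec.end - spec.start).days + 1) * 24
    times = [t0 + timedelta(hours=h) for h in range(n_hours)]
    site = SiteGeometry(latitude=spec.latitude, longitude=spec.longitude,
                        sensor_height=10.0, tree_height=1.0,
                        utc_offset=spec.utc_offset)

    hours = np.arange(n_hours)
    local_hour = hours % 24

    # temperature: mean + slow drift + diurnal sinusoid (max ~15:00) + AR(1)
    drift = spec.t_seasonal_amplitude * np.sin(2 * math.pi * hours / (n_hours + 1e-9))
    diurnal = spec.t_amplitude * np.sin(2 * math.pi * (local_hour - 9.0) / 24.0)
    noise = _ar1(rng, n_hours, spec.t_persistence, spec.t_noise_sd)
    t_air = spec.t_mean + drift + diurnal + noise

    # rain: marked Poisson process, exponential depths spread over 1-3 h
    precip = np.zeros(n_hours)
    n_days = n_hours // 24
    n_events = rng.poisson(spec.rain_events_per_day * n_days)
    for _ in range(n_events):
        start_h = int(rng.integers(0, n_hours))
        depth = rng.exponential(spec.rain_mean_depth)
        span = int(rng.integers(1, 4))
        for k in range(span):
            if start_h + k < n_hours:
                precip[start_h + k] += depth / span

    # cloud modulation: AR(1) latent factor mapped into [0.15, 1], damped in rain
    latent = _ar1(rng, n_hours, spec.cloud_persistence, spec.cloud_noise_sd)
    cloud = np.clip(spec.clear_sky_fraction + latent, 0.15, 1.0)
    cloud = np.where(precip > 0, np.minimum(cloud, 0.25), cloud)

    rad_global = np.zeros(n_hours)
    for i, ts in enumerate(times):
        sin_beta = solar_elevation(ts + timedelta(minutes=30), site)
        if sin_beta > 0.0:
            doy = ts.timetuple().tm_yday
            s0 = SOLAR_CONSTANT * (1 + 0.033 * math.cos(2 * math.pi * doy / 365.0))
            rad_global[i] = s0 * sin_beta * spec.clear_sky_transmissivity * cloud[i]

    # relative humidity: anti-correlated with the temperature anomaly
    rh = spec.rh_mean - spec.rh_temp_slope * (t_air - spec.t_mean) \
        + rng.normal(0.0, 0.03, n_hours)
    rh = np.where(precip > 0, np.maximum(rh, 0.9), rh)
    rh = np.clip(rh, 0.15, 1.0)

    wind = spec.wind_mean + _ar1(rng, n_hours, spec.wind_persistence, spec.wind_noise_sd)
    wind = np.maximum(wind, 0.0)

    pressure = np.full(n_hours, spec.pressure)

    df = pd.DataFrame({
        "timestamp": pd.to_datetime(times),
        "t_air": t_air,
        "rh": rh,
        "pressure": pressure,
        "wind": wind,
        "rad_global": rad_global,
        "precip": precip,
    })[FORCING_COLUMNS]
    df["missing"] = False
    return df


def _ar1(rng: np.random.Generator, n: int, phi: float, innovation_sd: float) -> np.ndarray:
    """Stationary zero-mean AR(1) series with the given marginal innovation s.d."""
    x = np.empty(n)
    scale = innovation_sd * math.sqrt(max(1.0 - phi * phi, 1e-12))
    x[0] = rng.normal(0.0, innovation_sd)
    eps = rng.normal(0.0, scale, n)
    for i in range(1, n):
        x[i] = phi * x[i - 1] + eps[i]
    return x
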