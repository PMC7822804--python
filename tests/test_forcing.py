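"""Forcing module: file reading, derived meteorology, radiation, PET."""

import math
from datetime import datetime

import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from urbantree import forcing as fo

SITE = fo.SiteGeometry(latitude=48.13, longitude=11.58,
                       sensor_height=20.0, tree_height=15.0, utc_offset=1.0)


# ---------------------------------------------------------------------------
# reading & aggregation
# ---------------------------------------------------------------------------

def _write_forcing(tmp_path, rows, columns=None):
    columns = columns or fo.FORCING_COLUMNS
    path = tmp_path / "forcing.csv"
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return path


def test_quarter_hour_rows_aggregate_to_hourly_means_and_precip_sums(tmp_path):
    rows = [[f"2015-07-01T10:{m:02d}", t, 0.5, 95.6, 1.0, 500.0, 0.5]
            for m, t in zip((0, 15, 30, 45), (20.0, 21.0, 22.0, 23.0))]
    df = fo.read_forcing(_write_forcing(tmp_path, rows))
    assert len(df) == 1
    assert df.loc[0, "t_air"] == pytest.approx(21.5)
    assert df.loc[0, "precip"] == pytest.approx(2.0)


def test_missing_column_raises_schema_error_naming_it(tmp_path):
    cols = [c for c in fo.FORCING_COLUMNS if c != "wind"]
    rows = [["2015-07-01T10:00", 20.0, 0.5, 95.6, 500.0, 0.0]]
    with pytest.raises(fo.SchemaError, match="wind"):
        fo.read_forcing(_write_forcing(tmp_path, rows, cols))


def test_schema_remap_and_percent_humidity_rescaling(tmp_path):
    rows = [[f"2015-07-01T{h:02d}:00", 20.0, 55.0, 95.6, 1.0, 400.0, 0.0]
            for h in (10, 11)]
    cols = ["timestamp", "Temp", "rh", "pressure", "wind", "rad_global", "precip"]
    df = fo.read_forcing(_write_forcing(tmp_path, rows, cols),
                         schema={"t_air": "Temp"})
    assert df.loc[0, "t_air"] == 20.0
    assert df.loc[0, "rh"] == pytest.approx(0.55)


def test_short_gaps_interpolated_long_gaps_flagged(tmp_path):
    hours = [0, 1, 4, 5, 11, 12]  # one 2-h gap (filled), one 5-h gap (flagged)
    rows = [[f"2015-07-01T{h:02d}:00", 20.0 + h, 0.5, 95.6, 1.0, 0.0, 0.0]
            for h in hours]
    df = fo.read_forcing(_write_forcing(tmp_path, rows))
    assert len(df) == 13
    filled = df[df["timestamp"] == "2015-07-01T02:00"]
    assert not filled["missing"].iloc[0]
    assert filled["t_air"].iloc[0] == pytest.approx(22.0)
    assert df["missing"].sum() == 5


def test_non_monotonic_timestamps_rejected(tmp_path):
    rows = [["2015-07-01T11:00", 20.0, 0.5, 95.6, 1.0, 0.0, 0.0],
            ["2015-07-01T10:00", 20.0, 0.5, 95.6, 1.0, 0.0, 0.0]]
    with pytest.raises(fo.ForcingFormatError):
        fo.read_forcing(_write_forcing(tmp_path, rows))


# ---------------------------------------------------------------------------
# vapor pressure & concentrations
# ---------------------------------------------------------------------------

def magnus_oracle(t):
    return 0.6108 * math.exp(17.27 * t / (t + 237.3))


@pytest.mark.parametrize("t, expected, tol", [(0.0, 0.611, 0.01), (20.0, 2.34, 0.03)])
def test_saturation_vapor_pressure_matches_magnus(t, expected, tol):
    assert fo.saturation_vapor_pressure(t) == pytest.approx(expected, abs=tol)
    assert fo.saturation_vapor_pressure(t) == pytest.approx(magnus_oracle(t), rel=1e-12)


def test_saturation_vapor_pressure_monotonic_and_bounded():
    assert fo.saturation_vapor_pressure(30.0) > fo.saturation_vapor_pressure(20.0)
    with pytest.raises(ValueError):
        fo.saturation_vapor_pressure(80.0)


def test_vapor_concentrations_ideal_gas_values():
    # hand evaluation: c = 18 * e[Pa] / (8.314 * 293.15)
    c_leaf, c_air = fo.vapor_concentrations(20.0, 0.5)
    assert c_leaf == pytest.approx(17.3, abs=0.1)
    assert c_air == pytest.approx(8.65, abs=0.05)


@given(t=st.floats(-20.0, 45.0), rh=st.floats(0.0, 1.0))
@settings(deadline=None, max_examples=50)
def test_leaf_minus_air_concentration_nonnegative(t, rh):
    c_leaf, c_air = fo.vapor_concentrations(t, rh)
    assert c_leaf - c_air >= -1e-12
    assert c_air == pytest.approx(rh * c_leaf)


def test_saturated_air_equalizes_concentrations():
    c_leaf, c_air = fo.vapor_concentrations(25.0, 1.0)
    assert c_leaf == pytest.approx(c_air)


# ---------------------------------------------------------------------------
# radiation partition
# ---------------------------------------------------------------------------

def test_partition_zero_radiation(site):
    assert fo.partition_radiation(0.0, datetime(2015, 7, 1, 12), site) == (0.0, 0.0)


def test_overcast_hour_is_all_diffuse(site):
    # 40 W m-2 at high sun: clearness index far below 0.22
    direct, diffuse = fo.partition_radiation(40.0, datetime(2015, 7, 1, 12), site)
    assert direct == pytest.approx(0.0, abs=1e-9)
    assert diffuse == pytest.approx(40.0)


def test_clear_midday_has_dominant_direct_beam(site):
    direct, diffuse = fo.partition_radiation(850.0, datetime(2015, 7, 1, 12), site)
    assert direct > diffuse


def test_night_radiation_assigned_diffuse(site):
    direct, diffuse = fo.partition_radiation(10.0, datetime(2015, 7, 1, 0), site)
    assert direct == 0.0 and diffuse == 10.0


@given(rad=st.floats(0.0, 1100.0), hour=st.integers(0, 23), day=st.integers(1, 28),
       month=st.integers(1, 12))
@settings(deadline=None, max_examples=80)
def test_partition_conserves_global_radiation(rad, hour, day, month):
    direct, diffuse = fo.partition_radiation(rad, datetime(2015, month, day, hour), SITE)
    assert direct + diffuse == pytest.approx(rad, abs=1e-6)
    assert direct >= 0.0 and diffuse >= 0.0


# ---------------------------------------------------------------------------
# friction velocity
# ---------------------------------------------------------------------------

def test_friction_velocity_log_profile_value(site):
    # u* = 0.41 * 1 / ln((20 - 0.67*15) / (0.1*15))
    expected = 0.41 / math.log((20.0 - 10.05) / 1.5)
    assert fo.friction_velocity(1.0, site) == pytest.approx(expected, rel=1e-9)
    assert expected == pytest.approx(0.217, abs=0.001)


def test_calm_wind_floored(site):
    assert fo.friction_velocity(0.0, site) == fo.friction_velocity(0.1, site)
    assert fo.friction_velocity(0.0, site) > 0.0


@given(u1=st.floats(0.0, 10.0), u2=st.floats(0.0, 10.0))
@settings(deadline=None, max_examples=50)
def test_friction_velocity_monotone_in_wind(u1, u2):
    lo, hi = sorted((u1, u2))
    assert fo.friction_velocity(hi, SITE) >= fo.friction_velocity(lo, SITE)


def test_sensor_below_displacement_height_rejected():
    short_mast = fo.SiteGeometry(48.0, 11.0, sensor_height=5.0, tree_height=15.0)
    with pytest.raises(ValueError, match="displacement"):
        fo.friction_velocity(1.0, short_mast)


# ---------------------------------------------------------------------------
# potential evapotranspiration
# ---------------------------------------------------------------------------

def pet_oracle(t_max, t_min, doy, lat, heat_idx):
    """Independent straight-line evaluation of the Camargo/Pereira-Pruitt
    daily Thornthwaite chain."""
    decl = math.radians(23.45) * math.sin(2 * math.pi * (284 + doy) / 365.0)
    cosarg = max(-1.0, min(1.0, -math.tan(math.radians(lat)) * math.tan(decl)))
    n = 2.0 * math.degrees(math.acos(cosarg)) / 15.0
    tef = 0.36 * (3.0 * t_max - t_min) * n / (24.0 - n)
    tef = min(max(tef, t_min), t_max)
    if tef <= 0.0:
        return 0.0
    a = 6.75e-7 * heat_idx ** 3 - 7.71e-5 * heat_idx ** 2 \
        + 1.7912e-2 * heat_idx + 0.49239
    return 16.0 * (10.0 * tef / heat_idx) ** a / 30.0


def test_munich_july_pet_matches_independent_oracle(site):
    heat_idx = fo.heat_index(fo.DEFAULT_MONTHLY_NORMALS)
    got = fo.daily_potential_et(30.0, 16.0, 200, site, heat_idx)
    assert got == pytest.approx(pet_oracle(30.0, 16.0, 200, site.latitude, heat_idx),
                                abs=0.05)
    assert 2.0 < got < 9.0  # plausible mm/day for a hot July day


def test_pet_zero_for_nonpositive_effective_temperature(site):
    assert fo.daily_potential_et(0.0, -5.0, 15, site) == 0.0


def test_pet_monotone_in_temperature(site):
    warm = fo.daily_potential_et(30.0, 15.0, 200, site)
    cool = fo.daily_potential_et(20.0, 10.0, 200, site)
    assert warm > cool


def test_pet_rejects_inverted_extremes(site):
    with pytest.raises(ValueError):
        fo.daily_potential_et(10.0, 20.0, 200, site)


def test_heat_index_ignores_subzero_months():
    assert fo.heat_index([10.0, -5.0]) == pytest.approx((10.0 / 5.0) ** 1.514)
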