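"""Shared fixtures: a demo site, tree traits, and cached long simulations."""

from datetime import date

import pytest

from urbantree import cli
from urbantree import simulator as sim
from urbantree.canopy_exchange import TreeTraits
from urbantree.forcing import SiteGeometry


@pytest.fixture
def site() -> SiteGeometry:
    """Munich-like site with the sensor above the canopy."""
    return SiteGeometry(latitude=48.13, longitude=11.58,
                        sensor_height=20.0, tree_height=15.0, utc_offset=1.0)


@pytest.fixture
def traits() -> TreeTraits:
    return TreeTraits(lai=2.5, height=15.0)


def _run_site(preset: str, seed: int, start: date, end: date):
    cfg = cli.load_config(preset)
    cfg["forcing"]["synthetic"]["start"] = start.isoformat()
    cfg["forcing"]["synthetic"]["end"] = end.isoformat()
    forcing, run_cfg = cli.build_run(cfg, seed=seed)
    hourly, summary = sim.run(forcing, run_cfg)
    return forcing, run_cfg, hourly, summary


@pytest.fixture(scope="session")
def two_site_runs():
    """60-day summer simulations of the open and sealed demo sites under
    identical synthetic forcing (same seed; configs differ in wind regime,
    soil depths, runoff fraction, and LAI)."""
    start, end = date(2015, 7, 1), date(2015, 8, 29)
    return {
        "open": _run_site("bordeaux", seed=11, start=start, end=end),
        "sealed": _run_site("pariser", seed=11, start=start, end=end),
    }
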