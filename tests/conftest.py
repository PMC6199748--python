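"""Shared fixtures: small geometric worlds and simulated data.

Everything is generated programmatically; no data files are shipped.
"""

import numpy as np
import pandas as pd
import pytest
from shapely.geometry import LineString, Polygon

from fjordtrack.geospatial import CoastModel, GeoPoint, LocalProjection
from fjordtrack.synthetic_data import WORLD_ORIGIN, ArchipelagoSpec, make_archipelago


@pytest.fixture(scope="session")
def world_projection():
    return LocalProjection(WORLD_ORIGIN)


@pytest.fixture(scope="session")
def halfplane_model(world_projection):
    """Land fills x >= 0 of the local frame; straight N-S coastline at x = 0."""
    proj = world_projection
    land_m = Polygon([(0, -300000), (400000, -300000), (400000, 300000), (0, 300000)])
    coast_m = LineString([(0, -300000), (0, 300000)])
    return CoastModel(
        "halfplane",
        land=[proj.project_inverse_geometry(land_m)],
        coastline=[proj.project_inverse_geometry(coast_m)],
        glacier_fronts=[],
        fjords=[],
    )


@pytest.fixture(scope="session")
def fjord_world():
    """Two-epoch archipelago from the default generator spec."""
    return make_archipelago(ArchipelagoSpec(seed=11))


@pytest.fixture(scope="session")
def simple_fjord_model(world_projection):
    """One square island with a single fjord notch and a glacier front.

    Built directly in the metre frame for easy hand-reasoning:
    land occupies x in [0, 60] km (y in [-50, 50] km) minus a fjord
    channel y in [-4, 4] km reaching x = 20 km, where a front line caps
    the fjord head.
    """
    proj = world_projection
    km = 1000.0
    land = Polygon([(0, -50 * km), (60 * km, -50 * km), (60 * km, 50 * km), (0, 50 * km)])
    channel = Polygon([(-1 * km, -4 * km), (20 * km, -4 * km), (20 * km, 4 * km), (-1 * km, 4 * km)])
    fjord = channel.intersection(land)
    land = land.difference(channel)
    front = LineString([(20 * km, -4 * km), (20 * km, 4 * km)])
    return CoastModel(
        "simple",
        land=[proj.project_inverse_geometry(land)],
        coastline=[proj.project_inverse_geometry(LineString(land.exterior.coords))],
        glacier_fronts=[proj.project_inverse_geometry(front)],
        fjords=[proj.project_inverse_geometry(fjord)],
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240907)


def track_frame(times, lons, lats, lcs=None, animal="w1"):
    n = len(times)
    return pd.DataFrame(
        {
            "animal_id": animal,
            "timestamp": pd.to_datetime(times),
            "lon": lons,
            "lat": lats,
            "lc": lcs if lcs is not None else ["1"] * n,
        }
    )


@pytest.fixture
def make_track():
    return track_frame
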