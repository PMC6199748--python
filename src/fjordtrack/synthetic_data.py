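"""Synthetic archipelago, whale tracks, Argos observations and ice fields.

Everything the pipeline consumes can be generated here with known ground
truth: a two-epoch coastal world (fjords cut into a west-facing coast,
glacier fronts capping the fjord heads, fronts retreating landward
between epochs), hourly correlated-random-walk tracks driven by a
4-state behaviour chain matched to the habitat classes, an Argos-like
observation process with location-class-dependent error, and seasonal
sea-ice fields grown as coastal bands.

All generators are bit-reproducible for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.ops import nearest_points

from .errors import ConfigurationError
from .geospatial import CoastModel, GeoPoint, LocalProjection
from .habitat_metrics import HABITAT_CLASSES, ICE_TYPES, HabitatConfig, IceField, classify_habitat, day_index
from .track_processing import LCErrorTable, rng_for_animal

__all__ = [
    "ArchipelagoSpec",
    "BehaviourSpec",
    "SimTruth",
    "make_archipelago",
    "simulate_tracks",
    "observe_argos",
    "make_ice_fields",
    "fixture",
    "generate_fixture",
    "Fixture",
    "FIXTURES",
    "WORLD_ORIGIN",
]

#: lon/lat origin of the synthetic world's local projection
WORLD_ORIGIN = GeoPoint(16.0, 78.0)


@dataclass(frozen=True)
class ArchipelagoSpec:
    n_fjords: int = 3
    fjord_depth_km: float = 25.0
    fjord_width_km: float = 10.0
    glacier_retreat_km: float = 4.0
    island_scale_km: float = 120.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.glacier_retreat_km < 0:
            raise ConfigurationError("glacier retreat must be >= 0")
        if self.n_fjords < 1:
            raise ConfigurationError("need at least one fjord")


@dataclass(frozen=True)
class BehaviourSpec:
    """Movement parameters per behaviour state (states = habitat classes)."""

    #: row-stochastic 4x4 matrix in HABITAT_CLASSES order
    transitions: tuple = (
        (0.97, 0.010, 0.015, 0.005),
        (0.020, 0.950, 0.020, 0.010),
        (0.030, 0.030, 0.900, 0.040),
        (0.010, 0.010, 0.030, 0.950),
    )
    #: lognormal (mu, sigma) of hourly speed in m/s per state
    speed_lognorm: tuple = ((-0.9, 0.5), (-0.45, 0.5), (-0.1, 0.4), (-0.2, 0.4))
    #: folded-normal sigma of the hourly turn in degrees per state
    turn_sigma_deg: tuple = (70.0, 45.0, 25.0, 35.0)
    #: day index after which a seasonal hazard pushes animals offshore (None = never)
    offshore_onset_day: int | None = 150
    offshore_hazard: float = 0.03
    period_label: str = "2013–2016"

    def __post_init__(self) -> None:
        t = np.asarray(self.transitions, dtype=float)
        if t.shape != (4, 4) or not np.allclose(t.sum(axis=1), 1.0):
            raise ConfigurationError("transition rows must be a 4x4 row-stochastic matrix")
        if np.any(t < 0):
            raise ConfigurationError("transition probabilities must be non-negative")


@dataclass
class SimTruth:
    """Ground truth: hourly path, behaviour state and habitat per animal."""

    locations: pd.DataFrame  # animal_id, timestamp, lon, lat, state, habitat
    period_label: str

    def budgets(self) -> pd.DataFrame:
        """Per-animal proportion of hours in each true habitat class."""
        rows = []
        for animal, sub in self.locations.groupby("animal_id", sort=True):
            counts = sub["habitat"].value_counts()
            row = {"animal_id": animal, "n_hours": len(sub)}
            for h in HABITAT_CLASSES:
                row[h] = counts.get(h, 0) / len(sub)
            rows.append(row)
        return pd.DataFrame(rows)

    def state_budgets(self) -> pd.DataFrame:
        rows = []
        for animal, sub in self.locations.groupby("animal_id", sort=True):
            counts = sub["state"].value_counts()
            row = {"animal_id": animal, "n_hours": len(sub)}
            for h in HABITAT_CLASSES:
                row[h] = counts.get(h, 0) / len(sub)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------
# Archipelago
# ---------------------------------------------------------------------


def make_archipelago(spec: ArchipelagoSpec) -> tuple[CoastModel, CoastModel]:
    """Build the two-epoch coastal world; returns (epoch-1, epoch-2) models.

    The main island has a wavy west-facing coast at x=0 of the local
    metre frame; ``n_fjords`` channels are cut eastward into it, each
    capped by a glacier-front line at its head. Epoch 2 deepens every
    channel by the retreat distance, so its fronts are strictly landward
    and its land area is no larger.
    """
    proj = LocalProjection(WORLD_ORIGIN)
    rng = np.random.default_rng(spec.seed)
    km = 1000.0
    L = spec.island_scale_km * km  # extent of land to the east
    S = max(spec.island_scale_km, spec.n_fjords * 3.0 * spec.fjord_width_km) * km  # N-S extent

    # wavy outer coastline along x ~ 0
    ys = np.linspace(-S / 2, S / 2, 241)
    phase = rng.uniform(0, 2 * np.pi, 3)
    amp = 0.015 * L
    xs = amp * (
        np.sin(2 * np.pi * ys / (S / 2.5) + phase[0])
        + 0.5 * np.sin(2 * np.pi * ys / (S / 7.0) + phase[1])
    )
    coast_pts = list(zip(xs, ys))
    base_land = Polygon(coast_pts + [(L, S / 2), (L, -S / 2)])
    if not base_land.is_valid:
        base_land = base_land.buffer(0)

    # fjord channels, evenly spaced along the coast
    centers = np.linspace(-S / 2 + 0.2 * S, S / 2 - 0.2 * S, spec.n_fjords)
    w = spec.fjord_width_km * km
    models = []
    for epoch_i, retreat in enumerate([0.0, spec.glacier_retreat_km * km]):
        depth = spec.fjord_depth_km * km + retreat
        land = base_land
        fjords, fronts = [], []
        for yc in centers:
            channel = Polygon(
                [
                    (-3 * km, yc - w / 2),
                    (depth, yc - w / 2),
                    (depth, yc + w / 2),
                    (-3 * km, yc + w / 2),
                ]
            )
            fjord_poly = channel.intersection(base_land)
            land = land.difference(channel)
            fjords.append(fjord_poly)
            fronts.append(LineString([(depth, yc - w / 2), (depth, yc + w / 2)]))
        if not land.is_valid:
            raise ConfigurationError("generated land polygon is invalid")
        label = "1995–2001" if epoch_i == 0 else "2013–2016"
        land_ll = proj.project_inverse_geometry(land)
        coast_ll = [proj.project_inverse_geometry(LineString(g.exterior.coords)) for g in _polys(land)]
        fronts_ll = [proj.project_inverse_geometry(f) for f in fronts]
        fjords_ll = [proj.project_inverse_geometry(f) for f in fjords]
        models.append(
            CoastModel(
                epoch_label=label,
                land=_polys(land_ll) if land_ll.geom_type == "MultiPolygon" else [land_ll],
                coastline=coast_ll,
                glacier_fronts=fronts_ll,
                fjords=fjords_ll,
            )
        )
    return models[0], models[1]


def _polys(geom):
    if geom.geom_type == "Polygon":
        return [geom]
    return list(geom.geoms)


# ---------------------------------------------------------------------
# Track simulation
# ---------------------------------------------------------------------


def simulate_tracks(
    model: CoastModel,
    behaviour: BehaviourSpec,
    n_animals: int,
    days: float,
    seed: int,
    start_date: str | pd.Timestamp = "2014-07-20",
    habitat_cfg: HabitatConfig | None = None,
) -> SimTruth:
    """Hourly 4-state correlated-random-walk tracks with known truth.

    Each hour the behaviour state evolves by the transition matrix (plus
    an optional seasonal hazard forcing the offshore state); the step is
    drawn from the state's speed/turn distributions, steered toward the
    state's habitat when outside it; steps that would land on shore are
    redrawn (up to 20 times, then reflected). The true habitat per hour
    is obtained by replaying the true positions through the classifier.
    """
    if not model.glacier_fronts or not model.fjords:
        raise ConfigurationError("simulation world needs glacier fronts and fjords")
    cfg = habitat_cfg or HabitatConfig()
    proj = LocalProjection(WORLD_ORIGIN)
    land = proj.project_geometry(model.land_union)
    shapely.prepare(land)
    glacier = proj.project_geometry(model.glacier_union)
    coastline = proj.project_geometry(model.coastline_union)
    fjord = proj.project_geometry(model.fjord_union)
    shapely.prepare(fjord)
    fjord_targets = [proj.project_geometry(f).representative_point() for f in model.fjords]
    front_starts = [proj.project_geometry(f).interpolate(0.5, normalized=True) for f in model.glacier_fronts]

    trans = np.asarray(behaviour.transitions, dtype=float)
    cum_trans = np.cumsum(trans, axis=1)
    start = pd.Timestamp(start_date)
    n_hours = int(round(days * 24))
    frames = []
    for a in range(n_animals):
        animal_id = f"sim-{a + 1:02d}"
        rng = rng_for_animal(seed, animal_id)
        t0 = start + pd.Timedelta(days=int(rng.integers(0, 5)))
        times = pd.date_range(t0, periods=n_hours, freq="1h")
        didx = day_index(times)
        # start just seaward of a random glacier front
        fs = front_starts[int(rng.integers(0, len(front_starts)))]
        pos = np.array([fs.x - 1500.0, fs.y])
        if land.covers(Point(pos)):
            pos = np.array([fs.x - 4000.0, fs.y])
        state = 0  # Glacier-Fronts
        heading = rng.uniform(0, 2 * np.pi)
        xs = np.empty(n_hours)
        ys = np.empty(n_hours)
        states = np.empty(n_hours, dtype=int)
        for h in range(n_hours):
            xs[h], ys[h] = pos
            states[h] = state
            # state transition for the next hour
            u = rng.random()
            state = int(np.searchsorted(cum_trans[state], u))
            if (
                behaviour.offshore_onset_day is not None
                and didx[h] >= behaviour.offshore_onset_day
                and rng.random() < behaviour.offshore_hazard
            ):
                state = 3  # At-Sea
            pos, heading = _step(
                pos, heading, state, behaviour, rng, land, glacier, coastline, fjord, fjord_targets, cfg
            )
        frames.append(
            pd.DataFrame(
                {"animal_id": animal_id, "timestamp": times, "x": xs, "y": ys, "state": states}
            )
        )
    truth = pd.concat(frames, ignore_index=True)
    lon, lat = proj.inverse(truth["x"].to_numpy(), truth["y"].to_numpy())
    truth["lon"] = lon
    truth["lat"] = lat
    truth["state"] = [HABITAT_CLASSES[s] for s in truth["state"]]
    classified = classify_habitat(
        truth[["animal_id", "timestamp", "lon", "lat"]], model, cfg, projection=proj
    )
    truth["habitat"] = classified["habitat"].to_numpy()
    truth["period"] = behaviour.period_label
    return SimTruth(
        locations=truth[["animal_id", "timestamp", "lon", "lat", "state", "habitat", "period"]],
        period_label=behaviour.period_label,
    )


def _step(pos, heading, state, behaviour, rng, land, glacier, coastline, fjord, fjord_targets, cfg):
    mu, sigma = behaviour.speed_lognorm[state]
    thr_m = cfg.radius_threshold_km * 1000.0
    pt = Point(pos)
    d_glacier = glacier.distance(pt)
    d_coast = coastline.distance(pt)
    in_fjord = fjord.covers(pt)
    in_zone = (
        (state == 0 and d_glacier < 0.7 * thr_m)
        or (state == 1 and in_fjord and d_glacier > 1.2 * thr_m)
        or (state == 2 and d_coast < 0.6 * thr_m and not in_fjord and d_glacier > 1.2 * thr_m)
        or (state == 3 and d_coast > 1.2 * thr_m)
    )
    speed = float(np.exp(rng.normal(mu, sigma)))
    if in_zone:
        turn = abs(rng.normal(0.0, math.radians(behaviour.turn_sigma_deg[state])))
        heading = heading + turn * (1 if rng.random() < 0.5 else -1)
    else:
        target = _target_for(state, pt, glacier, coastline, fjord_targets)
        heading = math.atan2(target[0] - pos[0], target[1] - pos[1]) + rng.normal(0.0, math.radians(15.0))
        speed = max(speed, 1.8)
    step_len = speed * 3600.0
    if not in_zone:
        # don't overshoot the target (e.g. past a glacier front into land)
        dist_t = math.hypot(target[0] - pos[0], target[1] - pos[1])
        step_len = min(step_len, max(dist_t, 200.0))
    fallback = None
    for attempt in range(21):
        cand = pos + step_len * np.array([math.sin(heading), math.cos(heading)])
        mid = (pos + cand) / 2.0
        if not land.covers(Point(cand)) and not land.covers(Point(mid)):
            if not in_zone or _in_habitat(state, Point(cand), glacier, coastline, fjord, thr_m):
                return cand, heading
            if fallback is None:
                fallback = (cand, heading)  # at sea but drifting out of habitat
        if attempt == 19:
            heading = heading + math.pi  # reflect
        else:
            heading = rng.uniform(0, 2 * np.pi)
            step_len = float(np.exp(rng.normal(mu, sigma))) * 3600.0
    if fallback is not None:
        return fallback
    return pos, heading  # trapped: stay in place


def _in_habitat(state, pt, glacier, coastline, fjord, thr_m) -> bool:
    """Habitat-class membership of a candidate position, precedence order."""
    d_glacier = glacier.distance(pt)
    if state == 0:
        return d_glacier < thr_m
    if d_glacier < thr_m:
        return False
    in_fjord = fjord.covers(pt)
    if state == 1:
        return in_fjord
    if in_fjord:
        return False
    d_coast = coastline.distance(pt)
    return (d_coast < thr_m) if state == 2 else (d_coast > thr_m)


def _target_for(state, pt, glacier, coastline, fjord_targets):
    if state == 0:  # Glacier-Fronts
        q = nearest_points(glacier, pt)[0]
        return np.array([q.x - 800.0, q.y])  # aim slightly seaward of the front
    if state == 1:  # Fjords
        q = min(fjord_targets, key=lambda f: f.distance(pt))
        return np.array([q.x, q.y])
    if state == 2:  # Coastal
        q = nearest_points(coastline, pt)[0]
        # aim at a point ~2 km seaward of the nearest coast
        v = np.array([pt.x - q.x, pt.y - q.y])
        norm = np.hypot(*v)
        if norm < 1.0:
            v, norm = np.array([-1.0, 0.0]), 1.0
        return np.array([q.x, q.y]) + 1200.0 * v / norm
    return np.array([pt.x - 30000.0, pt.y])  # At-Sea: due west


# ---------------------------------------------------------------------
# Argos observation model
# ---------------------------------------------------------------------


def observe_argos(
    truth: SimTruth,
    lc_mix: dict,
    lc_errors: LCErrorTable,
    mean_interval_hours: float,
    seed: int,
) -> pd.DataFrame:
    """Thin the true hourly grid into Argos-like fixes with LC-dependent error.

    Uplink gaps are exponential with the given mean (rounded to whole
    hours, minimum one hour); each retained point is perturbed uniformly
    within the disc of its drawn class's error radius (class Z reuses the
    class-B radius). Returns an ArgosFix frame
    (``animal_id, timestamp, lon, lat, lc``).
    """
    if mean_interval_hours <= 0:
        raise ConfigurationError("mean_interval_hours must be positive")
    classes = list(lc_mix)
    probs = np.array([lc_mix[c] for c in classes], dtype=float)
    if not math.isclose(probs.sum(), 1.0, rel_tol=1e-9):
        raise ConfigurationError("lc_mix must sum to 1")
    proj = LocalProjection(WORLD_ORIGIN)
    frames = []
    for animal_id, sub in truth.locations.groupby("animal_id", sort=True):
        rng = rng_for_animal(seed, f"obs:{animal_id}")
        n = len(sub)
        idx = []
        i = 0
        while i < n:
            idx.append(i)
            gap = max(1, int(round(rng.exponential(mean_interval_hours))))
            i += gap
        sel = sub.iloc[idx]
        lcs = rng.choice(classes, size=len(sel), p=probs)
        radii = np.array([lc_errors.radius(c) for c in lcs])
        x, y = proj.forward(sel["lon"].to_numpy(), sel["lat"].to_numpy())
        r = radii * np.sqrt(rng.random(len(sel)))
        theta = rng.random(len(sel)) * 2.0 * np.pi
        lon, lat = proj.inverse(x + r * np.cos(theta), y + r * np.sin(theta))
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": animal_id,
                    "timestamp": sel["timestamp"].to_numpy(),
                    "lon": lon,
                    "lat": lat,
                    "lc": lcs,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------
# Ice fields
# ---------------------------------------------------------------------


def make_ice_fields(
    model: CoastModel,
    dates,
    freeze_onset_day: int,
    seed: int = 0,
    growth_m_per_day: float = 120.0,
) -> list[IceField]:
    """Seasonal ice as coastal bands: fast ice against the shore, drift
    classes in decreasing concentration seaward, all growing with days
    past the freeze onset (day index relative to 7 July)."""
    proj = LocalProjection(WORLD_ORIGIN)
    land = proj.project_geometry(model.land_union)
    fields = []
    for date in sorted(pd.Timestamp(d) for d in dates):
        g = float(day_index([date])[0]) - freeze_onset_day
        if g <= 0:
            fields.append(IceField(date=date, polygons=()))
            continue
        fast_w = growth_m_per_day * g
        widths = [fast_w, fast_w * 1.6, fast_w * 2.2, fast_w * 2.8, fast_w * 3.4]
        types = ["Fast ice", "Very Close Drift Ice", "Close Drift Ice", "Open Drift Ice", "Very Open Drift Ice"]
        polys = []
        prev = land
        for w_outer, ice_type in zip(widths, types):
            ring = land.buffer(w_outer).difference(prev)
            prev = land.buffer(w_outer)
            if not ring.is_empty:
                polys.append((ice_type, proj.project_inverse_geometry(ring)))
        fields.append(IceField(date=date, polygons=tuple(polys)))
    return fields


# ---------------------------------------------------------------------
# Shipped fixtures
# ---------------------------------------------------------------------


@dataclass(frozen=True)
class Fixture:
    name: str
    archipelago: ArchipelagoSpec
    epoch: int  # 0 = epoch-1 geometry, 1 = epoch-2 geometry
    behaviour: BehaviourSpec
    n_animals: int
    days: float
    start_date: str
    lc_mix: dict = field(default_factory=dict)
    lc_errors: LCErrorTable = field(default_factory=LCErrorTable)
    mean_interval_hours: float = 2.0
    freeze_onset_day: int = 120


_ARCH = ArchipelagoSpec(n_fjords=3, fjord_depth_km=22.0, fjord_width_km=6.0, glacier_retreat_km=4.0, seed=11)

FIXTURES = {
    # fewer animals, shorter records, coarser errors, earlier freeze-up
    "period1": Fixture(
        name="period1",
        archipelago=_ARCH,
        epoch=0,
        behaviour=BehaviourSpec(
            transitions=(
                (0.980, 0.005, 0.010, 0.005),
                (0.040, 0.920, 0.030, 0.010),
                (0.050, 0.020, 0.890, 0.040),
                (0.020, 0.010, 0.030, 0.940),
            ),
            speed_lognorm=((-0.75, 0.5), (-0.35, 0.5), (0.0, 0.4), (-0.1, 0.4)),
            turn_sigma_deg=(75.0, 45.0, 25.0, 35.0),
            offshore_onset_day=100,
            offshore_hazard=0.04,
            period_label="1995–2001",
        ),
        n_animals=10,
        days=45.0,
        start_date="1999-07-25",
        lc_mix={"3": 0.04, "2": 0.06, "1": 0.10, "A": 0.36, "B": 0.40, "Z": 0.04},
        lc_errors=LCErrorTable({"3": 600.0, "2": 1200.0, "1": 2000.0, "A": 3000.0, "B": 5200.0}),
        mean_interval_hours=2.5,
        freeze_onset_day=95,
    ),
    # more animals, longer records, tighter errors, later freeze-up, retreated fronts
    "period2": Fixture(
        name="period2",
        archipelago=_ARCH,
        epoch=1,
        behaviour=BehaviourSpec(
            transitions=(
                (0.970, 0.012, 0.013, 0.005),
                (0.030, 0.940, 0.020, 0.010),
                (0.050, 0.030, 0.880, 0.040),
                (0.020, 0.010, 0.030, 0.940),
            ),
            speed_lognorm=((-0.9, 0.5), (-0.5, 0.5), (-0.15, 0.4), (-0.25, 0.4)),
            turn_sigma_deg=(65.0, 40.0, 25.0, 35.0),
            offshore_onset_day=140,
            offshore_hazard=0.03,
            period_label="2013–2016",
        ),
        n_animals=16,
        days=90.0,
        start_date="2014-07-20",
        lc_mix={"3": 0.06, "2": 0.08, "1": 0.13, "A": 0.25, "B": 0.45, "Z": 0.03},
        lc_errors=LCErrorTable({"3": 400.0, "2": 800.0, "1": 1400.0, "A": 2800.0, "B": 5000.0}),
        mean_interval_hours=1.8,
        freeze_onset_day=130,
    ),
}


def fixture(name: str) -> Fixture:
    try:
        return FIXTURES[name]
    except KeyError:
        raise ConfigurationError(f"unknown fixture {name!r}; choose from {sorted(FIXTURES)}") from None


def generate_fixture(name: str, seed: int):
    """Run a shipped fixture end to end on the generator side.

    Returns ``(coast_model, truth, argos_fixes, ice_fields)``.
    """
    fx = fixture(name)
    m1, m2 = make_archipelago(fx.archipelago)
    model = (m1, m2)[fx.epoch]
    truth = simulate_tracks(model, fx.behaviour, fx.n_animals, fx.days, seed, start_date=fx.start_date)
    fixes = observe_argos(truth, fx.lc_mix, fx.lc_errors, fx.mean_interval_hours, seed)
    t0 = pd.Timestamp(fx.start_date)
    ice_dates = pd.date_range(t0, t0 + pd.Timedelta(days=int(fx.days)), freq="5D")
    ice = make_ice_fields(model, ice_dates, fx.freeze_onset_day, seed)
    return model, truth, fixes, ice
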