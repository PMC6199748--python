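"""Independent oracle implementations used by the test-suite only.

Deliberately written with different math from the package: haversine on
the mean-Earth-radius sphere for distances, the spherical law of
cosines for vertex angles, and exhaustive subset search for the SDA
filter. Nothing here imports the package's geometry code.
"""

import itertools
import math

import numpy as np
import pandas as pd

MEAN_RADIUS = 6371008.8

VMAX_DEFAULT = 3.0
SPIKE_RULES_DEFAULT = ((15.0, 2.5), (25.0, 5.0))


def hav_m(lon1, lat1, lon2, lat2) -> float:
    phi1, phi2 = math.radians(lat1), math.radians(lat2)
    dphi = phi2 - phi1
    dlam = math.radians(lon2 - lon1)
    h = math.sin(dphi / 2) ** 2 + math.cos(phi1) * math.cos(phi2) * math.sin(dlam / 2) ** 2
    return 2 * MEAN_RADIUS * math.asin(min(1.0, math.sqrt(h)))


def central_angle(lon1, lat1, lon2, lat2) -> float:
    return hav_m(lon1, lat1, lon2, lat2) / MEAN_RADIUS


def vertex_angle_deg(lonp, latp, loni, lati, lons, lats) -> float:
    """Spherical angle at vertex i of the triangle (p, i, s)."""
    a = central_angle(loni, lati, lonp, latp)
    b = central_angle(loni, lati, lons, lats)
    c = central_angle(lonp, latp, lons, lats)
    if a == 0 or b == 0:
        return 180.0
    cos_c = (math.cos(c) - math.cos(a) * math.cos(b)) / (math.sin(a) * math.sin(b))
    return math.degrees(math.acos(max(-1.0, min(1.0, cos_c))))


def subset_valid(lon, lat, tsec, keep, vmax=VMAX_DEFAULT, spike_rules=SPIKE_RULES_DEFAULT) -> bool:
    """SDA post-conditions on a kept index subset, oracle arithmetic."""
    k = list(keep)
    for j in range(1, len(k) - 1):
        p, i, s = k[j - 1], k[j], k[j + 1]
        d_in = hav_m(lon[p], lat[p], lon[i], lat[i])
        d_out = hav_m(lon[i], lat[i], lon[s], lat[s])
        dt_in = tsec[i] - tsec[p]
        dt_out = tsec[s] - tsec[i]
        v_in = d_in / dt_in if dt_in > 0 else (math.inf if d_in > 0 else 0.0)
        v_out = d_out / dt_out if dt_out > 0 else (math.inf if d_out > 0 else 0.0)
        if v_in > vmax and v_out > vmax:
            return False
        angle = vertex_angle_deg(lon[p], lat[p], lon[i], lat[i], lon[s], lat[s])
        for max_angle, min_leg in spike_rules:
            if angle < max_angle and d_in / 1000.0 > min_leg and d_out / 1000.0 > min_leg:
                return False
    return True


def brute_force_sda(track: pd.DataFrame, vmax=VMAX_DEFAULT, spike_rules=SPIKE_RULES_DEFAULT):
    """Maximum-retention kept subset; ties keep the earliest fixes.

    LC Z rows are always removed. Returns sorted kept positional indices.
    """
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    tsec = track["timestamp"].to_numpy().astype("datetime64[s]").astype("int64")
    nonz = [i for i in range(len(track)) if track["lc"].iloc[i] != "Z"]
    for size in range(len(nonz), -1, -1):
        valid = [
            list(keep)
            for keep in itertools.combinations(nonz, size)
            if subset_valid(lon, lat, tsec, keep, vmax, spike_rules)
        ]
        if valid:
            return min(valid)
    return []


def is_borderline(track: pd.DataFrame, vmax=VMAX_DEFAULT, spike_rules=SPIKE_RULES_DEFAULT, tol=0.006) -> bool:
    """True if any index triple sits within float-vs-model noise of a rule
    threshold, where spherical and ellipsoidal distances may legitimately
    disagree (0.3% apart). Used to reject razor-edge random tracks."""
    lon = track["lon"].to_numpy()
    lat = track["lat"].to_numpy()
    tsec = track["timestamp"].to_numpy().astype("datetime64[s]").astype("int64")
    n = len(track)
    for p in range(n - 2):
        for i in range(p + 1, n - 1):
            for s in range(i + 1, n):
                d_in = hav_m(lon[p], lat[p], lon[i], lat[i])
                d_out = hav_m(lon[i], lat[i], lon[s], lat[s])
                for dt, d in ((tsec[i] - tsec[p], d_in), (tsec[s] - tsec[i], d_out)):
                    if dt > 0 and abs(d / dt - vmax) < vmax * tol:
                        return True
                angle = vertex_angle_deg(lon[p], lat[p], lon[i], lat[i], lon[s], lat[s])
                for max_angle, min_leg in spike_rules:
                    if abs(angle - max_angle) < 1.0:
                        return True
                    if angle < max_angle + 1.0:
                        for d in (d_in, d_out):
                            if abs(d / 1000.0 - min_leg) < min_leg * tol:
                                return True
    return False


def random_argos_track(rng: np.random.Generator, n: int) -> pd.DataFrame:
    """Random small track: plausible base movement plus planted artefacts.

    Normal steps imply speeds well below 3 m/s and outliers well above
    3.5 m/s, so the package's ellipsoidal distances and this oracle's
    spherical distances cannot disagree about threshold crossings.
    """
    t = pd.Timestamp("2014-08-01")
    lon, lat = 16.0, 78.0
    recs = []
    for _ in range(n):
        lc = rng.choice(["3", "2", "1", "A", "B", "Z"], p=[0.1, 0.1, 0.15, 0.3, 0.3, 0.05])
        recs.append((t, lon, lat, lc))
        dt_h = float(rng.uniform(0.75, 3.0))
        t = t + pd.Timedelta(hours=dt_h)
        step = float(rng.uniform(0, 2.4)) * dt_h * 3600.0  # <= 2.4 m/s
        ang = float(rng.uniform(0, 2 * math.pi))
        lat += step * math.cos(ang) / 110574.0
        lon += step * math.sin(ang) / (111320.0 * math.cos(math.radians(lat)))
    df = pd.DataFrame(recs, columns=["timestamp", "lon", "lat", "lc"])
    df.insert(0, "animal_id", "x")
    # planted artefacts: large displacements (fast + spiky)
    for i in range(1, n - 1):
        r = rng.random()
        if r < 0.15:
            df.loc[i, "lon"] += rng.choice([-1, 1]) * rng.uniform(0.4, 1.5)
            df.loc[i, "lat"] += rng.choice([-1, 1]) * rng.uniform(0.2, 0.8)
        elif r < 0.25:
            df.loc[i, "lat"] += rng.uniform(0.08, 0.2)
    return df


def random_nonborderline_track(rng: np.random.Generator, n: int, max_tries: int = 50) -> pd.DataFrame:
    """Random track rejected-sampled away from rule-threshold razor edges."""
    for _ in range(max_tries):
        df = random_argos_track(rng, n)
        if not is_borderline(df):
            return df
    return df  # pragma: no cover - vanishingly unlikely
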