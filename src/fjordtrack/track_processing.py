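"""Three-stage Argos track filtration.

Stage 1: speed-distance-angle (SDA) filter — drops unusable location-class
Z fixes, fixes that would require unrealistic swimming speeds from both
neighbours, and sharp out-and-back "spikes" with long legs.

Stage 2: particle-based on-land correction — each on-land fix is replaced
by the mean of the at-sea members of a cloud of particles drawn uniformly
in a disc whose radius is the fix's location-class error; fixes that
cannot be rescued are dropped.

Stage 3: hourly interpolation along the track-line, skipping gaps longer
than a configurable maximum and dropping interpolated points that land on
shore.

Tracks are pandas DataFrames with columns
``animal_id, timestamp, lon, lat, lc`` (one row per Argos uplink).
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, InternalError
from .geospatial import (
    CoastModel,
    GeoPoint,
    LocalProjection,
    geodesic_distance_arrays,
    points_on_land,
)

__all__ = [
    "LC_CLASSES",
    "LCErrorTable",
    "SdaConfig",
    "CorrectionConfig",
    "InterpConfig",
    "sda_filter",
    "correct_onland",
    "interpolate_hourly",
    "processing_report",
    "onland_percent",
    "rng_for_animal",
]

LC_CLASSES = ("3", "2", "1", "A", "B", "Z")
#: quality order, best first (used for duplicate-timestamp resolution)
LC_QUALITY = {"3": 0, "2": 1, "1": 2, "A": 3, "B": 4, "Z": 5}

TRACK_COLUMNS = ["animal_id", "timestamp", "lon", "lat", "lc"]


@dataclass(frozen=True)
class LCErrorTable:
    """Per-location-class error radius in metres (class Z reuses class B)."""

    radii: dict = field(
        default_factory=lambda: {"3": 500.0, "2": 1000.0, "1": 1500.0, "A": 2500.0, "B": 4000.0}
    )

    def __post_init__(self) -> None:
        missing = {"3", "2", "1", "A", "B"} - set(self.radii)
        if missing:
            raise ConfigurationError(f"LCErrorTable missing classes: {sorted(missing)}")
        if any(r <= 0 for r in self.radii.values()):
            raise ConfigurationError("LCErrorTable radii must be positive")
        order = ["B", "A", "1", "2", "3"]
        vals = [self.radii[c] for c in order]
        if any(a < b for a, b in zip(vals, vals[1:])):
            raise ConfigurationError("LCErrorTable radii must be non-increasing from B to 3")

    def radius(self, lc: str) -> float:
        if lc == "Z":
            return self.radii["B"]
        try:
            return self.radii[lc]
        except KeyError:
            raise ConfigurationError(f"no error radius configured for location class {lc!r}") from None


@dataclass(frozen=True)
class SdaConfig:
    """SDA filter thresholds: max speed and (max_angle deg, min_leg km) spike rules."""

    vmax: float = 3.0
    spike_rules: tuple = ((15.0, 2.5), (25.0, 5.0))

    def __post_init__(self) -> None:
        if self.vmax <= 0:
            raise ConfigurationError("vmax must be positive")


@dataclass(frozen=True)
class CorrectionConfig:
    n_particles: int = 50
    seed: int = 0
    lc_errors: LCErrorTable = field(default_factory=LCErrorTable)
    #: "disc" (uniform within the error radius) or "gaussian" (sd = radius)
    placement: str = "disc"

    def __post_init__(self) -> None:
        if self.n_particles < 1:
            raise ConfigurationError("n_particles must be >= 1")
        if self.placement not in ("disc", "gaussian"):
            raise ConfigurationError(f"unknown particle placement {self.placement!r}")


@dataclass(frozen=True)
class InterpConfig:
    step: pd.Timedelta = pd.Timedelta(hours=1)
    max_gap: pd.Timedelta = pd.Timedelta(hours=12)
    #: "projected" (straight lines in the local frame) or "greatcircle"
    method: str = "projected"

    def __post_init__(self) -> None:
        if not (pd.Timedelta(0) < self.step <= self.max_gap):
            raise ConfigurationError("require 0 < step <= max_gap")


def rng_for_animal(seed: int, animal_id: str) -> np.random.Generator:
    """Deterministic per-animal generator, independent of batch composition."""
    digest = hashlib.sha256(f"{seed}:{animal_id}".encode()).digest()
    return np.random.default_rng(int.from_bytes(digest[:8], "little"))


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in TRACK_COLUMNS if c not in track.columns]
    if missing:
        raise InputError(f"track missing columns: {missing}")
    if len(track) == 0:
        return track
    per_animal_sorted = track.groupby("animal_id", sort=False)["timestamp"].apply(
        lambda s: s.is_monotonic_increasing
    )
    if not per_animal_sorted.all():
        raise InputError("track timestamps must be sorted within each animal")
    return track


# ---------------------------------------------------------------------
# Stage 1: SDA filter
# ---------------------------------------------------------------------


def _pair_speeds(lon, lat, times) -> np.ndarray:
    """Speed (m/s) between consecutive fixes; inf for zero elapsed time."""
    d = geodesic_distance_arrays(lon[:-1], lat[:-1], lon[1:], lat[1:])
    dt = np.diff(times.astype("datetime64[s]").astype("int64")).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        v = np.where(dt > 0, d / np.where(dt > 0, dt, 1.0), np.where(d > 0, np.inf, 0.0))
    return v

def _bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing (radians) from point 1 toward point 2."""
    phi1, phi2 = np.radians(lat1), np.radians(lat2)
    dlam = np.radians(lon2) - np.radians(lon1)
    return np.arctan2(
        np.sin(dlam) * np.cos(phi2),
        np.cos(phi1) * np.sin(phi2) - np.sin(phi1) * np.cos(phi2) * np.cos(dlam),
    )


def _internal_angles_and_legs(lon, lat):
    """Per-interior-vertex (angle deg in [0,180], leg_in km, leg_out km).

    The angle between the two legs emanating from the vertex is taken
    from spherical initial bearings at the vertex (out-and-back
    geometry -> small angle).
    """
    n = len(lon)
    angles = np.full(n, np.nan)
    leg_in = np.full(n, np.nan)
    leg_out = np.full(n, np.nan)
    if n < 3:
        return angles, leg_in, leg_out
    b_prev = _bearing_rad(lon[1:-1], lat[1:-1], lon[:-2], lat[:-2])
    b_next = _bearing_rad(lon[1:-1], lat[1:-1], lon[2:], lat[2:])
    diff = np.abs(np.angle(np.exp(1j * (b_prev - b_next))))
    d_in = geodesic_distance_arrays(lon[1:-1], lat[1:-1], lon[:-2], lat[:-2])
    d_out = geodesic_distance_arrays(lon[1:-1], lat[1:-1], lon[2:], lat[2:])
    zero = (d_in == 0) | (d_out == 0)
    angles[1:-1] = np.where(zero, 180.0, np.degrees(diff))
    leg_in[1:-1] = d_in / 1000.0
    leg_out[1:-1] = d_out / 1000.0
    return angles, leg_in, leg_out


def sda_violations(lon, lat, times, cfg: SdaConfig) -> list[tuple[int, str]]:
    """Indices of fixes violating the SDA post-conditions for this kept set."""
    n = len(lon)
    out: list[tuple[int, str]] = []
    if n < 3:
        return out
    v = _pair_speeds(np.asarray(lon), np.asarray(lat), np.asarray(times))
    angles, leg_in, leg_out = _internal_angles_and_legs(np.asarray(lon), np.asarray(lat))
    for i in range(1, n - 1):
        if v[i - 1] > cfg.vmax and v[i] > cfg.vmax:
            out.append((i, "speed"))
            continue
        for max_angle, min_leg in cfg.spike_rules:
            if angles[i] < max_angle and leg_in[i] > min_leg and leg_out[i] > min_leg:
                out.append((i, f"spike<{max_angle:g}deg"))
                break
    return out


def sda_filter(
    track: pd.DataFrame, cfg: SdaConfig | None = None, max_skip: int = 10
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Speed-distance-angle filter (single animal or multi-animal frame).

    Returns ``(kept, removed)`` with ``removed`` carrying a ``reason``
    column. LC Z fixes are always removed. The remaining kept subset is
    the largest one in which no kept fix requires a speed above ``vmax``
    from *both* its kept neighbours and no kept interior fix forms an
    out-and-back spike (internal angle below a rule's threshold with
    both legs longer than the rule's minimum); ties between equally
    large subsets are broken by removing later fixes first.

    Both constraints are local to a kept fix and its two kept
    neighbours, so the maximal subset is found exactly by a longest-path
    dynamic program over (previous, current) index pairs. ``max_skip``
    bounds how many consecutive fixes a kept segment may bridge; the
    result is exact whenever no optimal solution drops more than
    ``max_skip`` fixes in a row.
    """
    cfg = cfg or SdaConfig()
    track = _check_track(track)
    kept_parts, removed_parts = [], []
    for _, sub in track.groupby("animal_id", sort=False):
        k, r = _sda_one(sub.reset_index(drop=True), cfg, max_skip)
        kept_parts.append(k)
        removed_parts.append(r)
    kept = pd.concat(kept_parts, ignore_index=True) if kept_parts else track.iloc[0:0].copy()
    removed = (
        pd.concat(removed_parts, ignore_index=True)
        if removed_parts
        else track.iloc[0:0].assign(reason=pd.Series(dtype=str))
    )
    return kept, removed


class _TripleChecker:
    """Evaluates the SDA constraint on an index triple (p, i, s)."""

    def __init__(self, lon, lat, times, cfg: SdaConfig, window: int | None = None):
        self.cfg = cfg
        self.t = np.asarray(times).astype("datetime64[s]").astype("int64")
        n = len(lon)
        lon, lat = np.asarray(lon), np.asarray(lat)
        self.lon, self.lat = lon, lat
        # pairwise distances/speeds for index offsets up to the DP window
        w = window if window is not None else n
        self._dist_by_offset: list[np.ndarray | None] = [None] * (min(w, n - 1) + 1 if n > 1 else 1)
        for d in range(1, len(self._dist_by_offset)):
            self._dist_by_offset[d] = geodesic_distance_arrays(lon[:-d], lat[:-d], lon[d:], lat[d:])

    def _dist(self, i, j) -> float:
        return float(self._dist_by_offset[j - i][i])

    def _speed(self, i, j) -> float:
        dt = self.t[j] - self.t[i]
        d = self._dist(i, j)
        if dt <= 0:
            return np.inf if d > 0 else 0.0
        return d / dt

    def ok(self, p, i, s) -> bool:
        return self.reason(p, i, s) is None

    def reason(self, p, i, s) -> str | None:
        if self._speed(p, i) > self.cfg.vmax and self._speed(i, s) > self.cfg.vmax:
            return "speed"
        n1 = self._dist(p, i)
        n2 = self._dist(i, s)
        if n1 > 0 and n2 > 0:
            b1 = _bearing_rad(self.lon[i], self.lat[i], self.lon[p], self.lat[p])
            b2 = _bearing_rad(self.lon[i], self.lat[i], self.lon[s], self.lat[s])
            angle = math.degrees(abs(np.angle(np.exp(1j * (b1 - b2)))))
            for max_angle, min_leg in self.cfg.spike_rules:
                if angle < max_angle and n1 / 1000.0 > min_leg and n2 / 1000.0 > min_leg:
                    return f"spike<{max_angle:g}deg"
        return None


def _sda_one(sub: pd.DataFrame, cfg: SdaConfig, max_skip: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    reasons = pd.Series(index=sub.index, dtype=object)
    is_z = sub["lc"].astype(str) == "Z"
    reasons[is_z] = "LC Z"
    cand = list(sub.index[~is_z])
    n = len(cand)
    if n > 2:
        lon = sub["lon"].to_numpy()[cand]
        lat = sub["lat"].to_numpy()[cand]
        times = sub["timestamp"].to_numpy()[cand]
        chk = _TripleChecker(lon, lat, times, cfg, window=min(max_skip, n))
        keep_rel = _max_retention_dp(n, chk, min(max_skip, n))
        kept_set = set(keep_rel)
        kept_sorted = sorted(keep_rel)
        for pos, j in enumerate(cand):
            rel = pos
            if rel in kept_set:
                continue
            reasons[j] = _diagnose(rel, kept_sorted, chk)
    kept = sub.loc[[j for j in cand if reasons[j] is None or pd.isna(reasons[j])]].copy()
    removed = sub.loc[reasons.notna()].copy()
    removed["reason"] = reasons[reasons.notna()]
    return kept, removed


def _max_retention_dp(n: int, chk: _TripleChecker, w: int) -> list[int]:
    """Largest valid kept subset, lexicographically smallest on ties.

    States are (previous kept, current kept) pairs with gaps bounded by
    ``w``; the constraint applies to each interior kept fix and its two
    kept neighbours.
    """
    # len2[i][d] = number of kept fixes from i onward, given previous kept is i-d
    len2 = [dict() for _ in range(n)]
    for i in range(n - 1, -1, -1):
        for d in range(1, min(i, w) + 1):
            p = i - d
            best = 0
            for s in range(i + 1, min(i + w, n - 1) + 1):
                if chk.ok(p, i, s):
                    cont = len2[s].get(s - i, 0)
                    if cont > best:
                        best = cont
            len2[i][d] = 1 + best
    # len1[i] = kept count if i is the first kept fix (no constraint on the first link)
    len1 = [0] * n
    for i in range(n):
        best = 0
        for s in range(i + 1, min(i + w, n - 1) + 1):
            cont = len2[s].get(s - i, 0)
            if cont > best:
                best = cont
        len1[i] = 1 + best
    total = max(len1)
    # forward reconstruction, preferring the smallest next index
    first = min(i for i in range(n) if len1[i] == total)
    keep = [first]
    remaining = total - 1
    p: int | None = None
    i = first
    while remaining > 0:
        for s in range(i + 1, min(i + w, n - 1) + 1):
            if len2[s].get(s - i, 0) == remaining and (p is None or chk.ok(p, i, s)):
                keep.append(s)
                p, i = i, s
                remaining -= 1
                break
        else:  # pragma: no cover - DP guarantees a successor exists
            raise RuntimeError("SDA reconstruction failed")
    return keep


def _diagnose(rel: int, kept_sorted: list[int], chk: _TripleChecker) -> str:
    """Reason label for a removed fix: what would break if it were kept."""
    prev = max((k for k in kept_sorted if k < rel), default=None)
    nxt = min((k for k in kept_sorted if k > rel), default=None)
    if prev is not None and nxt is not None:
        why = chk.reason(prev, rel, nxt)
        if why:
            return why
    return "filtered"


# ---------------------------------------------------------------------
# Stage 2: on-land correction
# ---------------------------------------------------------------------


def correct_onland(
    track: pd.DataFrame,
    model: CoastModel,
    cfg: CorrectionConfig | None = None,
    projection: LocalProjection | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Particle-correct on-land fixes; returns ``(corrected, removed)``.

    At-sea fixes pass through untouched (``provenance == "original"``).
    Each on-land fix spawns ``n_particles`` particles in a disc of its
    location-class error radius; the fix moves to the mean of the at-sea
    particles (``provenance == "particle-corrected"``). Fixes with no
    at-sea particle, or still on land after the move, are removed.
    Deterministic for a fixed seed, per animal.
    """
    cfg = cfg or CorrectionConfig()
    track = _check_track(track)
    if len(track) == 0:
        out = track.copy()
        out["provenance"] = pd.Series(dtype=str)
        return out, out.copy()
    parts_kept, parts_removed = [], []
    for animal_id, sub in track.groupby("animal_id", sort=False):
        rng = rng_for_animal(cfg.seed, str(animal_id))
        k, r = _correct_one(sub.reset_index(drop=True), model, cfg, rng, projection)
        parts_kept.append(k)
        parts_removed.append(r)
    corrected = pd.concat(parts_kept, ignore_index=True)
    removed = pd.concat(parts_removed, ignore_index=True)
    return corrected, removed


def _correct_one(sub, model, cfg, rng, projection):
    lon = sub["lon"].to_numpy().copy()
    lat = sub["lat"].to_numpy().copy()
    onland = points_on_land(lon, lat, model)
    provenance = np.where(onland, "", "original").astype(object)
    drop = np.zeros(len(sub), dtype=bool)
    for i in np.nonzero(onland)[0]:
        radius = cfg.lc_errors.radius(str(sub["lc"].iloc[i]))
        proj = projection or LocalProjection(GeoPoint(lon[i], lat[i]))
        x0, y0 = proj.forward(lon[i], lat[i])
        if cfg.placement == "disc":
            r = radius * np.sqrt(rng.random(cfg.n_particles))
            theta = rng.random(cfg.n_particles) * 2.0 * np.pi
            px = x0 + r * np.cos(theta)
            py = y0 + r * np.sin(theta)
        else:  # gaussian
            px = x0 + rng.normal(0.0, radius, cfg.n_particles)
            py = y0 + rng.normal(0.0, radius, cfg.n_particles)
        plon, plat = proj.inverse(px, py)
        at_sea = ~points_on_land(plon, plat, model)
        if not at_sea.any():
            drop[i] = True
            continue
        mx, my = float(px[at_sea].mean()), float(py[at_sea].mean())
        new_lon, new_lat = proj.inverse(mx, my)
        if points_on_land(np.array([new_lon]), np.array([new_lat]), model)[0]:
            drop[i] = True
            continue
        lon[i], lat[i] = float(new_lon), float(new_lat)
        provenance[i] = "particle-corrected"
    out = sub.copy()
    out["lon"] = lon
    out["lat"] = lat
    out["provenance"] = provenance
    removed = out.loc[drop].copy()
    removed["provenance"] = "removed-still-on-land"
    return out.loc[~drop].copy(), removed


# ---------------------------------------------------------------------
# Stage 3: hourly interpolation
# ---------------------------------------------------------------------


def interpolate_hourly(
    track: pd.DataFrame,
    model: CoastModel,
    cfg: InterpConfig | None = None,
    projection: LocalProjection | None = None,
) -> pd.DataFrame:
    """Resample each animal's track onto the whole-hour UTC grid.

    Points are linear interpolations between bracketing fixes in the
    local projected frame; no points are produced inside gaps longer than
    ``cfg.max_gap``; interpolated points falling on land are dropped.
    Returns columns ``animal_id, timestamp, lon, lat``.
    """
    cfg = cfg or InterpConfig()
    track = _check_track(track)
    out_parts = []
    for animal_id, sub in track.groupby("animal_id", sort=False):
        if len(sub) < 2:
            continue
        out_parts.append(_interp_one(sub.reset_index(drop=True), model, cfg, projection))
    if not out_parts:
        return pd.DataFrame(columns=["animal_id", "timestamp", "lon", "lat"])
    return pd.concat(out_parts, ignore_index=True)


def _interp_one(sub, model, cfg, projection):
    times = pd.DatetimeIndex(sub["timestamp"])
    lon = sub["lon"].to_numpy()
    lat = sub["lat"].to_numpy()
    proj = projection or LocalProjection.for_bounds(lon, lat)
    x, y = proj.forward(lon, lat)

    step = cfg.step
    out_t: list[pd.Timestamp] = []
    out_x: list[float] = []
    out_y: list[float] = []
    seen: set[pd.Timestamp] = set()
    for i in range(len(sub) - 1):
        t0, t1 = times[i], times[i + 1]
        if t1 - t0 > cfg.max_gap or t1 <= t0:
            continue
        first = t0.ceil(step)
        for t in pd.date_range(first, t1, freq=step):
            if t in seen:
                continue
            seen.add(t)
            if cfg.method == "greatcircle":
                frac = (t - t0) / (t1 - t0)
                gx, gy = _slerp(lon[i], lat[i], lon[i + 1], lat[i + 1], float(frac), proj)
            else:
                frac = float((t - t0) / (t1 - t0))
                gx = x[i] + frac * (x[i + 1] - x[i])
                gy = y[i] + frac * (y[i + 1] - y[i])
            out_t.append(t)
            out_x.append(gx)
            out_y.append(gy)
    if not out_t:
        return pd.DataFrame(columns=["animal_id", "timestamp", "lon", "lat"])
    glon, glat = proj.inverse(np.array(out_x), np.array(out_y))
    keep = ~points_on_land(glon, glat, model)
    return pd.DataFrame(
        {
            "animal_id": sub["animal_id"].iloc[0],
            "timestamp": pd.DatetimeIndex(out_t)[keep],
            "lon": np.asarray(glon)[keep],
            "lat": np.asarray(glat)[keep],
        }
    )


def _slerp(lon0, lat0, lon1, lat1, frac, proj):
    """Great-circle interpolation, returned in the projected frame."""
    v0 = _unit(lon0, lat0)
    v1 = _unit(lon1, lat1)
    omega = np.arccos(np.clip(np.dot(v0, v1), -1.0, 1.0))
    if omega < 1e-12:
        v = v0
    else:
        v = (np.sin((1 - frac) * omega) * v0 + np.sin(frac * omega) * v1) / np.sin(omega)
    v = v / np.linalg.norm(v)
    lat = np.degrees(np.arcsin(v[2]))
    lon = np.degrees(np.arctan2(v[1], v[0]))
    xx, yy = proj.forward(lon, lat)
    return float(xx), float(yy)


def _unit(lon, lat):
    lam, phi = np.radians(lon), np.radians(lat)
    return np.array([np.cos(phi) * np.cos(lam), np.cos(phi) * np.sin(lam), np.sin(phi)])


# ---------------------------------------------------------------------
# Bookkeeping
# ---------------------------------------------------------------------


def onland_percent(n_onland: int, n_total: int) -> int:
    """On-land share as an integer percent (half rounds up)."""
    if n_total <= 0:
        raise InputError("n_total must be positive")
    if not 0 <= n_onland <= n_total:
        raise InputError("n_onland must be between 0 and n_total")
    return int(np.floor(100.0 * n_onland / n_total + 0.5))


def processing_report(
    raw: pd.DataFrame,
    sda_kept: pd.DataFrame,
    sda_removed: pd.DataFrame,
    corrected: pd.DataFrame,
    correction_removed: pd.DataFrame,
    interpolated: pd.DataFrame,
) -> pd.DataFrame:
    """Per-animal and pooled stage bookkeeping.

    Columns: raw fixes, SDA removals by reason, on-land count/percent,
    correction success percent, post-correction removals, interpolated
    count. Raises if the stage outputs do not reconcile.
    """
    animals = list(dict.fromkeys(raw["animal_id"]))
    rows = []
    for animal in animals + ["__pooled__"]:
        def _sel(df):
            return df if animal == "__pooled__" else df[df["animal_id"] == animal]

        r, k, rm = _sel(raw), _sel(sda_kept), _sel(sda_removed)
        co, crm, it = _sel(corrected), _sel(correction_removed), _sel(interpolated)
        if len(k) + len(rm) != len(r):
            raise InternalError(
                f"SDA outputs do not reconcile for {animal}: {len(k)} + {len(rm)} != {len(r)}"
            )
        if len(co) + len(crm) != len(k):
            raise InternalError(
                f"correction outputs do not reconcile for {animal}: {len(co)} + {len(crm)} != {len(k)}"
            )
        n_onland = int((co["provenance"] == "particle-corrected").sum()) + len(crm)
        n_corrected_ok = int((co["provenance"] == "particle-corrected").sum())
        rows.append(
            {
                "animal_id": "all" if animal == "__pooled__" else animal,
                "n_raw": len(r),
                "n_sda_removed_lcz": int((rm["reason"] == "LC Z").sum()) if len(rm) else 0,
                "n_sda_removed_speed": int((rm["reason"] == "speed").sum()) if len(rm) else 0,
                "n_sda_removed_spike": int(rm["reason"].astype(str).str.startswith("spike").sum())
                if len(rm)
                else 0,
                "n_sda_removed_other": int((rm["reason"] == "filtered").sum()) if len(rm) else 0,
                "n_sda_kept": len(k),
                "n_onland": n_onland,
                "pct_onland": onland_percent(n_onland, len(k)) if len(k) else 0,
                "pct_corrected": onland_percent(n_corrected_ok, n_onland) if n_onland else 100,
                "n_removed_after_correction": len(crm),
                "n_interpolated": len(it),
            }
        )
    return pd.DataFrame(rows)
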