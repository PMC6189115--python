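"""Stopover detection and migration-leg durations from satellite tracks.

A stopover is a maximal window of consecutive fixes all lying within a
25-km radius for at least 24 h.  The window is anchored at its first fix
and extended greedily — deterministic and order-stable.  Leg duration is
the time from the last fix inside an origin region to the first subsequent
fix inside a destination region (regions are lon/lat bounding boxes or
point/radius circles).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

EARTH_RADIUS_KM = 6371.0
DEFAULT_RADIUS_KM = 25.0
DEFAULT_MIN_HOURS = 24.0
SPEED_SANITY_KMH = 120.0


class IncompleteLegError(ValueError):
    """Raised when a track never completes the requested migration leg."""


def haversine_km(lon1, lat1, lon2, lat2) -> float:
    """Great-circle distance in km (spherical Earth, radius 6371 km)."""
    lon1, lat1, lon2, lat2 = map(np.radians, (lon1, lat1, lon2, lat2))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(a, 0.0, 1.0)))


@dataclass(frozen=True)
class Stopover:
    start: pd.Timestamp
    end: pd.Timestamp
    centroid_lon: float
    centroid_lat: float

    @property
    def duration_days(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)


def _check_track(track: pd.DataFrame) -> pd.DataFrame:
    t = pd.to_datetime(track["timestamp"])
    if not t.is_monotonic_increasing or t.duplicated().any():
        raise ValueError("track timestamps must be strictly increasing")
    out = track.copy()
    out["timestamp"] = t
    return out


def speed_filter(track: pd.DataFrame,
                 max_speed_kmh: float = SPEED_SANITY_KMH) -> pd.DataFrame:
    """Opt-in sanity filter dropping fixes that imply implausible speeds."""
    track = _check_track(track)
    keep = [0]
    for i in range(1, len(track)):
        prev = track.iloc[keep[-1]]
        cur = track.iloc[i]
        dt_h = (cur["timestamp"] - prev["timestamp"]) / pd.Timedelta(hours=1)
        d = haversine_km(prev["lon"], prev["lat"], cur["lon"], cur["lat"])
        if dt_h <= 0 or d / dt_h <= max_speed_kmh:
            keep.append(i)
    return track.iloc[keep].reset_index(drop=True)


def detect_stopovers(
    track: pd.DataFrame,
    radius_km: float = DEFAULT_RADIUS_KM,
    min_hours: float = DEFAULT_MIN_HOURS,
) -> list:
    """Maximal within-radius dwell windows lasting at least ``min_hours``.

    Each window is anchored at its first fix; fixes are added while they
    stay within ``radius_km`` of the anchor.  Windows meeting the duration
    threshold become stopovers; the scan resumes at the first fix outside
    the window, so stopovers are non-overlapping and ordered.
    """
    track = _check_track(track)
    if len(track) < 2:
        raise ValueError("need at least two fixes")
    lon = track["lon"].to_numpy(float)
    lat = track["lat"].to_numpy(float)
    ts = track["timestamp"].to_numpy()
    n = len(track)
    stopovers = []
    i = 0
    while i < n - 1:
        j = i + 1
        while j < n and haversine_km(lon[i], lat[i], lon[j], lat[j]) <= radius_km:
            j += 1
        span_h = (ts[j - 1] - ts[i]) / np.timedelta64(1, "h")
        if span_h >= min_hours:
            stopovers.append(Stopover(
                start=pd.Timestamp(ts[i]), end=pd.Timestamp(ts[j - 1]),
                centroid_lon=float(lon[i:j].mean()),
                centroid_lat=float(lat[i:j].mean()),
            ))
            i = j
        else:
            i += 1
    return stopovers


def in_region(lon, lat, region) -> bool:
    """Membership test for a (lon_min, lat_min, lon_max, lat_max) box or a
    (lon, lat, radius_km) circle."""
    if len(region) == 4:
        lon_min, lat_min, lon_max, lat_max = region
        return bool(lon_min <= lon <= lon_max and lat_min <= lat <= lat_max)
    if len(region) == 3:
        clon, clat, rad = region
        return bool(haversine_km(lon, lat, clon, clat) <= rad)
    raise ValueError("region must be a 4-tuple box or 3-tuple circle")


def leg_duration(track: pd.DataFrame, origin, destination,
                 *, allow_equal_regions: bool = False) -> float:
    """Days from the last fix inside ``origin`` to the first later fix
    inside ``destination``."""
    if origin == destination and not allow_equal_regions:
        raise ValueError("origin and destination regions are identical")
    track = _check_track(track)
    inside_o = [in_region(r["lon"], r["lat"], origin) for _, r in track.iterrows()]
    inside_d = [in_region(r["lon"], r["lat"], destination) for _, r in track.iterrows()]
    o_idx = [i for i, v in enumerate(inside_o) if v]
    if not o_idx:
        raise IncompleteLegError("track never inside the origin region")
    # last origin fix that still has a later destination fix
    d_after = None
    start = None
    for i in reversed(o_idx):
        later = [j for j in range(i + 1, len(track)) if inside_d[j]]
        if later:
            start, d_after = i, later[0]
            break
    if d_after is None:
        raise IncompleteLegError("track never enters the destination region "
                                 "after leaving the origin")
    dt = track["timestamp"].iloc[d_after] - track["timestamp"].iloc[start]
    return dt / pd.Timedelta(days=1)


def summarize_durations(legs) -> dict:
    """Sample mean, sd (n-1), median and n of a collection of durations."""
    arr = np.asarray(list(legs), float)
    if arr.size == 0:
        raise ValueError("no leg durations to summarise")
    return {
        "mean": float(arr.mean()),
        "sd": float(arr.std(ddof=1)) if arr.size > 1 else 0.0,
        "median": float(np.median(arr)),
        "n": int(arr.size),
    }
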