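"""GPS track regularization, trip segmentation and step/turn geometry.

Raw fixes are linearly interpolated (in lon and lat independently) onto a
regular grid — 5-minute spacing by default — without interpolating across
gaps longer than ``max_gap_s`` (tracks are split into separate segments
there).  Foraging trips are maximal periods spent beyond a distance
threshold from the colony for at least a minimum duration, with points
inside the colony radius removed.

Distances are great-circle (haversine, R = 6371 km); bearings from
spherical trigonometry.  Turning angle is signed with positive =
counter-clockwise (left turn); the von Mises emission used downstream is
symmetric around its mean, so results do not depend on this convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "EARTH_RADIUS_KM",
    "TrackSegment",
    "Trip",
    "haversine_km",
    "bearing_rad",
    "wrap_angle",
    "interpolate_track",
    "steps_turns",
    "segment_trips",
    "segments_to_frame",
]

logger = logging.getLogger(__name__)

EARTH_RADIUS_KM = 6371.0


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 degree coordinates."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    a = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return EARTH_RADIUS_KM * 2 * np.arcsin(np.sqrt(np.clip(a, 0, 1)))


def bearing_rad(lon1, lat1, lon2, lat2):
    """Initial great-circle bearing, radians clockwise from north."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    y = np.sin(dlon) * np.cos(lat2)
    x = np.cos(lat1) * np.sin(lat2) - np.sin(lat1) * np.cos(lat2) * np.cos(dlon)
    return np.arctan2(y, x)


def wrap_angle(x):
    """Wrap angle(s) to (-pi, pi]."""
    x = np.asarray(x, dtype=float)
    w = x - 2 * np.pi * np.floor((x + np.pi) / (2 * np.pi))
    w = np.where(w <= -np.pi, np.pi, w)
    return w if w.ndim else float(w)


@dataclass
class TrackSegment:
    """A gap-free regularized position series for one bird.

    ``data`` columns: timestamp, lon, lat, interpolated, and after
    :func:`steps_turns` also step_km (NaN at the last point) and turn_rad
    (NaN at end points and where undefined).
    """

    bird_id: str
    data: pd.DataFrame

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class Trip:
    """A foraging trip: a maximal period beyond ``dist_km`` of the colony."""

    bird_id: str
    trip_id: str
    data: pd.DataFrame
    start: pd.Timestamp
    end: pd.Timestamp
    max_distance_km: float

    @property
    def duration_h(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


def interpolate_track(
    fixes: pd.DataFrame,
    interval_s: float = 300.0,
    max_gap_s: float = 3600.0,
) -> list[TrackSegment]:
    """Regularize raw fixes to a fixed interval, splitting at long gaps.

    ``fixes`` needs columns bird_id, timestamp, lon, lat; sorted in time per
    bird with no duplicate timestamps.  Output timestamps lie on a grid of
    exact ``interval_s`` multiples anchored at each segment's first raw fix
    (never extrapolating beyond the raw span).  Would-be segments with
    fewer than 2 fixes are dropped with a warning.
    """
    segments: list[TrackSegment] = []
    for bird_id, g in fixes.groupby("bird_id", sort=True):
        g = g.reset_index(drop=True)
        t = pd.to_datetime(g["timestamp"])
        if t.dt.tz is None:
            t = t.dt.tz_localize("UTC")
        tsec = t.astype("int64").to_numpy() / 1e9
        if np.any(np.diff(tsec) <= 0):
            raise ValueError(f"fixes for {bird_id} not strictly increasing in time")
        gap_breaks = np.where(np.diff(tsec) > max_gap_s)[0]
        bounds = np.concatenate([[0], gap_breaks + 1, [len(g)]])
        seg_no = 0
        for b0, b1 in zip(bounds[:-1], bounds[1:]):
            if b1 - b0 < 2:
                logger.warning("dropping segment of %s with <2 fixes", bird_id)
                continue
            ts = tsec[b0:b1]
            lon = g["lon"].to_numpy()[b0:b1]
            lat = g["lat"].to_numpy()[b0:b1]
            grid = ts[0] + interval_s * np.arange(int(np.floor((ts[-1] - ts[0]) / interval_s)) + 1)
            gi = np.interp(grid, ts, lon)
            ga = np.interp(grid, ts, lat)
            interp_flag = ~np.isin(grid, ts)
            seg = pd.DataFrame({
                "timestamp": pd.to_datetime(grid * 1e9, utc=True),
                "lon": gi,
                "lat": ga,
                "interpolated": interp_flag,
            })
            segments.append(TrackSegment(bird_id=str(bird_id), data=seg))
            seg_no += 1
    return segments


def steps_turns(segment: TrackSegment) -> TrackSegment:
    """Fill per-point step length (km, to next point) and signed turn (rad).

    Coincident consecutive points give step 0 and an undefined (NaN) turn
    at the adjacent vertices.
    """
    d = segment.data
    lon = d["lon"].to_numpy()
    lat = d["lat"].to_numpy()
    n = len(d)
    step = np.full(n, np.nan)
    turn = np.full(n, np.nan)
    if n >= 2:
        step[:-1] = haversine_km(lon[:-1], lat[:-1], lon[1:], lat[1:])
        brg = bearing_rad(lon[:-1], lat[:-1], lon[1:], lat[1:])
        brg = np.where(step[:-1] > 0, brg, np.nan)
        if n >= 3:
            # compass bearings grow clockwise; positive turn = CCW = -d(bearing)
            turn[1:-1] = wrap_angle(-(brg[1:] - brg[:-1]))
            turn[1:-1] = np.where(np.isnan(brg[1:]) | np.isnan(brg[:-1]), np.nan, turn[1:-1])
    out = d.copy()
    out["step_km"] = step
    out["turn_rad"] = turn
    return TrackSegment(bird_id=segment.bird_id, data=out)


def segment_trips(
    segments: list[TrackSegment],
    colony: tuple[float, float],
    min_away_h: float = 6.0,
    dist_km: float = 5.0,
    colony_radius_km: float = 1.0,
) -> list[Trip]:
    """Delimit foraging trips: >= ``min_away_h`` spent > ``dist_km`` from
    the colony, with points inside ``colony_radius_km`` discarded.

    A brief dip back inside ``dist_km`` ends the trip (no bridging rule);
    each maximal beyond-threshold run is evaluated separately.
    """
    clon, clat = colony
    trips: list[Trip] = []
    counters: dict[str, int] = {}
    for seg in segments:
        d = seg.data
        dist = haversine_km(d["lon"].to_numpy(), d["lat"].to_numpy(), clon, clat)
        away = dist > dist_km
        if not away.any():
            continue
        edges = np.diff(away.astype(int))
        starts = list(np.where(edges == 1)[0] + 1)
        ends = list(np.where(edges == -1)[0] + 1)
        if away[0]:
            starts = [0] + starts
        if away[-1]:
            ends = ends + [len(d)]
        for a, b in zip(starts, ends):
            sub = d.iloc[a:b]
            dur_h = (sub["timestamp"].iloc[-1] - sub["timestamp"].iloc[0]) / pd.Timedelta(hours=1)
            if dur_h < min_away_h:
                continue
            keep = dist[a:b] > colony_radius_km
            sub = sub.loc[keep]
            k = counters.get(seg.bird_id, 0) + 1
            counters[seg.bird_id] = k
            trips.append(Trip(
                bird_id=seg.bird_id,
                trip_id=f"{seg.bird_id}_trip{k:02d}",
                data=sub.reset_index(drop=True),
                start=sub["timestamp"].iloc[0],
                end=sub["timestamp"].iloc[-1],
                max_distance_km=float(dist[a:b].max()),
            ))
    return trips


def segments_to_frame(segments: list[TrackSegment]) -> pd.DataFrame:
    """Stack segments into one table with bird_id and track_id columns."""
    frames = []
    for i, seg in enumerate(segments):
        f = seg.data.copy()
        f.insert(0, "bird_id", seg.bird_id)
        f.insert(1, "track_id", f"{seg.bird_id}_seg{i:03d}")
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["bird_id", "track_id", "timestamp", "lon", "lat"])
    return pd.concat(frames, ignore_index=True)
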