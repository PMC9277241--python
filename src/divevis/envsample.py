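"""Environmental covariates for biologging tables.

Solar geometry, time of day, and point sampling of gridded fields
(Secchi-disc depth, cloud cover, bathymetry).  Fields are carried as
:class:`xarray.DataArray` objects on regular lon/lat grids; on disk they are
stored as long-format CSV (columns ``time, lat, lon, value`` — ``time``
omitted for static fields), which keeps every artifact plain text.

Conventions
-----------
* Secchi-disc depth ``zsd_m`` is positive metres; larger = clearer water.
* ``cloud_pct`` is total cloud cover in percent, 0–100.
* ``solar_deg`` is solar elevation: positive above the horizon, negative
  below, 0 at rise/set.  No atmospheric refraction correction is applied.
* ``water_depth_m`` is positive down (depth, not elevation).
* ``time_of_day_h`` is hours from UTC midnight, cyclic on 24.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "CIVIL_TWILIGHT_DEG",
    "EnvFields",
    "solar_angle",
    "time_of_day",
    "cyclic_hour_distance",
    "sample_field",
    "annotate",
    "write_fields",
    "read_fields",
]

logger = logging.getLogger(__name__)

#: Solar elevation of civil twilight (degrees). Used only for reporting the
#: fraction of dives occurring in darkness, never as a model filter.
CIVIL_TWILIGHT_DEG = -6.0

_J2000_EPOCH = pd.Timestamp("2000-01-01 12:00:00", tz="UTC")


def _to_utc_index(timestamp) -> pd.DatetimeIndex:
    ts = pd.DatetimeIndex(np.atleast_1d(np.asarray(timestamp, dtype="object")))
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    else:
        ts = ts.tz_convert("UTC")
    return ts


def solar_angle(timestamp, lon, lat):
    """Solar elevation (degrees) at UTC ``timestamp`` and position.

    Implements the NOAA solar-position equations (Meeus truncations):
    geometric mean longitude/anomaly -> equation of centre -> apparent
    ecliptic longitude -> declination, plus the equation of time, then the
    local hour angle from true solar time.  Accuracy is a few hundredths of
    a degree over the satellite era, well inside the 0.5 deg contract.

    Parameters are scalars or broadcastable arrays; ``lon`` in deg E,
    ``lat`` in deg N.  Returns scalar or ndarray of elevations in
    [-90, 90].
    """
    ts = _to_utc_index(timestamp)
    # Julian centuries since J2000.0
    jd_frac = (ts - _J2000_EPOCH) / pd.Timedelta(days=1)
    t = np.asarray(jd_frac, dtype=float) / 36525.0
    lon = np.asarray(lon, dtype=float)
    lat = np.asarray(lat, dtype=float)

    deg = np.pi / 180.0
    l0 = np.mod(280.46646 + t * (36000.76983 + 0.0003032 * t), 360.0)
    m = 357.52911 + t * (35999.05029 - 0.0001537 * t)
    ecc = 0.016708634 - t * (0.000042037 + 1.267e-7 * t)
    mrad = m * deg
    c = (
        np.sin(mrad) * (1.914602 - t * (0.004817 + 0.000014 * t))
        + np.sin(2 * mrad) * (0.019993 - 0.000101 * t)
        + np.sin(3 * mrad) * 0.000289
    )
    true_long = l0 + c
    omega = (125.04 - 1934.136 * t) * deg
    lambda_app = (true_long - 0.00569 - 0.00478 * np.sin(omega)) * deg
    eps0 = 23.0 + (26.0 + (21.448 - t * (46.815 + t * (0.00059 - t * 0.001813))) / 60.0) / 60.0
    eps = (eps0 + 0.00256 * np.cos(omega)) * deg
    decl = np.arcsin(np.sin(eps) * np.sin(lambda_app))

    y = np.tan(eps / 2.0) ** 2
    l0rad = l0 * deg
    eot_min = 4.0 / deg * (
        y * np.sin(2 * l0rad)
        - 2.0 * ecc * np.sin(mrad)
        + 4.0 * ecc * y * np.sin(mrad) * np.cos(2 * l0rad)
        - 0.5 * y * y * np.sin(4 * l0rad)
        - 1.25 * ecc * ecc * np.sin(2 * mrad)
    )

    minutes_utc = (
        np.asarray(ts.hour, dtype=float) * 60.0
        + np.asarray(ts.minute, dtype=float)
        + np.asarray(ts.second, dtype=float) / 60.0
        + np.asarray(ts.microsecond, dtype=float) / 6.0e7
    )
    tst = np.mod(minutes_utc + eot_min + 4.0 * lon, 1440.0)
    ha = (tst / 4.0 - 180.0) * deg

    latr = lat * deg
    sin_el = np.sin(latr) * np.sin(decl) + np.cos(latr) * np.cos(decl) * np.cos(ha)
    el = np.arcsin(np.clip(sin_el, -1.0, 1.0)) / deg
    if np.ndim(timestamp) == 0 and np.ndim(lon) == 0 and np.ndim(lat) == 0 and el.size == 1:
        return float(el[0] if el.ndim else el)
    return el


def time_of_day(timestamp):
    """Fractional hours from UTC midnight, in [0, 24)."""
    ts = _to_utc_index(timestamp)
    h = (
        np.asarray(ts.hour, dtype=float)
        + np.asarray(ts.minute, dtype=float) / 60.0
        + np.asarray(ts.second, dtype=float) / 3600.0
        + np.asarray(ts.microsecond, dtype=float) / 3.6e9
    )
    return h if h.ndim else float(h)


def cyclic_hour_distance(a, b, period: float = 24.0):
    """Shortest distance between two times of day on the 24 h circle."""
    d = np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)) % period
    out = np.minimum(d, period - d)
    return out if out.ndim else float(out)


# ---------------------------------------------------------------------------
# gridded fields


@dataclass
class EnvFields:
    """Bundle of the three gridded covariate fields.

    zsd : daily Secchi-disc depth, dims (time, lat, lon), metres
    cloud : hourly cloud cover, dims (time, lat, lon), percent
    bathymetry : static water depth, dims (lat, lon), metres positive down
    """

    zsd: xr.DataArray
    cloud: xr.DataArray
    bathymetry: xr.DataArray

    def bounds(self) -> tuple[float, float, float, float]:
        """(lon_min, lon_max, lat_min, lat_max) of the Zsd grid."""
        lon = self.zsd.lon.values
        lat = self.zsd.lat.values
        return float(lon.min()), float(lon.max()), float(lat.min()), float(lat.max())


def _axis_fractions(coords: np.ndarray, q: np.ndarray):
    """Cell index and fraction for linear interpolation along one axis."""
    idx = np.searchsorted(coords, q, side="right") - 1
    idx = np.clip(idx, 0, len(coords) - 2)
    frac = (q - coords[idx]) / (coords[idx + 1] - coords[idx])
    return idx, frac


def sample_field(
    field: xr.DataArray,
    timestamp,
    lon,
    lat,
    space_method: str = "nearest",
    time_method: str = "nearest",
):
    """Sample a gridded field at query points.

    ``space_method``: ``nearest`` (cell centre) or ``bilinear``.
    ``time_method``: ``nearest`` on the field's own time axis (hourly
    fields take the nearest hour) or ``day`` (daily fields match the UTC
    calendar day, so 23:59 and 00:01 straddle two fields); ignored for
    static fields.  Queries outside the grid domain return NaN with a
    logged warning; callers drop those rows and report the count.
    """
    lon = np.atleast_1d(np.asarray(lon, dtype=float))
    lat = np.atleast_1d(np.asarray(lat, dtype=float))
    scalar = lon.size == 1 and np.ndim(lat) <= 1

    lons = field.lon.values
    lats = field.lat.values
    oob = (
        (lon < lons.min()) | (lon > lons.max()) | (lat < lats.min()) | (lat > lats.max())
    )
    if oob.any():
        logger.warning("%d field queries outside grid domain -> NaN", int(oob.sum()))

    if "time" in field.dims:
        ts = _to_utc_index(timestamp)
        ft = pd.DatetimeIndex(field.time.values)
        if ft.tz is None:
            ft = ft.tz_localize("UTC")
        if time_method == "day":
            t_int = ft.normalize().asi8
            q_int = ts.normalize().asi8
            tidx = np.clip(np.searchsorted(t_int, q_int), 0, len(t_int) - 1)
        else:
            t_int = ft.asi8
            q_int = ts.asi8
            pos = np.searchsorted(t_int, q_int)
            pos = np.clip(pos, 1, len(t_int) - 1)
            left = pos - 1
            choose_right = (t_int[pos] - q_int) < (q_int - t_int[left])
            tidx = np.where(choose_right, pos, left)
        if ts.size == 1 and lon.size > 1:
            tidx = np.full(lon.shape, tidx[0])
        vals3 = field.values  # (time, lat, lon)
    else:
        tidx = None
        vals2 = field.values  # (lat, lon)

    if space_method == "nearest":
        ilon = np.clip(np.searchsorted(lons, lon), 1, len(lons) - 1)
        ilon = np.where(np.abs(lons[ilon] - lon) < np.abs(lon - lons[ilon - 1]), ilon, ilon - 1)
        ilat = np.clip(np.searchsorted(lats, lat), 1, len(lats) - 1)
        ilat = np.where(np.abs(lats[ilat] - lat) < np.abs(lat - lats[ilat - 1]), ilat, ilat - 1)
        if tidx is None:
            out = vals2[ilat, ilon]
        else:
            out = vals3[tidx, ilat, ilon]
    elif space_method == "bilinear":
        ix, fx = _axis_fractions(lons, lon)
        iy, fy = _axis_fractions(lats, lat)
        fx = np.clip(fx, 0.0, 1.0)
        fy = np.clip(fy, 0.0, 1.0)

        def _corner(dy, dx):
            if tidx is None:
                return vals2[iy + dy, ix + dx]
            return vals3[tidx, iy + dy, ix + dx]

        out = (
            _corner(0, 0) * (1 - fx) * (1 - fy)
            + _corner(0, 1) * fx * (1 - fy)
            + _corner(1, 0) * (1 - fx) * fy
            + _corner(1, 1) * fx * fy
        )
    else:  # pragma: no cover - contract
        raise ValueError(f"unknown space_method {space_method!r}")

    out = np.where(oob, np.nan, np.asarray(out, dtype=float))
    return out if (out.size > 1 or not scalar) else float(out[0])


def annotate(
    fixes: pd.DataFrame,
    env: EnvFields,
    zsd_space_method: str = "nearest",
) -> pd.DataFrame:
    """Append environmental covariates to a fix (or dive/bout) table.

    Requires columns ``timestamp, lon, lat``.  Adds ``solar_deg, tod_h,
    zsd_m, cloud_pct, water_depth_m`` plus ``env_missing`` flagging rows
    with any covariate outside the grid domain.  Row count is preserved.
    """
    out = fixes.copy()
    ts = out["timestamp"]
    out["solar_deg"] = solar_angle(ts, out["lon"].values, out["lat"].values)
    out["tod_h"] = time_of_day(ts)
    out["zsd_m"] = sample_field(env.zsd, ts, out["lon"].values, out["lat"].values,
                                space_method=zsd_space_method, time_method="day")
    out["cloud_pct"] = sample_field(env.cloud, ts, out["lon"].values, out["lat"].values,
                                    space_method="bilinear", time_method="nearest")
    out["water_depth_m"] = sample_field(env.bathymetry, ts, out["lon"].values,
                                        out["lat"].values, space_method="nearest")
    out["env_missing"] = out[["zsd_m", "cloud_pct", "water_depth_m"]].isna().any(axis=1)
    n_miss = int(out["env_missing"].sum())
    if n_miss:
        logger.warning("annotate: %d rows with missing environmental covariates", n_miss)
    return out


# ---------------------------------------------------------------------------
# plain-text grid I/O (long-format CSV)


def _field_to_frame(field: xr.DataArray) -> pd.DataFrame:
    df = field.to_dataframe(name="value").reset_index()
    return df


def write_fields(env: EnvFields, out_dir: str | Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _field_to_frame(env.zsd).to_csv(out_dir / "zsd.csv", index=False)
    _field_to_frame(env.cloud).to_csv(out_dir / "cloud.csv", index=False)
    _field_to_frame(env.bathymetry).to_csv(out_dir / "bathymetry.csv", index=False)


def _frame_to_field(df: pd.DataFrame, name: str) -> xr.DataArray:
    dims = [c for c in ("time", "lat", "lon") if c in df.columns]
    if "time" in dims:
        df = df.assign(time=pd.to_datetime(df["time"]))
    ds = df.set_index(dims)["value"].to_xarray()
    ds.name = name
    return ds


def read_fields(in_dir: str | Path) -> EnvFields:
    in_dir = Path(in_dir)
    return EnvFields(
        zsd=_frame_to_field(pd.read_csv(in_dir / "zsd.csv"), "zsd_m"),
        cloud=_frame_to_field(pd.read_csv(in_dir / "cloud.csv"), "cloud_pct"),
        bathymetry=_frame_to_field(pd.read_csv(in_dir / "bathymetry.csv"), "water_depth_m"),
    )
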