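"""Seeded synthetic biologging data with known ground truth.

Emulates the data a colony-based tracking study of a pursuit-diving
seabird produces: 5-min GPS fixes over multi-day foraging trips, 0.5 Hz
time-depth-recorder traces, and the gridded environmental fields the
analysis consumes (daily Secchi-disc depth, hourly cloud cover, static
bathymetry).  The movement process is the same 3-state HMM the analysis
fits (rest / area-restricted search / transit) with transition
probabilities depending on local Zsd; dives are daylight-gated negative
binomial counts per 5-min fix whose rate and depth depend on solar angle
x Zsd; inter-dive intervals follow a fast/slow two-process mixture so a
bout-ending criterion exists by construction.

Every random draw flows from one root seed through named substreams
(``env``, ``track``, ``dive``), so identical configs give byte-identical
outputs and individual stages can be regenerated independently.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr
from scipy import ndimage, stats

from . import envsample
from .envsample import EnvFields
from .movehmm import ARS, HMMParams, simulate_series, transition_matrix

__all__ = [
    "SimConfig",
    "SimOutput",
    "EnvTruth",
    "DiveRateTruth",
    "DepthTruth",
    "BoutTruth",
    "default_hmm_truth",
    "substream",
    "gen_env_fields",
    "gen_tracks",
    "gen_dives_and_tdr",
    "simulate",
    "write_output",
]

#: Default colony (lon deg E, lat deg N): a small island off southeast
#: Ireland, placing simulated trips over Celtic Sea shelf waters.
DEFAULT_COLONY = (-6.586, 52.138)


def substream(seed: int, name: str) -> np.random.Generator:
    """Named, independent RNG substream derived from the root seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(zlib.crc32(name.encode()),)))


def default_hmm_truth() -> HMMParams:
    """True movement parameters: rest, ARS and transit at 5-min resolution.

    Step means/sd in km per 5 min (transit ~ 36 km/h flight); transitions
    on the natural Zsd (m) scale.  Clearer water raises the
    transit -> ARS switching rate (+0.5 per m) and ARS persistence.
    """
    beta0 = np.full((3, 3), -2.5)
    beta_z = np.zeros((3, 3))
    beta0[2, 1], beta_z[2, 1] = -6.25, 0.5     # transit -> ARS: more likely in clear water
    beta0[1, 0], beta_z[1, 0] = -1.0, -0.2     # ARS -> rest: stickier ARS in clear water
    beta0[1, 2], beta_z[1, 2] = -1.0, -0.2
    np.fill_diagonal(beta0, 0.0)
    return HMMParams(
        step_mean=np.array([0.08, 0.7, 3.0]),
        step_sd=np.array([0.06, 0.5, 1.0]),
        turn_mean=np.zeros(3),
        turn_kappa=np.array([0.8, 0.4, 8.0]),
        beta0=beta0,
        beta_z=beta_z,
        delta=np.array([0.2, 0.3, 0.5]),
        zero_mass=np.array([0.05, 0.0, 0.0]),
    )


@dataclass
class EnvTruth:
    """Parameters of the generated environmental fields."""

    zsd_mean_m: float = 7.5
    zsd_sd_m: float = 2.6
    zsd_corr_len_cells: float = 5.0
    zsd_cell_deg: float = 0.04          # ~4 km
    cloud_cell_deg: float = 0.25
    cloud_corr_len_cells: float = 2.0
    cloud_time_corr_h: float = 3.0
    lon_halfwidth_deg: float = 3.0
    lat_halfwidth_deg: float = 2.0
    bathy_base_m: float = 20.0          # water depth at colony, positive down
    bathy_slope_m_per_km: float = 1.0
    cloud_from_zsd: bool = False        # optional confounding experiments


@dataclass
class DiveRateTruth:
    """Log-link predictor of dive count per 5-min fix.

    rate = exp(base + surface(alpha, zsd) + tod_effect(tod) + bird_intercept),
    forced to zero below the daylight gate.  The solar x Zsd surface is a
    Gaussian bump: dive rate peaks at low-moderate solar elevations
    (dawn/dusk) and moderate Zsd.
    """

    base_log_rate: float = -2.3
    surf_amp: float = 2.5
    alpha_peak_deg: float = 18.0
    alpha_width_deg: float = 22.0
    zsd_peak_m: float = 8.0
    zsd_width_m: float = 4.0
    tod_amp: float = 0.5
    tod_peak_h: float = 17.0
    bird_sd: float = 0.25
    gate_deg: float = -6.0
    theta: float = 2.5                  # negative binomial size
    ars_only: bool = False              # emit dives only in the true ARS state

    def surface(self, alpha, zsd):
        alpha = np.asarray(alpha, dtype=float)
        zsd = np.asarray(zsd, dtype=float)
        return self.surf_amp * np.exp(
            -((alpha - self.alpha_peak_deg) / self.alpha_width_deg) ** 2
            - ((zsd - self.zsd_peak_m) / self.zsd_width_m) ** 2
        )

    def tod_effect(self, tod_h):
        tod_h = np.asarray(tod_h, dtype=float)
        return self.tod_amp * np.cos(2 * np.pi * (tod_h - self.tod_peak_h) / 24.0)

    def linear_predictor(self, alpha, zsd, tod_h, bird_intercept=0.0):
        return (self.base_log_rate + self.surface(alpha, zsd)
                + self.tod_effect(tod_h) + bird_intercept)


@dataclass
class DepthTruth:
    """Identity-link predictor of dive maximum depth (m).

    depth = base + surface(alpha, zsd) + cloud_coef*(cloud-50) +
    state_effect + N(0, noise_sd), truncated to (floor, cap].  Depth grows
    with solar elevation and water clarity; transit dives are shallower.
    """

    base_m: float = 3.0
    amp_m: float = 9.0
    alpha_mid_deg: float = 15.0
    alpha_scale_deg: float = 12.0
    zsd_ref_m: float = 10.0
    zsd_max_gain: float = 1.3
    cloud_coef_m_per_pct: float = -0.02
    state_effect_m: tuple[float, float, float] = (0.0, 0.0, -3.0)
    noise_sd_m: float = 4.0
    floor_m: float = 1.05
    cap_m: float = 42.0

    def surface(self, alpha, zsd):
        alpha = np.asarray(alpha, dtype=float)
        zsd = np.asarray(zsd, dtype=float)
        light = 1.0 / (1.0 + np.exp(-(alpha - self.alpha_mid_deg) / self.alpha_scale_deg))
        clarity = np.clip(zsd / self.zsd_ref_m, 0.0, self.zsd_max_gain)
        return self.amp_m * light * clarity

    def mean_depth(self, alpha, zsd, cloud_pct, state):
        eff = np.asarray(self.state_effect_m, dtype=float)[np.asarray(state, dtype=int)]
        return (self.base_m + self.surface(alpha, zsd)
                + self.cloud_coef_m_per_pct * (np.asarray(cloud_pct, dtype=float) - 50.0)
                + eff)


@dataclass
class BoutTruth:
    """Two-process inter-dive interval mixture (fast within-bout, slow between)."""

    rate_fast: float = 1.0 / 20.0   # per second
    rate_slow: float = 1.0 / 600.0
    p_fast: float = 0.7

    def __post_init__(self):
        if not (0 < self.p_fast < 1):
            raise ValueError("fast fraction must lie in (0, 1)")
        if not (self.rate_fast > self.rate_slow > 0):
            raise ValueError("need rate_fast > rate_slow > 0")

    def sample_gaps(self, n: int, rng: np.random.Generator) -> np.ndarray:
        fast = rng.random(n) < self.p_fast
        lam = np.where(fast, self.rate_fast, self.rate_slow)
        return rng.exponential(1.0 / lam)


@dataclass
class SimConfig:
    """Full specification of one synthetic colony study."""

    seed: int = 0
    colony: tuple[float, float] = DEFAULT_COLONY
    n_birds: int = 5
    n_trips_per_bird: int = 2
    days_per_trip: float = 2.0
    fix_interval_s: float = 300.0
    tdr_hz: float = 0.5
    start_date: str = "2021-06-15"
    hmm_truth: HMMParams = field(default_factory=default_hmm_truth)
    dive_rate_truth: DiveRateTruth = field(default_factory=DiveRateTruth)
    depth_truth: DepthTruth = field(default_factory=DepthTruth)
    env_truth: EnvTruth = field(default_factory=EnvTruth)
    bout_truth: BoutTruth = field(default_factory=BoutTruth)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["hmm_truth"] = self.hmm_truth.to_dict()
        return d

    @property
    def n_days(self) -> int:
        # one rest day at the colony between trips
        per_bird = self.n_trips_per_bird * (self.days_per_trip + 1)
        return int(np.ceil(per_bird)) + 1


@dataclass
class SimOutput:
    """Generated tables plus the ground truth that produced them."""

    config: SimConfig
    gps: pd.DataFrame
    tdr: pd.DataFrame
    env: EnvFields
    truth_states: pd.DataFrame
    truth_dives: pd.DataFrame


# ---------------------------------------------------------------------------
# environmental fields


def _smooth_unit_field(rng, shape, sigma):
    """Smoothed standard-normal field (unit marginal variance)."""
    white = rng.standard_normal(shape)
    sm = ndimage.gaussian_filter(white, sigma=sigma, mode="wrap")
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def gen_env_fields(config: SimConfig) -> EnvFields:
    """Generate Zsd, cloud and bathymetry grids covering the colony region.

    Zsd is a log-normal random surface: exp of a smoothed Gaussian field,
    with the log-scale moments chosen so the field matches the configured
    arithmetic mean and s.d. (defaults 7.5 m and 2.6 m).  Cloud cover maps
    a smoothed space-time Gaussian field through the normal CDF onto
    [0, 100] %.  Bathymetry is a deterministic ramp: water depth (positive
    down) increasing with distance from the colony.
    """
    et = config.env_truth
    rng = substream(config.seed, "env")
    clon, clat = config.colony
    t0 = pd.Timestamp(config.start_date, tz="UTC")

    lon_z = np.round(np.arange(clon - et.lon_halfwidth_deg, clon + et.lon_halfwidth_deg
                               + et.zsd_cell_deg / 2, et.zsd_cell_deg), 6)
    lat_z = np.round(np.arange(clat - et.lat_halfwidth_deg, clat + et.lat_halfwidth_deg
                               + et.zsd_cell_deg / 2, et.zsd_cell_deg), 6)
    days = pd.date_range(t0, periods=config.n_days, freq="D")
    m, s = et.zsd_mean_m, et.zsd_sd_m
    sig2 = np.log1p((s / m) ** 2)
    mu = np.log(m) - sig2 / 2.0
    g = _smooth_unit_field(rng, (len(days), len(lat_z), len(lon_z)),
                           sigma=(0.5, et.zsd_corr_len_cells, et.zsd_corr_len_cells))
    zsd = xr.DataArray(np.exp(mu + np.sqrt(sig2) * g),
                       coords={"time": days, "lat": lat_z, "lon": lon_z},
                       dims=("time", "lat", "lon"), name="zsd_m")

    lon_c = np.round(np.arange(clon - et.lon_halfwidth_deg, clon + et.lon_halfwidth_deg
                               + et.cloud_cell_deg / 2, et.cloud_cell_deg), 6)
    lat_c = np.round(np.arange(clat - et.lat_halfwidth_deg, clat + et.lat_halfwidth_deg
                               + et.cloud_cell_deg / 2, et.cloud_cell_deg), 6)
    hours = pd.date_range(t0, periods=config.n_days * 24, freq="h")
    gc = _smooth_unit_field(rng, (len(hours), len(lat_c), len(lon_c)),
                            sigma=(et.cloud_time_corr_h, et.cloud_corr_len_cells,
                                   et.cloud_corr_len_cells))
    if et.cloud_from_zsd:
        # optional confounder: cloudy where water is turbid
        zc = zsd.interp(lon=lon_c, lat=lat_c, method="nearest").reindex(
            time=hours, method="ffill").values
        zc = (np.nan_to_num(zc, nan=m) - m) / s
        gc = 0.7 * (-zc) + np.sqrt(1 - 0.49) * gc
    cloud = xr.DataArray(100.0 * stats.norm.cdf(gc),
                         coords={"time": hours, "lat": lat_c, "lon": lon_c},
                         dims=("time", "lat", "lon"), name="cloud_pct")

    glon, glat = np.meshgrid(lon_z, lat_z)
    from .trackproc import haversine_km

    dist = haversine_km(glon, glat, clon, clat)
    bathy = xr.DataArray(et.bathy_base_m + et.bathy_slope_m_per_km * dist,
                         coords={"lat": lat_z, "lon": lon_z},
                         dims=("lat", "lon"), name="water_depth_m")
    return EnvFields(zsd=zsd, cloud=cloud, bathymetry=bathy)


# ---------------------------------------------------------------------------
# tracks


def _advance(lon, lat, bearing, step_km):
    """Local-tangent-plane position update (adequate at few-km steps)."""
    r = np.pi / 180.0
    dlat = step_km / envlib_radius() * np.cos(bearing) / r
    dlon = step_km / envlib_radius() * np.sin(bearing) / (np.cos(lat * r)) / r
    return lon + dlon, lat + dlat


def envlib_radius() -> float:
    from .trackproc import EARTH_RADIUS_KM

    return EARTH_RADIUS_KM


def gen_tracks(config: SimConfig, env: EnvFields) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate GPS fixes for every bird and trip, plus true states.

    State at each fix is drawn from the Markov chain with Gamma evaluated
    at the local Zsd of the departure point; steps from the state's gamma,
    turns from its von Mises; positions advance on a local tangent plane
    and reflect off the interior margin of the environmental grid so
    covariates stay defined.  Birds spend a rest day at the colony between
    trips (a few within-colony fixes are emitted so trip segmentation sees
    a gap).
    """
    truth = config.hmm_truth
    rng = substream(config.seed, "track")
    t0 = pd.Timestamp(config.start_date, tz="UTC")
    clon, clat = config.colony
    lon_min, lon_max, lat_min, lat_max = env.bounds()
    margin = 0.15
    lo_lon, hi_lon = lon_min + margin, lon_max - margin
    lo_lat, hi_lat = lat_min + margin, lat_max - margin

    gps_rows = []
    truth_rows = []
    steps_per_trip = int(round(config.days_per_trip * 86400.0 / config.fix_interval_s))
    for b in range(config.n_birds):
        bird = f"bird{b:02d}"
        for k in range(config.n_trips_per_bird):
            trip_id = f"{bird}_truetrip{k}"
            day_offset = k * (config.days_per_trip + 1)
            t_start = t0 + pd.Timedelta(hours=6) + pd.Timedelta(days=day_offset)
            # leave from just outside the trip-distance threshold
            brg0 = rng.uniform(0, 2 * np.pi)
            lon, lat = _advance(clon, clat, brg0, 6.0)
            heading = brg0
            state = int(np.searchsorted(np.cumsum(truth.delta), rng.random()))
            times = t_start + pd.to_timedelta(np.arange(steps_per_trip) * config.fix_interval_s, unit="s")
            for t in range(steps_per_trip):
                z_here = envsample.sample_field(env.zsd, times[t], lon, lat,
                                                time_method="day")
                if np.isnan(z_here):
                    raise ValueError("track left the environmental grid; enlarge the extent")
                if t > 0:
                    gam = transition_matrix(truth.beta0, truth.beta_z, z_here)
                    state = int(np.searchsorted(np.cumsum(gam[state]), rng.random()))
                state = min(state, 2)
                gps_rows.append((bird, times[t], lon, lat))
                # emissions for the step leaving this fix
                if rng.random() < truth.zero_mass[state]:
                    step = 0.0
                    turn = rng.vonmises(truth.turn_mean[state], truth.turn_kappa[state])
                else:
                    mu, sd = truth.step_mean[state], truth.step_sd[state]
                    step = rng.gamma((mu / sd) ** 2, sd * sd / mu)
                    turn = rng.vonmises(truth.turn_mean[state], truth.turn_kappa[state])
                truth_rows.append((bird, trip_id, times[t], state, lon, lat, z_here))
                heading = heading - turn  # positive turn = counter-clockwise
                lon, lat = _advance(lon, lat, heading, step)
                if lon < lo_lon or lon > hi_lon:
                    lon = np.clip(2 * np.clip(lon, lo_lon, hi_lon) - lon, lo_lon, hi_lon)
                    heading = -heading
                if lat < lo_lat or lat > hi_lat:
                    lat = np.clip(2 * np.clip(lat, lo_lat, hi_lat) - lat, lo_lat, hi_lat)
                    heading = np.pi - heading
            # colony interlude so trips separate cleanly
            t_home = times[-1] + pd.Timedelta(seconds=config.fix_interval_s)
            for j in range(3):
                gps_rows.append((bird, t_home + pd.Timedelta(seconds=j * config.fix_interval_s),
                                 clon + rng.normal(0, 1e-3), clat + rng.normal(0, 1e-3)))
    gps = pd.DataFrame(gps_rows, columns=["bird_id", "timestamp", "lon", "lat"])
    truth_states = pd.DataFrame(
        truth_rows, columns=["bird_id", "trip_id", "timestamp", "state", "lon", "lat", "zsd_true"])
    return gps, truth_states


# ---------------------------------------------------------------------------
# dives and depth traces


def gen_dives_and_tdr(
    config: SimConfig,
    truth_states: pd.DataFrame,
    env: EnvFields,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate per-fix dive counts, dive depths and the 0.5 Hz TDR trace.

    Counts are negative binomial with the configured log-link predictor,
    forced to zero below the daylight gate (solar angle < -6 deg by
    default).  Each dive is rendered as a symmetric triangular profile on
    the sample grid whose peak sample equals the true maximum depth, so
    detection at the 1 m threshold recovers the truth exactly; surface
    gaps are drawn from the fast/slow bout mixture (minimum 3 samples).
    Returns (tdr table, true dive list).
    """
    rt = config.dive_rate_truth
    dt_cfg = config.depth_truth
    rng = substream(config.seed, "dive")
    dt = 1.0 / config.tdr_hz
    half_win = config.fix_interval_s / 2.0

    if truth_states.empty:
        return (pd.DataFrame(columns=["bird_id", "timestamp", "depth_m"]),
                pd.DataFrame(columns=["bird_id", "start", "end", "max_depth_m",
                                      "fix_timestamp", "state"]))

    ts = truth_states.copy()
    ts["solar_deg"] = envsample.solar_angle(ts["timestamp"], ts["lon"].values, ts["lat"].values)
    ts["tod_h"] = envsample.time_of_day(ts["timestamp"])
    ts["cloud_pct"] = envsample.sample_field(env.cloud, ts["timestamp"], ts["lon"].values,
                                             ts["lat"].values, space_method="bilinear")
    if ts[["zsd_true", "cloud_pct"]].isna().any().any():
        raise ValueError("fix outside environmental grid; cannot evaluate dive predictor")

    birds = sorted(ts["bird_id"].unique())
    intercepts = {b: rng.normal(0.0, rt.bird_sd) for b in birds}
    eta = rt.linear_predictor(ts["solar_deg"].values, ts["zsd_true"].values,
                              ts["tod_h"].values,
                              np.array([intercepts[b] for b in ts["bird_id"]]))
    if not np.all(np.isfinite(eta)):
        raise ValueError("dive-rate predictor non-finite; check dive_rate_truth coefficients")
    mu = np.exp(eta)
    gated = ts["solar_deg"].values < rt.gate_deg
    p_nb = rt.theta / (rt.theta + mu)
    counts = rng.negative_binomial(rt.theta, p_nb)
    counts = np.where(gated, 0, counts)
    if rt.ars_only:
        counts = np.where(ts["state"].values == ARS, counts, 0)

    dive_rows = []
    tdr_frames = []
    min_gap = 3 * dt
    for bird in birds:
        bi = ts["bird_id"].values == bird
        idx = np.where(bi & (counts > 0))[0]
        bird_dives = []
        for i in idx:
            n = int(counts[i])
            fix_time = ts["timestamp"].iloc[i]
            w0 = fix_time - pd.Timedelta(seconds=half_win - dt)
            alpha = ts["solar_deg"].iloc[i]
            state = int(ts["state"].iloc[i])
            mean_d = dt_cfg.mean_depth(alpha, ts["zsd_true"].iloc[i],
                                       ts["cloud_pct"].iloc[i], state)
            a_tr = (dt_cfg.floor_m - mean_d) / dt_cfg.noise_sd_m
            b_tr = (dt_cfg.cap_m - mean_d) / dt_cfg.noise_sd_m
            depths = stats.truncnorm.rvs(a_tr, b_tr, loc=mean_d, scale=dt_cfg.noise_sd_m,
                                         size=n, random_state=rng)
            gaps = config.bout_truth.sample_gaps(n, rng)
            gaps = np.maximum(np.ceil(gaps / dt) * dt, min_gap)
            cursor = 0.0 + float(np.ceil(rng.uniform(0, 4 * dt) / dt)) * dt
            for j in range(n):
                n_samp = int(max(3, round(depths[j])))
                if n_samp % 2 == 0:
                    n_samp += 1
                dur = n_samp * dt
                if cursor + dur > 2 * half_win - dt:
                    break  # window full; truth is what is rendered
                start = w0 + pd.Timedelta(seconds=cursor)
                dive_rows.append({
                    "bird_id": bird, "start": start,
                    "end": start + pd.Timedelta(seconds=dur),
                    "duration_s": dur, "max_depth_m": float(depths[j]),
                    "n_samples": n_samp, "fix_timestamp": fix_time, "state": state,
                })
                bird_dives.append((start, n_samp, float(depths[j])))
                cursor += dur + gaps[j]
        # render the 0.5 Hz trace spanning this bird's fixes
        t_first = ts.loc[bi, "timestamp"].min() - pd.Timedelta(seconds=half_win)
        t_last = ts.loc[bi, "timestamp"].max() + pd.Timedelta(seconds=half_win)
        n_samples = int((t_last - t_first).total_seconds() / dt) + 1
        trace = np.zeros(n_samples)
        for start, n_samp, maxd in bird_dives:
            i0 = int(round((start - t_first).total_seconds() / dt))
            c = (n_samp - 1) / 2.0
            w = 1.0 - np.abs(np.arange(n_samp) - c) / (c + 1.0)
            trace[i0:i0 + n_samp] = 1.0 + (maxd - 1.0) * w
        tdr_frames.append(pd.DataFrame({
            "bird_id": bird,
            "timestamp": t_first + pd.to_timedelta(np.arange(n_samples) * dt, unit="s"),
            "depth_m": trace,
        }))
    tdr = pd.concat(tdr_frames, ignore_index=True) if tdr_frames else pd.DataFrame(
        columns=["bird_id", "timestamp", "depth_m"])
    truth_dives = pd.DataFrame(dive_rows) if dive_rows else pd.DataFrame(
        columns=["bird_id", "start", "end", "duration_s", "max_depth_m",
                 "n_samples", "fix_timestamp", "state"])
    return tdr, truth_dives


def simulate_hmm_dataset(
    params: HMMParams,
    n_tracks: int,
    n_steps: int,
    rng: np.random.Generator,
    zsd_mean: float = 7.5,
    zsd_sd: float = 2.6,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Step/turn/Zsd series straight from the movement process.

    A lean path for parameter-recovery experiments: no geography, just the
    observation series the HMM likelihood consumes.  Zsd along each track
    is a positive AR(1)-smoothed series with the configured moments.
    Returns (frame with track_id/step_km/turn_rad/zsd, true states).
    """
    frames = []
    all_states = []
    phi = 0.9  # temporal persistence of encountered Zsd
    for k in range(n_tracks):
        e = rng.normal(0.0, 1.0, n_steps)
        g = np.empty(n_steps)
        g[0] = e[0]
        for t in range(1, n_steps):
            g[t] = phi * g[t - 1] + np.sqrt(1 - phi * phi) * e[t]
        z = np.maximum(zsd_mean + zsd_sd * g, 0.5)
        states, steps, turns = simulate_series(params, z, rng)
        frames.append(pd.DataFrame({
            "track_id": f"track{k:03d}", "step_km": steps,
            "turn_rad": turns, "zsd": z,
        }))
        all_states.append(states)
    return pd.concat(frames, ignore_index=True), np.concatenate(all_states)


def simulate_fix_table(
    truth: DiveRateTruth,
    n_fixes: int,
    n_birds: int,
    rng: np.random.Generator,
    zsd_mean: float = 7.5,
    zsd_sd: float = 2.6,
    ar_rho: float = 0.4,
) -> pd.DataFrame:
    """Annotated fix table straight from the dive-rate truth.

    A lean design for smooth-recovery experiments: covariates are drawn
    with independent margins (solar angle uniform over the daylight range,
    Zsd positive-normal, cloud uniform, time of day uniform) so the solar
    x Zsd surface is identifiable without the diel concurvity a physical
    track imposes.  Counts are negative binomial from the truth predictor;
    an AR(1) latent log-rate wobble with coefficient ``ar_rho`` induces the
    serial correlation the AR(1) working model is meant to absorb.
    """
    bird = np.repeat([f"bird{b:02d}" for b in range(n_birds)],
                     int(np.ceil(n_fixes / n_birds)))[:n_fixes]
    trip = np.char.add(bird.astype(str), "_t0")
    alpha = rng.uniform(truth.gate_deg, 55.0, n_fixes)
    zsd = np.maximum(rng.normal(zsd_mean, zsd_sd, n_fixes), 0.5)
    cloud = rng.uniform(0.0, 100.0, n_fixes)
    tod = rng.uniform(0.0, 24.0, n_fixes)
    intercepts = dict(zip(np.unique(bird), rng.normal(0, truth.bird_sd, n_birds)))
    eta = truth.linear_predictor(alpha, zsd, tod,
                                 np.array([intercepts[b] for b in bird]))
    if ar_rho > 0:
        e = rng.normal(0.0, 0.25, n_fixes)
        w = np.empty(n_fixes)
        w[0] = e[0]
        for t in range(1, n_fixes):
            same = bird[t] == bird[t - 1]
            w[t] = ar_rho * w[t - 1] + np.sqrt(1 - ar_rho ** 2) * e[t] if same else e[t]
        eta = eta + w
    mu = np.exp(eta)
    counts = rng.negative_binomial(truth.theta, truth.theta / (truth.theta + mu))
    return pd.DataFrame({
        "bird_id": bird, "trip_id": trip, "solar_deg": alpha, "zsd_m": zsd,
        "cloud_pct": cloud, "tod_h": tod, "dive_count": counts,
    })


def simulate_bout_table(
    truth: DepthTruth,
    n_bouts: int,
    n_birds: int,
    rng: np.random.Generator,
    bird_sd_m: float = 1.0,
    zsd_mean: float = 7.5,
    zsd_sd: float = 2.6,
    state_probs: tuple[float, float, float] = (0.15, 0.6, 0.25),
) -> pd.DataFrame:
    """Annotated bout table straight from the depth truth (no water-depth
    effect, so that term is a true null for shrinkage checks)."""
    bird = np.repeat([f"bird{b:02d}" for b in range(n_birds)],
                     int(np.ceil(n_bouts / n_birds)))[:n_bouts]
    alpha = rng.uniform(-5.0, 55.0, n_bouts)
    zsd = np.maximum(rng.normal(zsd_mean, zsd_sd, n_bouts), 0.5)
    cloud = rng.uniform(0.0, 100.0, n_bouts)
    tod = rng.uniform(0.0, 24.0, n_bouts)
    wdepth = rng.uniform(20.0, 120.0, n_bouts)
    state = rng.choice(3, size=n_bouts, p=np.asarray(state_probs))
    intercepts = dict(zip(np.unique(bird), rng.normal(0, bird_sd_m, n_birds)))
    mean_d = truth.mean_depth(alpha, zsd, cloud, state) \
        + np.array([intercepts[b] for b in bird])
    depth = np.clip(mean_d + rng.normal(0, truth.noise_sd_m, n_bouts),
                    truth.floor_m, truth.cap_m)
    from .movehmm import STATES

    return pd.DataFrame({
        "bird_id": bird, "solar_deg": alpha, "zsd_m": zsd, "cloud_pct": cloud,
        "tod_h": tod, "water_depth_m": wdepth,
        "hmm_state": [STATES[s] for s in state], "max_depth_m": depth,
    })


def simulate(config: SimConfig) -> SimOutput:
    """Run the full generator: fields, tracks, dives, TDR."""
    env = gen_env_fields(config)
    gps, truth_states = gen_tracks(config, env)
    tdr, truth_dives = gen_dives_and_tdr(config, truth_states, env)
    return SimOutput(config=config, gps=gps, tdr=tdr, env=env,
                     truth_states=truth_states, truth_dives=truth_dives)


def write_output(sim: SimOutput, out_dir: str | Path) -> None:
    """Write all generated tables and grids as plain CSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim.gps.to_csv(out / "gps.csv", index=False)
    sim.tdr.to_csv(out / "tdr.csv", index=False)
    sim.truth_states.to_csv(out / "truth_states.csv", index=False)
    sim.truth_dives.to_csv(out / "truth_dives.csv", index=False)
    envsample.write_fields(sim.env, out / "env")
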