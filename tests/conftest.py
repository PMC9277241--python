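"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from divevis import movehmm, synthio


# ---------------------------------------------------------------------------
# independent oracles (never call the code paths they check)


def brute_force_loglik(params: movehmm.HMMParams, df: pd.DataFrame) -> float:
    """Log-likelihood by explicit summation over all 3^T state paths."""
    steps = df["step_km"].to_numpy(float)
    turns = df["turn_rad"].to_numpy(float)
    z = df["zsd"].to_numpy(float)
    T = steps.size

    def emis(s, t):
        mu, sd = params.step_mean[s], params.step_sd[s]
        a = (mu / sd) ** 2
        if steps[t] > 0:
            d = stats.gamma.logpdf(steps[t], a, scale=sd * sd / mu)
            if params.zero_mass[s] > 0:
                d += np.log1p(-params.zero_mass[s])
        else:
            d = np.log(params.zero_mass[s]) if params.zero_mass[s] > 0 else -1e10
        if np.isfinite(turns[t]):
            d += stats.vonmises.logpdf(turns[t], params.turn_kappa[s],
                                       loc=params.turn_mean[s])
        return d

    gam = movehmm.transition_matrix(params.beta0, params.beta_z, z)
    total = -np.inf
    for path in itertools.product(range(3), repeat=T):
        lp = np.log(params.delta[path[0]]) + emis(path[0], 0)
        for t in range(1, T):
            lp += np.log(gam[t, path[t - 1], path[t]]) + emis(path[t], t)
        total = np.logaddexp(total, lp)
    return float(total)


def brute_force_viterbi(params: movehmm.HMMParams, df: pd.DataFrame) -> np.ndarray:
    """Most probable path by exhaustive enumeration (ties: lowest indices)."""
    steps = df["step_km"].to_numpy(float)
    turns = df["turn_rad"].to_numpy(float)
    z = df["zsd"].to_numpy(float)
    T = steps.size

    def emis(s, t):
        mu, sd = params.step_mean[s], params.step_sd[s]
        a = (mu / sd) ** 2
        if steps[t] > 0:
            d = stats.gamma.logpdf(steps[t], a, scale=sd * sd / mu)
            if params.zero_mass[s] > 0:
                d += np.log1p(-params.zero_mass[s])
        else:
            d = np.log(params.zero_mass[s]) if params.zero_mass[s] > 0 else -1e10
        if np.isfinite(turns[t]):
            d += stats.vonmises.logpdf(turns[t], params.turn_kappa[s],
                                       loc=params.turn_mean[s])
        return d

    gam = movehmm.transition_matrix(params.beta0, params.beta_z, z)
    best_lp, best_path = -np.inf, None
    for path in itertools.product(range(3), repeat=T):
        lp = np.log(params.delta[path[0]]) + emis(path[0], 0)
        for t in range(1, T):
            lp += np.log(gam[t, path[t - 1], path[t]]) + emis(path[t], t)
        if lp > best_lp + 1e-12:
            best_lp, best_path = lp, path
    return np.asarray(best_path)


def noaa_oracle_elevation(ts: pd.Timestamp, lon: float, lat: float) -> float:
    """Solar elevation by the Michalsky (Astronomical Almanac) algorithm.

    A formulation independent of the package's Meeus-series implementation:
    ecliptic longitude from mean longitude + anomaly corrections, right
    ascension/declination, and the hour angle from Greenwich mean sidereal
    time.  Accurate to ~0.01 deg over 1950-2050.
    """
    ts = pd.Timestamp(ts)
    if ts.tz is None:
        ts = ts.tz_localize("UTC")
    n = (ts - pd.Timestamp("2000-01-01 12:00", tz="UTC")) / pd.Timedelta(days=1)
    d = np.pi / 180.0
    mnlong = (280.460 + 0.9856474 * n) % 360.0
    mnanom = (357.528 + 0.9856003 * n) % 360.0
    eclong = (mnlong + 1.915 * np.sin(mnanom * d) + 0.020 * np.sin(2 * mnanom * d)) % 360.0
    oblq = 23.439 - 0.0000004 * n
    ra = np.degrees(np.arctan2(np.cos(oblq * d) * np.sin(eclong * d),
                               np.cos(eclong * d))) % 360.0
    dec = np.degrees(np.arcsin(np.sin(oblq * d) * np.sin(eclong * d)))
    hour = ts.hour + ts.minute / 60.0 + ts.second / 3600.0 + ts.microsecond / 3.6e9
    gmst = (6.697375 + 0.0657098242 * n + hour) % 24.0
    lmst = (gmst + lon / 15.0) % 24.0
    ha = (lmst * 15.0 - ra + 180.0) % 360.0 - 180.0
    return float(np.degrees(np.arcsin(
        np.sin(dec * d) * np.sin(lat * d)
        + np.cos(dec * d) * np.cos(lat * d) * np.cos(ha * d))))


def random_hmm_params(rng: np.random.Generator, with_z: bool = True,
                      zero_mass: bool = False) -> movehmm.HMMParams:
    """A random valid parameter set for oracle comparisons."""
    return movehmm.HMMParams(
        step_mean=rng.uniform(0.05, 3.0, 3),
        step_sd=rng.uniform(0.05, 1.5, 3),
        turn_mean=rng.uniform(-np.pi, np.pi, 3),
        turn_kappa=rng.uniform(0.1, 8.0, 3),
        beta0=rng.normal(-1.5, 1.0, (3, 3)),
        beta_z=rng.normal(0.0, 0.4, (3, 3)) if with_z else np.zeros((3, 3)),
        delta=rng.dirichlet(np.ones(3)),
        zero_mass=rng.uniform(0.01, 0.2, 3) if zero_mass else np.zeros(3),
    )


# ---------------------------------------------------------------------------
# fixtures


@pytest.fixture(scope="session")
def small_sim():
    """One small simulated colony shared across read-only tests."""
    cfg = synthio.SimConfig(seed=11, n_birds=2, n_trips_per_bird=1, days_per_trip=1.0)
    return synthio.simulate(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
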