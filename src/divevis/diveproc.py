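"""Dive detection, bout structure and dive-to-track assignment.

A dive is a maximal run of depth samples strictly greater than a threshold
(1 m by default) in a fixed-rate depth series.  Dives cluster into bouts;
the bout-ending criterion (BEC) is estimated by fitting a two-process
broken-stick model to the log-frequency of binned inter-dive intervals
(Sibly-style nonlinear least squares):

    log f(t) = log( Nf*lf*exp(-lf*t) + Ns*ls*exp(-ls*t) ),

with the criterion at the intersection of the two processes,

    bec = log(Nf*lf / (Ns*ls)) / (lf - ls).

Dives are assigned to the track fix nearest in time to the dive start
(ties break to the earlier fix).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

__all__ = [
    "BoutModel",
    "subsample_depth",
    "detect_dives",
    "fit_bec",
    "bec_from_rates",
    "assign_bouts",
    "attach_dives",
]

logger = logging.getLogger(__name__)


@dataclass
class BoutModel:
    """Fitted two-process inter-dive interval model."""

    n_fast: float
    rate_fast: float  # lf, per second
    n_slow: float
    rate_slow: float  # ls, per second
    bec_s: float
    residual_ss: float
    converged: bool
    message: str = ""


def bec_from_rates(n_fast: float, rate_fast: float, n_slow: float, rate_slow: float) -> float:
    """Intersection of the fast and slow interval processes (seconds)."""
    return float(np.log((n_fast * rate_fast) / (n_slow * rate_slow)) / (rate_fast - rate_slow))


def _infer_dt(ts: pd.Series) -> float:
    d = np.diff(ts.astype("int64").to_numpy()) / 1e9
    if d.size == 0:
        raise ValueError("depth series needs >= 2 samples")
    dt = float(np.median(d))
    if dt <= 0:
        raise ValueError("non-increasing timestamps in depth series")
    return dt


def subsample_depth(series: pd.DataFrame, target_hz: float = 0.5) -> pd.DataFrame:
    """Decimate a depth series to ``target_hz`` by keeping every k-th sample.

    The source rate must be an integer multiple of the target rate; no
    interpolation is performed.  Timestamps are preserved.
    """
    ts = pd.to_datetime(series["timestamp"])
    dt = _infer_dt(ts)
    source_hz = 1.0 / dt
    k = source_hz / target_hz
    if abs(k - round(k)) > 1e-6 or round(k) < 1:
        raise ValueError(
            f"source rate {source_hz:g} Hz is not an integer multiple of {target_hz:g} Hz"
        )
    k = int(round(k))
    return series.iloc[::k].reset_index(drop=True)


def detect_dives(series: pd.DataFrame, threshold_m: float = 1.0) -> pd.DataFrame:
    """Detect dives as maximal runs of depth > ``threshold_m`` (strict).

    ``series``: columns timestamp, depth_m (positive down) at a fixed rate;
    a ``bird_id`` column is carried through if present.  Negative depths are
    clipped to 0 with a logged count.  Returns one row per dive with
    start/end, duration_s and max_depth_m.
    """
    depth = series["depth_m"].to_numpy(dtype=float).copy()
    neg = depth < 0
    if neg.any():
        logger.warning("clipping %d negative depth samples to 0", int(neg.sum()))
        depth[neg] = 0.0
    ts = pd.to_datetime(series["timestamp"])
    dt = _infer_dt(ts)
    wet = depth > threshold_m
    if not wet.any():
        return pd.DataFrame(columns=["bird_id", "start", "end", "duration_s", "max_depth_m"])
    edges = np.diff(wet.astype(int))
    starts = list(np.where(edges == 1)[0] + 1)
    ends = list(np.where(edges == -1)[0] + 1)
    if wet[0]:
        starts = [0] + starts
    if wet[-1]:
        ends = ends + [len(depth)]
    bird = series["bird_id"].iloc[0] if "bird_id" in series.columns else ""
    rows = []
    tnp = ts.to_numpy()
    for a, b in zip(starts, ends):
        rows.append({
            "bird_id": bird,
            "start": tnp[a],
            "end": tnp[a] + np.timedelta64(int((b - a) * dt * 1e9), "ns"),
            "duration_s": (b - a) * dt,
            "max_depth_m": float(depth[a:b].max()),
        })
    return pd.DataFrame(rows)


def fit_bec(
    inter_dive_intervals: np.ndarray,
    bin_width_s: float | str = 5.0,
    min_slow_count: float = 5.0,
) -> BoutModel:
    """Estimate the bout-ending criterion from inter-dive intervals.

    Bins the intervals (default 5 s width; ``"auto"`` scales the width
    with the fast-process quartile, making the estimate scale-equivariant)
    and fits the two-process frequency model to the binned counts by
    nonlinear least squares on the square-root scale — a variance-
    stabilizing transform that keeps sparse tail bins (zeros included)
    informative instead of dropping them.  Flagged as non-converged when
    the optimizer fails, the two rates coincide, or the slow process
    carries fewer than ``min_slow_count`` intervals.
    """
    x = np.asarray(inter_dive_intervals, dtype=float)
    x = x[np.isfinite(x) & (x > 0)]
    if x.size < 50:
        raise ValueError("need >= 50 inter-dive intervals to estimate a BEC")
    if bin_width_s == "auto":
        bin_width_s = max(float(np.quantile(x, 0.25)) / 2.0, 1e-9)
    edges = np.arange(0.0, x.max() + 2 * bin_width_s, bin_width_s)
    counts, _ = np.histogram(x, bins=edges)
    mids = 0.5 * (edges[:-1] + edges[1:])

    # moment-style starting values: fast = below-median mass, slow = tail
    med = np.median(x)
    fast0 = x[x <= med]
    slow0 = x[x > np.quantile(x, 0.75)]
    lf0 = 1.0 / max(fast0.mean(), 1e-6)
    ls0 = 1.0 / max(slow0.mean(), 1e-6)
    if ls0 >= lf0:
        ls0 = lf0 / 10.0
    p0 = np.log([0.7 * x.size, lf0, 0.3 * x.size, ls0])

    def resid(logp):
        nf, lf, ns, ls = np.exp(np.clip(logp, -50, 50))
        f = (nf * lf * np.exp(-lf * mids) + ns * ls * np.exp(-ls * mids)) * bin_width_s
        return np.sqrt(f) - np.sqrt(counts)

    res = optimize.least_squares(resid, p0, method="lm", max_nfev=5000)
    nf, lf, ns, ls = np.exp(res.x)
    if lf < ls:  # enforce fast/slow labels
        nf, lf, ns, ls = ns, ls, nf, lf
    rss = float(np.sum(res.fun ** 2))
    ok = bool(res.success)
    msg = ""
    if not ok:
        msg = "optimizer failed"
    elif lf / ls < 1.5:
        ok = False
        msg = "processes indistinguishable (rate_fast ~ rate_slow)"
    elif ns < min_slow_count:
        ok = False
        msg = f"slow process too small (Ns = {ns:.1f} < {min_slow_count})"
    bec = bec_from_rates(nf, lf, ns, ls) if (ok and nf * lf > ns * ls) else np.nan
    if ok and not np.isfinite(bec):
        ok = False
        msg = "no positive intersection between processes"
    return BoutModel(n_fast=float(nf), rate_fast=float(lf), n_slow=float(ns),
                     rate_slow=float(ls), bec_s=float(bec), residual_ss=rss,
                     converged=ok, message=msg)


def assign_bouts(dives: pd.DataFrame, bec_s: float) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Group dives into bouts: a new bout starts when the surface gap since
    the previous dive's end exceeds ``bec_s``.

    Returns (dives with ``bout_id``, bout table with per-bout max depth).
    """
    out = []
    bouts = []
    for bird, g in dives.groupby("bird_id", sort=True):
        g = g.sort_values("start").reset_index(drop=True)
        gaps = (pd.to_datetime(g["start"]).iloc[1:].to_numpy()
                - pd.to_datetime(g["end"]).iloc[:-1].to_numpy()) / np.timedelta64(1, "s")
        new_bout = np.concatenate([[True], gaps > bec_s])
        bout_no = np.cumsum(new_bout)
        g = g.assign(bout_id=[f"{bird}_bout{int(b):04d}" for b in bout_no])
        out.append(g)
        for bid, bg in g.groupby("bout_id", sort=False):
            bouts.append({
                "bout_id": bid,
                "bird_id": bird,
                "n_dives": len(bg),
                "start": bg["start"].min(),
                "end": bg["end"].max(),
                "max_depth_m": bg["max_depth_m"].max(),
            })
    dives_out = pd.concat(out, ignore_index=True) if out else dives.assign(bout_id=[])
    return dives_out, pd.DataFrame(bouts)


def attach_dives(
    dives: pd.DataFrame,
    fixes: pd.DataFrame,
    interval_s: float = 300.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Assign each dive to the nearest-in-time track fix of the same bird.

    Nearness uses the dive start; ties break to the earlier fix.  Dives
    farther than ``interval_s / 2`` from every fix stay unassigned (NaT)
    with a logged count.  Returns (dives with ``assigned_fix``, per-fix
    table with ``dive_count`` for every input fix).
    """
    dives = dives.copy()
    dives["assigned_fix"] = pd.Series(pd.NaT, index=dives.index, dtype=object)
    counts = fixes[["bird_id", "timestamp"]].copy()
    counts["dive_count"] = 0
    n_unassigned = 0
    for bird, g in dives.groupby("bird_id", sort=False):
        f = fixes.loc[fixes["bird_id"] == bird]
        if f.empty:
            n_unassigned += len(g)
            continue
        ft = pd.to_datetime(f["timestamp"]).astype("int64").to_numpy() / 1e9
        order = np.argsort(ft)
        ft = ft[order]
        fidx = f.index.to_numpy()[order]
        dt = pd.to_datetime(g["start"]).astype("int64").to_numpy() / 1e9
        pos = np.searchsorted(ft, dt)
        pos = np.clip(pos, 1, max(len(ft) - 1, 1)) if len(ft) > 1 else np.zeros_like(pos)
        left = np.maximum(pos - 1, 0)
        d_left = np.abs(dt - ft[left])
        d_right = np.abs(ft[pos] - dt)
        choose_right = d_right < d_left  # tie -> earlier fix
        best = np.where(choose_right, pos, left)
        dist = np.minimum(d_left, d_right)
        ok = dist <= interval_s / 2.0
        n_unassigned += int((~ok).sum())
        assigned = fidx[best]
        ts_assigned = pd.to_datetime(f.loc[assigned, "timestamp"]).to_numpy()
        dives.loc[g.index[ok], "assigned_fix"] = ts_assigned[ok]
        add = pd.Series(assigned[ok]).value_counts()
        counts.loc[add.index, "dive_count"] += add.values
    if n_unassigned:
        logger.warning("attach_dives: %d dives outside any fix window", n_unassigned)
    dives["assigned_fix"] = pd.to_datetime(dives["assigned_fix"], utc=True)
    return dives, counts
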