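"""End-to-end orchestration: simulate -> preprocess -> dives -> annotate ->
HMM -> GAMs -> report.

``run_all`` executes every stage on a synthetic colony (or pre-generated
run directory data), writes all intermediate artifacts under a fixed run
layout and renders a JSON + markdown report whose every number is
recomputable from the run directory::

    run_dir/
      config.yaml
      data/            gps.csv tdr.csv truth_*.csv env/
      intermediates/   segments.csv trips.csv dives.csv bouts.csv fix_table.csv
      fit/             hmm_*.json decoded.csv curves.csv *_table.csv
      report/          report.json report.md
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diveproc, envsample, movehmm, synthio, trackproc
from .smoothfit import fit_dive_depth_model, fit_dive_rate_model

__all__ = ["run_all", "dives_in_ars_fraction", "render_report", "config_hash"]

logger = logging.getLogger(__name__)


def config_hash(config: synthio.SimConfig) -> str:
    payload = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def dives_in_ars_fraction(decoded_states: np.ndarray, fix_counts: np.ndarray) -> float:
    """Fraction of dive-containing fixes decoded as area-restricted search.

    Returns NaN (flagged by a warning) when no fix contains a dive.
    """
    decoded_states = np.asarray(decoded_states)
    fix_counts = np.asarray(fix_counts)
    has_dive = fix_counts > 0
    if not has_dive.any():
        logger.warning("no dive-containing fixes; ARS fraction undefined")
        return float("nan")
    return float(np.mean(decoded_states[has_dive] == movehmm.ARS))


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.Timestamp):
        return o.isoformat()
    raise TypeError(type(o))


def run_all(
    config: synthio.SimConfig,
    out_dir: str | Path,
    n_restarts: int = 2,
    fallback_bec_s: float = 300.0,
) -> dict:
    """Run the whole analysis chain on a simulated colony; return the report.

    Any stage failure raises with the stage name; artifacts written so far
    remain in place for inspection.
    """
    out = Path(out_dir)
    for sub in ("data", "intermediates", "fit", "report"):
        (out / sub).mkdir(parents=True, exist_ok=True)

    stage = "simulate"
    try:
        sim = synthio.simulate(config)
        synthio.write_output(sim, out / "data")
        (out / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))
        logger.info("simulate: %d fixes, %d TDR samples, %d true dives",
                    len(sim.gps), len(sim.tdr), len(sim.truth_dives))

        stage = "preprocess"
        segments = trackproc.interpolate_track(sim.gps, interval_s=config.fix_interval_s)
        segments = [trackproc.steps_turns(s) for s in segments]
        trips = trackproc.segment_trips(segments, config.colony)
        if not trips:
            raise RuntimeError("no foraging trips detected")
        trip_frames = []
        for tr in trips:
            f = tr.data.copy()
            f.insert(0, "bird_id", tr.bird_id)
            f.insert(1, "trip_id", tr.trip_id)
            trip_frames.append(f)
        fixes = pd.concat(trip_frames, ignore_index=True)
        trackproc.segments_to_frame(segments).to_csv(
            out / "intermediates" / "segments.csv", index=False)
        trip_summary = pd.DataFrame([{
            "trip_id": t.trip_id, "bird_id": t.bird_id, "start": t.start,
            "end": t.end, "duration_h": t.duration_h,
            "max_distance_km": t.max_distance_km} for t in trips])
        trip_summary.to_csv(out / "intermediates" / "trips.csv", index=False)
        logger.info("preprocess: %d segments -> %d trips, %d trip fixes",
                    len(segments), len(trips), len(fixes))

        stage = "dives"
        dives_all = []
        for bird, g in sim.tdr.groupby("bird_id"):
            d = diveproc.detect_dives(g.reset_index(drop=True))
            if len(d):
                d["bird_id"] = bird
                dives_all.append(d)
        dives = (pd.concat(dives_all, ignore_index=True)
                 if dives_all else pd.DataFrame(
                     columns=["bird_id", "start", "end", "duration_s", "max_depth_m"]))
        gaps = []
        for _, g in dives.groupby("bird_id"):
            g = g.sort_values("start")
            gaps.append((pd.to_datetime(g["start"]).iloc[1:].to_numpy()
                         - pd.to_datetime(g["end"]).iloc[:-1].to_numpy())
                        / np.timedelta64(1, "s"))
        gaps = np.concatenate(gaps) if gaps else np.array([])
        bec_s = fallback_bec_s
        bout_model = None
        if gaps.size >= 50:
            bout_model = diveproc.fit_bec(gaps)
            if bout_model.converged:
                bec_s = bout_model.bec_s
            else:
                logger.warning("BEC fit flagged (%s); falling back to %.0f s",
                               bout_model.message, fallback_bec_s)
        dives, bouts = diveproc.assign_bouts(dives, bec_s)
        dives, fix_counts = diveproc.attach_dives(dives, fixes,
                                                  interval_s=config.fix_interval_s)
        dives.to_csv(out / "intermediates" / "dives.csv", index=False)
        bouts.to_csv(out / "intermediates" / "bouts.csv", index=False)
        logger.info("dives: %d detected, %d bouts, bec=%.0f s",
                    len(dives), len(bouts), bec_s)

        stage = "annotate"
        fixes = envsample.annotate(fixes, sim.env)
        fixes["dive_count"] = fix_counts["dive_count"].to_numpy()
        fixes.to_csv(out / "intermediates" / "fix_table.csv", index=False)

        stage = "hmm"
        hmm_data = fixes.rename(columns={"trip_id": "track_id", "zsd_m": "zsd"})
        fit_null = movehmm.fit_hmm(hmm_data, formula="null", n_restarts=n_restarts,
                                   seed=config.seed)
        fit_zsd = movehmm.fit_hmm(hmm_data, formula="zsd", n_restarts=n_restarts,
                                  seed=config.seed)
        dec_null = fit_null.viterbi_states
        dec_zsd = fit_zsd.viterbi_states
        presence = fixes["dive_count"].to_numpy() > 0
        comparison = movehmm.compare_models(fit_null, fit_zsd, dec_null, dec_zsd, presence)
        ars_fraction = dives_in_ars_fraction(dec_zsd, fixes["dive_count"].to_numpy())
        z_lo, z_hi = np.percentile(fixes["zsd_m"].dropna(), [2, 98])
        curves = movehmm.transition_curves(fit_zsd, np.linspace(z_lo, z_hi, 25),
                                           data=hmm_data)
        for name, fit in (("hmm_null", fit_null), ("hmm_zsd", fit_zsd)):
            (out / "fit" / f"{name}.json").write_text(json.dumps({
                "params": fit.params.to_dict(), "loglik": fit.loglik,
                "n_params": fit.n_params, "aic": fit.aic,
                "converged": fit.converged}, indent=1))
        pd.DataFrame({"timestamp": fixes["timestamp"], "bird_id": fixes["bird_id"],
                      "state_null": dec_null, "state_zsd": dec_zsd}).to_csv(
            out / "fit" / "decoded.csv", index=False)
        curves.to_csv(out / "fit" / "curves.csv", index=False)

        stage = "gam_rate"
        rate = fit_dive_rate_model(fixes)
        rate.table.to_csv(out / "fit" / "rate_table.csv", index=False)

        stage = "gam_depth"
        state_of_fix = dict(zip(zip(fixes["bird_id"], fixes["timestamp"]), dec_zsd))
        bout_rows = bouts.copy()
        bstart = pd.to_datetime(bout_rows["start"])
        nearest = []
        for bird, g in bout_rows.groupby("bird_id"):
            f = fixes[fixes["bird_id"] == bird]
            ft = pd.to_datetime(f["timestamp"]).astype("int64").to_numpy()
            bt = pd.to_datetime(g["start"]).astype("int64").to_numpy()
            pos = np.clip(np.searchsorted(ft, bt), 1, max(len(ft) - 1, 1))
            best = np.where((ft[pos] - bt) < (bt - ft[pos - 1]), pos, pos - 1)
            nearest.append(pd.Series(f.index.to_numpy()[best], index=g.index))
        bout_rows["fix_index"] = pd.concat(nearest).sort_index()
        fix_cov = fixes.loc[bout_rows["fix_index"],
                            ["timestamp", "solar_deg", "zsd_m", "cloud_pct",
                             "tod_h", "water_depth_m"]].reset_index(drop=True)
        bout_table = pd.concat([bout_rows.reset_index(drop=True), fix_cov], axis=1)
        bout_table["hmm_state"] = [
            movehmm.STATES[state_of_fix[(b, t)]]
            for b, t in zip(bout_table["bird_id"], bout_table["timestamp"])]
        depth = fit_dive_depth_model(bout_table)
        depth.table.to_csv(out / "fit" / "depth_table.csv", index=False)
        depth.state_contrasts.to_csv(out / "fit" / "state_contrasts.csv", index=False)

        stage = "report"
        if len(dives):
            assigned = dives.dropna(subset=["assigned_fix"]).merge(
                fixes[["bird_id", "timestamp", "lon", "lat"]],
                left_on=["bird_id", "assigned_fix"],
                right_on=["bird_id", "timestamp"], how="inner")
            # covariates are appended from the nearest track point, so the
            # dive's light level is the fix's solar angle
            dive_solar = envsample.solar_angle(
                pd.to_datetime(assigned["assigned_fix"]),
                assigned["lon"].to_numpy(), assigned["lat"].to_numpy())
        else:
            dive_solar = np.array([])
        frac_dark = (float(np.mean(dive_solar < envsample.CIVIL_TWILIGHT_DEG))
                     if np.size(dive_solar) else float("nan"))
        per_day = (dives.assign(day=pd.to_datetime(dives["start"]).dt.date)
                   .groupby(["bird_id", "day"]).size()) if len(dives) else pd.Series(dtype=float)

        report = {
            "config_hash": config_hash(config),
            "seed": config.seed,
            "trips": {
                "count": len(trips),
                "n_fixes": int(len(fixes)),
                "mean_duration_h": float(trip_summary["duration_h"].mean()),
                "mean_max_distance_km": float(trip_summary["max_distance_km"].mean()),
            },
            "dives": {
                "count": int(len(dives)),
                "per_day_mean": float(per_day.mean()) if len(per_day) else 0.0,
                "per_day_sd": float(per_day.std(ddof=1)) if len(per_day) > 1 else 0.0,
                "depth_mean_m": float(dives["max_depth_m"].mean()) if len(dives) else 0.0,
                "depth_sd_m": float(dives["max_depth_m"].std(ddof=1)) if len(dives) > 1 else 0.0,
                "depth_max_m": float(dives["max_depth_m"].max()) if len(dives) else 0.0,
                "n_bouts": int(len(bouts)),
                "bec_s": float(bec_s),
                "bec_converged": bool(bout_model.converged) if bout_model else False,
                "fraction_below_civil_twilight": frac_dark,
            },
            "zsd_encountered": {
                "mean_m": float(fixes["zsd_m"].mean()),
                "sd_m": float(fixes["zsd_m"].std(ddof=1)),
            },
            "hmm": {
                "aic_null": fit_null.aic,
                "aic_zsd": fit_zsd.aic,
                "delta_aic_null_minus_zsd": comparison["delta_aic"],
                "state_agreement_pct": 100.0 * comparison["state_agreement"],
                "metrics_null": comparison["metrics_a"],
                "metrics_zsd": comparison["metrics_b"],
                "dives_in_ars_pct": 100.0 * ars_fraction,
            },
            "rate_model": {
                "table": rate.table.to_dict(orient="records"),
                "deviance_explained_pct": 100.0 * rate.deviance_explained,
                "auc_pct": 100.0 * rate.auc,
                "rho": rate.rho,
                "theta": rate.fit.theta,
            },
            "depth_model": {
                "table": depth.table.to_dict(orient="records"),
                "deviance_explained_pct": 100.0 * depth.deviance_explained,
                "state_contrasts": depth.state_contrasts.to_dict(orient="records"),
            },
            "conservation": {
                "dives_detected": int(len(dives)),
                "dives_assigned": int(dives["assigned_fix"].notna().sum()),
                "sum_fix_counts": int(fixes["dive_count"].sum()),
            },
        }
        (out / "report" / "report.json").write_text(
            json.dumps(report, indent=1, default=_json_default, sort_keys=True))
        (out / "report" / "report.md").write_text(render_report(report))
        return report
    except Exception as e:  # noqa: BLE001 - annotate stage then re-raise
        raise RuntimeError(f"pipeline stage '{stage}' failed: {e}") from e


def render_report(report: dict) -> str:
    """Markdown rendering of the run report."""
    r = report
    lines = [
        "# divevis run report",
        f"config `{r['config_hash']}`, seed {r['seed']}",
        "",
        "## Trips",
        f"- {r['trips']['count']} foraging trips; mean duration "
        f"{r['trips']['mean_duration_h']:.1f} h; mean max range "
        f"{r['trips']['mean_max_distance_km']:.1f} km",
        "",
        "## Dives",
        f"- {r['dives']['count']} dives in {r['dives']['n_bouts']} bouts "
        f"(BEC {r['dives']['bec_s']:.0f} s)",
        f"- {r['dives']['per_day_mean']:.1f} +/- {r['dives']['per_day_sd']:.1f} "
        "dives per bird-day",
        f"- depth {r['dives']['depth_mean_m']:.1f} +/- {r['dives']['depth_sd_m']:.1f} m, "
        f"max {r['dives']['depth_max_m']:.1f} m",
        f"- fraction of dives below civil twilight (solar < -6 deg): "
        f"{100 * r['dives']['fraction_below_civil_twilight']:.2f}%",
        "",
        "## Secchi-disc depth encountered",
        f"- {r['zsd_encountered']['mean_m']:.2f} +/- {r['zsd_encountered']['sd_m']:.2f} m",
        "",
        "## Movement HMM",
        f"- AIC: null {r['hmm']['aic_null']:.1f} vs +Zsd {r['hmm']['aic_zsd']:.1f} "
        f"(delta {r['hmm']['delta_aic_null_minus_zsd']:.1f})",
        f"- decoded-state agreement {r['hmm']['state_agreement_pct']:.1f}%",
        f"- dives in ARS state: {r['hmm']['dives_in_ars_pct']:.1f}%",
        "",
        "## Dive-rate model",
        f"- deviance explained {r['rate_model']['deviance_explained_pct']:.1f}%, "
        f"AUC {r['rate_model']['auc_pct']:.1f}%, rho "
        f"{(r['rate_model']['rho'] or 0):.2f}",
        "",
        "## Dive-depth model",
        f"- deviance explained {r['depth_model']['deviance_explained_pct']:.1f}%",
    ]
    for c in r["depth_model"]["state_contrasts"]:
        lines.append(f"- {c['state']} vs rest: {c['contrast_m']:+.2f} m "
                     f"(p = {c['p_value']:.3g})")
    return "\n".join(lines) + "\n"
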