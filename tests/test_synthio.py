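"""Synthetic-data generator: field statistics, process truth, determinism."""

import numpy as np
import pandas as pd
import pytest

from divevis import diveproc, envsample, movehmm, synthio


class TestEnvFields:
    def test_zsd_field_matches_configured_moments(self):
        cfg = synthio.SimConfig(seed=21)
        env = synthio.gen_env_fields(cfg)
        vals = env.zsd.values.ravel()
        assert vals.mean() == pytest.approx(7.5, abs=0.3)
        assert vals.std() == pytest.approx(2.6, abs=0.5)
        assert (vals > 0).all()

    def test_cloud_bounded_and_bathymetry_ramp(self):
        cfg = synthio.SimConfig(seed=21)
        env = synthio.gen_env_fields(cfg)
        assert ((env.cloud.values >= 0) & (env.cloud.values <= 100)).all()
        # water depth grows away from the colony (positive-down ramp)
        b = env.bathymetry.values
        assert b.min() == pytest.approx(cfg.env_truth.bathy_base_m, abs=1.0)
        assert b.max() > b.min() + 50

    def test_zero_correlation_length_gives_white_noise(self):
        cfg = synthio.SimConfig(seed=5)
        cfg.env_truth.zsd_corr_len_cells = 1e-6
        env = synthio.gen_env_fields(cfg)
        f = np.log(env.zsd.values[0])
        lag1 = np.corrcoef(f[:, :-1].ravel(), f[:, 1:].ravel())[0, 1]
        assert abs(lag1) < 0.1

    def test_same_seed_gives_identical_fields(self):
        a = synthio.gen_env_fields(synthio.SimConfig(seed=9))
        b = synthio.gen_env_fields(synthio.SimConfig(seed=9))
        np.testing.assert_array_equal(a.zsd.values, b.zsd.values)
        np.testing.assert_array_equal(a.cloud.values, b.cloud.values)


class TestTracks:
    def test_zero_slopes_match_analytic_transition_frequencies(self, rng):
        p = synthio.default_hmm_truth()
        p.beta_z = np.zeros((3, 3))
        n = 10_000
        states, _, _ = movehmm.simulate_series(p, np.full(n, 7.5), rng)
        gamma = p.transition_matrix(0.0)
        for i in range(3):
            from_i = states[:-1] == i
            n_i = from_i.sum()
            for j in range(3):
                freq = np.mean(states[1:][from_i] == j)
                se = np.sqrt(gamma[i, j] * (1 - gamma[i, j]) / n_i)
                assert abs(freq - gamma[i, j]) < max(3 * se, 1e-3)

    def test_state_step_ordering_is_preserved(self, small_sim):
        ts = small_sim.truth_states
        # mean realized displacement per state follows the construction
        seg = ts.sort_values(["bird_id", "timestamp"])
        means = []
        for s in range(3):
            m = seg["state"].to_numpy()[:-1] == s
            same_bird = seg["bird_id"].to_numpy()[:-1] == seg["bird_id"].to_numpy()[1:]
            from divevis.trackproc import haversine_km
            d = haversine_km(seg["lon"].to_numpy()[:-1][m & same_bird[:len(m)]],
                             seg["lat"].to_numpy()[:-1][m & same_bird[:len(m)]],
                             seg["lon"].to_numpy()[1:][m & same_bird[:len(m)]],
                             seg["lat"].to_numpy()[1:][m & same_bird[:len(m)]])
            means.append(d.mean() if d.size else 0.0)
        assert means[movehmm.TRANSIT] > means[movehmm.ARS] > means[movehmm.REST]

    def test_no_birds_gives_empty_tables(self):
        cfg = synthio.SimConfig(seed=2, n_birds=0)
        env = synthio.gen_env_fields(cfg)
        gps, truth = synthio.gen_tracks(cfg, env)
        assert len(gps) == 0 and len(truth) == 0

    def test_fixes_at_exact_interval(self, small_sim):
        for _, g in small_sim.truth_states.groupby(["bird_id", "trip_id"]):
            dt = g["timestamp"].diff().dropna() / pd.Timedelta(seconds=1)
            assert (dt == small_sim.config.fix_interval_s).all()


class TestDives:
    def test_no_dives_below_daylight_gate(self, small_sim):
        td = small_sim.truth_dives
        ts = small_sim.truth_states.set_index(["bird_id", "timestamp"])
        sol = [envsample.solar_angle(r.fix_timestamp,
                                     ts.loc[(r.bird_id, r.fix_timestamp), "lon"],
                                     ts.loc[(r.bird_id, r.fix_timestamp), "lat"])
               for r in td.itertuples()]
        assert (np.asarray(sol) >= small_sim.config.dive_rate_truth.gate_deg).all()

    def test_daily_dive_counts_in_reported_band(self):
        # band = field-study mean +/- 1 s.d. of dives per bird-day
        cfg = synthio.SimConfig(seed=31, n_birds=5, n_trips_per_bird=2,
                                days_per_trip=2.0)
        sim = synthio.simulate(cfg)
        bird_days = cfg.n_birds * cfg.n_trips_per_bird * cfg.days_per_trip
        assert bird_days >= 20
        rate = len(sim.truth_dives) / bird_days
        assert 34 <= rate <= 100

    def test_no_dive_exceeds_depth_cap(self, small_sim):
        assert (small_sim.truth_dives["max_depth_m"]
                <= small_sim.config.depth_truth.cap_m).all()
        assert (small_sim.truth_dives["max_depth_m"] > 1.0).all()

    def test_trace_exceeds_threshold_exactly_during_dives(self, small_sim):
        # round trip: re-detecting dives recovers the truth exactly
        for bird, g in small_sim.tdr.groupby("bird_id"):
            det = diveproc.detect_dives(g.reset_index(drop=True))
            truth = small_sim.truth_dives[small_sim.truth_dives["bird_id"] == bird]
            assert len(det) == len(truth)
            np.testing.assert_allclose(
                np.sort(det["max_depth_m"]), np.sort(truth["max_depth_m"]), atol=1e-9)

    def test_ars_only_flag_confines_dives_to_ars(self):
        cfg = synthio.SimConfig(seed=13, n_birds=2, n_trips_per_bird=1,
                                days_per_trip=1.0)
        cfg.dive_rate_truth.ars_only = True
        sim = synthio.simulate(cfg)
        assert len(sim.truth_dives) > 0
        assert (sim.truth_dives["state"] == movehmm.ARS).all()


class TestDeterminism:
    def test_identical_config_gives_identical_output(self):
        cfg = dict(seed=17, n_birds=2, n_trips_per_bird=1, days_per_trip=0.5)
        a = synthio.simulate(synthio.SimConfig(**cfg))
        b = synthio.simulate(synthio.SimConfig(**cfg))
        pd.testing.assert_frame_equal(a.gps, b.gps)
        pd.testing.assert_frame_equal(a.tdr, b.tdr)
        pd.testing.assert_frame_equal(a.truth_dives, b.truth_dives)
        np.testing.assert_array_equal(a.env.zsd.values, b.env.zsd.values)

    def test_rate_predictor_rejects_nonfinite_coefficients(self):
        cfg = synthio.SimConfig(seed=1, n_birds=1, n_trips_per_bird=1,
                                days_per_trip=0.25)
        cfg.dive_rate_truth.base_log_rate = np.inf
        env = synthio.gen_env_fields(cfg)
        gps, truth = synthio.gen_tracks(cfg, env)
        with pytest.raises(ValueError, match="non-finite|coefficients"):
            synthio.gen_dives_and_tdr(cfg, truth, env)
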