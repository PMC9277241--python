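"""Dive detection, bout criterion estimation and dive-fix assignment."""

import numpy as np
import pandas as pd
import pytest

from divevis import diveproc


def _depth_series(depths, hz=0.5, t0="2021-06-15 09:00", bird="b0"):
    base = pd.Timestamp(t0, tz="UTC")
    dt = 1.0 / hz
    return pd.DataFrame({
        "bird_id": bird,
        "timestamp": [base + pd.Timedelta(seconds=i * dt) for i in range(len(depths))],
        "depth_m": depths,
    })


class TestSubsample:
    def test_4hz_to_half_hz_keeps_every_eighth(self):
        s = _depth_series(np.arange(32.0), hz=4.0)
        out = diveproc.subsample_depth(s, target_hz=0.5)
        assert len(out) == 4
        np.testing.assert_allclose(out["depth_m"], [0, 8, 16, 24])

    def test_half_hz_is_identity(self):
        s = _depth_series([0, 1, 2, 3], hz=0.5)
        out = diveproc.subsample_depth(s, target_hz=0.5)
        pd.testing.assert_frame_equal(out, s)

    def test_non_integer_ratio_is_rejected(self):
        s = _depth_series(np.zeros(20), hz=0.7)
        with pytest.raises(ValueError, match="integer multiple"):
            diveproc.subsample_depth(s, target_hz=0.5)

    def test_3hz_is_exact_sixfold_decimation(self):
        s = _depth_series(np.arange(30.0), hz=3.0)
        out = diveproc.subsample_depth(s, target_hz=0.5)
        assert len(out) == 5


class TestDetectDives:
    def test_single_run_duration_and_max(self):
        s = _depth_series([0, 0.5, 1.2, 3.0, 0.8, 0])
        d = diveproc.detect_dives(s)
        assert len(d) == 1
        assert d["max_depth_m"].iloc[0] == pytest.approx(3.0)
        assert d["duration_s"].iloc[0] == pytest.approx(4.0)

    def test_threshold_is_strictly_greater(self):
        s = _depth_series([0.2, 1.0, 1.0, 0.9, 0.0])
        assert len(diveproc.detect_dives(s)) == 0

    def test_subthreshold_sample_splits_runs(self):
        s = _depth_series([0, 2.0, 2.5, 0.5, 1.8, 2.2, 0])
        d = diveproc.detect_dives(s)
        assert len(d) == 2

    def test_negative_depths_clipped(self, caplog):
        s = _depth_series([-0.5, 2.0, -0.1, 0.0])
        d = diveproc.detect_dives(s)
        assert len(d) == 1


class TestBoutCriterion:
    def test_two_process_mixture_recovers_analytic_bec(self, rng):
        p, lf, ls, n = 0.7, 1 / 20.0, 1 / 600.0, 2000
        fast = rng.random(n) < p
        iv = rng.exponential(np.where(fast, 1 / lf, 1 / ls))
        bm = diveproc.fit_bec(iv)
        true_bec = diveproc.bec_from_rates(p * n, lf, (1 - p) * n, ls)
        assert bm.converged
        assert bm.rate_fast > bm.rate_slow
        assert bm.bec_s == pytest.approx(true_bec, rel=0.20)
        # criterion lies between the two process means
        assert 20.0 < bm.bec_s < 600.0

    def test_single_exponential_is_flagged(self, rng):
        bm = diveproc.fit_bec(rng.exponential(100.0, 600))
        assert not bm.converged
        assert "indistinguishable" in bm.message or "slow process" in bm.message

    def test_vanishing_slow_process_is_flagged(self, rng):
        # p -> 1: essentially no slow intervals to pin the criterion
        iv = np.concatenate([rng.exponential(20.0, 1000), rng.exponential(600.0, 2)])
        bm = diveproc.fit_bec(iv)
        assert not bm.converged

    def test_scale_equivariance(self, rng):
        p, n = 0.7, 3000
        fast = rng.random(n) < p
        iv = rng.exponential(np.where(fast, 20.0, 600.0))
        b1 = diveproc.fit_bec(iv, bin_width_s="auto")
        s = 7.0
        b2 = diveproc.fit_bec(iv * s, bin_width_s="auto")
        assert b2.bec_s == pytest.approx(s * b1.bec_s, rel=0.02)


class TestBouts:
    def _dives(self, gaps_s, dur=10.0, bird="b0"):
        rows = []
        t = pd.Timestamp("2021-06-15 09:00", tz="UTC")
        for g in np.concatenate([[0.0], np.asarray(gaps_s, dtype=float)]):
            t = t + pd.Timedelta(seconds=g)
            rows.append({"bird_id": bird, "start": t,
                         "end": t + pd.Timedelta(seconds=dur),
                         "duration_s": dur, "max_depth_m": 5.0})
            t = t + pd.Timedelta(seconds=dur)
        return pd.DataFrame(rows)

    def test_single_long_gap_splits_bouts(self):
        dives, bouts = diveproc.assign_bouts(self._dives([10, 10, 900]), bec_s=300)
        sizes = sorted(bouts["n_dives"])
        assert sizes == [1, 3]

    def test_infinite_bec_gives_one_bout(self):
        _, bouts = diveproc.assign_bouts(self._dives([10, 500, 2000]), bec_s=np.inf)
        assert len(bouts) == 1

    def test_zero_bec_gives_one_bout_per_dive(self):
        dives, bouts = diveproc.assign_bouts(self._dives([10, 500, 2000]), bec_s=0)
        assert len(bouts) == len(dives)

    def test_bout_max_depth_is_max_over_members(self):
        d = self._dives([10, 10])
        d.loc[1, "max_depth_m"] = 12.0
        _, bouts = diveproc.assign_bouts(d, bec_s=300)
        assert bouts["max_depth_m"].iloc[0] == 12.0


class TestAttachDives:
    def _fixes(self, times_s, bird="b0"):
        base = pd.Timestamp("2021-06-15 09:00", tz="UTC")
        return pd.DataFrame({
            "bird_id": bird,
            "timestamp": [base + pd.Timedelta(seconds=float(s)) for s in times_s],
        })

    def _dives_at(self, starts_s, bird="b0"):
        base = pd.Timestamp("2021-06-15 09:00", tz="UTC")
        return pd.DataFrame({
            "bird_id": bird,
            "start": [base + pd.Timedelta(seconds=float(s)) for s in starts_s],
            "end": [base + pd.Timedelta(seconds=float(s) + 8) for s in starts_s],
            "max_depth_m": 5.0,
        })

    def test_nearest_fix_wins(self):
        dives, counts = diveproc.attach_dives(self._dives_at([299]),
                                              self._fixes([0, 300, 600]))
        assert dives["assigned_fix"].iloc[0] == self._fixes([300])["timestamp"].iloc[0]

    def test_exact_tie_goes_to_earlier_fix(self):
        dives, counts = diveproc.attach_dives(self._dives_at([150]),
                                              self._fixes([0, 300, 600]))
        assert dives["assigned_fix"].iloc[0] == self._fixes([0])["timestamp"].iloc[0]

    def test_multiple_dives_accumulate_on_one_fix(self):
        dives, counts = diveproc.attach_dives(self._dives_at([290, 300, 310]),
                                              self._fixes([0, 300, 600]))
        assert counts["dive_count"].tolist() == [0, 3, 0]

    def test_distant_dive_stays_unassigned(self):
        dives, counts = diveproc.attach_dives(self._dives_at([5000]),
                                              self._fixes([0, 300, 600]))
        assert dives["assigned_fix"].isna().all()
        assert counts["dive_count"].sum() == 0

    def test_counts_conserve_assigned_dives(self, rng):
        starts = np.sort(rng.uniform(0, 3600, 40))
        dives, counts = diveproc.attach_dives(self._dives_at(starts),
                                              self._fixes(np.arange(0, 3601, 300)))
        assert counts["dive_count"].sum() == dives["assigned_fix"].notna().sum()
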