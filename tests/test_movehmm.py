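"""Movement HMM: transition structure, likelihood, decoding, comparison."""

import numpy as np
import pandas as pd
import pytest

from divevis import movehmm, synthio
from .conftest import brute_force_loglik, brute_force_viterbi, random_hmm_params


class TestTransitionMatrix:
    def test_zero_coefficients_give_uniform_rows(self):
        g = movehmm.transition_matrix(np.zeros((3, 3)), np.zeros((3, 3)), 3.0)
        np.testing.assert_allclose(g, np.full((3, 3), 1 / 3))

    def test_large_negative_intercepts_give_identity(self):
        b0 = np.full((3, 3), -20.0)
        np.fill_diagonal(b0, 0.0)
        g = movehmm.transition_matrix(b0, np.zeros((3, 3)), 0.0)
        off = g[~np.eye(3, dtype=bool)]
        assert (off < 1e-8).all()

    def test_rows_sum_to_one(self, rng):
        for _ in range(20):
            p = random_hmm_params(rng)
            g = movehmm.transition_matrix(p.beta0, p.beta_z, float(rng.normal(7, 3)))
            np.testing.assert_allclose(g.sum(axis=1), 1.0, atol=1e-12)

    def test_nonfinite_covariate_is_rejected(self):
        with pytest.raises(ValueError):
            movehmm.transition_matrix(np.zeros((3, 3)), np.zeros((3, 3)), np.nan)


class TestStationary:
    def test_uniform_matrix(self):
        pi = movehmm.stationary_dist(np.full((3, 3), 1 / 3))
        np.testing.assert_allclose(pi, 1 / 3)

    def test_doubly_stochastic_is_uniform(self):
        g = np.array([[0.5, 0.3, 0.2], [0.2, 0.5, 0.3], [0.3, 0.2, 0.5]])
        np.testing.assert_allclose(movehmm.stationary_dist(g), 1 / 3, atol=1e-12)

    def test_matches_matrix_power_limit(self, rng):
        for _ in range(20):
            g = rng.dirichlet(np.ones(3), size=3)
            pi = movehmm.stationary_dist(g)
            limit = np.linalg.matrix_power(g, 1000)[0]
            np.testing.assert_allclose(pi, limit, atol=1e-8)


class TestLoglik:
    def test_single_point_collapses_to_mixture_density(self, rng):
        p = random_hmm_params(rng)
        # identical emissions in all states: loglik independent of delta
        p = movehmm.HMMParams(
            step_mean=np.full(3, 1.0), step_sd=np.full(3, 0.5),
            turn_mean=np.zeros(3), turn_kappa=np.full(3, 1.0),
            beta0=p.beta0, beta_z=p.beta_z, delta=p.delta)
        df = pd.DataFrame({"step_km": [0.8], "turn_rad": [np.nan], "zsd": [7.0]})
        from scipy import stats
        expected = stats.gamma.logpdf(0.8, (1.0 / 0.5) ** 2, scale=0.25)
        assert movehmm.hmm_loglik(p, df) == pytest.approx(float(expected), abs=1e-10)

    def test_matches_enumeration_oracle_small_T(self, rng):
        for _ in range(10):
            p = random_hmm_params(rng, zero_mass=True)
            T = int(rng.integers(2, 8))
            _, steps, turns = movehmm.simulate_series(p, np.full(T, 7.0), rng)
            df = pd.DataFrame({"step_km": steps, "turn_rad": turns,
                               "zsd": rng.normal(7, 2, T)})
            got = movehmm.hmm_loglik(p, df)
            want = brute_force_loglik(p, df)
            assert got == pytest.approx(want, abs=1e-8)

    def test_negative_step_is_rejected(self, rng):
        p = random_hmm_params(rng)
        df = pd.DataFrame({"step_km": [1.0, -0.1], "turn_rad": [np.nan, 0.1],
                           "zsd": [7.0, 7.0]})
        with pytest.raises(ValueError):
            movehmm.hmm_loglik(p, df)


class TestViterbi:
    def test_matches_enumeration_argmax(self, rng):
        for _ in range(10):
            p = random_hmm_params(rng)
            T = int(rng.integers(3, 8))
            _, steps, turns = movehmm.simulate_series(p, np.full(T, 7.0), rng)
            df = pd.DataFrame({"step_km": steps, "turn_rad": turns,
                               "zsd": rng.normal(7, 2, T)})
            got = movehmm.viterbi(p, df)
            want = brute_force_viterbi(p, df)
            np.testing.assert_array_equal(got, want)

    def test_dominant_emission_gives_constant_path(self):
        p = movehmm.HMMParams(
            step_mean=np.array([0.01, 5.0, 50.0]), step_sd=np.array([0.01, 0.5, 5.0]),
            turn_mean=np.zeros(3), turn_kappa=np.zeros(3),
            beta0=np.zeros((3, 3)), beta_z=np.zeros((3, 3)),
            delta=np.full(3, 1 / 3))
        df = pd.DataFrame({"step_km": np.full(20, 5.0),
                           "turn_rad": np.full(20, np.nan), "zsd": np.full(20, 7.0)})
        assert (movehmm.viterbi(p, df) == 1).all()


class TestFit:
    def test_frozen_zero_slope_matches_null_loglik(self, rng):
        p = synthio.default_hmm_truth()
        df, _ = synthio.simulate_hmm_dataset(p, 5, 200, rng)
        null = movehmm.fit_hmm(df, formula="null", n_restarts=1, seed=1)
        # evaluate the null MLE under the zsd formula (slopes exactly zero)
        ll = movehmm.hmm_loglik(null.params, df, formula="zsd")
        assert ll == pytest.approx(null.loglik, abs=1e-6)

    def test_mle_dominates_truth_from_true_inits(self, rng):
        p = synthio.default_hmm_truth()
        df, _ = synthio.simulate_hmm_dataset(p, 10, 200, rng)
        fit = movehmm.fit_hmm(df, formula="zsd", inits=p, n_restarts=1, seed=0)
        ll_truth = movehmm.hmm_loglik(p, df, formula="zsd")
        assert fit.loglik >= ll_truth - 1e-6

    def test_canonical_state_order_by_step_mean(self, rng):
        p = synthio.default_hmm_truth()
        df, _ = synthio.simulate_hmm_dataset(p, 10, 300, rng)
        fit = movehmm.fit_hmm(df, formula="null", n_restarts=2, seed=3)
        assert np.all(np.diff(fit.params.step_mean) > 0)

    def test_aic_identity_and_posterior_normalization(self, rng):
        p = synthio.default_hmm_truth()
        df, _ = synthio.simulate_hmm_dataset(p, 5, 200, rng)
        fit = movehmm.fit_hmm(df, formula="null", n_restarts=1, seed=0)
        assert fit.aic == pytest.approx(2 * fit.n_params - 2 * fit.loglik)
        np.testing.assert_allclose(fit.state_probs.sum(axis=1), 1.0, atol=1e-10)

    def test_aic_prefers_null_when_slope_is_zero(self, rng):
        p = synthio.default_hmm_truth()
        p.beta_z = np.zeros((3, 3))
        wins = 0
        for rep in range(5):
            df, _ = synthio.simulate_hmm_dataset(p, 10, 300, rng)
            null = movehmm.fit_hmm(df, formula="null", n_restarts=1, seed=rep)
            zsd = movehmm.fit_hmm(df, formula="zsd", inits=null.params,
                                  n_restarts=1, seed=rep)
            wins += null.aic < zsd.aic
        assert wins >= 3

    def test_decoded_share_matches_stationary_on_homogeneous_data(self, rng):
        p = synthio.default_hmm_truth()
        z = np.full(20000, 7.5)
        states, steps, turns = movehmm.simulate_series(p, z, rng)
        df = pd.DataFrame({"step_km": steps, "turn_rad": turns, "zsd": z})
        dec = movehmm.viterbi(p, df)
        pi = movehmm.stationary_dist(p.transition_matrix(7.5))
        dec_share = np.bincount(dec, minlength=3) / dec.size
        true_share = np.bincount(states, minlength=3) / states.size
        np.testing.assert_allclose(true_share, pi, atol=0.03)
        np.testing.assert_allclose(dec_share, pi, atol=0.06)


class TestCurves:
    def test_monotone_transit_to_ars_curve_and_ci_covers_estimate(self, rng):
        p = synthio.default_hmm_truth()
        df, _ = synthio.simulate_hmm_dataset(p, 15, 300, rng)
        fit = movehmm.fit_hmm(df, formula="zsd", inits=p, n_restarts=1, seed=0)
        zg = np.linspace(3, 12, 15)
        curves = movehmm.transition_curves(fit, zg, data=df)
        ta = curves[(curves["kind"] == "transition") & (curves["from"] == "transit")
                    & (curves["to"] == "ars")].sort_values("zsd")
        assert fit.params.beta_z[movehmm.TRANSIT, movehmm.ARS] > 0
        assert np.all(np.diff(ta["estimate"]) > 0)
        ok = (curves["lo"] <= curves["estimate"] + 1e-12) & \
             (curves["estimate"] <= curves["hi"] + 1e-12)
        assert ok.all()

    def test_bootstrap_and_delta_intervals_agree(self, rng):
        p = synthio.default_hmm_truth()
        df, _ = synthio.simulate_hmm_dataset(p, 12, 250, rng)
        fit = movehmm.fit_hmm(df, formula="zsd", inits=p, n_restarts=1, seed=0)
        zg = np.array([5.0, 7.5, 10.0])
        delta = movehmm.transition_curves(fit, zg, data=df)
        boot = movehmm.bootstrap_transition_curves(fit, df, zg, n_boot=20, seed=1)
        d = delta[(delta["kind"] == "transition") & (delta["from"] == "transit")
                  & (delta["to"] == "ars")].sort_values("zsd")
        b = boot[(boot["from"] == "transit") & (boot["to"] == "ars")].sort_values("zsd")
        wd = (d["hi"] - d["lo"]).to_numpy()
        wb = (b["hi"] - b["lo"]).to_numpy()
        assert np.all(np.abs(wb - wd) <= 0.5 * np.maximum(wd, wb) + 1e-3)


class TestCompareModels:
    def _dummy_fit(self, aic_like):
        p = synthio.default_hmm_truth()
        return movehmm.HMMFit(params=p, loglik=-aic_like / 2, n_params=0,
                              formula="null", converged=True,
                              state_probs=np.zeros((1, 3)),
                              viterbi_states=np.zeros(1, dtype=int), n_obs=1)

    def test_identical_decodings_agree_fully(self):
        dec = np.array([0, 1, 2, 1, 1])
        rep = movehmm.compare_models(self._dummy_fit(10), self._dummy_fit(12),
                                     dec, dec, dec == 1)
        assert rep["state_agreement"] == 1.0

    def test_perfect_ars_dive_alignment(self):
        dec = np.array([0, 1, 1, 2, 0, 1])
        dive = dec == movehmm.ARS
        rep = movehmm.compare_models(self._dummy_fit(0), self._dummy_fit(0),
                                     dec, dec, dive)
        m = rep["metrics_a"]
        assert (m["hit_rate"], m["miss_rate"], m["precision"]) == (1.0, 0.0, 1.0)

    def test_hand_built_confusion_table(self):
        # dives: 40 decoded ARS, 10 not; no-dive fixes: 20 ARS, 130 not
        dec = np.array([1] * 40 + [0] * 10 + [1] * 20 + [0] * 130)
        dive = np.array([True] * 50 + [False] * 150)
        rep = movehmm.compare_models(self._dummy_fit(0), self._dummy_fit(0),
                                     dec, dec, dive)
        m = rep["metrics_a"]
        assert m["hit_rate"] == pytest.approx(0.8)
        assert m["miss_rate"] == pytest.approx(0.2)
        assert m["precision"] == pytest.approx(40 / 60)

    def test_length_mismatch_is_rejected(self):
        with pytest.raises(ValueError):
            movehmm.compare_models(self._dummy_fit(0), self._dummy_fit(0),
                                   np.zeros(3), np.zeros(4), np.zeros(3, dtype=bool))
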