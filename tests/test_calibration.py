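import datetime as dt
import math

import numpy as np
import pytest
from scipy import optimize

from srstream import (
    CQParams,
    McmcConfig,
    SampleRecord,
    concentration_closed_form,
    log_likelihood,
    posterior_predictive,
    posterior_summary,
    r_squared,
    run_mcmc,
)
from srstream.calibration import DEFAULT_PRIOR_BOUNDS, Chains, _coefficient_of_determination


def records_with_log_residuals(residuals, cq, trend, q=0.5, t0=dt.date(2000, 6, 1)):
    """Records whose log-concentration residuals from the model are exactly `residuals`."""
    recs = []
    for i, r in enumerate(residuals):
        date = t0 + dt.timedelta(days=14 * i)
        t = (date - dt.date(1986, 4, 26)).days
        model = concentration_closed_form(q, float(t), cq, trend)
        recs.append(SampleRecord(date=date, q=q, c=float(model * math.exp(r))))
    return recs


class TestLogLikelihood:
    def test_perfect_fit_unit_sigma(self, cq_params, trend_params):
        recs = records_with_log_residuals([0.0, 0.0], cq_params, trend_params)
        ll = log_likelihood(cq_params, 1.0, recs, trend_params)
        assert ll == pytest.approx(-math.log(2 * math.pi), rel=1e-12)

    def test_hand_computed_three_records(self, cq_params, trend_params):
        resid = [0.1, -0.2, 0.05]
        sigma = 0.109
        recs = records_with_log_residuals(resid, cq_params, trend_params)
        # independent term-by-term arithmetic
        expected = sum(
            -0.5 * (r / sigma) ** 2 - 0.5 * math.log(2 * math.pi * sigma**2) for r in resid
        )
        assert log_likelihood(cq_params, sigma, recs, trend_params) == pytest.approx(expected, rel=1e-12)

    def test_inflating_observations_decreases_likelihood(self, cq_params, trend_params):
        recs = records_with_log_residuals([0.0] * 5, cq_params, trend_params)
        doubled = [SampleRecord(r.date, r.q, 2 * r.c) for r in recs]
        assert log_likelihood(cq_params, 0.109, doubled, trend_params) < log_likelihood(
            cq_params, 0.109, recs, trend_params
        )

    def test_invalid_parameters_return_minus_inf(self, cq_params, trend_params):
        recs = records_with_log_residuals([0.0] * 3, cq_params, trend_params)
        assert log_likelihood((-1.0, 1.37, 2117.0), 0.109, recs, trend_params) == -np.inf
        assert log_likelihood(cq_params, -0.1, recs, trend_params) == -np.inf

    def test_record_order_invariance(self, cq_params, trend_params):
        rng = np.random.default_rng(5)
        recs = records_with_log_residuals(rng.normal(0, 0.1, 30), cq_params, trend_params)
        perm = [recs[i] for i in rng.permutation(len(recs))]
        assert log_likelihood(cq_params, 0.109, recs, trend_params) == pytest.approx(
            log_likelihood(cq_params, 0.109, perm, trend_params), rel=1e-14
        )


class TestRunMcmc:
    def test_same_seed_gives_identical_chains(self, noisy_dataset, trend_params):
        records, _ = noisy_dataset
        cfg = McmcConfig(n_walkers=8, n_draws=60, n_burn=20, seed=9, sigma_mode="fixed")
        ch1 = run_mcmc(records, trend_params, cfg)
        ch2 = run_mcmc(records, trend_params, cfg)
        assert np.array_equal(ch1.samples, ch2.samples)

    def test_prior_only_quantiles_match_prior(self, trend_params):
        cfg = McmcConfig(n_walkers=24, n_draws=1200, n_burn=200, seed=4, prior_only=True)
        ch = run_mcmc([], trend_params, cfg)
        flat = ch.flat
        for i, name in enumerate(ch.param_names):
            lo, hi = np.log(DEFAULT_PRIOR_BOUNDS[name])
            u = (np.log(flat[:, i]) - lo) / (hi - lo)  # should be Uniform(0, 1)
            assert abs(np.median(u) - 0.5) < 0.08, name
            assert abs(np.quantile(u, 0.25) - 0.25) < 0.08, name

    def test_too_few_records_rejected(self, trend_params, cq_params):
        recs = records_with_log_residuals([0.0] * 5, cq_params, trend_params)
        with pytest.raises(ValueError, match="at least 20"):
            run_mcmc(recs, trend_params, McmcConfig())

    def test_identifiable_ratios_sharpen_with_more_data_and_less_noise(self, trend_params, cq_params):
        """Medians of the identifiable combinations b/a and d/b move toward truth as the
        record grows and the measurement noise shrinks (the overall scale of (a, b, d)
        is unidentified and stays prior-driven)."""
        from srstream import SyntheticConfig, generate_dataset

        def ratio_err(noise_cv, keep_every, seed):
            records, _ = generate_dataset(SyntheticConfig(noise_cv=noise_cv, seed=seed))
            records = records[::keep_every]
            cfg = McmcConfig(n_walkers=16, n_draws=500, n_burn=200, seed=seed)
            s = posterior_summary(run_mcmc(records, trend_params, cfg))
            ba = s.params["b"].best_fit / s.params["a"].best_fit
            db = s.params["d"].best_fit / s.params["b"].best_fit
            return max(
                abs(ba - cq_params.b / cq_params.a) / (cq_params.b / cq_params.a),
                abs(db - cq_params.d / cq_params.b) / (cq_params.d / cq_params.b),
            )

        seeds = (6, 7, 8)
        coarse = np.median([ratio_err(noise_cv=0.109, keep_every=16, seed=s) for s in seeds])  # ~44 records
        sharp = np.median([ratio_err(noise_cv=0.02, keep_every=1, seed=s) for s in seeds])  # ~705 records
        assert sharp < coarse

    def test_map_matches_log_space_least_squares(self, noisy_dataset, trend_params):
        """With sigma fixed and flat (log-uniform) priors, the posterior mode is the
        log-space least-squares optimum; compare the identifiable combinations."""
        records, _ = noisy_dataset
        q = np.array([r.q for r in records])
        c = np.array([r.c for r in records])
        t = np.array([r.t_days for r in records], float)

        def sse(log_theta):
            a, b, d = np.exp(log_theta)
            pred = concentration_closed_form(q, t, CQParams(a, b, d), trend_params)
            return float(np.sum((np.log(c) - np.log(pred)) ** 2))

        ls = optimize.minimize(sse, np.log([0.5, 1.0, 1000.0]), method="Nelder-Mead",
                               options={"xatol": 1e-10, "fatol": 1e-12, "maxfev": 8000})
        a_ls, b_ls, d_ls = np.exp(ls.x)
        cfg = McmcConfig(n_walkers=16, n_draws=500, n_burn=200, seed=2, sigma_mode="fixed")
        ch = run_mcmc(records, trend_params, cfg)
        summ = posterior_summary(ch, records, trend_params)
        m = summ.map_estimate
        # the scale direction is unidentified; compare the identified ratios
        assert m["d"] / m["b"] == pytest.approx(d_ls / b_ls, rel=0.05)
        assert m["b"] / m["a"] == pytest.approx(b_ls / a_ls, rel=0.05)


class TestPosteriorSummary:
    def _chains(self, samples, names=("a",)):
        cfg = McmcConfig(n_walkers=8, n_draws=60, n_burn=0, seed=0, sigma_mode="fixed")
        return Chains(samples=samples, param_names=names, acceptance_rate=0.5, rhat={}, config=cfg)

    def test_constant_chain_collapses(self):
        ch = self._chains(np.full((2, 50, 1), 3.25))
        s = posterior_summary(ch)
        iv = s.params["a"]
        assert iv.best_fit == iv.lo_2p5 == iv.hi_97p5 == 3.25

    def test_percentiles_follow_linear_interpolation_convention(self):
        vals = np.arange(1.0, 101.0).reshape(1, 100, 1)
        s = posterior_summary(self._chains(vals))
        # order-statistics oracle: x_(k) interpolated at rank 1 + p*(n-1)
        def oracle(p):
            rank = p * 99.0
            lo = math.floor(rank)
            return (1.0 + lo) + (rank - lo) * 1.0
        assert s.params["a"].lo_2p5 == pytest.approx(oracle(0.025), rel=1e-12)
        assert s.params["a"].hi_97p5 == pytest.approx(oracle(0.975), rel=1e-12)
        assert s.params["a"].best_fit == pytest.approx(50.5, rel=1e-12)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(8)
        vals = rng.lognormal(0, 1, 400)
        s1 = posterior_summary(self._chains(vals.reshape(1, -1, 1)))
        s2 = posterior_summary(self._chains(rng.permutation(vals).reshape(1, -1, 1)))
        assert s1.params["a"] == s2.params["a"]

    def test_empty_chains_rejected(self):
        with pytest.raises(ValueError):
            posterior_summary(self._chains(np.empty((1, 0, 1))))


class TestRSquared:
    def test_perfect_predictions(self, noisefree_dataset, trend_params, cq_params):
        records, _ = noisefree_dataset
        assert r_squared(records[:200], cq_params, trend_params) == pytest.approx(1.0, abs=1e-12)

    def test_mean_prediction_scores_zero(self):
        obs = np.array([1.0, 2.0, 3.0, 6.0])
        assert _coefficient_of_determination(obs, np.full(4, obs.mean())) == pytest.approx(0.0)

    def test_hand_made_four_points(self):
        obs = np.array([1.0, 2.0, 3.0, 4.0])
        fit = np.array([1.1, 1.9, 3.2, 3.8])
        ss_res = 0.01 + 0.01 + 0.04 + 0.04
        ss_tot = (1.5**2 + 0.5**2) * 2
        assert _coefficient_of_determination(obs, fit) == pytest.approx(1 - ss_res / ss_tot, rel=1e-12)

    def test_zero_variance_rejected(self, trend_params, cq_params):
        with pytest.raises(ValueError):
            _coefficient_of_determination(np.ones(5), np.ones(5))


class TestPosteriorPredictive:
    def _degenerate_chains(self, cq, sigma_fixed=0.0, n=20):
        cfg = McmcConfig(n_walkers=8, n_draws=60, n_burn=0, seed=0, sigma_mode="fixed", sigma_fixed=sigma_fixed)
        row = np.array([cq.a, cq.b, cq.d])
        samples = np.tile(row, (1, n, 1))
        return Chains(samples=samples, param_names=("a", "b", "d"), acceptance_rate=1.0, rhat={}, config=cfg)

    def test_degenerate_chain_zero_noise_collapses_to_point(self, cq_params, trend_params):
        ch = self._degenerate_chains(cq_params)
        q = np.array([0.1, 0.5, 2.0])
        t = np.array([5000.0, 7000.0, 9000.0])
        bands = posterior_predictive(ch, q, t, trend_params, quantiles=(0.05, 0.5, 0.95), seed=1)
        point = concentration_closed_form(q, t, cq_params, trend_params)
        for arr in bands.values():
            np.testing.assert_allclose(arr, point, rtol=1e-12)

    def test_band_nesting(self, noisy_dataset, trend_params, cq_params):
        ch = self._degenerate_chains(cq_params, sigma_fixed=0.109)
        q = np.geomspace(0.01, 3.0, 15)
        t = np.full(15, 7000.0)
        bands = posterior_predictive(ch, q, t, trend_params, quantiles=(0.025, 0.25, 0.75, 0.975), seed=3)
        assert np.all(bands[0.025] <= bands[0.25])
        assert np.all(bands[0.25] <= bands[0.75])
        assert np.all(bands[0.75] <= bands[0.975])

    def test_empirical_coverage_of_95_band(self, cq_params, trend_params):
        rng = np.random.default_rng(17)
        n = 1000
        q = rng.uniform(0.01, 3.0, n)
        t = rng.uniform(3000.0, 11000.0, n)
        sigma = 0.109
        truth = concentration_closed_form(q, t, cq_params, trend_params)
        obs = truth * np.exp(rng.normal(0.0, sigma, n) - sigma**2 / 2)
        ch = self._degenerate_chains(cq_params, sigma_fixed=sigma, n=400)
        bands = posterior_predictive(ch, q, t, trend_params, quantiles=(0.025, 0.975), seed=5)
        inside = np.mean((obs >= bands[0.025]) & (obs <= bands[0.975]))
        assert abs(inside - 0.95) < 0.05

    def test_invalid_quantiles_rejected(self, cq_params, trend_params):
        ch = self._degenerate_chains(cq_params)
        with pytest.raises(ValueError):
            posterior_predictive(ch, [0.1], [5000.0], trend_params, quantiles=(0.0, 0.5))


class TestMcmcConfig:
    def test_burn_must_be_less_than_draws(self):
        with pytest.raises(ValueError):
            McmcConfig(n_draws=100, n_burn=100)

    def test_walker_minimum_scales_with_free_parameters(self):
        with pytest.raises(ValueError):
            McmcConfig(n_walkers=6, sigma_mode="estimated")
        assert McmcConfig(n_walkers=6, sigma_mode="fixed").n_walkers == 6
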