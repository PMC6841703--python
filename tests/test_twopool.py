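import numpy as np
import pytest

from primingkit.twopool import (
    DEFAULT_PRIORS,
    TwoPoolParams,
    fit_quality,
    log_posterior,
    mcmc_fit,
    two_pool_rate,
)

DAYS = np.array([1.0, 3.0, 8.0, 15.0, 35.0, 65.0])


class TestRateModel:
    def test_direct_evaluation_at_t0(self):
        p = TwoPoolParams(f1=0.01, k1=0.1, k2=1e-4)
        # k1 f1 C + k2 (1-f1) C = 0.1*0.01*1000 + 1e-4*0.99*1000
        assert two_pool_rate(0.0, p) == pytest.approx(1.0 + 0.099, abs=1e-12)

    def test_single_pool_collapse(self):
        # f1 -> 1 leaves only the fast exponential
        p = TwoPoolParams(f1=1 - 1e-12, k1=0.1, k2=1e-4)
        t = np.array([0.0, 5.0, 20.0])
        assert two_pool_rate(t, p) == pytest.approx(
            0.1 * 1000 * np.exp(-0.1 * t), rel=1e-9
        )

    def test_strictly_decreasing_and_decaying(self):
        p = TwoPoolParams(f1=0.05, k1=0.2, k2=5e-4)
        t = np.linspace(0, 500, 200)
        r = two_pool_rate(t, p)
        assert np.all(np.diff(r) < 0)
        # fast pool exhausted, slow pool decayed by e^(-k2*500)
        assert r[-1] < 0.05 * r[0]

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            TwoPoolParams(f1=0.5, k1=1e-4, k2=0.1)   # k1 <= k2
        with pytest.raises(ValueError):
            TwoPoolParams(f1=1.5, k1=0.1, k2=1e-4)


class TestLogPosterior:
    def test_outside_prior_box(self):
        p = TwoPoolParams(f1=0.8, k1=0.1, k2=1e-4)   # f1 above prior hi
        obs = two_pool_rate(DAYS, p)
        assert log_posterior(p, DAYS, obs) == -np.inf

    def test_perfect_fit_normalizing_constant(self):
        p = TwoPoolParams(f1=0.02, k1=0.1, k2=1e-4)
        obs = two_pool_rate(DAYS, p)
        sd = 0.3
        expected = -DAYS.size / 2 * np.log(2 * np.pi * sd**2)
        assert log_posterior(p, DAYS, obs, noise_sd=sd) == \
            pytest.approx(expected, abs=1e-10)

    def test_brute_force_gaussian_sum(self):
        p = TwoPoolParams(f1=0.03, k1=0.2, k2=5e-4)
        days = np.array([1.0, 8.0, 35.0])
        obs = np.array([7.0, 2.0, 0.8])
        sd = 0.5
        pred = two_pool_rate(days, p)
        expected = sum(
            -0.5 * ((o - m) / sd) ** 2 - np.log(sd) - 0.5 * np.log(2 * np.pi)
            for o, m in zip(obs, pred)
        )
        assert log_posterior(p, days, obs, noise_sd=sd) == \
            pytest.approx(expected, abs=1e-10)

    def test_invalid_noise_sd(self):
        p = TwoPoolParams(f1=0.02, k1=0.1, k2=1e-4)
        with pytest.raises(ValueError):
            log_posterior(p, DAYS, two_pool_rate(DAYS, p), noise_sd=0.0)


class TestFitQuality:
    def test_perfect_predictions(self):
        p = TwoPoolParams(f1=0.02, k1=0.15, k2=2e-4)
        obs = two_pool_rate(DAYS, p)
        r2, rmse = fit_quality(DAYS, obs, p)
        assert r2 == pytest.approx(1.0, abs=1e-10)
        assert rmse == pytest.approx(0.0, abs=1e-10)

    def test_direct_arithmetic(self):
        """obs (0,2), pred (1,1): SS_res = 2, SS_tot = 2 -> r2 = 0, rmse = 1."""
        obs = np.array([0.0, 2.0])
        pred = np.array([1.0, 1.0])
        ss_res = np.sum((obs - pred) ** 2)
        ss_tot = np.sum((obs - obs.mean()) ** 2)
        assert 1 - ss_res / ss_tot == 0.0
        assert np.sqrt(ss_res / 2) == 1.0
        # same arithmetic through the API, via a model that predicts (1,1)
        # is impossible exactly; assert the formula on a near-constant model
        p = TwoPoolParams(f1=1e-8, k1=1.0, k2=1e-8)
        t = np.array([0.0, 1e-6])
        r2, rmse = fit_quality(t, two_pool_rate(t, p) + np.array([-1.0, 1.0]), p)
        assert r2 == pytest.approx(0.0, abs=1e-4)
        assert rmse == pytest.approx(1.0, abs=1e-4)

    def test_permutation_invariance(self):
        p = TwoPoolParams(f1=0.02, k1=0.15, k2=2e-4)
        obs = two_pool_rate(DAYS, p) * 1.05
        r2a, rma = fit_quality(DAYS, obs, p)
        perm = np.array([3, 0, 5, 1, 4, 2])
        r2b, rmb = fit_quality(DAYS[perm], obs[perm], p)
        assert r2a == pytest.approx(r2b, abs=1e-12)
        assert rma == pytest.approx(rmb, abs=1e-12)

    def test_zero_variance_flagged(self):
        p = TwoPoolParams(f1=0.02, k1=0.15, k2=2e-4)
        r2, rmse = fit_quality([1.0, 2.0], [0.5, 0.5], p)
        assert np.isnan(r2)


@pytest.fixture(scope="module")
def fit():
    truth = TwoPoolParams(f1=0.02, k1=0.15, k2=2e-4)
    rng = np.random.default_rng(3)
    dense = np.arange(1.0, 66.0, 2.0)
    obs = two_pool_rate(dense, truth) * (1 + 0.02 * rng.normal(size=dense.size))
    return truth, dense, obs, mcmc_fit(
        dense, obs, n_chains=3, n_iter=6000, seed=11,
        noise_sd=0.02, relative_noise=True,
    )


class TestMCMC:

    def test_map_recovers_truth_on_dense_data(self, fit):
        truth, _, _, summ = fit
        for name, true_val in (("f1", truth.f1), ("k1", truth.k1),
                               ("k2", truth.k2)):
            assert summ.map_estimate[name] == pytest.approx(
                true_val, rel=0.10
            ), name

    def test_draws_respect_support(self, fit):
        _, _, _, summ = fit
        draws = summ.draws
        for i, name in enumerate(("f1", "k1", "k2")):
            lo, hi = DEFAULT_PRIORS[name]
            assert draws[:, i].min() >= lo and draws[:, i].max() <= hi
        assert np.all(draws[:, 1] > draws[:, 2])   # k1 > k2 everywhere

    def test_bit_identical_under_seed(self):
        truth = TwoPoolParams(f1=0.03, k1=0.1, k2=3e-4)
        rng = np.random.default_rng(0)
        obs = two_pool_rate(DAYS, truth) * (1 + 0.05 * rng.normal(size=6))
        a = mcmc_fit(DAYS, obs, n_iter=2000, seed=4)
        b = mcmc_fit(DAYS, obs, n_iter=2000, seed=4)
        assert np.array_equal(a.draws, b.draws)
        assert a.map_estimate == b.map_estimate

    def test_diagnostics_fields(self, fit):
        _, _, _, summ = fit
        assert 0.0 <= summ.acceptance_rate <= 1.0
        assert all(v >= 1.0 for v in summ.gelman_rubin.values())
        for name in ("f1", "k1", "k2"):
            assert summ.constraint_class[name] in (
                "well_constrained", "poorly_constrained"
            )
            lo, hi = DEFAULT_PRIORS[name]
            assert lo <= summ.point_estimate[name] <= hi

    def test_rhat_matches_arviz(self, fit):
        """Cross-check the in-package split-R-hat against arviz."""
        az = pytest.importorskip("arviz")
        _, _, _, summ = fit
        n_chains = 3
        chains = summ.draws.reshape(n_chains, -1, 3)
        for i, name in enumerate(("f1", "k1", "k2")):
            ref = float(az.rhat(az.convert_to_dataset(
                chains[:, :, i]
            ))["x"].values)
            # arviz uses rank-normalization; agreement is approximate
            assert summ.gelman_rubin[name] == pytest.approx(ref, abs=0.05)
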