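"""The confounded-model sampler: prior recovery, quadrature equivalence."""

import numpy as np
import pytest
from scipy import stats

from dirichletclock.jc69 import PairCountData, mismatch_loglik
from dirichletclock.mcmc_dating import (
    McmcSettings,
    log_posterior,
    run_mcmc,
    run_mcmc_batch,
    summarize_trace,
)
from dirichletclock.rate_priors import (
    GammaSpec,
    LocusRateVector,
    RatePriorSpec,
    dirichlet_partition_logpdf,
)

TIME_PRIOR = GammaSpec(100.0, 100.0)
IID_GOOD = RatePriorSpec("iid_gamma", GammaSpec(2.0, 4.0))
DIR_GOOD = RatePriorSpec("dirichlet", GammaSpec(2.0, 4.0), 1.0)

FAST = McmcSettings(n_iter=16000, burn_in=1500, thin=2, seed=0)


def make_data(rng, L, N=1000, t=1.0):
    mu = rng.gamma(2.0, 0.25, L)
    d = 2.0 * t * mu
    x = rng.binomial(N, 0.75 * (1 - np.exp(-4 * d / 3)))
    return [PairCountData(N, int(v)) for v in x]


class TestLogPosterior:
    def test_no_data_reduces_to_priors(self):
        v = LocusRateVector(np.array([0.4, 0.6]))
        lp = log_posterior(1.2, v, [], TIME_PRIOR, IID_GOOD)
        expected = float(TIME_PRIOR.logpdf(1.2)) + float(
            GammaSpec(2, 4).logpdf(v.rates).sum()
        )
        assert lp == pytest.approx(expected, rel=1e-12)

    def test_dimension_mismatch_rejected(self, rng):
        data = make_data(rng, 3)
        with pytest.raises(ValueError):
            log_posterior(1.0, LocusRateVector(np.array([0.5, 0.5])), data, TIME_PRIOR, IID_GOOD)

    def test_likelihood_invariant_under_confounded_rescaling(self, rng):
        # (t, mu) -> (c t, mu / c) changes only the prior terms
        data = make_data(rng, 4)
        mu = np.array([0.4, 0.5, 0.6, 0.7])
        c = 1.7
        for spec in (IID_GOOD, DIR_GOOD):
            delta = log_posterior(
                1.0 * c, LocusRateVector(mu / c), data, TIME_PRIOR, spec
            ) - log_posterior(1.0, LocusRateVector(mu), data, TIME_PRIOR, spec)
            prior_delta = log_posterior(
                1.0 * c, LocusRateVector(mu / c), [], TIME_PRIOR, spec
            ) - log_posterior(1.0, LocusRateVector(mu), [], TIME_PRIOR, spec)
            assert delta == pytest.approx(prior_delta, abs=1e-9)


class TestPriorSampling:
    def test_time_prior_recovered_without_data(self):
        trace = run_mcmc([], TIME_PRIOR, IID_GOOD, McmcSettings(n_iter=40000, burn_in=2000, seed=4))
        assert trace.t_samples.mean() == pytest.approx(1.0, abs=0.01)
        s = summarize_trace(trace)["t"]
        assert s["ci_low"] == pytest.approx(0.813, abs=0.02)
        assert s["ci_high"] == pytest.approx(1.205, abs=0.02)

    @pytest.mark.parametrize("kind,L", [("iid_gamma", 1), ("iid_gamma", 10),
                                        ("dirichlet", 1), ("dirichlet", 10)])
    def test_prior_recovery_ks(self, kind, L):
        spec = (
            RatePriorSpec("iid_gamma", GammaSpec(2, 4))
            if kind == "iid_gamma"
            else RatePriorSpec("dirichlet", GammaSpec(2, 4), 1.0)
        )
        settings = McmcSettings(n_iter=60000, burn_in=2000, thin=20, seed=8)
        bt = run_mcmc_batch(None, 0, TIME_PRIOR, spec, settings, L=L)
        t = bt.t[:, 0]
        assert stats.kstest(t, "gamma", args=(100.0, 0, 0.01)).pvalue > 0.001
        if kind == "dirichlet":
            # mubar marginal is G(2,4) for every L under the partition prior
            mb = bt.mubar[:, 0]
            assert stats.kstest(mb, "gamma", args=(2.0, 0, 0.25)).pvalue > 0.001


class TestQuadratureEquivalence:
    """Low-dimensional deterministic integration of the same posterior."""

    @staticmethod
    def _quad_iid(data, rate_prior, t_grid):
        # inner integrals over each mu_i factorize under the i.i.d. prior
        mu = np.geomspace(1e-4, 50, 1500)
        lg = GammaSpec(rate_prior.shape, rate_prior.rate).logpdf(mu)
        post = []
        for t in t_grid:
            tot = float(TIME_PRIOR.logpdf(t))
            for c in data:
                integ = lg + mismatch_loglik(c.n_diff, c.n_sites, 2.0 * t * mu)
                m = integ.max()
                tot += m + np.log(np.trapezoid(np.exp(integ - m), mu))
            post.append(tot)
        post = np.array(post)
        w = np.exp(post - post.max())
        w /= np.trapezoid(w, t_grid)
        return float(np.trapezoid(t_grid * w, t_grid))

    def test_iid_matches_quadrature_L3(self, rng):
        data = make_data(rng, 3)
        t_grid = np.linspace(0.6, 1.6, 121)
        target = self._quad_iid(data, GammaSpec(2, 4), t_grid)
        trace = run_mcmc(data, TIME_PRIOR, IID_GOOD, FAST)
        mcse = trace.t_samples.std() / np.sqrt(max(trace.ess["t"], 1.0))
        assert trace.t_samples.mean() == pytest.approx(target, abs=3 * mcse + 0.003)

    def test_dirichlet_matches_quadrature_L2(self, rng):
        data = make_data(rng, 2)
        mu = np.geomspace(1e-3, 20, 400)
        M1, M2 = np.meshgrid(mu, mu, indexing="ij")
        pts = np.stack([M1, M2], axis=-1)
        lprior = dirichlet_partition_logpdf(pts, 2.0, 4.0, 1.0)
        t_grid = np.linspace(0.6, 1.6, 81)
        post = []
        for t in t_grid:
            integ = (
                lprior
                + mismatch_loglik(data[0].n_diff, data[0].n_sites, 2 * t * M1)
                + mismatch_loglik(data[1].n_diff, data[1].n_sites, 2 * t * M2)
            )
            m = integ.max()
            val = np.trapezoid(np.trapezoid(np.exp(integ - m), mu, axis=1), mu)
            post.append(m + np.log(val) + float(TIME_PRIOR.logpdf(t)))
        post = np.array(post)
        w = np.exp(post - post.max())
        w /= np.trapezoid(w, t_grid)
        target = float(np.trapezoid(t_grid * w, t_grid))
        trace = run_mcmc(data, TIME_PRIOR, DIR_GOOD, FAST)
        mcse = trace.t_samples.std() / np.sqrt(max(trace.ess["t"], 1.0))
        assert trace.t_samples.mean() == pytest.approx(target, abs=3 * mcse + 0.003)


class TestTraceSummaries:
    def test_constant_trace_degenerates(self):
        from dirichletclock.mcmc_dating import McmcTrace

        tr = McmcTrace(
            t_samples=np.full(100, 2.0),
            mu_samples=np.full((100, 1), 0.5),
            mubar_samples=np.full(100, 0.5),
            acceptance={},
            ess={},
        )
        s = summarize_trace(tr)
        assert s["t"]["ci_low"] == s["t"]["ci_high"] == s["t"]["mean"] == 2.0
        assert s["t"]["ess"] == 0.0

    def test_iid_gamma_trace_summary(self, rng):
        from dirichletclock.mcmc_dating import McmcTrace

        draws = rng.gamma(2.0, 0.25, 40000)
        tr = McmcTrace(draws, np.empty((draws.size, 0)), np.full(draws.size, np.nan), {}, {})
        s = summarize_trace(tr)["t"]
        assert s["mean"] == pytest.approx(0.5, abs=0.01)
        assert s["ci_low"] == pytest.approx(0.0606, abs=0.01)
        assert s["ci_high"] == pytest.approx(1.3929, abs=0.05)

    def test_quantiles_match_sorted_bruteforce(self, rng):
        draws = rng.normal(0, 1, 999)
        from dirichletclock.mcmc_dating import McmcTrace

        tr = McmcTrace(draws, np.empty((999, 0)), np.full(999, np.nan), {}, {})
        s = summarize_trace(tr)["t"]
        srt = np.sort(draws)
        # brute-force linear-interpolation quantile
        def bq(q):
            pos = q * (len(srt) - 1)
            lo = int(np.floor(pos))
            return srt[lo] + (pos - lo) * (srt[min(lo + 1, len(srt) - 1)] - srt[lo])

        assert s["ci_low"] == pytest.approx(bq(0.025), abs=1e-9)
        assert s["ci_high"] == pytest.approx(bq(0.975), abs=1e-9)


class TestReproducibility:
    def test_same_seed_identical_trace(self, rng):
        data = make_data(rng, 2)
        s = McmcSettings(n_iter=2000, burn_in=500, seed=12)
        a = run_mcmc(data, TIME_PRIOR, IID_GOOD, s)
        b = run_mcmc(data, TIME_PRIOR, IID_GOOD, s)
        assert np.array_equal(a.t_samples, b.t_samples)

    def test_independent_seeds_agree_within_mcse(self, rng):
        data = make_data(rng, 5)
        a = run_mcmc(data, TIME_PRIOR, IID_GOOD, McmcSettings(n_iter=16000, burn_in=1500, seed=1))
        b = run_mcmc(data, TIME_PRIOR, IID_GOOD, McmcSettings(n_iter=16000, burn_in=1500, seed=2))
        mcse = np.hypot(
            a.t_samples.std() / np.sqrt(max(a.ess["t"], 1)),
            b.t_samples.std() / np.sqrt(max(b.ess["t"], 1)),
        )
        assert a.t_samples.mean() == pytest.approx(b.t_samples.mean(), abs=3 * mcse)

    def test_acceptance_rates_in_tuned_band(self, rng):
        data = make_data(rng, 10)
        tr = run_mcmc(data, TIME_PRIOR, DIR_GOOD, FAST)
        for name, rate in tr.acceptance.items():
            assert 0.1 < rate < 0.6, f"{name} acceptance {rate}"
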