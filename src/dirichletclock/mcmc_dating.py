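"""Metropolis-within-Gibbs sampler for the two-species dating posterior.

The target is ``f(t, mu | D) ∝ f(t) f(mu) prod_i f(x_i | d_i = 2 t mu_i)``
under the strict clock (both branches at a locus share the locus rate, so the
locus distance is ``2 t mu_i``), with either locus-rate prior.

Because times and rates enter the likelihood only through their products, a
plain coordinate sampler mixes poorly along the (t, mu) ridge.  The kernel
therefore has three blocks per sweep:

a. a log-scale random walk on t;
b. log-scale random walks on the locus rates — all loci at once with
   per-locus accept/reject under the i.i.d. prior (the conditionals are
   independent given t), a sequential sweep under the Dirichlet prior (whose
   joint density couples loci through the mean rate);
c. a "mixing" move that multiplies t by c and divides every rate by c, with
   log-Jacobian ``(1 - L) log c``, which travels along the confounded ridge
   without touching the likelihood.

Step sizes are tuned during burn-in toward ~0.3 acceptance and then frozen,
preserving detailed balance for the retained sample.  The sampler runs many
independent replicate chains simultaneously (state arrays are vectorized over
chains); ``run_mcmc`` is the single-dataset surface.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .jc69 import PairCountData, mismatch_loglik, pair_log_likelihood
from .rate_priors import (
    GammaSpec,
    LocusRateVector,
    RatePriorSpec,
    rate_prior_log_density,
)

__all__ = [
    "McmcSettings",
    "McmcTrace",
    "BatchTrace",
    "log_posterior",
    "run_mcmc",
    "run_mcmc_batch",
    "summarize_trace",
    "ess",
]

_TARGET_ACCEPT = 0.3


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length and proposal settings.

    Defaults (2,000 burn-in, 20,000 sampling iterations, thin 2) keep the
    Monte Carlo standard error of the posterior mean of t below ~0.01 in the
    L = 100 study.
    """

    n_iter: int = 20000
    burn_in: int = 2000
    thin: int = 2
    step_t: float = 0.05
    step_mu: float = 0.3
    step_mix: float = 0.05
    tune: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.burn_in < 0 or self.burn_in >= self.n_iter:
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


@dataclass
class McmcTrace:
    """Post-burn-in, thinned draws of (t, mu) with derived mean rate."""

    t_samples: np.ndarray
    mu_samples: np.ndarray  # (n_samples, L)
    mubar_samples: np.ndarray
    acceptance: dict
    ess: dict
    warnings: list = field(default_factory=list)


@dataclass
class BatchTrace:
    """Draws for a batch of independent replicate chains.

    ``t`` and ``mubar`` have shape (n_samples, R).  Per-chain full rate
    matrices are not stored (the table experiments only summarize t and the
    mean rate).
    """

    t: np.ndarray
    mubar: np.ndarray
    acceptance: dict


def _prior_logpdf_t(time_prior: GammaSpec, t):
    return (time_prior.shape - 1.0) * np.log(t) - time_prior.rate * t


def log_posterior(
    t: float,
    rates: LocusRateVector,
    data: Sequence[PairCountData],
    time_prior: GammaSpec,
    rate_prior: RatePriorSpec,
) -> float:
    """Unnormalized log-posterior ``log f(t) + log f(mu) + sum_i log f(x_i | 2 t mu_i)``.

    With no data the likelihood term vanishes (prior-sampling mode).
    """
    if t <= 0:
        raise ValueError("t must be positive")
    if len(data) and len(data) != rates.L:
        raise ValueError(
            f"data has {len(data)} loci but the rate vector has {rates.L}"
        )
    lp = float(time_prior.logpdf(t)) + float(rate_prior_log_density(rates.rates, rate_prior))
    for c, mu_i in zip(data, rates.rates):
        lp += pair_log_likelihood(c, 2.0 * t * mu_i)
    return lp


# ---------------------------------------------------------------------------
# Core batched sampler
# ---------------------------------------------------------------------------

def _rate_prior_terms(mu, spec: RatePriorSpec):
    """Non-constant part of the log rate prior, per chain; mu is (R, L)."""
    L = mu.shape[1]
    logmu = np.log(mu)
    if spec.kind == "iid_gamma":
        a, b = spec.gamma.shape, spec.gamma.rate
        return (a - 1.0) * logmu.sum(axis=1) - b * mu.sum(axis=1)
    am, bm, a = spec.gamma.shape, spec.gamma.rate, spec.concentration
    mubar = mu.mean(axis=1)
    return (a - 1.0) * logmu.sum(axis=1) + (am - L * a) * np.log(mubar) - bm * mubar


def _run_batch_core(
    x: Optional[np.ndarray],
    n_sites: int,
    L: int,
    time_prior: GammaSpec,
    rate_prior: RatePriorSpec,
    settings: McmcSettings,
    rng: np.random.Generator,
    n_chains: int,
    store_mu: bool,
):
    at, bt = time_prior.shape, time_prior.rate
    R = n_chains
    have_data = x is not None and L > 0

    # Initialization: t at the time-prior mean; rates at the per-locus JC69
    # MLE distance over 2t, floored at 1e-6 (saturated loci included).
    t = np.full(R, time_prior.mean())
    if L > 0:
        if have_data:
            phat = np.clip(x / n_sites, 0.0, 0.74)
            dhat = -0.75 * np.log1p(-4.0 * phat / 3.0)
            mu = np.clip(dhat / (2.0 * t[:, None]), 1e-6, None)
        else:
            mu = np.full((R, L), rate_prior.gamma.mean())
    else:
        mu = np.zeros((R, 0))

    if have_data:
        ll = mismatch_loglik(x, n_sites, 2.0 * t[:, None] * mu)
        if not np.all(np.isfinite(ll)):
            raise RuntimeError(
                "non-finite log-likelihood at initialization; check the input counts"
            )
    else:
        ll = np.zeros((R, max(L, 1)))

    s_t = np.full(R, settings.step_t)
    s_mu = np.full(R, settings.step_mu)
    s_mix = np.full(R, settings.step_mix)

    is_dirichlet = rate_prior.kind == "dirichlet"
    if is_dirichlet:
        am, bm, conc = rate_prior.gamma.shape, rate_prior.gamma.rate, rate_prior.concentration
    else:
        a_g, b_g = rate_prior.gamma.shape, rate_prior.gamma.rate

    n_total = settings.burn_in + settings.n_iter
    acc = np.zeros((3, R))
    ntry = np.zeros(3)
    keep_t, keep_mubar, keep_mu = [], [], []

    for it in range(n_total):
        # --- block a: t ---
        z = rng.standard_normal(R)
        tp = t * np.exp(s_t * z)
        dlp = (at - 1.0) * np.log(tp / t) - bt * (tp - t) + np.log(tp / t)
        if have_data:
            llp = mismatch_loglik(x, n_sites, 2.0 * tp[:, None] * mu)
            dlp = dlp + (llp - ll).sum(axis=1)
        accd = np.log(rng.random(R)) < dlp
        t = np.where(accd, tp, t)
        if have_data:
            ll = np.where(accd[:, None], llp, ll)
        acc[0] += accd
        ntry[0] += 1

        # --- block b: locus rates ---
        if L > 0:
            if not is_dirichlet:
                zmat = rng.standard_normal((R, L))
                mup = mu * np.exp(s_mu[:, None] * zmat)
                dlp = (a_g - 1.0) * np.log(mup / mu) - b_g * (mup - mu) + np.log(mup / mu)
                if have_data:
                    llp = mismatch_loglik(x, n_sites, 2.0 * t[:, None] * mup)
                    dlp = dlp + llp - ll
                accd = np.log(rng.random((R, L))) < dlp
                mu = np.where(accd, mup, mu)
                if have_data:
                    ll = np.where(accd, llp, ll)
                acc[1] += accd.mean(axis=1)
            else:
                # sequential sweep: the joint density couples loci via mubar
                mubar = mu.mean(axis=1)
                zmat = rng.standard_normal((R, L))
                umat = np.log(rng.random((R, L)))
                for i in range(L):
                    mui = mu[:, i]
                    mupi = mui * np.exp(s_mu * zmat[:, i])
                    mubarp = mubar + (mupi - mui) / L
                    dlp = (
                        (conc - 1.0) * np.log(mupi / mui)
                        + (am - L * conc) * np.log(mubarp / mubar)
                        - bm * (mubarp - mubar)
                        + np.log(mupi / mui)
                    )
                    if have_data:
                        llpi = mismatch_loglik(x[:, i], n_sites, 2.0 * t * mupi)
                        dlp = dlp + llpi - ll[:, i]
                    accd = umat[:, i] < dlp
                    mu[:, i] = np.where(accd, mupi, mui)
                    mubar = np.where(accd, mubarp, mubar)
                    if have_data:
                        ll[:, i] = np.where(accd, llpi, ll[:, i])
                    acc[1] += accd / L
            ntry[1] += 1

            # --- block c: mixing move t -> ct, mu -> mu/c ---
            z = rng.standard_normal(R)
            c = np.exp(s_mix * z)
            tp = t * c
            mup = mu / c[:, None]
            dlp = (
                (at - 1.0) * np.log(c)
                - bt * (tp - t)
                + _rate_prior_terms(mup, rate_prior)
                - _rate_prior_terms(mu, rate_prior)
                + (1.0 - L) * np.log(c)
            )
            accd = np.log(rng.random(R)) < dlp
            t = np.where(accd, tp, t)
            mu = np.where(accd[:, None], mup, mu)
            acc[2] += accd
            ntry[2] += 1

        # --- burn-in tuning ---
        if settings.tune and it < settings.burn_in and (it + 1) % 100 == 0:
            for k, s in enumerate((s_t, s_mu, s_mix)):
                if ntry[k]:
                    rate = acc[k] / ntry[k]
                    s *= np.exp(np.clip(rate - _TARGET_ACCEPT, -0.5, 0.5))
            acc[:] = 0.0
            ntry[:] = 0.0
        if it == settings.burn_in - 1:
            acc[:] = 0.0
            ntry[:] = 0.0

        if it >= settings.burn_in and (it - settings.burn_in) % settings.thin == 0:
            keep_t.append(t.copy())
            keep_mubar.append(mu.mean(axis=1) if L > 0 else t * np.nan)
            if store_mu:
                keep_mu.append(mu.copy())

    rates = {
        "t": acc[0] / max(ntry[0], 1),
        "mu": acc[1] / max(ntry[1], 1),
        "mix": acc[2] / max(ntry[2], 1),
    }
    t_arr = np.array(keep_t)
    mubar_arr = np.array(keep_mubar)
    mu_arr = np.array(keep_mu) if store_mu else None
    return t_arr, mubar_arr, mu_arr, rates


def run_mcmc_batch(
    x: Optional[np.ndarray],
    n_sites: int,
    time_prior: GammaSpec,
    rate_prior: RatePriorSpec,
    settings: McmcSettings,
    rng: Optional[np.random.Generator] = None,
    L: Optional[int] = None,
) -> BatchTrace:
    """Run independent chains for a batch of replicate datasets.

    ``x`` is an (R, L) mismatch-count matrix sharing ``n_sites``; pass
    ``x=None`` with an explicit ``L`` (and R inferred as 1) for
    prior-sampling mode.
    """
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    if x is not None:
        x = np.asarray(x)
        R, Lx = x.shape
        L = Lx
    else:
        R = 1
        L = 0 if L is None else L
    t, mubar, _, rates = _run_batch_core(
        x, n_sites, L, time_prior, rate_prior, settings, rng, R, store_mu=False
    )
    return BatchTrace(t=t, mubar=mubar, acceptance=rates)


def run_mcmc(
    data: Sequence[PairCountData],
    time_prior: GammaSpec,
    rate_prior: RatePriorSpec,
    settings: McmcSettings,
    rng: Optional[np.random.Generator] = None,
) -> McmcTrace:
    """Sample the posterior for one dataset (possibly empty = prior mode)."""
    if rng is None:
        rng = np.random.default_rng(settings.seed)
    L = len(data)
    if L:
        n_sites_set = {c.n_sites for c in data}
        if len(n_sites_set) != 1:
            raise ValueError("all loci must share n_sites in this sampler")
        n_sites = n_sites_set.pop()
        x = np.array([[c.n_diff for c in data]])
    else:
        n_sites = 0
        x = None
    t, mubar, mu, rates = _run_batch_core(
        x, n_sites, L, time_prior, rate_prior, settings, rng, 1, store_mu=L > 0
    )
    trace = McmcTrace(
        t_samples=t[:, 0],
        mu_samples=mu[:, 0, :] if mu is not None else np.zeros((t.shape[0], 0)),
        mubar_samples=mubar[:, 0],
        acceptance={k: float(v[0]) for k, v in rates.items()},
        ess={},
    )
    trace.ess = {
        "t": ess(trace.t_samples),
        "mubar": ess(trace.mubar_samples) if L else np.nan,
    }
    if trace.ess["t"] < 100:
        trace.warnings.append(
            f"ESS for t is {trace.ess['t']:.0f} < 100: chain may not have converged"
        )
    return trace


# ---------------------------------------------------------------------------
# Summaries
# ---------------------------------------------------------------------------

def ess(samples: np.ndarray) -> float:
    """Effective sample size via the autocorrelation-time estimate."""
    import arviz

    samples = np.asarray(samples, dtype=float)
    if samples.size < 4 or np.allclose(samples, samples.flat[0]):
        return 0.0
    return float(arviz.ess(samples[None, :]))


def summarize_trace(trace: McmcTrace) -> dict:
    """Posterior mean, equal-tail 95% CI and ESS for t and the mean rate."""
    if trace.t_samples.size == 0:
        raise ValueError("empty trace")
    out = {}
    for name, s in (("t", trace.t_samples), ("mubar", trace.mubar_samples)):
        if s.size == 0 or np.all(np.isnan(s)):
            continue
        out[name] = {
            "mean": float(np.mean(s)),
            "ci_low": float(np.quantile(s, 0.025)),
            "ci_high": float(np.quantile(s, 0.975)),
            "ess": ess(s),
        }
    return out
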