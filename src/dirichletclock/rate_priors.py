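"""Priors on per-locus substitution rates for molecular-clock dating.

Two priors on the locus mean rates ``mu = (mu_1, ..., mu_L)`` are provided:

* the conventional i.i.d. gamma prior, ``mu_i ~ G(shape, rate)`` independently
  for every locus, and
* a Dirichlet partition prior: the across-loci mean rate
  ``mubar = (1/L) * sum(mu_i)`` receives a gamma prior ``G(alpha_mu, beta_mu)``
  and the total rate ``L * mubar`` is partitioned among loci by a symmetric
  Dirichlet with concentration ``alpha``, ``mu_i = L * mubar * y_i``.

The i.i.d. prior shrinks the prior variance of ``mubar`` like ``v / L``, so
with many loci it pins the average rate to the prior mean — and, because times
and rates are confounded in the likelihood, it thereby pins divergence times,
wrongly so when the prior rate is misspecified.  The partition prior keeps the
marginal of ``mubar`` equal to ``G(alpha_mu, beta_mu)`` for every ``L``.

All gamma distributions here are parameterized by (shape, rate), so that
``G(2, 4)`` has mean ``2/4 = 0.5``.  This matches the convention of the
molecular dating literature; be careful not to confuse ``rate`` with the
scipy ``scale`` (their reciprocal).

Densities are evaluated in log space with :func:`scipy.special.gammaln` for
every normalizing constant, so joint densities remain finite for thousands of
loci.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Optional

import numpy as np
from scipy import special, stats

__all__ = [
    "GammaSpec",
    "RatePriorSpec",
    "LocusRateVector",
    "MomentSummary",
    "iid_log_prior",
    "dirichlet_log_prior",
    "sample_locus_rates",
    "marginal_moments",
    "pairwise_correlation",
    "iid_workaround_spec",
    "iid_gamma_logpdf_sum",
    "dirichlet_partition_logpdf",
]


@dataclass(frozen=True)
class GammaSpec:
    """A gamma distribution ``G(shape, rate)`` with mean ``shape / rate``.

    Used both for rate priors (per-locus or on the mean rate) and for the
    prior on the divergence time.
    """

    shape: float
    rate: float

    def __post_init__(self) -> None:
        if not (self.shape > 0 and self.rate > 0):
            raise ValueError(
                f"gamma shape and rate must be positive, got {self.shape}, {self.rate}"
            )

    def mean(self) -> float:
        return self.shape / self.rate

    def variance(self) -> float:
        return self.shape / self.rate**2

    def logpdf(self, x):
        return stats.gamma.logpdf(x, self.shape, scale=1.0 / self.rate)

    def ppf(self, q):
        return stats.gamma.ppf(q, self.shape, scale=1.0 / self.rate)

    def equal_tail_interval(self, mass: float = 0.95) -> tuple[float, float]:
        lo = (1.0 - mass) / 2.0
        return float(self.ppf(lo)), float(self.ppf(1.0 - lo))

    def sample(self, size, rng: np.random.Generator):
        return rng.gamma(self.shape, 1.0 / self.rate, size)


@dataclass(frozen=True)
class RatePriorSpec:
    """Which locus-rate prior to use and its hyperparameters.

    ``kind="iid_gamma"``: ``gamma`` is the per-locus prior.
    ``kind="dirichlet"``: ``gamma`` is the prior on the mean rate ``mubar`` and
    ``concentration`` is the symmetric Dirichlet parameter alpha (smaller
    alpha means more rate variation among loci).
    """

    kind: Literal["iid_gamma", "dirichlet"]
    gamma: GammaSpec
    concentration: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in ("iid_gamma", "dirichlet"):
            raise ValueError(f"unknown rate prior kind {self.kind!r}")
        if self.kind == "dirichlet":
            if self.concentration is None or not self.concentration > 0:
                raise ValueError("dirichlet prior requires concentration > 0")


@dataclass
class LocusRateVector:
    """The positive per-locus mean rates ``mu_i`` (substitutions/site/time-unit)."""

    rates: np.ndarray

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        if self.rates.ndim != 1 or self.rates.size == 0:
            raise ValueError("rates must be a non-empty 1-D vector")
        if not np.all(self.rates > 0):
            raise ValueError("all locus rates must be positive")

    @property
    def L(self) -> int:
        return self.rates.size

    def mean_rate(self) -> float:
        """The across-loci mean rate mubar."""
        return float(self.rates.mean())

    def proportions(self) -> np.ndarray:
        """Rate proportions y_i = mu_i / (L * mubar); they sum to 1."""
        return self.rates / self.rates.sum()


@dataclass(frozen=True)
class MomentSummary:
    """Marginal mean/variance of a locus rate and the pairwise correlation."""

    mean: float
    variance: float
    correlation: float


# ---------------------------------------------------------------------------
# Array-level densities (used directly by the MCMC and quadrature code).
# ---------------------------------------------------------------------------

def iid_gamma_logpdf_sum(mu, shape: float, rate: float, axis: int = -1):
    """Sum over loci of gamma log-densities, vectorized over leading axes."""
    mu = np.asarray(mu, dtype=float)
    L = mu.shape[axis]
    return (
        L * (shape * np.log(rate) - special.gammaln(shape))
        + (shape - 1.0) * np.log(mu).sum(axis=axis)
        - rate * mu.sum(axis=axis)
    )


def dirichlet_partition_logpdf(
    mu, mean_shape: float, mean_rate: float, concentration: float, axis: int = -1
):
    """Joint log-density of locus rates under the Dirichlet partition prior.

    Obtained from ``mubar ~ G(mean_shape, mean_rate)`` and
    ``y ~ Dirichlet(concentration, ..., concentration)`` through the change of
    variables ``mu_i = L * mubar * y_i`` (Jacobian ``1 / (L (L mubar)^{L-1})``),
    which collapses to::

        log f(mu) = am*log(bm) - lgamma(am) + lgamma(L*a) - L*lgamma(a)
                    - L*a*log(L) + (a-1)*sum_i log(mu_i)
                    + (am - L*a)*log(mubar) - bm*mubar

    with ``am = mean_shape``, ``bm = mean_rate``, ``a = concentration``.  For
    ``a = am/L`` this is exactly the product of L independent
    ``G(am/L, bm/L)`` densities; for ``L = 1`` it is the plain gamma on mu_1.
    """
    mu = np.asarray(mu, dtype=float)
    L = mu.shape[axis]
    am, bm, a = mean_shape, mean_rate, concentration
    mubar = mu.mean(axis=axis)
    const = (
        am * np.log(bm)
        - special.gammaln(am)
        + special.gammaln(L * a)
        - L * special.gammaln(a)
        - L * a * np.log(L)
    )
    return (
        const
        + (a - 1.0) * np.log(mu).sum(axis=axis)
        + (am - L * a) * np.log(mubar)
        - bm * mubar
    )


# ---------------------------------------------------------------------------
# Object-level operations.
# ---------------------------------------------------------------------------

def iid_log_prior(rates: LocusRateVector, spec: GammaSpec) -> float:
    """Joint log-density of the i.i.d. gamma prior, additive over loci."""
    return float(iid_gamma_logpdf_sum(rates.rates, spec.shape, spec.rate))


def dirichlet_log_prior(
    rates: LocusRateVector, mean_spec: GammaSpec, concentration: float
) -> float:
    """Joint log-density of the Dirichlet partition prior at ``rates``."""
    if not concentration > 0:
        raise ValueError("concentration must be positive")
    return float(
        dirichlet_partition_logpdf(
            rates.rates, mean_spec.shape, mean_spec.rate, concentration
        )
    )


def rate_prior_log_density(mu, spec: RatePriorSpec, axis: int = -1):
    """Log-density of either prior kind on an array of rate vectors."""
    if spec.kind == "iid_gamma":
        return iid_gamma_logpdf_sum(mu, spec.gamma.shape, spec.gamma.rate, axis=axis)
    return dirichlet_partition_logpdf(
        mu, spec.gamma.shape, spec.gamma.rate, spec.concentration, axis=axis
    )


def sample_locus_rates(
    spec: RatePriorSpec, L: int, rng: np.random.Generator
) -> LocusRateVector:
    """Draw one locus-rate vector from the prior.

    The Dirichlet draw is constructive: ``mubar`` from its gamma, proportions
    from L normalized ``gamma(concentration, 1)`` draws (well behaved even for
    concentration < 1), then ``mu_i = L * mubar * y_i``.  Consequently
    ``mean_rate()`` of the result is exactly ``G(alpha_mu, beta_mu)``
    distributed for every L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    if spec.kind == "iid_gamma":
        return LocusRateVector(spec.gamma.sample(L, rng))
    mubar = spec.gamma.sample(None, rng)
    g = rng.gamma(spec.concentration, 1.0, L)
    y = g / g.sum()
    return LocusRateVector(L * mubar * y)


def marginal_moments(spec: RatePriorSpec, L: int) -> MomentSummary:
    """Marginal mean and variance of a single locus rate, plus the pairwise
    correlation (0 for the i.i.d. prior)."""
    if L < 1:
        raise ValueError("L must be >= 1")
    g = spec.gamma
    if spec.kind == "iid_gamma":
        return MomentSummary(g.mean(), g.variance(), 0.0)
    am, bm, a = g.shape, g.rate, spec.concentration
    mean = am / bm
    # E(mu_i^2) = L^2 E(mubar^2) E(y_i^2) with mubar independent of y.
    var = am / bm**2 * (L * (am + 1.0) * (a + 1.0) / (L * a + 1.0) - am)
    if L == 1:
        corr = 1.0
    else:
        cov = am / bm**2 * (L * a * (am + 1.0) / (L * a + 1.0) - am)
        corr = cov / var
    return MomentSummary(mean, var, corr)


def pairwise_correlation(spec: RatePriorSpec, L: int) -> float:
    """Correlation between two distinct locus rates under the prior."""
    if spec.kind == "iid_gamma":
        return 0.0
    if L < 2:
        raise ValueError("pairwise correlation requires L >= 2")
    return marginal_moments(spec, L).correlation


def iid_workaround_spec(mean_spec: GammaSpec, L: int) -> GammaSpec:
    """The i.i.d. gamma ``G(alpha_mu/L, beta_mu/L)`` whose L-fold product equals
    the Dirichlet partition prior with concentration ``alpha_mu/L``.

    This is the recommendation for dating programs that only offer i.i.d.
    locus-rate priors: the per-locus mean stays ``alpha_mu/beta_mu`` while the
    prior variance of the mean rate no longer collapses as 1/L.
    """
    if L < 1:
        raise ValueError("L must be >= 1")
    return GammaSpec(mean_spec.shape / L, mean_spec.rate / L)
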