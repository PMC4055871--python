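"""Posterior of the two-species divergence time from exact locus distances.

When every locus is infinitely long, the per-locus molecular distances
``d_i = 2 t mu_i`` are known without error and the sequence likelihood
degenerates to a point constraint.  The time posterior is then

    f(t | d)  ∝  f(t) * t^{-L} * f_mu(d_1/(2t), ..., d_L/(2t)),

where ``f_mu`` is the joint locus-rate prior (i.i.d. gamma or Dirichlet
partition) and ``t^{-L}`` is the Jacobian of ``mu_i = d_i / (2t)``.  This is
the regime in which the i.i.d. prior shows its pathology: the posterior
concentrates wherever the rate prior says it should, no matter how wrong.

The posterior is computed by deterministic quadrature on a geometric time
grid, expanded until the boundary density is negligible, then normalized by
the trapezoid rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .rate_priors import (
    GammaSpec,
    dirichlet_partition_logpdf,
    iid_gamma_logpdf_sum,
)

__all__ = [
    "DistanceSet",
    "TimePosterior",
    "GridControl",
    "GridTruncationError",
    "posterior_time_iid",
    "posterior_time_dirichlet",
    "summarize_density",
    "read_distances_tsv",
    "write_distances_tsv",
]


class GridTruncationError(RuntimeError):
    """Raised when the time grid cannot be expanded to hold the posterior."""


@dataclass
class DistanceSet:
    """Per-locus molecular distances d_i > 0 (substitutions per site, both
    lineages summed)."""

    distances: np.ndarray

    def __post_init__(self) -> None:
        self.distances = np.atleast_1d(np.asarray(self.distances, dtype=float))
        if self.distances.size and not np.all(self.distances > 0):
            raise ValueError("all distances must be positive")

    @property
    def L(self) -> int:
        return self.distances.size


@dataclass
class TimePosterior:
    """A normalized posterior density of t on a grid, with summaries.

    Times are in units of 100 Myr.  ``density`` integrates to 1 over ``grid``
    by the trapezoid rule; the credibility interval is equal-tail 95%.
    """

    grid: np.ndarray
    density: np.ndarray
    mean: float = field(default=np.nan)
    sd: float = field(default=np.nan)
    cv: float = field(default=np.nan)
    ci95_low: float = field(default=np.nan)
    ci95_high: float = field(default=np.nan)


@dataclass(frozen=True)
class GridControl:
    """Quadrature grid policy: geometric spacing, automatic expansion.

    The grid starts at the time prior's [1e-8, 1 - 1e-8] quantile range and
    doubles outward until the density at each boundary falls below
    ``boundary_ratio`` times the maximum (posteriors can sit far from the
    prior: misspecified rate priors move the mean from 1 to 0.17 or 3.97).
    """

    n_points: int = 4096
    boundary_ratio: float = 1e-8
    max_expansions: int = 60


def _grid(lo: float, hi: float, n: int) -> np.ndarray:
    return np.geomspace(lo, hi, n)


def _posterior_from_log_kernel(log_kernel, time_prior: GammaSpec, control: GridControl) -> TimePosterior:
    lo = float(time_prior.ppf(1e-8))
    hi = float(time_prior.ppf(1.0 - 1e-8))
    lo = max(lo, 1e-12)
    for _ in range(control.max_expansions):
        t = _grid(lo, hi, control.n_points)
        logk = log_kernel(t)
        m = np.max(logk)
        if not np.isfinite(m):
            raise GridTruncationError("log-kernel is -inf everywhere on the grid")
        dens = np.exp(logk - m)
        bad_lo = dens[0] > control.boundary_ratio
        bad_hi = dens[-1] > control.boundary_ratio
        if not (bad_lo or bad_hi):
            z = np.trapezoid(dens, t)
            post = TimePosterior(grid=t, density=dens / z)
            return summarize_density(post)
        if bad_lo:
            lo /= 2.0
        if bad_hi:
            hi *= 2.0
    raise GridTruncationError(
        f"posterior mass still at the grid boundary after {control.max_expansions} "
        f"expansions; last range was [{lo:.3g}, {hi:.3g}]"
    )


def posterior_time_iid(
    data: DistanceSet,
    time_prior: GammaSpec,
    rate_prior: GammaSpec,
    grid_control: GridControl | None = None,
) -> TimePosterior:
    """Infinite-sites posterior of t under the i.i.d. gamma locus-rate prior.

    With no data (L = 0) the posterior is the time prior.
    """
    control = grid_control or GridControl()
    d = data.distances

    def log_kernel(t):
        lk = time_prior.logpdf(t)
        if d.size:
            mu = d[:, None] / (2.0 * t)
            lk = (
                lk
                + iid_gamma_logpdf_sum(mu, rate_prior.shape, rate_prior.rate, axis=0)
                - d.size * np.log(2.0 * t)
            )
        return lk

    return _posterior_from_log_kernel(log_kernel, time_prior, control)


def posterior_time_dirichlet(
    data: DistanceSet,
    time_prior: GammaSpec,
    mean_rate_prior: GammaSpec,
    concentration: float,
    grid_control: GridControl | None = None,
) -> TimePosterior:
    """Infinite-sites posterior of t under the Dirichlet partition prior.

    The rate proportions ``y_i = d_i / sum(d)`` do not depend on t, so the
    posterior reduces to the single-locus form driven by the mean distance —
    which is why time estimates stay calibrated no matter how many loci are
    stacked up.
    """
    control = grid_control or GridControl()
    d = data.distances

    def log_kernel(t):
        lk = time_prior.logpdf(t)
        if d.size:
            mu = d[:, None] / (2.0 * t)
            lk = (
                lk
                + dirichlet_partition_logpdf(
                    mu,
                    mean_rate_prior.shape,
                    mean_rate_prior.rate,
                    concentration,
                    axis=0,
                )
                - d.size * np.log(2.0 * t)
            )
        return lk

    return _posterior_from_log_kernel(log_kernel, time_prior, control)


def summarize_density(p: TimePosterior) -> TimePosterior:
    """Fill in trapezoid moments and the equal-tail 95% CI of a normalized
    grid density; returns the same object."""
    t, w = p.grid, p.density
    mean = float(np.trapezoid(t * w, t))
    var = float(np.trapezoid((t - mean) ** 2 * w, t))
    sd = float(np.sqrt(max(var, 0.0)))
    # cumulative trapezoid, inverted by linear interpolation
    mids = 0.5 * (w[1:] + w[:-1]) * np.diff(t)
    cdf = np.concatenate([[0.0], np.cumsum(mids)])
    cdf /= cdf[-1]
    lo, hi = np.interp([0.025, 0.975], cdf, t)
    p.mean = mean
    p.sd = sd
    p.cv = sd / mean if mean else np.nan
    p.ci95_low = float(lo)
    p.ci95_high = float(hi)
    return p


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def write_distances_tsv(data: DistanceSet, path) -> None:
    pd.DataFrame({"distance": data.distances}).to_csv(path, sep="\t", index=False)


def read_distances_tsv(path) -> DistanceSet:
    df = pd.read_csv(Path(path), sep="\t")
    if "distance" not in df.columns:
        raise ValueError(f"{path} has no 'distance' column")
    return DistanceSet(df["distance"].to_numpy())


def summary_row(label: str, L: int, p: TimePosterior) -> dict:
    """One TSV-ready summary row for a computed posterior."""
    return {
        "prior": label,
        "L": L,
        "mean": p.mean,
        "sd": p.sd,
        "cv": p.cv,
        "ci_low": p.ci95_low,
        "ci_high": p.ci95_high,
    }
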