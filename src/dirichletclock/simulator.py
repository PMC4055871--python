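"""Simulation of two-species data under the molecular clock.

Generates the two kinds of data the analyses consume:

* infinite-sites distance sets ``d_i = 2 t mu_i`` with locus rates drawn from
  the true-rate distribution, and
* finite-sites two-sequence loci: per-locus branch rates drawn from a
  mean-corrected log-normal around the locus rate, distances
  ``d_i = (r_i1 + r_i2) t``, and mismatch counts ``x_i ~ Binomial(N, p(d_i))``
  under JC69.

Binomial mismatch sampling replaces site-by-site sequence evolution: for two
sequences under JC69 the two are distributionally identical and the
likelihood sees only (N, x).  Explicit sequences can still be emitted for
interface realism.

Reproducibility: replicate r of a configuration with root seed s uses the
numpy ``SeedSequence((s, r))`` stream, so any single replicate can be
regenerated in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .infinite_sites import DistanceSet
from .jc69 import PairCountData, jc69_mismatch_prob
from .rate_priors import GammaSpec, RatePriorSpec, sample_locus_rates

__all__ = [
    "SimConfig",
    "ReplicateData",
    "simulate_distances_infinite",
    "simulate_branch_rates",
    "simulate_pair_alignment",
    "generate_replicates",
    "simulate_counts_batch",
    "replicate_rng",
    "write_replicate_tsv",
    "read_replicate_tsv",
]

_BASES = np.array(list("TCAG"))


@dataclass(frozen=True)
class SimConfig:
    """The simulation protocol for one experiment.

    Defaults are the two-species study conditions: true divergence time t = 1
    (one time unit = 100 Myr), true locus rates G(2, 4) (mean 0.5
    substitutions/site per 100 Myr), N = 1000 sites per locus, log-normal
    branch-rate log-variance sigma2 = 0.1, 100 replicates.
    """

    true_time: float = 1.0
    rate_spec: Union[RatePriorSpec, GammaSpec] = field(
        default_factory=lambda: GammaSpec(2.0, 4.0)
    )
    L: int = 100
    n_sites: int = 1000
    branch_log_var: float = 0.1
    n_replicates: int = 100
    seed: int = 0

    def __post_init__(self) -> None:
        if self.true_time < 0:
            raise ValueError("true_time must be >= 0")
        if self.L < 1 or self.n_sites < 1 or self.n_replicates < 1:
            raise ValueError("L, n_sites and n_replicates must be >= 1")
        if self.branch_log_var < 0:
            raise ValueError("branch_log_var must be >= 0 (0 = strict clock)")

    def rate_prior_spec(self) -> RatePriorSpec:
        if isinstance(self.rate_spec, RatePriorSpec):
            return self.rate_spec
        return RatePriorSpec(kind="iid_gamma", gamma=self.rate_spec)


@dataclass
class ReplicateData:
    """One simulated replicate: per-locus counts plus bookkeeping truth."""

    index: int
    counts: list
    true_distances: np.ndarray
    true_rates: np.ndarray


def replicate_rng(seed: int, index: int) -> np.random.Generator:
    """The seeded stream for replicate ``index`` under root ``seed``.

    The middle entropy word tags data-generation streams so they can never
    collide with analysis (MCMC) streams derived from the same root seed;
    ``SeedSequence`` pads with zeros, so e.g. ``(s,)`` and ``(s, 0)`` would
    otherwise be the same stream.
    """
    return np.random.default_rng(np.random.SeedSequence((int(seed), 83, int(index))))


def simulate_distances_infinite(cfg: SimConfig, rng: np.random.Generator) -> DistanceSet:
    """Exact distances d_i = 2 mu_i t with mu_i from the true-rate prior."""
    mu = sample_locus_rates(cfg.rate_prior_spec(), cfg.L, rng).rates
    return DistanceSet(2.0 * mu * cfg.true_time) if cfg.true_time > 0 else _zeros(cfg.L)


def _zeros(L: int) -> DistanceSet:
    ds = DistanceSet.__new__(DistanceSet)
    ds.distances = np.zeros(L)
    return ds


def simulate_branch_rates(mu_i, sigma2: float, rng: np.random.Generator):
    """Two branch rates r ~ LN(log mu_i - sigma2/2, sigma2), so E(r) = mu_i.

    sigma2 = 0 reproduces the strict clock: both branches get mu_i exactly.
    """
    mu_i = np.asarray(mu_i, dtype=float)
    if np.any(mu_i <= 0):
        raise ValueError("locus rate must be positive")
    if sigma2 == 0:
        return mu_i.copy(), mu_i.copy()
    mlog = np.log(mu_i) - sigma2 / 2.0
    s = np.sqrt(sigma2)
    return rng.lognormal(mlog, s), rng.lognormal(mlog, s)


def simulate_pair_alignment(
    d: float,
    n_sites: int,
    rng: np.random.Generator,
    emit_sequences: bool = False,
):
    """Mismatch count x ~ Binomial(N, p(d)); optionally an explicit sequence
    pair consistent with x (mismatch positions random, substituted base
    uniform over the three alternatives)."""
    if d < 0:
        raise ValueError("distance must be non-negative")
    p = jc69_mismatch_prob(d)
    x = int(rng.binomial(n_sites, p))
    data = PairCountData(n_sites, x)
    if not emit_sequences:
        return data
    seq1 = rng.integers(0, 4, n_sites)
    seq2 = seq1.copy()
    pos = rng.choice(n_sites, size=x, replace=False)
    seq2[pos] = (seq2[pos] + rng.integers(1, 4, x)) % 4
    return data, "".join(_BASES[seq1]), "".join(_BASES[seq2])


def _simulate_replicate_arrays(cfg: SimConfig, rng: np.random.Generator):
    mu = sample_locus_rates(cfg.rate_prior_spec(), cfg.L, rng).rates
    r1, r2 = simulate_branch_rates(mu, cfg.branch_log_var, rng)
    d = (r1 + r2) * cfg.true_time
    x = rng.binomial(cfg.n_sites, jc69_mismatch_prob(d))
    return mu, d, x


def generate_replicates(cfg: SimConfig) -> list[ReplicateData]:
    """All replicates of the protocol, each from its own child stream."""
    out = []
    for r in range(cfg.n_replicates):
        mu, d, x = _simulate_replicate_arrays(cfg, replicate_rng(cfg.seed, r))
        counts = [PairCountData(cfg.n_sites, int(xi)) for xi in x]
        out.append(ReplicateData(r, counts, d, mu))
    return out


def simulate_counts_batch(cfg: SimConfig, replicate_indices=None):
    """Mismatch-count matrix (replicates x loci) for the batch MCMC runner.

    Returns ``(x, d, mu)`` arrays of shape (R, L); row r is bit-identical to
    ``generate_replicates(cfg)[r]``.
    """
    idx = range(cfg.n_replicates) if replicate_indices is None else replicate_indices
    rows = [_simulate_replicate_arrays(cfg, replicate_rng(cfg.seed, r)) for r in idx]
    mu = np.array([row[0] for row in rows])
    d = np.array([row[1] for row in rows])
    x = np.array([row[2] for row in rows])
    return x, d, mu


def write_replicate_tsv(rep: ReplicateData, path) -> None:
    df = pd.DataFrame(
        {
            "locus": np.arange(len(rep.counts)),
            "N": [c.n_sites for c in rep.counts],
            "x": [c.n_diff for c in rep.counts],
            "true_d": rep.true_distances,
        }
    )
    df.to_csv(path, sep="\t", index=False)


def read_replicate_tsv(path, index: int = 0) -> ReplicateData:
    df = pd.read_csv(Path(path), sep="\t")
    counts = [PairCountData(int(n), int(x)) for n, x in zip(df["N"], df["x"])]
    return ReplicateData(index, counts, df["true_d"].to_numpy(), np.array([]))
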