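# dirichletclock

Bayesian divergence-time estimation with multiple loci, comparing two priors
on per-locus substitution rates: the conventional **i.i.d. gamma** prior and
a **Dirichlet partition** prior that stays calibrated as loci accumulate.

## The problem

Molecular sequences inform the *products* of divergence times and
substitution rates, never the two separately, so in Bayesian molecular-clock
dating the priors on times (fossil calibrations) and on rates matter even
with unlimited data. Dating programs typically give each locus its own mean
rate `mu_i` with an i.i.d. prior `mu_i ~ G(alpha, beta)`. That seems
innocent, but the prior variance of the across-loci mean rate
`mubar = (1/L) Σ mu_i` is `v/L`: with hundreds of loci the prior nails
`mubar` to its prior mean, and — through the time-rate confounding — nails
the divergence times too. If the prior rate is too fast the times come out
too young; too slow, too old; either way with deceptively narrow intervals
that tighten as more loci are added.

The fix implemented here puts the prior where the information actually is:
a gamma `G(alpha_mu, beta_mu)` on `mubar` itself, with the total rate
`L·mubar` partitioned among loci by a symmetric Dirichlet with
concentration `alpha` (`mu_i = L·mubar·y_i`). The marginal of `mubar` is
then `G(alpha_mu, beta_mu)` for *every* `L`, so time estimates stop
collapsing onto prior-driven point values. For programs that only accept
i.i.d. priors, `G(alpha_mu/L, beta_mu/L)` per locus is the exact special
case `alpha = alpha_mu/L` of the partition prior.

## What the package provides

- `rate_priors` — densities, samplers, moments and the pairwise correlation
  for both priors, including the `G(alpha_mu/L, beta_mu/L)` workaround.
- `infinite_sites` — the time posterior given exact per-locus distances
  (`d_i = 2 t mu_i`), by log-space quadrature on an auto-expanding grid.
- `jc69` — the JC69 two-sequence likelihood, distance MLE, and FASTA
  ingestion reduced to (sites, mismatches).
- `simulator` — seeded generation of distance sets and finite-sites loci
  (log-normal branch-rate noise, binomial JC69 mismatch counts).
- `mcmc_dating` — a Metropolis-within-Gibbs sampler for
  `f(t, mu | D)` with a time-rate mixing move, vectorized over replicate
  chains.
- `experiments` + a `dirichletclock` CLI (`simulate`, `infsites`, `mcmc`,
  `table`, `sweep`) driven by a plain-text control file; all outputs TSV.

See `docs/methods.md` for the model, the density derivation, and the
numerical choices.

## Worked example

One hundred loci with exact distances (`t = 1`, true rates `G(2,4)`, so the
true mean rate is 0.5 per 100 Myr), analyzed with the calibration
`t ~ G(100,100)` under three rate priors — ten times too fast `G(2,0.4)`,
well specified `G(2,4)`, ten times too slow `G(2,40)`:

```python
import numpy as np
from dirichletclock import (DistanceSet, GammaSpec,
                            posterior_time_iid, posterior_time_dirichlet)

rng = np.random.default_rng(1)
data = DistanceSet(2.0 * rng.gamma(2.0, 1/4, 100))
tp = GammaSpec(100, 100)
for name, b in (("fast", 0.4), ("good", 4.0), ("slow", 40.0)):
    iid = posterior_time_iid(data, tp, GammaSpec(2, b))
    dir_ = posterior_time_dirichlet(data, tp, GammaSpec(2, b), concentration=1.0)
    print(f"{name}: iid {iid.mean:.3f} ({iid.ci95_low:.3f},{iid.ci95_high:.3f})"
          f"   dirichlet {dir_.mean:.3f} ({dir_.ci95_low:.3f},{dir_.ci95_high:.3f})")
```

prints

```
fast: iid 0.157 (0.133,0.187)   dirichlet 0.982 (0.797,1.185)
good: iid 0.937 (0.834,1.051)   dirichlet 0.998 (0.814,1.202)
slow: iid 3.785 (3.538,4.045)   dirichlet 1.140 (0.953,1.345)
```

Under the i.i.d. prior the estimated age swings 24-fold (0.16 to 3.8 time
units, i.e. 16 to 380 Myr) purely with the analyst's rate prior, and the
intervals exclude the true `t = 1`. Under the Dirichlet prior all three
posteriors sit near the truth with widths comparable to the calibration —
the data simply cannot resolve time from rate, and the posterior honestly
says so.

The finite-sites analogue (1000 sites per locus, log-normal branch-rate
noise, full MCMC) is one command:

```sh
dirichletclock table --config examples/two_species.ctl --out-dir results/
```

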