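# Two-species prior-sensitivity study: finite-sites replicate table.
# Simulates L=100 loci of N=1000 sites at true t=1 (true rates G(2,4),
# log-normal branch-rate noise sigma2=0.1) and analyzes each replicate
# under six locus-rate priors.

[experiment]
mode = finite_sites

[simulation]
true_time = 1.0
rate_shape = 2.0
rate_rate = 4.0
L = 100
n_sites = 1000
sigma2 = 0.1
n_replicates = 30
seed = 1

[time_prior]
shape = 100
rate = 100

[rate_prior]
kind = iid_gamma
shape = 2
rate = 0.4

[rate_prior]
kind = iid_gamma
shape = 2
rate = 4

[rate_prior]
kind = iid_gamma
shape = 2
rate = 40

[rate_prior]
kind = dirichlet
shape = 2
rate = 0.4
concentration = 1

[rate_prior]
kind = dirichlet
shape = 2
rate = 4
concentration = 1

[rate_prior]
kind = dirichlet
shape = 2
rate = 40
concentration = 1

[mcmc]
n_iter = 20000
burn_in = 2000
thin = 2
seed = 7
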