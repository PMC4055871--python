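# Infinite-sites prior comparison: one seeded set of 100 exact distances
# (t=1, rates G(2,4)) analyzed under three i.i.d. and three Dirichlet
# locus-rate priors; emits grid densities and summary rows.

[experiment]
mode = infinite_sites

[simulation]
true_time = 1.0
rate_shape = 2.0
rate_rate = 4.0
L = 100
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
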