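# Default model parameters: the reference L1-aggregation parameter set.
# Units: cm, s; densities and concentrations in cm^-d.

[model]
dim = 2
rho_bar = 9000
sigma = 5.555e-6
rho_max = 28000
cushion = 2000
scale = 2
beta_a = 1.111e-5
alpha_a = 1500
gamma_a = 0.01
D_a = 1e-6
s_a = 0.01
beta_r = -1.111e-5
alpha_r = 1500
gamma_r = 0.001
D_r = 1e-5
s_r = 0.001
repellent_enabled = true

[scenario]
variant = attractant-repellent
dim = 2
extent = 1.0
resolution = 128
rho_bar = 9000
ic = uniform-noisy
seed = 0
noise_frac = 0.01
inject = false
t_end = 2e5
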