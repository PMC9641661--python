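# Reference configuration: the shipped feasible parameter set.
# All rates are per hour, all levels in arbitrary concentration units,
# times in hours (developmental time in hpf for the locus model).

[run]
seed = 0
output_dir = results

[basic_model]
alpha_h = 2.0
mu_h = 2.0
alpha_X = 0.3
mu_X = 0.3

[extended_model]
alpha_Y = 1.0
beta_Y = 4.0
mu_Y = 2.0
y_on_h_n = 4.0
y_on_h_p0 = 0.5
h_on_y_n = 4.0
h_on_y_p0 = 0.5
y_self_n = 4.0
y_self_p0 = 0.7
gate_basal_only = false

[profile]
m0 = 1.0
step1_time = 20.0
step1_fold = 1.5
step2_time = 60.0
step2_fold = 4.0
ramp_start_time = 20.0
ramp_end_time = 100.0
t_end = 150.0

[locus_model]
n_cells = 500
loci = pri-mir-9-5:30:1:0.25:0.05, pri-mir-9-4:30:1:0.25:0.05, pri-mir-9-1:36.5:1:6.0:0.15
decay_rate = 1.0
t_start = 24.0
t_stop = 48.0
dt = 0.01
baseline = 1.0
late_locus = pri-mir-9-1
control_fit_stop = 42.0
settle_time = 60.0

[solver]
rtol = 1e-8
atol = 1e-10
max_step = inf

[experiment]
fluctuation_amplitude = 0.2
fluctuation_correlation_time = 1.0
fluctuation_window = 100.0
fluctuation_settle = 60.0
n_seeds = 100
p1_factors = 0.5, 0.75, 1.0, 1.25, 1.5
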