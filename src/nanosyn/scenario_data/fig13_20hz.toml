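[scenario]
name = "fig13_20hz"
description = "20 Hz release train, receptors free to diffuse laterally"
protocol = "train"
frequency_hz = 20.0
n_events = 5

[params]
R = 1000.0
H_c = 20.0
r_ves = 20.0
nnt = 10000
ani = 0.0
n_r = 80
n_c = 0
D_dr = 400.0
R_std = 50.0
D_ani = 100.0
D = 0.3
D_r = 0.1
g_unit = 25.0
E_intra = 65.0
E_syn = 0.0
Res = 200.0
N_A = 6.022e+23
F = 96485.0
Rg = 8.3144
T = 300.0
affinity_scale = 1.0
release_offset = 0.0

[numerics]
dt_ns = 50.0
duration_ms = 3.0
n_reps = 20
b_rad = 5.0
grid_d = 20.0
receptor_grid_h = 10.0
seed = 0

[engine]
fixed_layout = false
field_enabled = true
drift_enabled = true
lateral_diffusion = true
lateral_confined = false
check_conservation = false
progress = false
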