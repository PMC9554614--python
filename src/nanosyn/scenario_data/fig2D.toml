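[scenario]
name = "fig2D"
description = "Peak current vs number of released molecules, ani = 0"
protocol = "single"

[params]
R = 1000.0
H_c = 20.0
r_ves = 20.0
nnt = 1000
ani = 0.0
n_r = 40
n_c = 40
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
b_rad = 5.0
grid_d = 20.0
receptor_grid_h = 10.0
seed = 0

[engine]
fixed_layout = false
field_enabled = true
drift_enabled = true
lateral_diffusion = false
lateral_confined = false
check_conservation = false
progress = false

[sweep]
param = "nnt"
values = [200, 1000, 2000, 5000, 10000, 20000]
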