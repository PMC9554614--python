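"""Fused per-step particle kernel (numba).

One call advances every free molecule of every batched repetition by one
time step: isotropic Brownian displacement (lateral components scaled by
1 - ani inside the nanocolumn zone), electrophoretic drift from the last
field solve, reflection at both membranes, absorption at the rim, and
collection of successful binding draws against nearby receptors.  A molecule
is binding-eligible when it lies inside a receptor's protrusion volume:
lateral (xy) distance <= b_rad and within b_rad of the postsynaptic
membrane.

The update rules are algebraically identical to the reference operations in
``nanosyn.molecules``; sin(theta) is obtained as a sign-corrected
sqrt(1 - cos^2 theta) instead of a second trig call.
"""

from __future__ import annotations

import math

import numba
import numpy as np

ERR_NONE = 0
ERR_REFLECT = 1
ERR_PAIR_OVERFLOW = 2

TWO_PI = 2.0 * math.pi


@numba.njit(cache=False, fastmath=True)
def step_and_bind(gen,                      # np.random.Generator
                  xs, ys, zs,               # float64[:] positions by molecule id
                  active, n_act,            # int64[:] ids of free molecules, count
                  rep_of,                   # int32[:] repetition of each molecule
                  dr, s_in, rani2, R2, Hc, zbind, brad2,
                  drift_on, drift_coef, dvx, dvy,   # float64[:, :] (n_reps, ncells)
                  fg_R, fg_d, fg_n,
                  tb_x0, tb_cell, tb_ncx, tb_ncy, tb_k, n_rec,
                  table, table_of_rep,      # int32[:, :] local receptor ids, int32[:]
                  rec_x, rec_y, rec_state,  # global receptor arrays
                  p_bind_state,             # float64[:] per-state capture probability
                  absorbed_per_rep,         # int64[:]
                  pair_mol, pair_rec):      # int64[:] output buffers
    n_keep = 0
    n_pairs = 0
    err = ERR_NONE
    max_pairs = pair_mol.shape[0]
    for i in range(n_act):
        idx = active[i]
        a = gen.random()
        b = gen.random()
        ct = math.cos(TWO_PI * a)
        st = math.sqrt(max(0.0, 1.0 - ct * ct))
        if a > 0.5:
            st = -st
        cph = 1.0 - 2.0 * b
        sph = math.sqrt(max(0.0, 1.0 - cph * cph))
        x = xs[idx]
        y = ys[idx]
        z = zs[idx]
        rep = rep_of[idx]
        s = s_in if x * x + y * y < rani2 else 1.0
        ddx = dr * sph * ct * s
        ddy = dr * sph * st * s
        if drift_on:
            cx = int((x + fg_R) / fg_d)
            cy = int((y + fg_R) / fg_d)
            if 0 <= cx < fg_n and 0 <= cy < fg_n:
                cell = cx * fg_n + cy
                ddx += drift_coef * s * dvx[rep, cell]
                ddy += drift_coef * s * dvy[rep, cell]
        x += ddx
        y += ddy
        z += dr * cph
        if z < 0.0:
            z = -z
        if z > Hc:
            z = 2.0 * Hc - z
            if z < 0.0 or z > Hc:
                err = ERR_REFLECT
        if x * x + y * y >= R2:
            absorbed_per_rep[rep] += 1
            continue
        xs[idx] = x
        ys[idx] = y
        zs[idx] = z
        active[n_keep] = idx
        n_keep += 1
        # binding trials against receptors of this repetition
        if z >= zbind:
            tcx = int((x - tb_x0) / tb_cell)
            tcy = int((y - tb_x0) / tb_cell)
            if 0 <= tcx < tb_ncx and 0 <= tcy < tb_ncy:
                base = (tcx * tb_ncy + tcy) * tb_k
                trow = table_of_rep[rep]
                offset = rep * n_rec
                for k in range(tb_k):
                    rl = table[trow, base + k]
                    if rl < 0:
                        break
                    rg = rl + offset
                    p = p_bind_state[rec_state[rg]]
                    if p <= 0.0:
                        continue
                    dx = x - rec_x[rg]
                    dy = y - rec_y[rg]
                    if dx * dx + dy * dy > brad2:
                        continue
                    if gen.random() < p:
                        if n_pairs < max_pairs:
                            pair_mol[n_pairs] = idx
                            pair_rec[n_pairs] = rg
                            n_pairs += 1
                        else:
                            err = ERR_PAIR_OVERFLOW
                        break
    return n_keep, n_pairs, err
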