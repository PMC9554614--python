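"""Coupled time loop: glutamate diffusion, receptor kinetics, cleft field.

The Monte Carlo repetitions of one scenario are advanced together as a single
batched state (one fused particle kernel call per time step over the free
molecules of every repetition), which keeps the per-step Python overhead
independent of the repetition count.  Sub-updates within a step follow the
causal order: drift gradients from the last field solve -> particle moves ->
boundary handling -> binding -> receptor Markov transitions -> (receptor
lateral diffusion) -> field re-solve for repetitions whose open-channel
configuration changed.

Randomness is split over three named streams spawned from the root seed
(layout, molecules+binding, receptors) so that results are reproducible
bit-for-bit for a fixed seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels
from .field import CleftField, GridSpec
from .kinetics import (DESENSITIZED_STATES, STATE_INDEX, STATES, KineticScheme,
                       default_scheme, equivalent_concentration)
from .molecules import BOUND, FREE, sample_disk
from .params import NumericsConfig, SimulationParameters
from .placement import ReceptorLayout, place_receptors

__all__ = ["EngineOptions", "SimulationResult", "run_single", "run_ensemble",
           "run_train", "run_random_release_events"]

UNRELEASED = 3
OPEN = STATE_INDEX["O2"]
_DESENS = np.array([1 if s in DESENSITIZED_STATES else 0 for s in STATES], dtype=np.int8)


@dataclass
class EngineOptions:
    """Feature switches of the engine."""

    fixed_layout: bool = False      #: one receptor layout shared by all repetitions
    field_enabled: bool = True      #: solve the cleft potential (driving-force feedback)
    drift_enabled: bool = True      #: electrophoretic drift of glutamate in the field
    lateral_diffusion: bool = False  #: receptor lateral diffusion on the 10 nm grid
    lateral_confined: bool = False  #: keep each receptor group on its side of the nanocolumn edge
    check_conservation: bool = False  #: assert free+bound+absorbed bookkeeping every step
    progress: bool = False          #: per-millisecond progress lines on stderr


@dataclass
class SimulationResult:
    """Traces and per-entity statistics of one batched run."""

    params: SimulationParameters
    numerics: NumericsConfig
    options: EngineOptions
    time_ms: np.ndarray             #: (n_steps,)
    current: np.ndarray             #: (n_reps, n_steps) pA
    n_open: np.ndarray              #: (n_reps, n_steps)
    desensitized: np.ndarray        #: (n_reps, n_steps) receptor counts
    absorbed: np.ndarray            #: (n_reps, n_steps) cumulative
    capture_counts: np.ndarray      #: (n_reps, n_molecules_per_rep)
    opening_counts: np.ndarray      #: (n_reps, n_receptors)
    max_depolarization_mV: np.ndarray  #: (n_reps,)
    layouts: list[ReceptorLayout]
    event_times_ms: np.ndarray = dc_field(default_factory=lambda: np.zeros(1))
    release_distances_nm: np.ndarray | None = None

    @property
    def n_reps(self) -> int:
        return self.current.shape[0]

    @property
    def mean_current(self) -> np.ndarray:
        return self.current.mean(axis=0, dtype=np.float64)

    @property
    def current_envelope(self) -> tuple[np.ndarray, np.ndarray]:
        return self.current.min(axis=0), self.current.max(axis=0)

    @property
    def mean_conductance_pS(self) -> np.ndarray:
        return self.n_open.mean(axis=0, dtype=np.float64) * self.params.g_unit

    @property
    def desensitized_fraction(self) -> np.ndarray:
        n_rec = self.opening_counts.shape[1]
        if n_rec == 0:
            return np.zeros_like(self.time_ms)
        return self.desensitized.mean(axis=0, dtype=np.float64) / n_rec

    def charge_per_rep_fC(self) -> np.ndarray:
        """Per-repetition total charge by trapezoidal integration (pA * ms = fC)."""
        return np.trapezoid(self.current.astype(np.float64), self.time_ms, axis=1)

    def event_peaks_pA(self) -> np.ndarray:
        """Peak of the mean current within each release interval."""
        edges = np.searchsorted(self.time_ms, self.event_times_ms)
        edges = np.append(edges, len(self.time_ms))
        mean = self.mean_current
        return np.array([mean[a:b].max() if b > a else 0.0
                         for a, b in zip(edges[:-1], edges[1:])])


# ---------------------------------------------------------------------------


class _RepField:
    """Per-repetition source-element bookkeeping for the fast field path."""

    def __init__(self, cleft: CleftField, elems: np.ndarray):
        self.cleft = cleft
        self.elems = np.asarray(elems, dtype=np.int64)
        self.W = cleft.green_block(self.elems) if len(self.elems) else np.zeros((0, 0))
        self.counts = np.zeros(len(self.elems), dtype=np.int64)

    def clone_counts(self) -> "_RepField":
        other = _RepField.__new__(_RepField)
        other.cleft = self.cleft
        other.elems = self.elems
        other.W = self.W
        other.counts = np.zeros(len(self.elems), dtype=np.int64)
        return other

    def slot_of(self, elem: int) -> int:
        hit = np.flatnonzero(self.elems == elem)
        if len(hit):
            return int(hit[0])
        # grow: one more Green column
        self.elems = np.append(self.elems, elem)
        m = len(self.elems)
        W = np.empty((m, m))
        W[:m - 1, :m - 1] = self.W
        col = self.cleft._green(int(elem))
        W[:m - 1, m - 1] = col[self.elems[:m - 1]]
        W[m - 1, :m - 1] = W[:m - 1, m - 1]
        W[m - 1, m - 1] = col[elem]
        self.W = W
        self.counts = np.append(self.counts, 0)
        return m - 1


class _Batch:
    """Mutable state of a batched simulation."""

    def __init__(self, params: SimulationParameters, numerics: NumericsConfig,
                 n_reps: int, seed: int, options: EngineOptions,
                 layout: ReceptorLayout | None = None,
                 scheme: KineticScheme | None = None,
                 n_events: int = 1, event_interval_ms: float | None = None,
                 release_centers: np.ndarray | None = None):
        self.params = params
        self.numerics = numerics
        self.options = options
        self.n_reps = n_reps
        self.n_events = n_events
        self.scheme = scheme or default_scheme(params.affinity_scale)
        self.scheme.check_dt(numerics.dt_s)

        ss = np.random.SeedSequence(seed)
        ss_layout, ss_mol, ss_rec = ss.spawn(3)
        self.gen_layout = np.random.default_rng(ss_layout)
        self.gen_mol = np.random.default_rng(ss_mol)
        self.gen_rec = np.random.default_rng(ss_rec)

        self.n_steps = numerics.n_steps
        if event_interval_ms is None:
            self.event_steps = np.zeros(1, dtype=np.int64)
        else:
            step_int = event_interval_ms / numerics.dt_ms
            if step_int < 1:
                raise ValueError("release interval shorter than one time step")
            self.event_steps = np.round(np.arange(n_events) * step_int).astype(np.int64)

        self._init_receptors(layout)
        self._init_molecules(release_centers)
        self._init_field()
        if options.lateral_diffusion:
            self._init_lattice()
        self._init_tables()
        self._init_traces()

    # -- initialisation ----------------------------------------------------

    def _init_receptors(self, layout: ReceptorLayout | None) -> None:
        p = self.params
        if layout is not None:
            layouts = [layout] * self.n_reps
        elif self.options.fixed_layout:
            layouts = [place_receptors(p, self.gen_layout)] * self.n_reps
        else:
            layouts = [place_receptors(p, self.gen_layout) for _ in range(self.n_reps)]
        self.layouts = layouts
        self.n_rec = len(layouts[0])
        n_tot = self.n_rec * self.n_reps
        self.rec_x = np.concatenate([lo.x for lo in layouts]) if n_tot else np.zeros(0)
        self.rec_y = np.concatenate([lo.y for lo in layouts]) if n_tot else np.zeros(0)
        self.rec_group = np.concatenate(
            [(lo.group == "random").astype(np.int8) for lo in layouts]) if n_tot else np.zeros(0, np.int8)
        self.rec_state = np.zeros(n_tot, dtype=np.int8)  # all C0
        self.rep_of_rec = np.repeat(np.arange(self.n_reps, dtype=np.int64), self.n_rec)
        self.opening_count = np.zeros(n_tot, dtype=np.int64)
        self.bound_ids = np.full((n_tot, 2), -1, dtype=np.int64)
        self.bound_count = np.zeros(n_tot, dtype=np.int8)

    def _init_molecules(self, release_centers: np.ndarray | None) -> None:
        p = self.params
        if release_centers is None:
            release_centers = np.tile([p.release_offset, 0.0], (self.n_reps, 1))
        self.release_centers = np.asarray(release_centers, dtype=float)
        n_tot = p.nnt * self.n_reps * self.n_events
        self.xs = np.zeros(n_tot)
        self.ys = np.zeros(n_tot)
        self.zs = np.zeros(n_tot)
        self.status = np.full(n_tot, UNRELEASED, dtype=np.int8)
        self.capture_count = np.zeros(n_tot, dtype=np.int32)
        # molecule id layout: (event, rep, j)
        self.rep_of_mol = np.tile(np.repeat(np.arange(self.n_reps, dtype=np.int32), p.nnt),
                                  self.n_events)
        self.active = np.zeros(n_tot, dtype=np.int64)
        self.n_act = 0
        self.absorbed_per_rep = np.zeros(self.n_reps, dtype=np.int64)
        self.released = 0

    def _release_event(self, ev: int) -> None:
        p = self.params
        n = p.nnt * self.n_reps
        if n == 0:
            return
        start = ev * n
        ids = np.arange(start, start + n, dtype=np.int64)
        cx = np.repeat(self.release_centers[:, 0], p.nnt)
        cy = np.repeat(self.release_centers[:, 1], p.nnt)
        r = p.r_ves * np.sqrt(self.gen_mol.random(n))
        th = 2.0 * np.pi * self.gen_mol.random(n)
        self.xs[ids] = cx + r * np.cos(th)
        self.ys[ids] = cy + r * np.sin(th)
        self.zs[ids] = 0.0
        self.status[ids] = FREE
        self.active[self.n_act:self.n_act + n] = ids
        self.n_act += n
        self.released += n

    def _init_field(self) -> None:
        self.cur_I = np.zeros(self.n_reps)
        self.cur_nopen = np.zeros(self.n_reps, dtype=np.int64)
        self.cur_desens = np.zeros(self.n_reps, dtype=np.int64)
        self.max_depol = np.zeros(self.n_reps)
        self.drift_live = False
        if not self.options.field_enabled:
            self.cleft = None
            self.rep_fields = None
            self.rec_slot = np.zeros(max(1, len(self.rec_x)), dtype=np.int64)
            self.dvx = np.zeros((1, 1))
            self.dvy = np.zeros((1, 1))
            return
        self.cleft = CleftField(self.params, self.numerics)
        spec = self.cleft.spec
        self.rec_slot = np.zeros(max(1, len(self.rec_x)), dtype=np.int64)
        self.rep_fields: list[_RepField] = []
        shared: _RepField | None = None
        for r in range(self.n_reps):
            sl = slice(r * self.n_rec, (r + 1) * self.n_rec)
            if self.n_rec == 0:
                rf = _RepField(self.cleft, np.zeros(0, dtype=np.int64))
            elif (self.options.fixed_layout or self.layouts[0] is self.layouts[r]) and shared is not None:
                rf = shared.clone_counts()
            else:
                cells = spec.cell_of(self.rec_x[sl], self.rec_y[sl])
                red = self.cleft.reduced_index(cells)
                elems = np.unique(red)
                rf = _RepField(self.cleft, elems)
            if r == 0:
                shared = rf
            if self.n_rec:
                cells = spec.cell_of(self.rec_x[sl], self.rec_y[sl])
                red = self.cleft.reduced_index(cells)
                self.rec_slot[sl] = np.searchsorted(rf.elems, red)
            self.rep_fields.append(rf)
        if self.options.drift_enabled:
            ncell = spec.n * spec.n
            self.dvx = np.zeros((self.n_reps, ncell))
            self.dvy = np.zeros((self.n_reps, ncell))
        else:
            self.dvx = np.zeros((1, 1))
            self.dvy = np.zeros((1, 1))

    def _init_tables(self) -> None:
        num, p = self.numerics, self.params
        c_eq = equivalent_concentration(num.b_rad)
        k_on = self.scheme.binding_rate_by_state()
        self.p_bind_state = k_on * c_eq * num.dt_s
        if np.any(self.p_bind_state >= 1.0):
            raise ValueError("binding probability k_on * C_eq * dt >= 1; reduce the time step")
        self.bind_target = self.scheme.binding_target_by_state()
        self.mk_cum, self.mk_target, self.mk_unbind = self.scheme.step_tables(num.dt_s)

        # spatial lookup: receptor candidates per 2*b_rad cell
        if self.n_rec == 0:
            self.tb = dict(x0=0.0, cell=1.0, ncx=1, ncy=1, k=0,
                           table=np.full((1, 1), -1, dtype=np.int32),
                           of_rep=np.zeros(self.n_reps, dtype=np.int32))
            return
        cell = 2.0 * num.b_rad
        if self.options.lateral_diffusion:
            ext = p.R + cell  # receptors may wander anywhere in the disk
        else:
            ext = float(np.max(np.abs(np.concatenate([self.rec_x, self.rec_y])))) + cell
        nc = int(np.ceil(2 * ext / cell))
        x0 = -ext
        centers = x0 + (np.arange(nc) + 0.5) * cell
        cxx, cyy = np.meshgrid(centers, centers, indexing="ij")
        reach = num.b_rad + cell * math.sqrt(0.5)
        shared = (not self.options.lateral_diffusion
                  and (self.options.fixed_layout
                       or all(lo is self.layouts[0] for lo in self.layouts)))
        n_tables = 1 if shared else self.n_reps
        lists: list[list[list[int]]] = []
        kmax = 1
        for ti in range(n_tables):
            sl = slice(ti * self.n_rec, (ti + 1) * self.n_rec)
            d2 = ((cxx.reshape(-1, 1) - self.rec_x[sl][None, :]) ** 2
                  + (cyy.reshape(-1, 1) - self.rec_y[sl][None, :]) ** 2)
            hits = d2 <= reach**2
            per_cell = [list(np.flatnonzero(h)) for h in hits]  # local receptor ids
            kmax = max(kmax, max((len(c) for c in per_cell), default=1))
            lists.append(per_cell)
        if self.options.lateral_diffusion:
            kmax += 4  # headroom for receptors drifting into the same cell
        table = np.full((n_tables, nc * nc * kmax), -1, dtype=np.int32)
        for ti, per_cell in enumerate(lists):
            for ci, recs in enumerate(per_cell):
                for j, rg in enumerate(recs):
                    table[ti, ci * kmax + j] = rg
        of_rep = (np.zeros(self.n_reps, dtype=np.int32) if shared
                  else np.arange(self.n_reps, dtype=np.int32))
        self.tb = dict(x0=x0, cell=cell, ncx=nc, ncy=nc, k=kmax, table=table, of_rep=of_rep)

    def _init_traces(self) -> None:
        n = (self.n_reps, self.n_steps)
        self.tr_I = np.zeros(n, dtype=np.float32)
        self.tr_nopen = np.zeros(n, dtype=np.int16)
        self.tr_desens = np.zeros(n, dtype=np.int16)
        self.tr_absorbed = np.zeros(n, dtype=np.int32)
        self.pair_mol = np.zeros(max(64, 4 * self.n_rec * self.n_reps), dtype=np.int64)
        self.pair_rec = np.zeros_like(self.pair_mol)

    def _init_lattice(self) -> None:
        h = self.numerics.receptor_grid_h
        R = self.params.R
        ncl = 2 * int(np.ceil(R / h))
        self.lat_n = ncl
        self.lat_h = h
        self.occupancy = np.full((self.n_reps, ncl, ncl), -1, dtype=np.int64)
        centers = (np.arange(ncl) + 0.5) * h - R
        self.lat_centers = centers
        in_disk = (centers[:, None] ** 2 + centers[None, :] ** 2) < R**2
        edge = in_disk & ~(np.roll(in_disk, 1, 0) & np.roll(in_disk, -1, 0)
                           & np.roll(in_disk, 1, 1) & np.roll(in_disk, -1, 1))
        self.edge_cells = np.argwhere(edge)
        self.lat_in_disk = in_disk
        # snap receptors onto free lattice cells
        for gid in range(len(self.rec_x)):
            r = self.rep_of_rec[gid]
            ci = int((self.rec_x[gid] + R) / h)
            cj = int((self.rec_y[gid] + R) / h)
            ci = min(max(ci, 0), ncl - 1)
            cj = min(max(cj, 0), ncl - 1)
            placed = False
            for ring in range(0, 6):
                for di in range(-ring, ring + 1):
                    for dj in range(-ring, ring + 1):
                        ni, nj = ci + di, cj + dj
                        if (0 <= ni < ncl and 0 <= nj < ncl and in_disk[ni, nj]
                                and self.occupancy[r, ni, nj] < 0):
                            self.occupancy[r, ni, nj] = gid
                            self._move_receptor(gid, ni, nj, update_field=False)
                            placed = True
                            break
                    if placed:
                        break
                if placed:
                    break
            if not placed:
                raise RuntimeError("could not snap receptor onto the lateral-diffusion lattice")
        self.lat_cell = np.zeros((len(self.rec_x), 2), dtype=np.int64)
        for r in range(self.n_reps):
            occ = self.occupancy[r]
            for ci, cj in zip(*np.nonzero(occ >= 0)):
                self.lat_cell[occ[ci, cj]] = (ci, cj)
        # confinement side is the receptor's starting position relative to the
        # nanocolumn disk (not its placement group)
        self.lat_inside_col = (self.rec_x**2 + self.rec_y**2
                               < (self.params.D_ani / 2.0) ** 2)

    def _bind_cells(self, x: float, y: float):
        """Binding-table cells whose centre lies within reach of (x, y)."""
        tb = self.tb
        reach = self.numerics.b_rad + tb["cell"] * math.sqrt(0.5)
        lo_x = int((x - reach - tb["x0"]) / tb["cell"])
        hi_x = int((x + reach - tb["x0"]) / tb["cell"])
        lo_y = int((y - reach - tb["x0"]) / tb["cell"])
        hi_y = int((y + reach - tb["x0"]) / tb["cell"])
        for ci in range(max(0, lo_x), min(tb["ncx"] - 1, hi_x) + 1):
            cx = tb["x0"] + (ci + 0.5) * tb["cell"]
            for cj in range(max(0, lo_y), min(tb["ncy"] - 1, hi_y) + 1):
                cy = tb["x0"] + (cj + 0.5) * tb["cell"]
                if (cx - x) ** 2 + (cy - y) ** 2 <= reach**2:
                    yield ci * tb["ncy"] + cj

    def _table_move(self, gid: int, old_x: float, old_y: float) -> None:
        """Re-register a moved receptor in its repetition's binding table."""
        tb = self.tb
        r = int(self.rep_of_rec[gid])
        ti = int(tb["of_rep"][r])
        local = gid - r * self.n_rec
        row = tb["table"][ti]
        k = tb["k"]
        for cell in self._bind_cells(old_x, old_y):
            base = cell * k
            for j in range(k):
                if row[base + j] == local:
                    row[base + j:base + k - 1] = row[base + j + 1:base + k]
                    row[base + k - 1] = -1
                    break
        for cell in self._bind_cells(self.rec_x[gid], self.rec_y[gid]):
            base = cell * k
            for j in range(k):
                if row[base + j] == local:
                    break
                if row[base + j] < 0:
                    row[base + j] = local
                    break
            else:
                raise RuntimeError("binding-table cell overflow during receptor diffusion")

    def _move_receptor(self, gid: int, ci: int, cj: int, update_field: bool = True) -> bool:
        """Place receptor gid at lattice cell (ci, cj); returns field-changed."""
        old_x, old_y = self.rec_x[gid], self.rec_y[gid]
        self.rec_x[gid] = self.lat_centers[ci]
        self.rec_y[gid] = self.lat_centers[cj]
        if hasattr(self, "tb") and self.tb["k"] > 0:
            self._table_move(gid, old_x, old_y)
        if self.cleft is None:
            return False
        r = int(self.rep_of_rec[gid])
        rf = self.rep_fields[r]
        cell = self.cleft.spec.cell_of(np.array([self.rec_x[gid]]),
                                       np.array([self.rec_y[gid]]))
        new_elem = int(self.cleft.reduced_index(cell)[0])
        old_slot = int(self.rec_slot[gid])
        new_slot = rf.slot_of(new_elem)
        self.rec_slot[gid] = new_slot
        if update_field and self.rec_state[gid] == OPEN and new_slot != old_slot:
            rf.counts[old_slot] -= 1
            rf.counts[new_slot] += 1
            return True
        return False

    # -- per-step sub-updates ---------------------------------------------

    def _apply_bindings(self, n_pairs: int) -> None:
        mols = self.pair_mol[:n_pairs]
        recs = self.pair_rec[:n_pairs]
        if n_pairs > 1:
            perm = self.gen_mol.permutation(n_pairs)
            mols, recs = mols[perm], recs[perm]
            _, first = np.unique(recs, return_index=True)
            mols, recs = mols[first], recs[first]
        # state may have advanced for duplicated receptors; all survivors are unique
        self.rec_state[recs] = self.bind_target[self.rec_state[recs]]
        slot = self.bound_count[recs]
        self.bound_ids[recs, slot] = mols
        self.bound_count[recs] = slot + 1
        self.status[mols] = BOUND
        self.capture_count[mols] += 1
        keep = self.status[self.active[:self.n_act]] == FREE
        kept = self.active[:self.n_act][keep]
        self.n_act = len(kept)
        self.active[:self.n_act] = kept

    def _markov_step(self, changed_reps: set[int]) -> None:
        st = self.rec_state
        u = self.gen_rec.random(len(st))
        cum = self.mk_cum[st]
        k = (u[:, None] >= cum).sum(axis=1)
        tgt = self.mk_target[st, k]
        ch = np.flatnonzero(tgt != st)
        if len(ch) == 0:
            return
        old = st[ch].copy()
        new = tgt[ch]
        unb = self.mk_unbind[old, k[ch]]
        # releases: one molecule back to the free pool at the capture site
        rel = ch[unb]
        if len(rel):
            slot = self.bound_count[rel] - 1
            mids = self.bound_ids[rel, slot]
            self.bound_ids[rel, slot] = -1
            self.bound_count[rel] = slot
            self.status[mids] = FREE
            self.xs[mids] = self.rec_x[rel]
            self.ys[mids] = self.rec_y[rel]
            self.zs[mids] = self.params.H_c - 0.1
            self.active[self.n_act:self.n_act + len(mids)] = mids
            self.n_act += len(mids)
        opened = ch[new == OPEN]
        closed = ch[old == OPEN]
        self.opening_count[opened] += 1
        ddes = _DESENS[new].astype(np.int64) - _DESENS[old]
        if np.any(ddes):
            np.add.at(self.cur_desens, self.rep_of_rec[ch], ddes)
        self.cur_nopen += np.bincount(self.rep_of_rec[opened], minlength=self.n_reps)
        self.cur_nopen -= np.bincount(self.rep_of_rec[closed], minlength=self.n_reps)
        st[ch] = new
        if self.cleft is not None:
            for gid in opened:
                self.rep_fields[self.rep_of_rec[gid]].counts[self.rec_slot[gid]] += 1
            for gid in closed:
                self.rep_fields[self.rep_of_rec[gid]].counts[self.rec_slot[gid]] -= 1
        for gid in np.concatenate([opened, closed]):
            changed_reps.add(int(self.rep_of_rec[gid]))

    def _lateral_step(self, changed_reps: set[int]) -> None:
        p = self.params
        dt_ns = self.numerics.dt_ns
        h = self.lat_h
        d_nm2_per_ns = p.D_r * 1e-3  # um^2/s -> nm^2/ns
        p_move = 4.0 * d_nm2_per_ns * dt_ns / h**2
        u = self.gen_rec.random(len(self.rec_x))
        movers = np.flatnonzero(u < p_move)
        if len(movers) == 0:
            return
        dirs = (self.gen_rec.random(len(movers)) * 4).astype(np.int64)
        steps = ((1, 0), (-1, 0), (0, 1), (0, -1))
        half_col2 = (p.D_ani / 2.0) ** 2
        for gid, d in zip(movers, dirs):
            r = int(self.rep_of_rec[gid])
            ci, cj = self.lat_cell[gid]
            ni, nj = ci + steps[d][0], cj + steps[d][1]
            inside_lattice = 0 <= ni < self.lat_n and 0 <= nj < self.lat_n
            in_disk = inside_lattice and self.lat_in_disk[ni, nj]
            if not in_disk:
                # left the synapse: replaced by a fresh closed receptor at the edge
                self._replace_at_edge(gid, r, changed_reps)
                continue
            if self.options.lateral_confined:
                r2 = self.lat_centers[ni] ** 2 + self.lat_centers[nj] ** 2
                if self.lat_inside_col[gid] != (r2 < half_col2):
                    continue
            if self.occupancy[r, ni, nj] >= 0:
                continue
            self.occupancy[r, ci, cj] = -1
            self.occupancy[r, ni, nj] = gid
            self.lat_cell[gid] = (ni, nj)
            if self._move_receptor(gid, ni, nj):
                changed_reps.add(r)

    def _replace_at_edge(self, gid: int, r: int, changed_reps: set[int]) -> None:
        # release any cargo at the old position, reset to C0, respawn on the rim
        if self.bound_count[gid] > 0:
            mids = self.bound_ids[gid, :self.bound_count[gid]]
            self.status[mids] = FREE
            self.xs[mids] = self.rec_x[gid]
            self.ys[mids] = self.rec_y[gid]
            self.zs[mids] = self.params.H_c - 0.1
            self.active[self.n_act:self.n_act + len(mids)] = mids
            self.n_act += len(mids)
            self.bound_ids[gid] = -1
            self.bound_count[gid] = 0
        old_state = self.rec_state[gid]
        if old_state == OPEN:
            self.cur_nopen[r] -= 1
            if self.cleft is not None:
                self.rep_fields[r].counts[self.rec_slot[gid]] -= 1
            changed_reps.add(r)
        if _DESENS[old_state]:
            self.cur_desens[r] -= 1
        self.rec_state[gid] = 0
        for _ in range(1000):
            e = self.edge_cells[int(self.gen_rec.random() * len(self.edge_cells))]
            if self.occupancy[r, e[0], e[1]] < 0:
                ci, cj = self.lat_cell[gid]
                self.occupancy[r, ci, cj] = -1
                self.occupancy[r, e[0], e[1]] = gid
                self.lat_cell[gid] = (e[0], e[1])
                self._move_receptor(gid, int(e[0]), int(e[1]), update_field=False)
                return
        raise RuntimeError("no free edge cell for receptor replacement")

    def _field_update(self, changed_reps: set[int]) -> None:
        if self.cleft is None:
            self.cur_I = self.cur_nopen * self.params.g_unit * self.params.E_intra * 1e-3
            return
        for r in changed_reps:
            rf = self.rep_fields[r]
            v_mV, q_A, I_pA = self.cleft.solve_sources(rf.W, rf.elems, rf.counts)
            self.cur_I[r] = I_pA
            if len(v_mV):
                self.max_depol[r] = max(self.max_depol[r], float(v_mV.max()))
            if self.options.drift_enabled:
                vflat = self.cleft.full_potential(rf.elems, q_A)
                gx, gy = self.cleft.gradient_grids(vflat)
                self.dvx[r] = gx
                self.dvy[r] = gy
                self.drift_live = True

    def _check_conservation(self) -> None:
        bound = int(self.bound_count.sum())
        absorbed = int(self.absorbed_per_rep.sum())
        if self.n_act + bound + absorbed != self.released:
            raise AssertionError(
                f"molecule bookkeeping broken: {self.n_act} free + {bound} bound + "
                f"{absorbed} absorbed != {self.released} released")

    # -- main loop ---------------------------------------------------------

    def run(self) -> SimulationResult:
        import sys

        p, num = self.params, self.numerics
        dr = num.step_length_nm(p.D)
        drift_c = _drift_coefficient(p, num)
        fg = self.cleft.spec if self.cleft is not None else GridSpec(p.R, num.grid_d)
        tb = self.tb
        next_ev = 0
        changed_reps: set[int] = set()
        for t in range(self.n_steps):
            if next_ev < self.n_events and t == self.event_steps[next_ev]:
                self._release_event(next_ev)
                next_ev += 1
            n_act, n_pairs, err = _kernels.step_and_bind(
                self.gen_mol, self.xs, self.ys, self.zs, self.active, self.n_act,
                self.rep_of_mol, dr, 1.0 - p.ani, (p.D_ani / 2.0) ** 2, p.R**2,
                p.H_c, p.H_c - num.b_rad, num.b_rad**2,
                self.drift_live and self.options.drift_enabled, drift_c,
                self.dvx, self.dvy, fg.R, fg.d, fg.n,
                tb["x0"], tb["cell"], tb["ncx"], tb["ncy"], tb["k"], self.n_rec,
                tb["table"], tb["of_rep"], self.rec_x, self.rec_y, self.rec_state,
                self.p_bind_state, self.absorbed_per_rep, self.pair_mol, self.pair_rec)
            if err == _kernels.ERR_REFLECT:
                raise RuntimeError("step length exceeds the cleft height; reduce the time step")
            if err == _kernels.ERR_PAIR_OVERFLOW:
                raise RuntimeError("binding-candidate buffer overflow")
            self.n_act = n_act
            if n_pairs:
                self._apply_bindings(n_pairs)
            changed_reps.clear()
            self._markov_step(changed_reps)
            if self.options.lateral_diffusion:
                self._lateral_step(changed_reps)
            if changed_reps or self.cleft is None:
                self._field_update(changed_reps)
            self.tr_I[:, t] = self.cur_I
            self.tr_nopen[:, t] = self.cur_nopen
            self.tr_desens[:, t] = self.cur_desens
            self.tr_absorbed[:, t] = self.absorbed_per_rep
            if self.options.check_conservation:
                self._check_conservation()
            if self.options.progress and t % max(1, self.n_steps // 20) == 0:
                print(f"[nanosyn] step {t}/{self.n_steps} "
                      f"free={self.n_act} open={int(self.cur_nopen.sum())}",
                      file=sys.stderr)
        return self._result()

    def _result(self) -> SimulationResult:
        p = self.params
        caps = self.capture_count.reshape(self.n_events, self.n_reps, p.nnt)
        caps = caps.transpose(1, 0, 2).reshape(self.n_reps, -1)
        time_ms = (np.arange(self.n_steps) + 1) * self.numerics.dt_ms
        dists = np.hypot(self.release_centers[:, 0], self.release_centers[:, 1])
        return SimulationResult(
            params=p, numerics=self.numerics, options=self.options,
            time_ms=time_ms,
            current=self.tr_I, n_open=self.tr_nopen, desensitized=self.tr_desens,
            absorbed=self.tr_absorbed, capture_counts=caps,
            opening_counts=self.opening_count.reshape(self.n_reps, self.n_rec),
            max_depolarization_mV=self.max_depol,
            layouts=self.layouts,
            event_times_ms=self.event_steps * self.numerics.dt_ms,
            release_distances_nm=dists,
        )


def _drift_coefficient(params, numerics) -> float:
    from .molecules import drift_coefficient_nm
    return drift_coefficient_nm(params, numerics)


# ---------------------------------------------------------------------------
# public entry points
# ---------------------------------------------------------------------------

def run_ensemble(params: SimulationParameters,
                 numerics: NumericsConfig | None = None, *,
                 n_reps: int | None = None, seed: int = 0,
                 options: EngineOptions | None = None,
                 layout: ReceptorLayout | None = None,
                 scheme: KineticScheme | None = None) -> SimulationResult:
    """Run ``n_reps`` Monte Carlo repetitions of a single quantal release.

    ``n_reps`` defaults to round(1e6/nnt) clipped to [20, 1000].  With
    ``options.fixed_layout`` one receptor layout is shared by every
    repetition; otherwise a fresh layout is drawn per repetition.
    """
    numerics = numerics or NumericsConfig()
    options = options or EngineOptions()
    reps = n_reps if n_reps is not None else numerics.default_reps(params.nnt)
    batch = _Batch(params, numerics, reps, seed, options, layout=layout, scheme=scheme)
    return batch.run()


def run_single(params: SimulationParameters,
               numerics: NumericsConfig | None = None, *,
               layout: ReceptorLayout | None = None,
               scheme: KineticScheme | None = None,
               seed: int = 0,
               options: EngineOptions | None = None) -> SimulationResult:
    """One repetition (a convenience wrapper around the batched engine)."""
    return run_ensemble(params, numerics, n_reps=1, seed=seed,
                        options=options, layout=layout, scheme=scheme)


def run_train(params: SimulationParameters,
              numerics: NumericsConfig | None = None, *,
              frequency_hz: float, n_events: int, seed: int = 0,
              n_reps: int = 20,
              options: EngineOptions | None = None) -> SimulationResult:
    """A train of ``n_events`` releases at ``frequency_hz``.

    Receptor states, molecule pools and (moving) layouts persist between
    releases within a repetition; the duration is n_events / frequency.
    """
    if n_events < 1:
        raise ValueError("n_events must be >= 1")
    interval_ms = 1000.0 / frequency_hz
    numerics = (numerics or NumericsConfig()).replace(duration_ms=interval_ms * n_events)
    options = options or EngineOptions()
    batch = _Batch(params, numerics, n_reps, seed, options,
                   n_events=n_events, event_interval_ms=interval_ms)
    return batch.run()


def run_random_release_events(params: SimulationParameters,
                              numerics: NumericsConfig | None = None, *,
                              n_events: int = 100, seed: int = 0,
                              options: EngineOptions | None = None) -> SimulationResult:
    """Independent releases at uniform random sites within the PSD disk.

    Each batched repetition is one event with its own release location; the
    receptor layout is shared so events differ only in the release site.
    The result's ``release_distances_nm`` pairs with ``charge_per_rep_fC()``.
    """
    numerics = numerics or NumericsConfig()
    options = options or EngineOptions(fixed_layout=True)
    options.fixed_layout = True
    rng = np.random.default_rng(np.random.SeedSequence([seed, 777]))
    cx, cy = sample_disk(n_events, params.D_dr / 2.0, 0.0, 0.0, rng)
    centers = np.column_stack([cx, cy])
    batch = _Batch(params, numerics, n_events, seed, options, release_centers=centers)
    return batch.run()
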