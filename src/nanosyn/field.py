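"""Finite-volume electrostatics of the synaptic cleft.

The cleft disk is covered by square elements of side ``grid_d``.  Neglecting
capacitive currents, charge balance in each element equates the transmembrane
current of its open channels, n_ij * g_unit * (E - v_ij), with the lateral
ohmic currents to the four neighbours, each (v_ij - v_neighbour) * H_c / Res.
The potential is clamped to 0 on the ring of elements outside the disk
(absorbing extracellular bath).  ``v`` is expressed in mV with the sign
convention that open channels depolarize the cleft (v > 0), so the effective
driving force of an open channel is E_intra - v.

`solve_potential` is the plain sparse direct solve of that linear system.
`CleftField` is an algebraically identical fast path used by the engine: it
precomputes the discrete Green's function of the Dirichlet Laplacian at the
receptor elements (one sparse LU, a handful of columns) and then resolves any
open-channel configuration with a tiny dense capacitance-matrix solve.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu, spsolve

__all__ = ["GridSpec", "PotentialGrid", "solve_potential", "gradients",
           "total_current", "CleftField"]


@dataclass(frozen=True)
class GridSpec:
    """Square element grid of size d covering the disk of radius R (nm)."""

    R: float
    d: float

    @property
    def n(self) -> int:
        """Elements per side."""
        return 2 * int(np.ceil(self.R / self.d))

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        c = (np.arange(self.n) + 0.5) * self.d - self.R
        return np.meshgrid(c, c, indexing="ij")  # (ix, iy)

    def mask(self) -> np.ndarray:
        """In-disk elements: centre strictly inside radius R."""
        cx, cy = self.centers()
        return cx**2 + cy**2 < self.R**2

    def cell_of(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Flat element index (ix * n + iy) of planar positions; -1 outside the grid."""
        ix = np.floor((np.asarray(x) + self.R) / self.d).astype(np.int64)
        iy = np.floor((np.asarray(y) + self.R) / self.d).astype(np.int64)
        ok = (ix >= 0) & (ix < self.n) & (iy >= 0) & (iy < self.n)
        return np.where(ok, ix * self.n + iy, -1)


@dataclass
class PotentialGrid:
    """Discretised cleft potential and per-element open-channel counts."""

    spec: GridSpec
    n_open: np.ndarray = dc_field(default=None)   # (n, n) int, zero outside disk
    v: np.ndarray = dc_field(default=None)        # (n, n) mV, zero outside disk

    def __post_init__(self) -> None:
        shape = (self.spec.n, self.spec.n)
        if self.n_open is None:
            self.n_open = np.zeros(shape, dtype=np.int64)
        if self.v is None:
            self.v = np.zeros(shape)
        self._mask = self.spec.mask()
        if np.any(self.n_open[~self._mask] != 0):
            raise ValueError("open channels recorded outside the cleft disk")
        if np.any(self.n_open < 0):
            raise ValueError("negative open-channel count")

    @property
    def mask(self) -> np.ndarray:
        return self._mask

    def populate(self, x: np.ndarray, y: np.ndarray) -> None:
        """Count one open channel per (x, y) position into the elements."""
        self.n_open[:] = 0
        flat = self.spec.cell_of(x, y)
        if np.any(flat < 0):
            raise ValueError("open channel outside the gridded region")
        np.add.at(self.n_open.reshape(-1), flat, 1)
        if np.any(self.n_open[~self._mask] != 0):
            raise ValueError("open channel outside the cleft disk")


def _laplacian(mask: np.ndarray, link_S: float) -> sp.csc_matrix:
    """K = link_S * (4 I - Adj) on in-disk elements, Dirichlet 0 outside (siemens)."""
    n = mask.shape[0]
    idx = -np.ones(mask.shape, dtype=np.int64)
    idx[mask] = np.arange(mask.sum())
    rows, cols, vals = [], [], []
    ii, jj = np.nonzero(mask)
    for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ni, nj = ii + di, jj + dj
        ok = (ni >= 0) & (ni < n) & (nj >= 0) & (nj < n)
        ok[ok] &= mask[ni[ok], nj[ok]]
        rows.append(idx[ii[ok], jj[ok]])
        cols.append(idx[ni[ok], nj[ok]])
        vals.append(np.full(ok.sum(), -link_S))
    rows.append(idx[ii, jj])
    cols.append(idx[ii, jj])
    vals.append(np.full(len(ii), 4.0 * link_S))
    m = mask.sum()
    return sp.csc_matrix((np.concatenate(vals),
                          (np.concatenate(rows), np.concatenate(cols))), shape=(m, m))


def _link_conductance(params) -> float:
    """H_c / Res in siemens (H_c nm -> m, Res Ohm cm -> Ohm m)."""
    return (params.H_c * 1e-9) / (params.Res * 1e-2)


def solve_potential(grid: PotentialGrid, params) -> PotentialGrid:
    """Direct sparse solve of the element current balance; fills ``grid.v`` (mV)."""
    mask = grid.mask
    K = _laplacian(mask, _link_conductance(params))
    c = grid.n_open[mask].astype(float) * params.g_unit * 1e-12  # S
    E = params.E_intra * 1e-3                                    # V
    A = K + sp.diags(c)
    b = c * E
    if not np.any(c):
        grid.v[:] = 0.0
        return grid
    v = spsolve(A.tocsc(), b)
    out = np.zeros(mask.shape)
    out[mask] = v * 1e3
    grid.v = out
    return grid


def gradients(grid: PotentialGrid) -> tuple[np.ndarray, np.ndarray]:
    """(dv/dx, dv/dy) per element in mV/nm.

    Centred differences in the interior; one-sided where a neighbour lies
    outside the disk; zero where both neighbours are outside.
    """
    d = grid.spec.d
    v = np.pad(grid.v, 1)
    mask = np.pad(grid.mask, 1)
    out = []
    for axis in (0, 1):
        vp = np.roll(v, -1, axis=axis)
        vm = np.roll(v, 1, axis=axis)
        mp = np.roll(mask, -1, axis=axis)
        mm = np.roll(mask, 1, axis=axis)
        g = np.where(mp & mm, (vp - vm) / (2 * d),
                     np.where(mp, (vp - v) / d,
                              np.where(mm, (v - vm) / d, 0.0)))
        g[~mask] = 0.0
        out.append(g[1:-1, 1:-1])
    return out[0], out[1]


def total_current(grid: PotentialGrid, params) -> tuple[float, float]:
    """Total synaptic current (pA) and conductance (pS) of the configuration.

    I = sum n_ij g_unit (E_intra - v_ij); with the field disabled (v = 0)
    this reduces to n_open * g_unit * E_intra.
    """
    n_tot = int(grid.n_open.sum())
    g_pS = n_tot * params.g_unit
    I_pA = float(np.sum(grid.n_open * params.g_unit * (params.E_intra - grid.v)) * 1e-3)
    return I_pA, g_pS


class CleftField:
    """Reduced solver for repeated open-configuration changes on a fixed geometry.

    For source elements S with per-element conductance C = n g_unit, the
    potential at the sources satisfies (I + W_SS C) v_S = W_SS C E with
    W_SS the Green's function block (ohms) of the Dirichlet Laplacian; the
    injected element currents are q_S = C (E - v_S) and the full-grid
    potential is one triangular solve K v = q.
    """

    def __init__(self, params, numerics) -> None:
        self.params = params
        self.spec = GridSpec(params.R, numerics.grid_d)
        self.mask = self.spec.mask()
        self._flat_of_reduced = np.flatnonzero(self.mask.reshape(-1))
        self._reduced_of_flat = -np.ones(self.spec.n * self.spec.n, dtype=np.int64)
        self._reduced_of_flat[self._flat_of_reduced] = np.arange(self.mask.sum())
        self.K = _laplacian(self.mask, _link_conductance(params))
        self.lu = splu(self.K)
        self._green_cols: dict[int, np.ndarray] = {}  # reduced idx -> K^-1 e (ohms)
        self._E = params.E_intra * 1e-3  # V
        self._g = params.g_unit * 1e-12  # S

    def reduced_index(self, flat_cells: np.ndarray) -> np.ndarray:
        red = self._reduced_of_flat[flat_cells]
        if np.any(red < 0):
            raise ValueError("receptor element outside the cleft disk")
        return red

    def _green(self, e: int) -> np.ndarray:
        col = self._green_cols.get(e)
        if col is None:
            rhs = np.zeros(self.K.shape[0])
            rhs[e] = 1.0
            col = self.lu.solve(rhs)
            self._green_cols[e] = col
        return col

    def green_block(self, elems: np.ndarray) -> np.ndarray:
        """W = U^T K^-1 U (ohms) for the given reduced element indices."""
        m = len(elems)
        W = np.empty((m, m))
        for j, e in enumerate(elems):
            W[:, j] = self._green(int(e))[elems]
        return W

    def solve_sources(self, W: np.ndarray, elems: np.ndarray,
                      counts: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
        """Potential (mV) at source elements and injected currents.

        Returns ``(v_mV, q_A, I_pA)`` for the active subset (counts > 0),
        aligned with ``elems``; entries with zero open channels get v from
        the same solve only implicitly (they are not sources).
        """
        act = counts > 0
        v_mV = np.zeros(len(elems))
        q_A = np.zeros(len(elems))
        if not np.any(act):
            return v_mV, q_A, 0.0
        C = counts[act] * self._g
        Wss = W[np.ix_(act, act)]
        rhs = Wss @ (C * self._E)
        M = np.eye(act.sum()) + Wss * C[None, :]
        v_act = np.linalg.solve(M, rhs)            # volts
        q_act = C * (self._E - v_act)              # amps
        v_mV[act] = v_act * 1e3
        q_A[act] = q_act
        return v_mV, q_A, float(q_act.sum() * 1e12)

    def full_potential(self, elems: np.ndarray, q_A: np.ndarray) -> np.ndarray:
        """Full-grid potential (mV, flat n*n array) from the injected currents."""
        rhs = np.zeros(self.K.shape[0])
        rhs[elems] = q_A
        v = self.lu.solve(rhs)
        out = np.zeros(self.spec.n * self.spec.n)
        out[self._flat_of_reduced] = v * 1e3
        return out

    def gradient_grids(self, v_flat_mV: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-element (dv/dx, dv/dy) in mV/nm as flat n*n arrays."""
        n = self.spec.n
        g = PotentialGrid(self.spec, v=v_flat_mV.reshape(n, n).copy())
        gx, gy = gradients(g)
        return gx.reshape(-1), gy.reshape(-1)
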