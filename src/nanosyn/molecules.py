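"""Glutamate molecule ensemble and reference Brownian-dynamics operations.

These are the readable single-repetition reference implementations of the
particle update rules; the engine runs an algebraically identical fused
kernel (see ``nanosyn._kernels``) over all repetitions at once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .field import GridSpec

__all__ = ["FREE", "BOUND", "ABSORBED", "MoleculeEnsemble", "init_release",
           "sample_unit_vectors", "step_positions", "apply_boundaries"]

FREE, BOUND, ABSORBED = 0, 1, 2


@dataclass
class MoleculeEnsemble:
    """Structure-of-arrays state of every released glutamate molecule (nm)."""

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    status: np.ndarray         # int8: FREE / BOUND / ABSORBED
    bound_to: np.ndarray       # int64 receptor id, -1 when unbound
    capture_count: np.ndarray  # int32, number of times ever bound

    def __len__(self) -> int:
        return len(self.x)

    @property
    def free(self) -> np.ndarray:
        return self.status == FREE

    def counts(self) -> tuple[int, int, int]:
        return (int(np.sum(self.status == FREE)), int(np.sum(self.status == BOUND)),
                int(np.sum(self.status == ABSORBED)))

    def validate(self, params) -> None:
        f = self.free
        if np.any(self.z[f] < 0) or np.any(self.z[f] > params.H_c):
            raise ValueError("free molecule outside the cleft height")
        if np.any(self.x[f] ** 2 + self.y[f] ** 2 >= params.R**2):
            raise ValueError("free molecule beyond the absorbing radius")
        if np.any((self.status == BOUND) & (self.bound_to < 0)):
            raise ValueError("bound molecule without a receptor id")
        if np.any(self.capture_count < 0):
            raise ValueError("negative capture count")


def sample_disk(n: int, radius: float, cx: float, cy: float,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Area-uniform points on a disk (two uniforms per point: radius then angle)."""
    r = radius * np.sqrt(rng.random(n))
    theta = 2.0 * np.pi * rng.random(n)
    return cx + r * np.cos(theta), cy + r * np.sin(theta)


def init_release(params, numerics, rng: np.random.Generator) -> MoleculeEnsemble:
    """Quantal release: nnt molecules at z = 0, area-uniform on the vesicle disk.

    The disk is centred ``release_offset`` nm from the synapse centre along x.
    """
    n = params.nnt
    x, y = sample_disk(n, params.r_ves, params.release_offset, 0.0, rng)
    return MoleculeEnsemble(
        x=x, y=y, z=np.zeros(n),
        status=np.zeros(n, dtype=np.int8),
        bound_to=np.full(n, -1, dtype=np.int64),
        capture_count=np.zeros(n, dtype=np.int32),
    )


def sample_unit_vectors(n: int, rng: np.random.Generator) -> np.ndarray:
    """Isotropic unit vectors from two uniforms: theta = 2 pi a, phi = arccos(1 - 2b)."""
    a = rng.random(n)
    b = rng.random(n)
    theta = 2.0 * np.pi * a
    phi = np.arccos(1.0 - 2.0 * b)
    sphi = np.sin(phi)
    return np.column_stack((sphi * np.cos(theta), sphi * np.sin(theta), np.cos(phi)))


def drift_coefficient_nm(params, numerics) -> float:
    """Displacement (nm) per unit potential gradient (mV/nm) per time step.

    dt * D * F / (Rg T) with D in m^2/s and the gradient converted from
    mV/nm to V/m.
    """
    D_SI = params.D * 1e-9  # um^2/ms -> m^2/s
    mob = D_SI * params.F / (params.Rg * params.T)  # m^2 / (V s)
    return numerics.dt_s * mob * 1e6 * 1e9  # (mV/nm -> V/m) and m -> nm


def step_positions(ens: MoleculeEnsemble, params, numerics,
                   gradient_grids: tuple[np.ndarray, np.ndarray, GridSpec] | None,
                   rng: np.random.Generator) -> MoleculeEnsemble:
    """One Brownian + drift step for every free molecule (no boundary handling).

    Each free molecule moves sqrt(6 D dt) along a fresh isotropic unit vector
    whose lateral components are scaled by (1 - ani) inside the nanocolumn
    zone, plus the lateral electrophoretic drift dt * (1-ani) * grad(v) *
    D F / (Rg T) evaluated at the molecule's field element.
    """
    f = np.flatnonzero(ens.free)
    if len(f) == 0:
        return ens
    u = sample_unit_vectors(len(f), rng)
    dr = numerics.step_length_nm(params.D)
    inside = ens.x[f] ** 2 + ens.y[f] ** 2 < (params.D_ani / 2.0) ** 2
    s = np.where(inside, 1.0 - params.ani, 1.0)
    dx = dr * u[:, 0] * s
    dy = dr * u[:, 1] * s
    dz = dr * u[:, 2]
    if gradient_grids is not None:
        gx, gy, spec = gradient_grids
        gx = np.asarray(gx).reshape(-1)
        gy = np.asarray(gy).reshape(-1)
        if gx.shape != (spec.n * spec.n,) or gy.shape != gx.shape:
            raise ValueError("gradient array shape does not match the field grid")
        cells = spec.cell_of(ens.x[f], ens.y[f])
        ok = cells >= 0
        coef = drift_coefficient_nm(params, numerics)
        dx[ok] += coef * s[ok] * gx[cells[ok]]
        dy[ok] += coef * s[ok] * gy[cells[ok]]
    ens.x[f] += dx
    ens.y[f] += dy
    ens.z[f] += dz
    return ens


def apply_boundaries(ens: MoleculeEnsemble, params) -> int:
    """Reflect at both membranes, absorb at the lateral rim; returns newly absorbed count.

    z < 0 -> |z|; z > H_c -> 2 H_c - z; x^2 + y^2 >= R^2 -> absorbed.
    """
    f = ens.free
    z = ens.z
    neg = f & (z < 0)
    z[neg] = -z[neg]
    over = f & (z > params.H_c)
    z[over] = 2.0 * params.H_c - z[over]
    still_out = f & ((z < 0) | (z > params.H_c))
    if np.any(still_out):
        raise RuntimeError("reflected position still outside the cleft; the step "
                           "length exceeds the cleft height - reduce the time step")
    absorbed = f & (ens.x**2 + ens.y**2 >= params.R**2)
    ens.status[absorbed] = ABSORBED
    return int(absorbed.sum())
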