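"""Model parameters, numerics configuration and closed-form helpers.

All geometric quantities are in nanometres, times in the units stated on each
field (the mixed nm / ns / ms / pS / mV unit system of the synaptic-cleft
literature).  Internally the engine converts to SI where electrostatics is
involved.
"""

from __future__ import annotations

import dataclasses
import math
import tomllib
from dataclasses import dataclass, field
from pathlib import Path

from scipy.optimize import brentq

__all__ = [
    "SimulationParameters",
    "NumericsConfig",
    "vesicle_content",
    "diffusion_reduction_from_filling",
    "filling_from_reduction",
    "displacement_to_diffusion_reduction",
]

#: Avogadro number, 1/mol
N_AVOGADRO = 6.022e23
#: Faraday constant, C/mol
FARADAY = 96485.0
#: Gas constant, J/(mol K)
GAS_CONSTANT = 8.3144


@dataclass
class SimulationParameters:
    """Physical and geometric parameters of the synapse model.

    Defaults are the reference values of the model: a cylindrical cleft of
    radius ``R`` and height ``H_c``, a vesicle of radius ``r_ves`` releasing
    ``nnt`` glutamate molecules at the presynaptic face, ``n_c`` receptors
    clustered in the nanocolumn plus ``n_r`` receptors spread uniformly over
    the postsynaptic density, and an anisotropy coefficient ``ani`` that
    reduces lateral glutamate displacement inside the nanocolumn zone of
    diameter ``D_ani``.
    """

    R: float = 1000.0          #: cleft (synaptic space) radius, nm
    H_c: float = 20.0          #: cleft height, nm
    r_ves: float = 20.0        #: vesicle radius, nm
    nnt: int = 1000            #: number of released glutamate molecules
    ani: float = 0.0           #: anisotropy coefficient in [0, 1)
    n_r: int = 40              #: receptors outside the nanocolumn (uniform in the PSD)
    n_c: int = 40              #: receptors inside the nanocolumn
    D_dr: float = 400.0        #: PSD diameter, nm
    R_std: float = 50.0        #: radial scale of the nanocolumn receptor distribution, nm
    D_ani: float = 100.0       #: diameter of the anisotropic (nanocolumn) zone, nm
    D: float = 0.3             #: glutamate diffusion coefficient, um^2/ms
    D_r: float = 0.1           #: receptor lateral diffusion coefficient, um^2/s
    g_unit: float = 25.0       #: unitary channel conductance, pS
    E_intra: float = 65.0      #: intracellular potential magnitude, mV
    E_syn: float = 0.0         #: synaptic reversal potential, mV
    Res: float = 200.0         #: resistivity of the extracellular medium, Ohm cm
    N_A: float = N_AVOGADRO    #: Avogadro number, 1/mol
    F: float = FARADAY         #: Faraday constant, C/mol
    Rg: float = GAS_CONSTANT   #: gas constant, J/(mol K)
    T: float = 300.0           #: absolute temperature, K
    affinity_scale: float = 1.0  #: multiplier applied to the K1 and K2 binding rates
    release_offset: float = 0.0  #: distance of the release-site centre from the synapse centre, nm

    def __post_init__(self) -> None:
        for name in ("R", "H_c", "r_ves", "D_dr", "R_std", "D_ani", "D", "g_unit", "Res", "T"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got {getattr(self, name)}")
        if not 0.0 <= self.ani < 1.0:
            raise ValueError(f"ani must lie in [0, 1), got {self.ani}")
        if self.nnt < 0 or self.n_r < 0 or self.n_c < 0:
            raise ValueError("nnt, n_r and n_c must be non-negative")
        if self.r_ves > self.R:
            raise ValueError("vesicle radius exceeds the cleft radius")
        if self.D_ani > 2 * self.R:
            raise ValueError("nanocolumn diameter exceeds the cleft diameter")
        if self.release_offset < 0 or self.release_offset + self.r_ves > self.R:
            raise ValueError("release site (offset + vesicle radius) must fit inside the cleft")
        if self.affinity_scale <= 0:
            raise ValueError("affinity_scale must be positive")
        if self.D_r < 0:
            raise ValueError("D_r must be non-negative")

    def replace(self, **kw) -> "SimulationParameters":
        return dataclasses.replace(self, **kw)


@dataclass
class NumericsConfig:
    """Discretisation and Monte Carlo settings."""

    dt_ns: float = 50.0          #: time step, ns
    duration_ms: float = 3.0     #: simulated time per release, ms
    n_reps: int | None = None    #: repetitions; None -> round(1e6/nnt) clipped to [20, 1000]
    b_rad: float = 5.0           #: binding (capture) radius, nm
    grid_d: float = 20.0         #: field element size, nm
    receptor_grid_h: float = 10.0  #: lateral-diffusion grid spacing, nm
    seed: int = 0                #: root RNG seed

    def __post_init__(self) -> None:
        if self.dt_ns <= 0:
            raise ValueError("dt must be positive")
        if self.duration_ms <= 0:
            raise ValueError("duration must be positive")
        if self.n_reps is not None and self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if self.b_rad <= 0 or self.grid_d <= 0 or self.receptor_grid_h <= 0:
            raise ValueError("b_rad, grid_d and receptor_grid_h must be positive")

    def replace(self, **kw) -> "NumericsConfig":
        return dataclasses.replace(self, **kw)

    @property
    def dt_ms(self) -> float:
        return self.dt_ns * 1e-6

    @property
    def dt_s(self) -> float:
        return self.dt_ns * 1e-9

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_ms / self.dt_ms))

    def step_length_nm(self, D_um2_per_ms: float) -> float:
        """Brownian step length sqrt(6 D dt) in nm (D in um^2/ms)."""
        d_nm2_per_ms = D_um2_per_ms * 1e6
        return math.sqrt(6.0 * d_nm2_per_ms * self.dt_ms)

    def default_reps(self, nnt: int) -> int:
        """Repetition count used when ``n_reps`` is None: round(1e6/nnt), clipped."""
        if self.n_reps is not None:
            return self.n_reps
        if nnt <= 0:
            return 20
        return int(min(1000, max(20, round(1_000_000 / nnt))))


# ---------------------------------------------------------------------------
# closed-form helpers
# ---------------------------------------------------------------------------

def vesicle_content(r_ves_nm: float, conc_mM: float) -> tuple[float, int]:
    """Volume (m^3) of a spherical vesicle and its neurotransmitter content.

    A 20 nm vesicle has a volume of ~3.35e-23 m^3; at 50 mM this holds about
    one thousand molecules.
    """
    if r_ves_nm <= 0 or conc_mM <= 0:
        raise ValueError("vesicle radius and concentration must be positive")
    r_m = r_ves_nm * 1e-9
    volume_m3 = 4.0 / 3.0 * math.pi * r_m**3
    volume_L = volume_m3 * 1e3
    n = volume_L * (conc_mM * 1e-3) * N_AVOGADRO
    return volume_m3, int(round(n))


_PI4 = math.pi / 4.0
_LARGE_NORM = math.pi**1.5 * (1.0 - _PI4)


def _small_branch(sigma: float) -> float:
    return 1.0 - sigma


def _large_branch(sigma: float) -> float:
    if not 0.0 <= sigma < _PI4:
        raise ValueError(f"filling fraction must lie in [0, pi/4) for this branch, got {sigma}")
    return 2.0 * math.sqrt(_PI4 - sigma) / _LARGE_NORM


def _branch_crossover() -> float:
    # sigma where the two branches intersect; cached at import time
    return brentq(lambda s: _large_branch(s) - _small_branch(s), 0.5, _PI4 - 1e-12, xtol=1e-12)


_SIGMA_CROSS = _branch_crossover()


def diffusion_reduction_from_filling(sigma: float) -> float:
    """Effective lateral diffusion reduction factor for obstacle filling fraction sigma.

    For dilute obstacles the factor is 1 - sigma; for dense packing it is
    2 sqrt(pi/4 - sigma) / (pi^1.5 (1 - pi/4)).  The branch is selected at the
    crossover filling fraction (~0.765) where the two expressions meet, so the
    returned factor is continuous in sigma.
    """
    if not 0.0 <= sigma < _PI4:
        raise ValueError(f"filling fraction must lie in [0, pi/4), got {sigma}")
    if sigma <= _SIGMA_CROSS:
        return _small_branch(sigma)
    return _large_branch(sigma)


def filling_from_reduction(factor: float, tol: float = 1e-6) -> float:
    """Invert the dense-packing branch: the sigma producing a given reduction factor.

    Only the dense branch is inverted (it spans factors (0, ~1.48]); e.g. a
    10x reduction in effective lateral diffusion (factor 0.1) corresponds to
    sigma ~ 0.78.
    """
    fmax = _large_branch(0.0)
    if not 0.0 < factor <= fmax:
        raise ValueError(f"factor must lie in (0, {fmax:.4f}] for the dense branch, got {factor}")
    return brentq(lambda s: _large_branch(s) - factor, 0.0, _PI4 - 1e-15, xtol=tol)


def displacement_to_diffusion_reduction(ani: float) -> float:
    """Convert the displacement-scaling convention to a diffusion-coefficient scaling.

    The position update scales each lateral displacement component by
    (1 - ani), which multiplies the lateral diffusion *coefficient* by
    (1 - ani)^2.  This helper returns that coefficient factor.
    """
    if not 0.0 <= ani <= 1.0:
        raise ValueError("ani must lie in [0, 1]")
    return (1.0 - ani) ** 2


# ---------------------------------------------------------------------------
# flat TOML-style config I/O
# ---------------------------------------------------------------------------

def _format_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, float):
        return repr(v)
    return str(v)


def save_config(path: str | Path, params: SimulationParameters,
                numerics: NumericsConfig | None = None) -> None:
    """Write a flat key/value TOML config mirroring the parameter symbol names."""
    lines = ["[params]"]
    for f in dataclasses.fields(params):
        lines.append(f"{f.name} = {_format_value(getattr(params, f.name))}")
    if numerics is not None:
        lines.append("")
        lines.append("[numerics]")
        for f in dataclasses.fields(numerics):
            v = getattr(numerics, f.name)
            if v is None:
                continue
            lines.append(f"{f.name} = {_format_value(v)}")
    Path(path).write_text("\n".join(lines) + "\n")


def load_config(path: str | Path) -> tuple[SimulationParameters, NumericsConfig]:
    """Read a config written by :func:`save_config` (missing keys use defaults)."""
    with open(path, "rb") as fh:
        raw = tomllib.load(fh)
    params = SimulationParameters(**raw.get("params", {}))
    numerics = NumericsConfig(**raw.get("numerics", {}))
    return params, numerics
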