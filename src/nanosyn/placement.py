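"""Receptor placement on the postsynaptic plane.

Nanocolumn receptors are drawn with radial distance -R_std ln(1-u) from the
synapse centre (angle uniform); receptors outside the nanocolumn are placed
area-uniformly over the PSD disk.  A hard-core exclusion keeps receptor
centres at least 10 nm apart (the physical receptor footprint).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["ReceptorLayout", "place_receptors", "sample_nanocolumn_radii", "MIN_RECEPTOR_DISTANCE"]

#: minimum centre-to-centre distance between receptors, nm
MIN_RECEPTOR_DISTANCE = 10.0

#: redraw rounds per receptor before the packing is declared infeasible
MAX_REDRAWS = 10_000


@dataclass
class ReceptorLayout:
    """Planar receptor positions (nm) at z = H_c with group labels."""

    x: np.ndarray
    y: np.ndarray
    group: np.ndarray  # "nanocolumn" | "random"

    def __len__(self) -> int:
        return len(self.x)

    def validate(self, R: float, D_dr: float) -> None:
        r2 = self.x**2 + self.y**2
        if np.any(r2 > R**2):
            raise ValueError("receptor outside the cleft radius")
        rnd = self.group == "random"
        if np.any(r2[rnd] > (D_dr / 2.0) ** 2 * (1 + 1e-12)):
            raise ValueError("randomly distributed receptor outside the PSD disk")
        if len(self) > 1:
            d2 = (self.x[:, None] - self.x[None, :]) ** 2 + (self.y[:, None] - self.y[None, :]) ** 2
            np.fill_diagonal(d2, np.inf)
            if d2.min() < (MIN_RECEPTOR_DISTANCE * (1 - 1e-12)) ** 2:
                raise ValueError("receptor pair closer than the 10 nm exclusion distance")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({"id": np.arange(len(self)), "x_nm": self.x,
                             "y_nm": self.y, "group": self.group})

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ReceptorLayout":
        df = pd.read_csv(path)
        return cls(df["x_nm"].to_numpy(float), df["y_nm"].to_numpy(float),
                   df["group"].to_numpy(str))


def sample_nanocolumn_radii(n: int, R_std: float, rng: np.random.Generator) -> np.ndarray:
    """Radial distances of nanocolumn receptors: -R_std ln(1 - u), u ~ U[0, 1)."""
    return -R_std * np.log1p(-rng.random(n))


def _too_close(x: float, y: float, xs: list[float], ys: list[float]) -> bool:
    lim2 = MIN_RECEPTOR_DISTANCE**2
    for xi, yi in zip(xs, ys):
        if (x - xi) ** 2 + (y - yi) ** 2 < lim2:
            return True
    return False


def place_receptors(params, rng: np.random.Generator | int) -> ReceptorLayout:
    """Draw a receptor layout for the given parameters.

    Nanocolumn receptors are placed first (redrawn until inside the cleft
    radius), then the uniformly distributed PSD receptors; every accepted
    position is rejected and redrawn while it violates the 10 nm exclusion
    against all previously accepted receptors.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    xs: list[float] = []
    ys: list[float] = []
    groups: list[str] = []

    for _ in range(params.n_c):
        for attempt in range(MAX_REDRAWS):
            r = -params.R_std * np.log1p(-rng.random())
            theta = rng.random() * 2.0 * np.pi
            x, y = r * np.cos(theta), r * np.sin(theta)
            if r > params.R:
                continue
            if not _too_close(x, y, xs, ys):
                xs.append(x); ys.append(y); groups.append("nanocolumn")
                break
        else:
            raise RuntimeError(
                f"could not place nanocolumn receptor {len(xs)} after {MAX_REDRAWS} redraws; "
                "packing infeasible for n_c with the 10 nm exclusion")

    psd_r = params.D_dr / 2.0
    for _ in range(params.n_r):
        for attempt in range(MAX_REDRAWS):
            r = psd_r * np.sqrt(rng.random())
            theta = rng.random() * 2.0 * np.pi
            x, y = r * np.cos(theta), r * np.sin(theta)
            if not _too_close(x, y, xs, ys):
                xs.append(x); ys.append(y); groups.append("random")
                break
        else:
            raise RuntimeError(
                f"could not place PSD receptor {len(xs)} after {MAX_REDRAWS} redraws; "
                "packing infeasible for n_r with the 10 nm exclusion")

    layout = ReceptorLayout(np.asarray(xs, float), np.asarray(ys, float),
                            np.asarray(groups, dtype=object))
    layout.validate(params.R, params.D_dr)
    return layout
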