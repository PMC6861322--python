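"""The ocean layer: discrete kernel diffusion, gas exchange, light, uptake.

Concentration fields live on a 2-D grid of square gridcells (edge ``delta``,
row 0 at the sea surface).  Per metabolite, diffusion follows a discrete
Gaussian-kernel exchange with its neighborhood,

    df(x_i) = A * sum_j (f(x_j) - f(x_i)) * exp(-d_j^2 / eta),

with ``A`` normalizing the kernel over the closed neighborhood (self term
included) so every pairwise transfer is a convex mixing step: mass is
conserved exactly and concentrations stay nonnegative.  ``eta = 4 * D * dt``;
``eta -> 0`` halts diffusion, ``eta -> inf`` relaxes each neighborhood toward
its local mean.  Updates are applied sequentially in place, in two sweeps
(forward then reversed cell order) to mitigate order dependence; each sweep
advances half the time step.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .units import hours_to_seconds

__all__ = [
    "OceanGrid",
    "SurfaceBoundary",
    "compute_eta",
    "diffusion_step",
    "surface_exchange",
    "light_at_depth",
    "partition_uptake",
]


def compute_eta(D: float, dt: float) -> float:
    """Kernel diffusivity control ``eta = 4 * D * dt`` (length^2 units)."""
    if D < 0:
        raise ValueError("diffusivity must be nonnegative")
    if dt <= 0:
        raise ValueError("time step must be positive")
    return 4.0 * D * dt


@njit(cache=True)
def _sweep(f, offsets, weights, reverse):  # pragma: no cover - compiled
    h, w = f.shape
    ncell = h * w
    noff = offsets.shape[0]
    for step in range(ncell):
        k = ncell - 1 - step if reverse else step
        i = k // w
        j = k % w
        norm = 1.0  # self term, exp(0) = 1
        for t in range(noff):
            ni = i + offsets[t, 0]
            nj = j + offsets[t, 1]
            if 0 <= ni < h and 0 <= nj < w:
                norm += weights[t]
        A = 1.0 / norm
        fc = f[i, j]
        acc = 0.0
        for t in range(noff):
            ni = i + offsets[t, 0]
            nj = j + offsets[t, 1]
            if 0 <= ni < h and 0 <= nj < w:
                tr = A * weights[t] * (f[ni, nj] - fc)
                f[ni, nj] -= tr
                acc += tr
        f[i, j] = fc + acc


_MOORE = np.array(
    [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)],
    dtype=np.int64,
)
_VON_NEUMANN = np.array([(-1, 0), (0, -1), (0, 1), (1, 0)], dtype=np.int64)


@dataclass
class SurfaceBoundary:
    """Atmospheric boundary: per-gas partial pressure and Henry constant."""

    partial_pressures_atm: dict[str, float] = field(default_factory=dict)
    henry_uM_atm: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (
            ("partial pressure", self.partial_pressures_atm),
            ("Henry constant", self.henry_uM_atm),
        ):
            for gas, val in table.items():
                if val < 0:
                    raise ValueError(f"{name} for {gas!r} must be nonnegative")

    def equilibrium_uM(self, gas: str) -> float:
        """Henry's-law dissolved equilibrium concentration ``K_H * p``."""
        if gas not in self.henry_uM_atm:
            raise KeyError(f"no Henry constant configured for gas {gas!r}")
        return self.henry_uM_atm[gas] * self.partial_pressures_atm.get(gas, 0.0)


@dataclass
class OceanGrid:
    """2-D concentration fields with per-metabolite diffusivities.

    ``fields[met]`` is a (height, width) array in uM; row 0 is the surface.
    ``diffusivities`` are in um^2/s, ``delta_um`` the gridcell edge in um and
    ``dt_h`` the time step in hours.
    """

    width: int
    height: int
    delta_um: float = 100.0
    dt_h: float = 0.1
    fields: dict[str, np.ndarray] = field(default_factory=dict)
    diffusivities: dict[str, float] = field(default_factory=dict)
    neighborhood: str = "moore"  # or "von_neumann"

    def __post_init__(self) -> None:
        if self.width < 1 or self.height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if self.delta_um <= 0 or self.dt_h <= 0:
            raise ValueError("gridcell edge and time step must be positive")
        for met, arr in list(self.fields.items()):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (self.height, self.width):
                raise ValueError(
                    f"field {met!r} has shape {arr.shape}, expected "
                    f"{(self.height, self.width)}"
                )
            if np.any(arr < 0):
                raise ValueError(f"field {met!r} has negative concentrations")
            self.fields[met] = arr

    def add_field(self, met: str, value: float | np.ndarray = 0.0,
                  diffusivity: float | None = None) -> None:
        arr = np.full((self.height, self.width), float(value)) \
            if np.isscalar(value) else np.asarray(value, dtype=float).copy()
        if arr.shape != (self.height, self.width):
            raise ValueError("field shape mismatch")
        if np.any(arr < 0):
            raise ValueError(f"field {met!r} has negative concentrations")
        self.fields[met] = arr
        if diffusivity is not None:
            self.diffusivities[met] = diffusivity

    def eta(self, met: str, dt_h: float | None = None) -> float:
        """``4 * D * dt`` in um^2, with the time step converted to seconds."""
        dt = self.dt_h if dt_h is None else dt_h
        return compute_eta(self.diffusivities.get(met, 0.0), hours_to_seconds(dt))

    def total_mass(self, met: str) -> float:
        return float(self.fields[met].sum())

    def offsets(self) -> np.ndarray:
        return _MOORE if self.neighborhood == "moore" else _VON_NEUMANN

    def depth_m(self, row: int) -> float:
        """Depth of a gridcell centre below the surface, in metres."""
        return (row + 0.5) * self.delta_um * 1e-6


def diffusion_step(grid: OceanGrid, metabolite: str,
                   dt_h: float | None = None) -> OceanGrid:
    """Advance one diffusion step for ``metabolite`` (two in-place sweeps).

    Each sweep uses ``eta`` computed from half the step so the pair advances
    one full ``dt``.  Mass is conserved exactly; a 1x1 grid (or ``eta = 0``)
    is the identity.
    """
    dt = grid.dt_h if dt_h is None else dt_h
    eta = grid.eta(metabolite, dt_h=dt / 2.0)
    f = grid.fields[metabolite]
    if eta == 0.0 or f.size == 1:
        return grid
    offsets = grid.offsets()
    d2 = (offsets[:, 0] ** 2 + offsets[:, 1] ** 2) * grid.delta_um**2
    weights = np.exp(-d2 / eta)
    _sweep(f, offsets, weights, False)
    _sweep(f, offsets, weights, True)
    return grid


def surface_exchange(grid: OceanGrid, boundary: SurfaceBoundary,
                     gases: list[str] | None = None,
                     dt_h: float | None = None) -> OceanGrid:
    """Relax the surface row toward Henry's-law equilibrium for each gas.

    The atmosphere is treated as a fixed-concentration slab one gridcell
    above the surface row, exchanged with the same Gaussian kernel as bulk
    diffusion; the relaxation factor ``w / (1 + w)`` is at most 1/2 so the
    row approaches ``K_H * p`` monotonically and never overshoots.
    """
    dt = grid.dt_h if dt_h is None else dt_h
    if gases is None:
        gases = [g for g in boundary.partial_pressures_atm if g in grid.fields]
    for gas in gases:
        c_eq = boundary.equilibrium_uM(gas)
        eta = grid.eta(gas, dt_h=dt)
        if eta == 0.0:
            continue
        w = np.exp(-grid.delta_um**2 / eta)
        lam = w / (1.0 + w)
        top = grid.fields[gas][0, :]
        top += lam * (c_eq - top)
    return grid


def light_at_depth(I0: float, k: float, y: float) -> float:
    """Beer-Lambert attenuation ``I = I0 * exp(-k * y)`` (y in metres)."""
    if y < 0:
        raise ValueError("depth must be nonnegative")
    return I0 * np.exp(-k * y)


def partition_uptake(available: float, requests: list[float],
                     tol: float = 1e-12) -> list[float]:
    """Divide a gridcell's available amount equally among competing cells.

    Each cell receives at most its demand; any share unclaimed by satisfied
    cells is re-divided among the still-unsatisfied ones until a fixed point
    (progressive water-filling).  The total allocated never exceeds
    ``available``.
    """
    if available < 0:
        raise ValueError("available amount must be nonnegative")
    n = len(requests)
    alloc = [0.0] * n
    if n == 0 or available == 0.0:
        return alloc
    remaining = float(available)
    unsatisfied = [i for i in range(n) if requests[i] > tol]
    while remaining > tol and unsatisfied:
        share = remaining / len(unsatisfied)
        progressed = False
        for i in list(unsatisfied):
            need = requests[i] - alloc[i]
            take = min(need, share)
            if take > 0:
                alloc[i] += take
                remaining -= take
                progressed = True
        unsatisfied = [i for i in unsatisfied if requests[i] - alloc[i] > tol]
        if not progressed:
            break
    return alloc
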