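"""Metabolite fields on the gut lattice.

The colon is a 225 x 8 lattice of 2 mm sites (0.05 mL each, 90 mL total at
defaults), proximal at column 0.  Metabolite amounts are stored as dense
(height, width) arrays per metabolite, in umol per site.  Water is symbolic:
always present, never depleted, never recorded.

Per timestep the environment is fed (a lactose pulse every 3 h into the six
proximal columns), diffused (forward-Euler 5-point Laplacian, no-flux walls),
and advected one column distally; everything leaving the distal face is
collected as the outflow ("fecal") record.  Oxygen diffuses but does not
advect.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

WATER = "h2o"


@dataclass(frozen=True)
class LatticeGeometry:
    width: int = 225
    height: int = 8
    dx_mm: float = 2.0
    site_volume_ml: float = 0.05
    timestep_s: float = 180.0

    @property
    def n_sites(self) -> int:
        return self.width * self.height

    @property
    def scale(self) -> float:
        """Scaling factor n of the site side length relative to the default."""
        return self.dx_mm / 2.0

    @property
    def dx_cm(self) -> float:
        return self.dx_mm / 10.0

    @property
    def total_volume_ml(self) -> float:
        return self.n_sites * self.site_volume_ml


@dataclass
class FeedingSchedule:
    """Nutrient pulse: `total` umol split over the first `n_columns` columns."""
    metabolite: str = "lcts"
    total: float = 211.0          # umol per pulse (lactose, per 3 h)
    period: int = 60              # timesteps between pulses
    n_columns: int = 6


@dataclass
class OxygenRegime:
    """One oxygen scenario per run.

    mode "none": no oxygen; "initial_uniform": `amount` umol placed in every
    site at t = 0; "boundary_release": `amount` umol per step in total, split
    over top and bottom rows, until `stop_step` (None = never stops).
    """
    mode: str = "none"
    amount: float = 0.0
    stop_step: int | None = None

    def __post_init__(self):
        if self.mode not in ("none", "initial_uniform", "boundary_release"):
            raise ValueError(f"unknown oxygen mode {self.mode!r}")


@dataclass
class OutflowRecord:
    timestep: int
    amounts: dict[str, float]     # umol removed at the distal column


class MetaboliteField:
    """Per-site metabolite amounts (umol) over the lattice."""

    def __init__(self, geometry: LatticeGeometry,
                 non_advecting: tuple[str, ...] = ("o2",)):
        self.geometry = geometry
        self.non_advecting = set(non_advecting)
        self._data: dict[str, np.ndarray] = {}

    def __contains__(self, met: str) -> bool:
        return met in self._data

    @property
    def metabolites(self) -> list[str]:
        return list(self._data)

    def array(self, met: str) -> np.ndarray:
        g = self.geometry
        if met not in self._data:
            self._data[met] = np.zeros((g.height, g.width))
        return self._data[met]

    def add(self, met: str, y: int, x: int, amount: float) -> None:
        if met == WATER:
            return
        self.array(met)[y, x] += amount

    def amounts_at(self, y: int, x: int, floor: float = 0.0) -> dict[str, float]:
        """Non-water amounts at one site, skipping entries <= floor."""
        out = {}
        for met, arr in self._data.items():
            v = arr[y, x]
            if v > floor:
                out[met] = v
        return out

    def total(self, met: str) -> float:
        arr = self._data.get(met)
        return float(arr.sum()) if arr is not None else 0.0

    def totals(self) -> dict[str, float]:
        return {met: float(arr.sum()) for met, arr in self._data.items()}

    def prune(self, tol: float = 0.0) -> None:
        """Drop all-zero arrays; clip tiny negatives from float round-off."""
        for met in list(self._data):
            arr = self._data[met]
            np.clip(arr, 0.0, None, out=arr)
            if tol >= 0 and not arr.any():
                del self._data[met]


def feed(field: MetaboliteField, schedule: FeedingSchedule, t: int) -> float:
    """Apply the feeding pulse if due; returns the amount added (umol)."""
    if t < 0:
        raise ValueError("negative timestep")
    if t % schedule.period != 0:
        return 0.0
    g = field.geometry
    ncol = min(schedule.n_columns, g.width)
    per_site = schedule.total / (ncol * g.height)
    field.array(schedule.metabolite)[:, :ncol] += per_site
    return schedule.total


def diffusion_coefficient(D_cm2_s: float, geometry: LatticeGeometry) -> float:
    """Dimensionless forward-Euler transfer fraction D*dt/dx^2 per neighbor."""
    return D_cm2_s * geometry.timestep_s / geometry.dx_cm**2


def diffuse(field: MetaboliteField, D_cm2_s: float = 4.4e-5) -> None:
    """One forward-Euler step of the 5-point Laplacian with no-flux walls."""
    g = field.geometry
    k = diffusion_coefficient(D_cm2_s, g)
    if 4.0 * k >= 1.0:
        raise ValueError(
            f"unstable diffusion step: 4*D*dt/dx^2 = {4 * k:.3f} >= 1")
    for met, arr in field._data.items():
        p = np.pad(arr, 1, mode="edge")   # reflecting (no-flux) boundaries
        lap = (p[:-2, 1:-1] + p[2:, 1:-1] + p[1:-1, :-2] + p[1:-1, 2:]
               - 4.0 * arr)
        arr += k * lap


def advect(field: MetaboliteField, t: int = 0) -> OutflowRecord:
    """Shift advecting metabolites one column distally; collect the outflow."""
    removed: dict[str, float] = {}
    for met, arr in field._data.items():
        if met in field.non_advecting:
            continue
        out = float(arr[:, -1].sum())
        if out > 0:
            removed[met] = out
        arr[:, 1:] = arr[:, :-1]
        arr[:, 0] = 0.0
    return OutflowRecord(timestep=t, amounts=removed)


def apply_oxygen(field: MetaboliteField, regime: OxygenRegime, t: int) -> float:
    """Apply the oxygen source for step t; returns umol added."""
    if regime.mode == "none" or regime.amount <= 0:
        return 0.0
    g = field.geometry
    if regime.mode == "initial_uniform":
        if t != 0:
            return 0.0
        field.array("o2")[:, :] += regime.amount
        return regime.amount * g.n_sites
    # boundary_release
    if regime.stop_step is not None and t >= regime.stop_step:
        return 0.0
    per_site = regime.amount / (2 * g.width)
    arr = field.array("o2")
    arr[0, :] += per_site
    arr[-1, :] += per_site
    return regime.amount
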