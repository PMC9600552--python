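"""Bacterial layer: growth, division, death, colonization, and mixing.

Populations are continuous-sized (number of bacteria), one per lattice site.
Growth follows the FBA solution (1e9 bacteria per umol ATP by default);
populations at or above 1e10 bacteria split in half into an empty
von-Neumann-adjacent site; populations above 2e10 (possible only when boxed
in) cease metabolism until space frees.  Mixing is a Kawasaki-style sweep:
in random order every site swaps its population (not its metabolites) with a
uniformly chosen site among itself and its first- and second-order
neighbors, each site swapping at most once per sweep.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fba import POPULATION_UNIT

EMPTY = -1

#: self + 4 adjacent + 4 diagonal neighbors; calibrated against the target
#: population diffusion constant of 5.7e-5 cm^2/s (see docs/methods.md)
MOORE8_SELF = ((0, 0), (0, 1), (0, -1), (1, 0), (-1, 0),
               (1, 1), (1, -1), (-1, 1), (-1, -1))

VON_NEUMANN = ((0, 1), (0, -1), (1, 0), (-1, 0))


@dataclass
class StochasticConfig:
    death_prob: float = 0.0075          # per population per timestep
    colonize_prob: float = 0.00005      # per empty site per timestep
    init_site_prob: float = 0.3
    initial_size: float = 5e7           # bacteria
    division_size: float = 1e10
    max_size: float = 2e10
    growth_yield: float = 1e9           # bacteria per umol ATP
    colonize_first_column_only: bool = False

    def __post_init__(self):
        for p in (self.death_prob, self.colonize_prob, self.init_site_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")


class BacterialLattice:
    """Species index (-1 = empty) and population size per site."""

    def __init__(self, height: int, width: int):
        self.height = height
        self.width = width
        self.species = np.full((height, width), EMPTY, dtype=np.int64)
        self.size = np.zeros((height, width))

    @property
    def occupied(self) -> np.ndarray:
        return self.species != EMPTY

    def total_biomass(self) -> float:
        return float(self.size[self.occupied].sum())

    def abundances(self, n_species: int) -> np.ndarray:
        """Total biomass per species index."""
        out = np.zeros(n_species)
        mask = self.occupied
        np.add.at(out, self.species[mask], self.size[mask])
        return out

    def counts(self, n_species: int) -> np.ndarray:
        out = np.zeros(n_species, dtype=np.int64)
        mask = self.occupied
        np.add.at(out, self.species[mask], 1)
        return out

    def place(self, y: int, x: int, species: int, size: float) -> None:
        self.species[y, x] = species
        self.size[y, x] = size

    def remove(self, y: int, x: int) -> None:
        self.species[y, x] = EMPTY
        self.size[y, x] = 0.0


def initialize(lattice: BacterialLattice, cfg: StochasticConfig,
               n_species: int, rng: np.random.Generator) -> int:
    """Seed an empty lattice: each site gains a random species with p=0.3."""
    if lattice.occupied.any():
        raise ValueError("initialize expects an empty lattice")
    mask = rng.random((lattice.height, lattice.width)) < cfg.init_site_prob
    n = int(mask.sum())
    lattice.species[mask] = rng.integers(0, n_species, size=n)
    lattice.size[mask] = cfg.initial_size
    return n


def grow(size: float, per_unit_atp: float, yield_per_umol: float = 1e9,
         unit: float = POPULATION_UNIT) -> float:
    """New population size after one step of ATP-proportional growth."""
    return size + per_unit_atp * (size / unit) * yield_per_umol


def divide(lattice: BacterialLattice, cfg: StochasticConfig,
           rng: np.random.Generator) -> int:
    """Split every eligible population into an empty adjacent site."""
    ys, xs = np.where(lattice.size >= cfg.division_size)
    n_div = 0
    order = rng.permutation(len(ys))
    for i in order:
        y, x = int(ys[i]), int(xs[i])
        empties = [(y + dy, x + dx) for dy, dx in VON_NEUMANN
                   if 0 <= y + dy < lattice.height and 0 <= x + dx < lattice.width
                   and lattice.species[y + dy, x + dx] == EMPTY]
        if not empties:
            continue
        ny, nx = empties[rng.integers(0, len(empties))]
        half = lattice.size[y, x] / 2.0
        lattice.place(ny, nx, int(lattice.species[y, x]), half)
        lattice.size[y, x] = half
        n_div += 1
    return n_div


def kill_and_colonize(lattice: BacterialLattice, cfg: StochasticConfig,
                      n_species: int, rng: np.random.Generator,
                      delete_distal: bool = True) -> tuple[float, int]:
    """Random deaths, distal washout, and colonization of empty sites.

    Returns (biomass removed, number of colonizations).
    """
    removed = 0.0
    occ = lattice.occupied
    deaths = occ & (rng.random(occ.shape) < cfg.death_prob)
    removed += float(lattice.size[deaths].sum())
    lattice.species[deaths] = EMPTY
    lattice.size[deaths] = 0.0

    if delete_distal:
        distal = lattice.species[:, -1] != EMPTY
        removed += float(lattice.size[distal, -1].sum())
        lattice.species[distal, -1] = EMPTY
        lattice.size[distal, -1] = 0.0

    empty = ~lattice.occupied
    if cfg.colonize_first_column_only:
        eligible = np.zeros_like(empty)
        eligible[:, 0] = empty[:, 0]
    else:
        eligible = empty
    new = eligible & (rng.random(empty.shape) < cfg.colonize_prob)
    n_new = int(new.sum())
    if n_new:
        lattice.species[new] = rng.integers(0, n_species, size=n_new)
        lattice.size[new] = cfg.initial_size
    return removed, n_new


def _sweep(lattice: BacterialLattice, rng: np.random.Generator,
           offsets, site_subset: np.ndarray | None = None) -> None:
    h, w = lattice.height, lattice.width
    swapped = np.zeros((h, w), dtype=bool)
    sites = rng.permutation(h * w) if site_subset is None else site_subset
    picks = rng.integers(0, len(offsets), size=len(sites))
    sp, sz = lattice.species, lattice.size
    for k in range(len(sites)):
        idx = sites[k]
        y, x = divmod(int(idx), w)
        if swapped[y, x]:
            continue
        dy, dx = offsets[picks[k]]
        ny, nx = y + dy, x + dx
        if not (0 <= ny < h and 0 <= nx < w):
            continue
        if dy == 0 and dx == 0:
            swapped[y, x] = True
            continue
        if swapped[ny, nx]:
            continue
        sp[y, x], sp[ny, nx] = sp[ny, nx], sp[y, x]
        sz[y, x], sz[ny, nx] = sz[ny, nx], sz[y, x]
        swapped[y, x] = True
        swapped[ny, nx] = True


def mix(lattice: BacterialLattice, rng: np.random.Generator,
        sweeps: float = 1.0, offsets=MOORE8_SELF,
        full_mixing: bool = False) -> None:
    """Kawasaki-style mixing of the bacterial layer.

    ``sweeps`` scales the amount of mixing (1/n^2 on rescaled lattices);
    fractional parts run a partial sweep over a random subset of sites.
    Metabolites do not move.  ``full_mixing=True`` instead assigns all
    populations to random non-overlapping sites.
    """
    if sweeps < 0:
        raise ValueError("sweeps must be >= 0")
    if full_mixing:
        perm = rng.permutation(lattice.height * lattice.width)
        lattice.species = lattice.species.ravel()[perm].reshape(
            lattice.height, lattice.width).copy()
        lattice.size = lattice.size.ravel()[perm].reshape(
            lattice.height, lattice.width).copy()
        return
    whole = int(np.floor(sweeps))
    frac = sweeps - whole
    for _ in range(whole):
        _sweep(lattice, rng, offsets)
    if frac > 0:
        n = lattice.height * lattice.width
        subset = rng.permutation(n)[: int(round(frac * n))]
        if len(subset):
            _sweep(lattice, rng, offsets, site_subset=subset)
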