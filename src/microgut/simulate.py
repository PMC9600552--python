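"""Timestep loop, experiment switches, replicates, and recording.

One timestep (3 simulated minutes) is: feeding pulse and oxygen source ->
per-population enzymatic-constraint FBA and growth -> division -> death,
distal washout and colonization -> bacterial mixing -> metabolite diffusion
-> advection with distal outflow collection.  Sites are solved in random
order; each site holds at most one population, so the solve phase has no
shared resources.  Everything stochastic draws from one seeded generator,
making runs bit-reproducible given (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import environment as env
from . import population as pop
from .environment import (FeedingSchedule, LatticeGeometry, MetaboliteField,
                          OutflowRecord, OxygenRegime)
from .fba import (DEFAULT_ENZYMATIC_CONSTRAINT, POPULATION_UNIT, FBAEngine,
                  OverrideSet, uptake_bounds)
from .models import CompiledModel
from .population import BacterialLattice, StochasticConfig

#: one simulated day, in timesteps
STEPS_PER_DAY = 480

TOY_GROUPS = {
    "bifid_toy": "Bifidobacterium",
    "facan_toy": "E. coli",
    "cross_toy": "B. hansenii",
}


@dataclass
class SimConfig:
    roster: tuple[str, ...] = ("bifid_toy", "facan_toy", "cross_toy")
    geometry: LatticeGeometry = field(default_factory=LatticeGeometry)
    feeding: FeedingSchedule = field(default_factory=FeedingSchedule)
    oxygen: OxygenRegime = field(default_factory=OxygenRegime)
    stochastic: StochasticConfig = field(default_factory=StochasticConfig)
    overrides: OverrideSet = field(default_factory=OverrideSet)
    enzymatic_a: float = DEFAULT_ENZYMATIC_CONSTRAINT
    metabolite_diffusion: float = 4.4e-5     # cm^2/s
    mixing_sweeps: float = 1.0
    full_mixing: bool = False
    horizon: int = 10080                     # 21 days
    seed: int = 0
    groups: dict[str, str] = field(default_factory=lambda: dict(TOY_GROUPS))
    record_threshold: float = 5e-5           # umol (1 uM at 0.05 mL)
    substrate_floor: float = 1e-9            # umol; below this a site solves to zero
    audit_solves: bool = False
    record_spatial: bool = True
    use_cache: bool = True

    def __post_init__(self):
        if self.horizon < 0:
            raise ValueError("horizon must be >= 0")
        if not self.roster:
            raise ValueError("roster must not be empty")


def rescaled_config(cfg: SimConfig, n: float) -> SimConfig:
    """Rescale the lattice resolution by factor n on the site side length.

    Width/height scale as 1/n (same physical extent); colonization and
    initialization probabilities and the number of mixing sweeps scale as
    1/n^2; the site volume scales as n^2 at fixed depth.  Advection remains
    one site per step (the sensitivity-analysis convention of the source
    model), so the transit time is preserved by the changed column count.
    """
    g = cfg.geometry
    geom = replace(g, width=max(2, round(g.width / n)),
                   height=max(1, round(g.height / n)),
                   dx_mm=g.dx_mm * n,
                   site_volume_ml=g.site_volume_ml * n * n)
    st = replace(cfg.stochastic,
                 colonize_prob=min(1.0, cfg.stochastic.colonize_prob / n**2),
                 init_site_prob=min(1.0, cfg.stochastic.init_site_prob / n**2))
    return replace(cfg, geometry=geom, stochastic=st,
                   mixing_sweeps=cfg.mixing_sweeps / n**2)


@dataclass
class RunRecord:
    """Everything a run produces, append-only and replayable from (config, seed)."""
    config: SimConfig
    species: list[str]
    abundance: np.ndarray | None = None          # (T+1, n_species) biomass
    column_abundance: np.ndarray | None = None   # (T+1, n_species, width)
    ledger: list = field(default_factory=list)   # (t, y, x, species, met, net umol)
    outflows: list = field(default_factory=list)
    inputs: dict = field(default_factory=dict)   # cumulative umol fed per metabolite
    biomass_uptake: dict = field(default_factory=dict)
    biomass_secretion: dict = field(default_factory=dict)
    growth_total: float = 0.0
    deaths_biomass: float = 0.0
    colonizations: int = 0
    n_solves: int = 0
    audit_max_imbalance: float = 0.0
    audit_failures: int = 0
    gibbs_violations: int = 0
    final_field_totals: dict = field(default_factory=dict)

    def ledger_frame(self):
        import pandas as pd
        return pd.DataFrame(
            self.ledger, columns=["timestep", "y", "x", "species",
                                  "metabolite", "net_umol"])

    def group_abundance(self) -> dict[str, np.ndarray]:
        """Abundance trajectories pooled by display group."""
        out: dict[str, np.ndarray] = {}
        for i, sp in enumerate(self.species):
            g = self.config.groups.get(sp, "others")
            out[g] = out.get(g, 0.0) + self.abundance[:, i]
        return out


class Simulation:
    """Mutable simulation state for one run."""

    def __init__(self, config: SimConfig, models: dict[str, CompiledModel],
                 formulas: dict[str, dict[str, int]] | None = None,
                 energies: dict[str, float] | None = None):
        missing = [s for s in config.roster if s not in models]
        if missing:
            raise KeyError(f"no compiled model for roster species {missing}")
        self.config = config
        self.species = list(config.roster)
        self.models = {s: models[s] for s in self.species}
        self.engines = {s: FBAEngine(models[s]) for s in self.species}
        self.rng = np.random.default_rng(config.seed)
        g = config.geometry
        self.field = MetaboliteField(g)
        self.lattice = BacterialLattice(g.height, g.width)
        self.t = 0
        self.record = RunRecord(config=config, species=self.species)
        self._abund = []
        self._col_abund = [] if config.record_spatial else None
        self._formulas = formulas
        self._energies = energies
        if config.audit_solves:
            if formulas is None:
                self._formulas = self._merge("formulas")
            if energies is None:
                self._energies = self._merge("energies")

    def _merge(self, attr: str) -> dict:
        out: dict = {}
        for m in self.models.values():
            out.update(getattr(m, attr))
        return out

    # -- setup ------------------------------------------------------------

    def initialize(self) -> None:
        pop.initialize(self.lattice, self.config.stochastic,
                       len(self.species), self.rng)
        added = env.apply_oxygen(self.field, self.config.oxygen, t=0)
        if added:
            self.record.inputs["o2"] = self.record.inputs.get("o2", 0.0) + added
        self._record_state()

    def _record_state(self) -> None:
        ab = self.lattice.abundances(len(self.species))
        self._abund.append(ab)
        if self._col_abund is not None:
            col = np.zeros((len(self.species), self.lattice.width))
            mask = self.lattice.occupied
            ys, xs = np.where(mask)
            np.add.at(col, (self.lattice.species[ys, xs], xs),
                      self.lattice.size[ys, xs])
            self._col_abund.append(col)

    # -- one timestep ------------------------------------------------------

    def step(self) -> None:
        cfg = self.config
        rec = self.record
        t = self.t

        fed = env.feed(self.field, cfg.feeding, t)
        if fed:
            met = cfg.feeding.metabolite
            rec.inputs[met] = rec.inputs.get(met, 0.0) + fed
        if t > 0:
            added = env.apply_oxygen(self.field, cfg.oxygen, t)
            if added:
                rec.inputs["o2"] = rec.inputs.get("o2", 0.0) + added

        self._metabolism_phase()
        pop.divide(self.lattice, cfg.stochastic, self.rng)
        removed, n_new = pop.kill_and_colonize(
            self.lattice, cfg.stochastic, len(self.species), self.rng)
        rec.deaths_biomass += removed
        rec.colonizations += n_new
        pop.mix(self.lattice, self.rng, sweeps=cfg.mixing_sweeps,
                full_mixing=cfg.full_mixing)
        env.diffuse(self.field, cfg.metabolite_diffusion)
        outflow = env.advect(self.field, t)
        rec.outflows.append(outflow)
        self.field.prune()
        self.t += 1
        self._record_state()

    def _metabolism_phase(self) -> None:
        cfg = self.config
        rec = self.record
        lat = self.lattice
        occupied = np.flatnonzero(lat.occupied.ravel())
        order = self.rng.permutation(len(occupied))
        width = lat.width
        for k in order:
            idx = int(occupied[k])
            y, x = divmod(idx, width)
            B = lat.size[y, x]
            if B >= cfg.stochastic.max_size:
                continue  # boxed-in population: metabolism suspended
            amounts = self.field.amounts_at(y, x, floor=cfg.substrate_floor)
            if not amounts:
                continue
            sp_idx = int(lat.species[y, x])
            sp = self.species[sp_idx]
            ov = cfg.overrides.resolve(sp, self.t)
            bounds = uptake_bounds(amounts, B)
            engine = self.engines[sp]
            if cfg.use_cache:
                res = engine.solve_cached(bounds, cfg.enzymatic_a, ov)
            else:
                res = engine.solve(bounds, cfg.enzymatic_a, ov)
            rec.n_solves += 1
            if res.status == "zero":
                continue
            units = B / POPULATION_UNIT
            for met, v in res.uptake.items():
                amt = v * units
                if met != env.WATER:
                    arr = self.field.array(met)
                    arr[y, x] = max(arr[y, x] - amt, 0.0)
                    rec.biomass_uptake[met] = rec.biomass_uptake.get(met, 0.0) + amt
            for met, v in res.secretion.items():
                amt = v * units
                if met != env.WATER:
                    self.field.add(met, y, x, amt)
                    rec.biomass_secretion[met] = \
                        rec.biomass_secretion.get(met, 0.0) + amt
            grown = pop.grow(B, res.growth_atp, cfg.stochastic.growth_yield)
            grown = min(grown, cfg.stochastic.max_size)
            rec.growth_total += grown - B
            lat.size[y, x] = grown
            if cfg.audit_solves:
                self._audit(res)
            thr = cfg.record_threshold
            for met, net in res.net_exchange().items():
                if met == env.WATER:
                    continue
                amt = net * units
                if abs(amt) >= thr:
                    rec.ledger.append((self.t, y, x, sp, met, amt))

    def _audit(self, res) -> None:
        from .validation import ATOM_TOL, atom_balance, gibbs_audit
        balance = atom_balance(res, self._formulas)
        worst = max(abs(v) for v in balance.values())
        self.record.audit_max_imbalance = max(
            self.record.audit_max_imbalance, worst)
        if worst > ATOM_TOL:
            self.record.audit_failures += 1
        if self._energies:
            _, admissible, _ = gibbs_audit(res, self._energies)
            if not admissible:
                self.record.gibbs_violations += 1

    # -- whole runs --------------------------------------------------------

    def run(self) -> RunRecord:
        self.initialize()
        for _ in range(self.config.horizon):
            self.step()
        rec = self.record
        rec.abundance = np.asarray(self._abund)
        if self._col_abund is not None:
            rec.column_abundance = np.asarray(self._col_abund)
        rec.final_field_totals = self.field.totals()
        return rec


def run(config: SimConfig, models: dict[str, CompiledModel] | None = None,
        **sim_kwargs) -> RunRecord:
    """Run one simulation to its horizon and return the record."""
    if models is None:
        from .toys import build_toy_models
        models = build_toy_models()
    sim = Simulation(config, models, **sim_kwargs)
    return sim.run()


def run_replicates(config: SimConfig, n: int, base_seed: int | None = None,
                   models: dict[str, CompiledModel] | None = None) -> list[RunRecord]:
    """n replicates differing only by seed (base_seed + replicate index)."""
    base = config.seed if base_seed is None else base_seed
    return [run(replace(config, seed=int(base + i)), models) for i in range(n)]


# ---------------------------------------------------------------------------
# Experiment switches
# ---------------------------------------------------------------------------

#: reaction ids carrying fructose-6-phosphate phosphoketolase activity,
#: in the AGORA naming and in the bundled toy naming
PHOSPHOKETOLASE_REACTIONS = ("R_PKL", "R_F6PE4PL", "F6PPK")

EXPERIMENTS = ("bifid_shunt_ko", "lactate_uptake_block",
               "lactate_uptake_block_bifido", "lactate_production_block",
               "lactose_uptake_block_non_bifido", "ecoli_o2_ko")


def _bifid_species(config: SimConfig) -> list[str]:
    return [s for s in config.roster
            if config.groups.get(s, "").startswith("Bifid")]


def apply_experiment(config: SimConfig, experiment: str,
                     activation_step: int | None = None) -> SimConfig:
    """Install the overrides of a named in-silico experiment.

    ``activation_step`` applies to time-triggered blocks (default 5040, the
    midpoint of the full 21-day horizon).
    """
    if experiment is None or experiment == "none":
        return config
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    ov = OverrideSet(
        reaction_knockouts={k: set(v) for k, v in
                            config.overrides.reaction_knockouts.items()},
        exchange_blocks=list(config.overrides.exchange_blocks))
    bifid = _bifid_species(config)
    if experiment == "bifid_shunt_ko":
        for sp in bifid:
            ov.reaction_knockouts.setdefault(sp, set()).update(
                PHOSPHOKETOLASE_REACTIONS)
    elif experiment == "lactate_uptake_block":
        for met in ("lac_L", "lac_D"):
            ov.exchange_blocks.append((None, met, "in", 0))
    elif experiment == "lactate_uptake_block_bifido":
        for sp in bifid:
            for met in ("lac_L", "lac_D"):
                ov.exchange_blocks.append((sp, met, "in", 0))
    elif experiment == "lactate_production_block":
        for sp in bifid:
            for met in ("lac_L", "lac_D"):
                ov.exchange_blocks.append((sp, met, "out", 0))
    elif experiment == "lactose_uptake_block_non_bifido":
        start = 5040 if activation_step is None else activation_step
        for sp in config.roster:
            if sp not in bifid:
                ov.exchange_blocks.append((sp, "lcts", "in", start))
    elif experiment == "ecoli_o2_ko":
        for sp in config.roster:
            if config.groups.get(sp, "") == "E. coli":
                ov.exchange_blocks.append((sp, "o2", "in", 0))
    return replace(config, overrides=ov)
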