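"""Enzymatic-constraint FBA: the per-population, per-timestep linear program.

Each local population solves

    maximize   f_objective                     (ATP drain flux)
    subject to S f = 0                         (internal steady state)
               sum(f) <= a                     (enzymatic summed-flux cap)
               uptake(m) <= F_ub(m)            (environment-limited uptake)
               0 <= f <= column upper bounds

with all quantities in umol per timestep per population unit (1 unit =
10^10 bacteria).  The summed-flux cap covers *all* columns, exchange and
objective fluxes included.  Among alternate optima the reported solution is
made deterministic by a secondary minimize-sum-of-fluxes criterion,
implemented either exactly (two LP stages) or, by default, as a composite
objective ``f_objective - eps * sum(f)`` with ``eps = 1e-6``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .models import CompiledModel

#: population unit: the flux normalization of Table-style parameters
POPULATION_UNIT = 1e10

#: default enzymatic constraint, umol flux per timestep per population unit
DEFAULT_ENZYMATIC_CONSTRAINT = 2.0

_EPS_TIEBREAK = 1e-6
_FEAS_TOL = 1e-9


@dataclass(frozen=True)
class EnzymaticConstraint:
    """Summed-flux cap ``a`` in umol per timestep per population unit."""
    a: float = DEFAULT_ENZYMATIC_CONSTRAINT

    def __post_init__(self):
        if not self.a > 0:
            raise ValueError("enzymatic constraint must be positive")


@dataclass(frozen=True)
class ResolvedOverrides:
    """Knockouts/blocks already resolved for one species at one timestep."""
    knocked_reactions: frozenset[str] = frozenset()
    blocked_uptake: frozenset[str] = frozenset()     # env metabolite ids
    blocked_secretion: frozenset[str] = frozenset()

    def key(self) -> tuple:
        return (tuple(sorted(self.knocked_reactions)),
                tuple(sorted(self.blocked_uptake)),
                tuple(sorted(self.blocked_secretion)))


NO_OVERRIDES = ResolvedOverrides()


@dataclass
class OverrideSet:
    """Per-species reaction knockouts and timed exchange blocks.

    ``exchange_blocks`` entries are (species_id or None for all species,
    env metabolite id, direction "in"/"out"/"both", activation timestep).
    Overrides only ever tighten bounds to zero.
    """
    reaction_knockouts: dict[str, set[str]] = field(default_factory=dict)
    exchange_blocks: list[tuple[str | None, str, str, int]] = field(default_factory=list)

    def resolve(self, species_id: str, t: int) -> ResolvedOverrides:
        blocked_in, blocked_out = set(), set()
        for spec, met, direction, start in self.exchange_blocks:
            if spec is not None and spec != species_id:
                continue
            if t < start:
                continue
            if direction in ("in", "both"):
                blocked_in.add(met)
            if direction in ("out", "both"):
                blocked_out.add(met)
        return ResolvedOverrides(
            knocked_reactions=frozenset(self.reaction_knockouts.get(species_id, ())),
            blocked_uptake=frozenset(blocked_in),
            blocked_secretion=frozenset(blocked_out))


@dataclass
class FluxBounds:
    """Per-metabolite uptake caps, umol per timestep per population unit."""
    uptake: dict[str, float]            # env metabolite -> F_ub (water absent = unbounded)

    def get(self, met: str) -> float:
        if met == "h2o":
            return math.inf
        return self.uptake.get(met, 0.0)


@dataclass
class FBAResult:
    species_id: str
    status: str                          # "optimal" | "zero"
    fluxes: np.ndarray                   # per-column, umol/step/unit
    growth_atp: float                    # objective flux, umol ATP/step/unit
    uptake: dict[str, float]             # F_in per env metabolite
    secretion: dict[str, float]          # F_out per env metabolite

    def net_exchange(self) -> dict[str, float]:
        """out - in per env metabolite (positive = released)."""
        out = dict(self.secretion)
        for m, v in self.uptake.items():
            out[m] = out.get(m, 0.0) - v
        return out


def uptake_bounds(local_amounts: dict[str, float], B: float,
                  unit: float = POPULATION_UNIT) -> FluxBounds:
    """Environment-limited per-unit uptake caps for a population of B bacteria.

    ``F_ub(m) = amount(m) / (B / unit)``: the whole population, acting for one
    timestep, can take up at most the amount present at the site.  Water is
    unconstrained.
    """
    if B <= 0:
        raise ValueError("population size must be positive")
    units = B / unit
    caps = {}
    for met, amount in local_amounts.items():
        if met == "h2o":
            continue
        if amount < 0:
            raise ValueError(f"negative amount for {met!r}: {amount}")
        caps[met] = amount / units
    return FluxBounds(uptake=caps)


def _zero_result(model: CompiledModel) -> FBAResult:
    return FBAResult(species_id=model.species_id, status="zero",
                     fluxes=np.zeros(model.n_cols), growth_atp=0.0,
                     uptake={}, secretion={})


class _HighsBackend:
    """Persistent HiGHS model: constraints built once, bounds mutated per solve.

    Uses the highspy-style binding vendored inside scipy; re-solves from the
    previous basis, which makes the thousands of per-site LPs of a lattice
    run cheap.  Results agree with :func:`scipy.optimize.linprog` (the
    fallback and cross-check path) to solver tolerance.
    """

    def __init__(self, model: CompiledModel, eps_tiebreak: float,
                 multi_uptake: dict[str, tuple[int, ...]]):
        from scipy.optimize._highspy import _core
        self._core = _core
        n = model.n_cols
        nm = model.S.shape[0]
        self._multi = list(multi_uptake.items())
        extra = sparse.lil_matrix((len(self._multi), n))
        for i, (_, cols) in enumerate(self._multi):
            for c in cols:
                extra[i, c] = 1.0
        lp = _core.HighsLp()
        lp.num_col_ = n
        lp.num_row_ = nm + 1 + len(self._multi)
        lp.sense_ = _core.ObjSense.kMaximize
        cost = np.full(n, -eps_tiebreak)
        cost[model.objective_col] += 1.0
        lp.col_cost_ = cost
        lp.col_lower_ = np.zeros(n)
        lp.col_upper_ = np.full(n, 1e30)
        lp.row_lower_ = np.concatenate(
            [np.zeros(nm), np.full(1 + len(self._multi), -1e30)])
        lp.row_upper_ = np.concatenate(
            [np.zeros(nm), np.full(1 + len(self._multi), 1e30)])
        A = sparse.vstack([model.S, np.ones((1, n)), extra]).tocsc()
        lp.a_matrix_.format_ = _core.MatrixFormat.kColwise
        lp.a_matrix_.start_ = A.indptr
        lp.a_matrix_.index_ = A.indices
        lp.a_matrix_.value_ = A.data
        h = _core._Highs()
        h.setOptionValue("output_flag", False)
        h.setOptionValue("presolve", "off")
        h.setOptionValue("primal_feasibility_tolerance", _FEAS_TOL)
        h.setOptionValue("dual_feasibility_tolerance", _FEAS_TOL)
        if h.passModel(lp) != _core.HighsStatus.kOk:
            raise RuntimeError("could not build HiGHS model")
        self._h = h
        self._n = n
        self._sum_row = nm
        self._idx = np.arange(n, dtype=np.int32)
        self._lo = np.zeros(n)
        self._a = None

    def solve(self, a: float, col_upper: np.ndarray,
              met_caps: dict[str, float] | None = None) -> np.ndarray:
        h = self._h
        if a != self._a:
            h.changeRowBounds(self._sum_row, -1e30, a)
            self._a = a
        big = max(a * 10.0, 1.0)
        for i, (met, _) in enumerate(self._multi):
            cap = met_caps.get(met, big) if met_caps else big
            h.changeRowBounds(self._sum_row + 1 + i, -1e30, min(cap, big))
        h.changeColsBounds(self._n, self._idx, self._lo,
                           np.minimum(col_upper, big))
        h.run()
        status = h.getModelStatus()
        if status != self._core.HighsModelStatus.kOptimal:
            raise RuntimeError(
                f"HiGHS terminated with {h.modelStatusToString(status)}")
        return np.asarray(self._h.getSolution().col_value)


class FBAEngine:
    """Solves the enzymatic-constraint LP for one compiled model.

    Holds the assembled constraint matrices, a persistent warm-started
    HiGHS model (when available; otherwise every solve goes through
    :func:`scipy.optimize.linprog`), and an optional memoization cache.
    The cache quantizes per-unit uptake bounds onto the dyadic grid
    ``a * k / Q`` after clamping them at ``a`` (bounds above the summed-flux
    cap are never binding), which keeps cached solutions feasible for the
    true bounds while under-estimating growth by at most ~1/Q relative.
    """

    def __init__(self, model: CompiledModel, cache_quantum: int = 128,
                 use_highs_backend: bool = True):
        self.model = model
        self.Q = cache_quantum
        n = model.n_cols
        self._c_obj = np.zeros(n)
        self._c_obj[model.objective_col] = -1.0
        self._ones = np.ones(n)
        self._A_eq = sparse.csr_matrix(model.S)
        self._b_eq = np.zeros(model.S.shape[0])
        self._multi_in = {met: cols for met, cols in model.exchange_in.items()
                          if len(cols) > 1}
        self._backend = None
        if use_highs_backend:
            try:
                self._backend = _HighsBackend(model, _EPS_TIEBREAK,
                                              self._multi_in)
            except Exception:
                self._backend = None
        self._cache: dict[tuple, FBAResult] = {}
        self.cache_hits = 0
        self.cache_misses = 0

    # -- LP assembly ------------------------------------------------------

    def _column_bounds(self, bounds: FluxBounds,
                       overrides: ResolvedOverrides) -> np.ndarray:
        m = self.model
        ub = m.col_upper.astype(float).copy()
        for met, cols in m.exchange_in.items():
            cap = bounds.get(met)
            if met in overrides.blocked_uptake:
                cap = 0.0
            for col in cols:
                ub[col] = min(ub[col], cap)
        for met, cols in m.exchange_out.items():
            if met in overrides.blocked_secretion:
                for col in cols:
                    ub[col] = 0.0
        for rid in overrides.knocked_reactions:
            if rid in m.rxn_cols:
                fwd, rev = m.rxn_cols[rid]
                ub[fwd] = 0.0
                if rev is not None:
                    ub[rev] = 0.0
        return ub

    def _solve_lp(self, c: np.ndarray, a: float, ub: np.ndarray,
                  extra_ub=None):
        A_rows = [self._ones]
        b_rows = [a]
        if extra_ub:
            for row, rhs in extra_ub:
                A_rows.append(row)
                b_rows.append(rhs)
        big = max(a * 10.0, 1.0)
        col_hi = np.minimum(ub, big)  # finite box for the solver; sum(f)<=a dominates
        res = linprog(c, A_ub=np.vstack(A_rows), b_ub=np.array(b_rows),
                      A_eq=self._A_eq, b_eq=self._b_eq,
                      bounds=np.column_stack([np.zeros_like(col_hi), col_hi]),
                      method="highs",
                      options={"presolve": False,
                               "primal_feasibility_tolerance": _FEAS_TOL,
                               "dual_feasibility_tolerance": _FEAS_TOL})
        return res

    def solve(self, bounds: FluxBounds, a: float = DEFAULT_ENZYMATIC_CONSTRAINT,
              overrides: ResolvedOverrides = NO_OVERRIDES,
              exact: bool = False) -> FBAResult:
        """One enzymatic-constraint FBA solve (per-unit quantities)."""
        m = self.model
        ub = self._column_bounds(bounds, overrides)
        if ub[m.objective_col] <= 0:
            return _zero_result(m)
        met_caps = None
        if self._multi_in:
            met_caps = {met: (0.0 if met in overrides.blocked_uptake
                              else bounds.get(met))
                        for met in self._multi_in}
        if not exact:
            if self._backend is not None:
                f = self._backend.solve(a, ub, met_caps)
            else:
                res = self._solve_lp(self._c_obj + _EPS_TIEBREAK * self._ones,
                                     a, ub)
                if res.status != 0:
                    raise RuntimeError(
                        f"LP solver failure for {m.species_id}: {res.message}")
                f = res.x
        else:
            res = self._solve_lp(self._c_obj, a, ub)
            if res.status != 0:
                raise RuntimeError(
                    f"LP solver failure for {m.species_id}: {res.message}")
            opt = -res.fun
            # second stage: among optima, minimize total flux
            row = -self._c_obj
            res2 = self._solve_lp(self._ones, a, ub,
                                  extra_ub=[(-row, -(opt - _FEAS_TOL))])
            if res2.status != 0:
                raise RuntimeError(
                    f"LP tie-break failure for {m.species_id}: {res2.message}")
            f = res2.x
        f = np.where(np.abs(f) < _FEAS_TOL, 0.0, f)
        uptake = {}
        for met, cols in m.exchange_in.items():
            v = sum(f[c] for c in cols)
            if v > 0:
                uptake[met] = v
        secretion = {}
        for met, cols in m.exchange_out.items():
            v = sum(f[c] for c in cols)
            if v > 0:
                secretion[met] = v
        growth = float(f[m.objective_col])
        return FBAResult(species_id=m.species_id,
                         status="optimal" if growth > 0 else "zero",
                         fluxes=f, growth_atp=growth,
                         uptake=uptake, secretion=secretion)

    # -- cached lattice path ---------------------------------------------

    def solve_cached(self, bounds: FluxBounds, a: float,
                     overrides: ResolvedOverrides = NO_OVERRIDES) -> FBAResult:
        """Memoized solve on down-quantized uptake bounds (always feasible)."""
        m = self.model
        quantum = a / self.Q
        key_items = []
        qbounds = {}
        for met in m.exchange_in:
            if met == "h2o":
                continue
            cap = bounds.get(met)
            if met in overrides.blocked_uptake:
                cap = 0.0
            k = self.Q if cap >= a else int(cap / quantum)
            if k > 0:
                key_items.append((met, k))
                qbounds[met] = k * quantum
        key = (a, tuple(key_items), overrides.key())
        hit = self._cache.get(key)
        if hit is not None:
            self.cache_hits += 1
            return hit
        self.cache_misses += 1
        result = self.solve(FluxBounds(uptake=qbounds), a=a, overrides=overrides)
        self._cache[key] = result
        return result


def solve_step(model: CompiledModel, B: float, bounds: FluxBounds,
               a: EnzymaticConstraint | float = DEFAULT_ENZYMATIC_CONSTRAINT,
               overrides: ResolvedOverrides = NO_OVERRIDES,
               exact: bool = False,
               engine: FBAEngine | None = None) -> FBAResult:
    """Solve one population-timestep; B only validates scale-invariance.

    All returned quantities are per population unit; callers convert to
    site totals with ``B / POPULATION_UNIT``.
    """
    if B <= 0:
        raise ValueError("population size must be positive")
    a_val = a.a if isinstance(a, EnzymaticConstraint) else float(a)
    eng = engine or FBAEngine(model)
    return eng.solve(bounds, a=a_val, overrides=overrides, exact=exact)


def dose_response(model: CompiledModel, metabolite: str,
                  grid: "list[float] | np.ndarray",
                  B: float = 5e9,
                  context: dict[str, float] | None = None,
                  a: float = DEFAULT_ENZYMATIC_CONSTRAINT,
                  site_volume_ml: float = 0.05,
                  unit: float = POPULATION_UNIT):
    """Single-site sweeps: growth and net secretion vs concentration.

    ``grid`` is in umol/mL; a population of ``B`` bacteria has access to one
    lattice site of ``site_volume_ml``.  Returns a pandas DataFrame with one
    row per concentration; growth and secretion columns are totals for the
    whole population per timestep (umol).
    """
    import pandas as pd

    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) < 0) or np.any(grid < 0):
        raise ValueError("grid must be non-negative and ascending")
    engine = FBAEngine(model)
    units = B / unit
    rows = []
    for conc in grid:
        amounts = dict(context or {})
        amounts[metabolite] = conc * site_volume_ml
        res = engine.solve(uptake_bounds(amounts, B, unit), a=a)
        row = {"concentration": conc, "growth_atp": res.growth_atp * units}
        for met, v in res.net_exchange().items():
            if met != "h2o":
                row[met] = v * units
        rows.append(row)
    df = pd.DataFrame(rows).fillna(0.0)
    return df
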