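"""Biochemical and thermodynamic plausibility audits.

Three checks, applied per FBA solution or per model:

* atom balance — the net exchange with the environment must carry no C, H,
  O or N (the objective drain is mass neutral and the system has no other
  sinks), to within 1e-8 umol per solution;
* Gibbs audit — the free energy of the outputs must not exceed that of the
  inputs, using standard transformed formation energies at pH 7 and ionic
  strength 0.1 M supplied as a table; equality is admissible only for
  (near-)zero-growth solutions;
* model checks — growth on lactose (or lactate for lactate specialists) and
  strictly zero growth when only water is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .fba import FBAEngine, FBAResult, FluxBounds, uptake_bounds
from .models import AUDIT_ELEMENTS, CompiledModel

ATOM_TOL = 1e-8          # umol per FBA solution
GIBBS_TOL = 1e-6         # J per population unit
NEGLIGIBLE_GROWTH = 1e-9  # umol ATP per unit per step


def atom_balance(result: FBAResult,
                 formulas: dict[str, dict[str, int]],
                 elements: tuple[str, ...] = AUDIT_ELEMENTS) -> dict[str, float]:
    """Net element exchange (umol of atoms, out minus in) of one solution."""
    net = {el: 0.0 for el in elements}
    for met, flux in result.net_exchange().items():
        if flux == 0.0:
            continue
        if met not in formulas:
            raise KeyError(f"no elemental formula for exchanged metabolite {met!r}")
        f = formulas[met]
        for el in elements:
            net[el] += flux * f.get(el, 0)
    return net


def gibbs_audit(result: FBAResult, energies: dict[str, float],
                tol: float = GIBBS_TOL) -> tuple[float, bool, bool]:
    """Free-energy check of one solution.

    Returns ``(delta_g, admissible, partial)`` where ``delta_g`` is the net
    Gibbs free energy of the exchanged metabolites, outputs minus inputs, in
    J per population unit per timestep (negative = energy dissipated, the
    thermodynamically admissible direction).  ``partial`` flags metabolites
    skipped for lack of an energy entry.
    """
    delta_g = 0.0
    partial = False
    for met, flux in result.net_exchange().items():
        if flux == 0.0:
            continue
        if met not in energies:
            partial = True
            continue
        delta_g += flux * energies[met]
    if delta_g < -tol:
        admissible = True
    elif delta_g <= tol:
        # no energy gain: admissible only at negligible growth
        admissible = result.growth_atp <= NEGLIGIBLE_GROWTH
    else:
        admissible = False
    return delta_g, admissible, partial


@dataclass
class AuditReport:
    n_solves: int = 0
    n_atom_failures: int = 0
    max_imbalance: float = 0.0
    n_gibbs_violations: int = 0
    n_partial: int = 0
    violations: list = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return self.n_atom_failures == 0 and self.n_gibbs_violations == 0

    def add(self, result: FBAResult, formulas, energies,
            context: tuple = ()) -> None:
        self.n_solves += 1
        balance = atom_balance(result, formulas)
        worst = max(abs(v) for v in balance.values())
        self.max_imbalance = max(self.max_imbalance, worst)
        if worst > ATOM_TOL:
            self.n_atom_failures += 1
            self.violations.append(("atoms", context, balance))
        dg, ok, partial = gibbs_audit(result, energies)
        if partial:
            self.n_partial += 1
        if not ok:
            self.n_gibbs_violations += 1
            self.violations.append(("gibbs", context, dg))

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"check": c, "context": str(ctx), "detail": str(d)}
             for c, ctx, d in self.violations])


def read_formula_csv(path) -> dict[str, dict[str, int]]:
    """Columns: id, formula (e.g. ``lcts, C12H22O11``)."""
    from .models import parse_formula
    df = pd.read_csv(path, dtype=str)
    return {r.id: parse_formula(r.formula) for r in df.itertuples(index=False)}


def read_gibbs_csv(path) -> dict[str, float]:
    """Columns: id, dG_J_per_mol (standard transformed, pH 7, I = 0.1 M)."""
    df = pd.read_csv(path)
    return dict(zip(df["id"], df["dG_J_per_mol"].astype(float)))


# ---------------------------------------------------------------------------
# Per-model validity checks
# ---------------------------------------------------------------------------

def model_checks(model: CompiledModel, a: float = 2.0,
                 substrate_amount: float = 10.0,
                 B: float = 5e9) -> dict[str, bool]:
    """Growth-substrate and no-spurious-growth checks for one compiled model.

    Returns flags: ``grows_on_lactose``, ``grows_on_lactate``, and
    ``no_growth_without_substrate`` (all uptake except water at zero).
    """
    engine = FBAEngine(model)

    def growth_on(amounts: dict[str, float]) -> float:
        return engine.solve(uptake_bounds(amounts, B), a=a).growth_atp

    return {
        "grows_on_lactose": growth_on({"lcts": substrate_amount}) > 1e-9,
        "grows_on_lactate": growth_on({"lac_L": substrate_amount}) > 1e-9,
        "no_growth_without_substrate": growth_on({}) == 0.0
        and engine.solve(FluxBounds(uptake={}), a=a).growth_atp == 0.0,
    }
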