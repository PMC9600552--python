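"""Metabolic model ingestion, curation, and compilation to LP-ready form.

A species is described by a genome-scale metabolic model (GEM): a set of
metabolites and stoichiometric reactions, read from SBML (level 3, FBC) or
built in memory.  Before simulation the model is *curated* (reactions
deleted/added/re-bounded, following a curation-edit table), its objective is
replaced by a mass-neutral ATP-hydrolysis drain (ATP production is the growth
proxy throughout), and it is *compiled*: every reversible reaction is split
into two irreversible columns so that all fluxes are >= 0, and exchange
reactions are indexed against the extracellular metabolite they carry.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import sparse

AUDIT_ELEMENTS = ("C", "H", "O", "N")

_FORMULA_TOKEN = re.compile(r"([A-Z][a-z]?)(\d*)")


def parse_formula(formula: str) -> dict[str, int]:
    """Parse an elemental formula string into element -> count.

    Only non-negative integer counts are accepted; an empty or None formula
    is an error at the call site, not here.
    """
    counts: dict[str, int] = {}
    pos = 0
    for m in _FORMULA_TOKEN.finditer(formula):
        if m.start() != pos:
            raise ValueError(f"cannot parse formula {formula!r}")
        pos = m.end()
        counts[m.group(1)] = counts.get(m.group(1), 0) + int(m.group(2) or 1)
    if pos != len(formula):
        raise ValueError(f"cannot parse formula {formula!r}")
    return counts


def env_id(met_id: str) -> str:
    """Bare environment identifier for an extracellular metabolite.

    Strips compartment decorations: ``lcts_e``, ``lcts[e]``, ``lcts(e)`` and
    ``M_lcts_e`` all map to ``lcts`` (BiGG-style ids, as in the AGORA GEMs).
    """
    m = met_id
    if m.startswith("M_"):
        m = m[2:]
    m = re.sub(r"(\[e\]|\(e\)|_e)$", "", m)
    return m


@dataclass
class MetaboliteSpec:
    id: str
    name: str = ""
    compartment: str = "c"
    formula: dict[str, int] | None = None
    gibbs_energy: float | None = None  # J/mol, pH 7, I = 0.1 M

    @property
    def extracellular(self) -> bool:
        return self.compartment == "e" or bool(re.search(r"(\[e\]|\(e\)|_e)$", self.id))


@dataclass
class ReactionSpec:
    id: str
    stoichiometry: dict[str, float]  # metabolite id -> signed coefficient
    reversible: bool = False
    kind: str = "internal"  # "internal" | "exchange"
    lower_bound: float = 0.0
    upper_bound: float = float("inf")
    name: str = ""


@dataclass
class CurationEdit:
    model_id: str
    action: str  # delete_reaction | add_reaction | set_reversible | set_bounds | set_objective
    reaction_id: str
    payload: dict = field(default_factory=dict)


@dataclass
class ModelDraft:
    id: str
    name: str = ""
    metabolites: dict[str, MetaboliteSpec] = field(default_factory=dict)
    reactions: dict[str, ReactionSpec] = field(default_factory=dict)
    objective_id: str | None = None

    def copy(self) -> "ModelDraft":
        return ModelDraft(
            id=self.id,
            name=self.name,
            metabolites={k: replace(v, formula=dict(v.formula) if v.formula else None)
                         for k, v in self.metabolites.items()},
            reactions={k: replace(v, stoichiometry=dict(v.stoichiometry))
                       for k, v in self.reactions.items()},
            objective_id=self.objective_id,
        )

    def add_metabolite(self, met: MetaboliteSpec) -> None:
        if met.id in self.metabolites:
            raise ValueError(f"duplicate metabolite id {met.id!r}")
        self.metabolites[met.id] = met

    def add_reaction(self, rxn: ReactionSpec) -> None:
        if rxn.id in self.reactions:
            raise ValueError(f"duplicate reaction id {rxn.id!r} in model {self.id!r}")
        for mid in rxn.stoichiometry:
            if mid not in self.metabolites:
                raise ValueError(
                    f"reaction {rxn.id!r} references unknown metabolite {mid!r}")
        self.reactions[rxn.id] = rxn

    def validate(self) -> None:
        for rxn in self.reactions.values():
            for mid in rxn.stoichiometry:
                if mid not in self.metabolites:
                    raise ValueError(
                        f"reaction {rxn.id!r} references unknown metabolite {mid!r}")
            if rxn.kind == "exchange":
                ext = [m for m in rxn.stoichiometry
                       if self.metabolites[m].extracellular]
                if len(rxn.stoichiometry) != 1 or len(ext) != 1:
                    raise ValueError(
                        f"exchange reaction {rxn.id!r} must touch exactly one "
                        f"extracellular metabolite")


# ---------------------------------------------------------------------------
# SBML I/O (libSBML, FBC package)
# ---------------------------------------------------------------------------

_EXCHANGE_ID = re.compile(r"^(R_)?(EX_|DM_|sink_|SINK_|Sink_)", re.IGNORECASE)


def load_sbml(path: str) -> ModelDraft:
    """Read an SBML (level 3, FBC) file into a :class:`ModelDraft`.

    Reactions whose id marks them as exchange/sink/demand, or whose
    stoichiometry touches a single metabolite, are flagged ``kind="exchange"``.
    """
    import libsbml

    doc = libsbml.readSBMLFromFile(str(path))
    if doc.getModel() is None or doc.getNumErrors() > 0 and any(
            doc.getError(i).getSeverity() >= libsbml.LIBSBML_SEV_ERROR
            for i in range(doc.getNumErrors())):
        raise ValueError(f"unreadable SBML file: {path}")
    model = doc.getModel()
    draft = ModelDraft(id=model.getId() or "model", name=model.getName() or "")

    for i in range(model.getNumSpecies()):
        sp = model.getSpecies(i)
        fbc_sp = sp.getPlugin("fbc")
        formula = None
        if fbc_sp is not None and fbc_sp.isSetChemicalFormula():
            formula = parse_formula(fbc_sp.getChemicalFormula())
        draft.add_metabolite(MetaboliteSpec(
            id=sp.getId(), name=sp.getName() or "",
            compartment=sp.getCompartment() or "c", formula=formula))

    def _param(pid):
        p = model.getParameter(pid)
        return p.getValue() if p is not None else None

    for i in range(model.getNumReactions()):
        rx = model.getReaction(i)
        stoich: dict[str, float] = {}
        for j in range(rx.getNumReactants()):
            sr = rx.getReactant(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) - sr.getStoichiometry()
        for j in range(rx.getNumProducts()):
            sr = rx.getProduct(j)
            stoich[sr.getSpecies()] = stoich.get(sr.getSpecies(), 0.0) + sr.getStoichiometry()
        for mid in stoich:
            if mid not in draft.metabolites:
                raise ValueError(
                    f"reaction {rx.getId()!r} references unknown metabolite {mid!r}")
        fbc_rx = rx.getPlugin("fbc")
        lb, ub = None, None
        if fbc_rx is not None:
            if fbc_rx.isSetLowerFluxBound():
                lb = _param(fbc_rx.getLowerFluxBound())
            if fbc_rx.isSetUpperFluxBound():
                ub = _param(fbc_rx.getUpperFluxBound())
        reversible = rx.getReversible() if rx.isSetReversible() else True
        if lb is None:
            lb = -float("inf") if reversible else 0.0
        if ub is None:
            ub = float("inf")
        kind = "exchange" if (_EXCHANGE_ID.match(rx.getId()) or len(stoich) == 1) \
            else "internal"
        draft.add_reaction(ReactionSpec(
            id=rx.getId(), stoichiometry=stoich, reversible=lb < 0,
            kind=kind, lower_bound=lb, upper_bound=ub, name=rx.getName() or ""))

    fbc_model = model.getPlugin("fbc")
    if fbc_model is not None and fbc_model.getNumObjectives() > 0:
        obj = fbc_model.getActiveObjective() or fbc_model.getObjective(0)
        if obj is not None and obj.getNumFluxObjectives() > 0:
            draft.objective_id = obj.getFluxObjective(0).getReaction()
    draft.validate()
    return draft


def write_sbml(draft: ModelDraft, path: str) -> None:
    """Write a draft as SBML level 3 with FBC v2 (formulas and flux bounds)."""
    import libsbml

    ns = libsbml.SBMLNamespaces(3, 1, "fbc", 2)
    doc = libsbml.SBMLDocument(ns)
    doc.setPackageRequired("fbc", False)
    model = doc.createModel()
    model.setId(draft.id)
    model.setName(draft.name or draft.id)
    fbc_model = model.getPlugin("fbc")
    fbc_model.setStrict(False)

    compartments = sorted({m.compartment for m in draft.metabolites.values()})
    for cid in compartments:
        c = model.createCompartment()
        c.setId(cid)
        c.setConstant(True)

    for met in draft.metabolites.values():
        sp = model.createSpecies()
        sp.setId(met.id)
        sp.setName(met.name or met.id)
        sp.setCompartment(met.compartment)
        sp.setConstant(False)
        sp.setHasOnlySubstanceUnits(True)
        sp.setBoundaryCondition(False)
        if met.formula:
            fbc_sp = sp.getPlugin("fbc")
            fbc_sp.setChemicalFormula(
                "".join(f"{el}{n if n != 1 else ''}" for el, n in sorted(met.formula.items())))

    def _bound_param(value, tag):
        pid = f"bnd_{tag}"
        if model.getParameter(pid) is None:
            p = model.createParameter()
            p.setId(pid)
            p.setValue(value)
            p.setConstant(True)
        return pid

    big = 1e6  # stands in for +inf in SBML flux bounds
    for rxn in draft.reactions.values():
        rx = model.createReaction()
        rx.setId(rxn.id)
        rx.setName(rxn.name or rxn.id)
        rx.setReversible(rxn.reversible)
        rx.setFast(False)
        for mid, coef in rxn.stoichiometry.items():
            sr = rx.createReactant() if coef < 0 else rx.createProduct()
            sr.setSpecies(mid)
            sr.setStoichiometry(abs(coef))
            sr.setConstant(True)
        lb = max(rxn.lower_bound, -big)
        ub = min(rxn.upper_bound, big)
        fbc_rx = rx.getPlugin("fbc")
        fbc_rx.setLowerFluxBound(_bound_param(lb, f"l{len(model.getListOfParameters())}_{rxn.id}"))
        fbc_rx.setUpperFluxBound(_bound_param(ub, f"u{len(model.getListOfParameters())}_{rxn.id}"))

    if draft.objective_id:
        obj = fbc_model.createObjective()
        obj.setId("obj")
        obj.setType("maximize")
        fo = obj.createFluxObjective()
        fo.setReaction(draft.objective_id)
        fo.setCoefficient(1.0)
        fbc_model.setActiveObjectiveId("obj")

    libsbml.writeSBMLToFile(doc, str(path))


# ---------------------------------------------------------------------------
# Curation
# ---------------------------------------------------------------------------

def read_curation_csv(path: str) -> list[CurationEdit]:
    """Read a curation-edit table: columns model_id, action, reaction_id, payload."""
    df = pd.read_csv(path, dtype=str).fillna("")
    edits = []
    for row in df.itertuples(index=False):
        payload = json.loads(row.payload) if row.payload else {}
        edits.append(CurationEdit(model_id=row.model_id, action=row.action,
                                  reaction_id=row.reaction_id, payload=payload))
    return edits


def write_curation_csv(edits: list[CurationEdit], path: str) -> None:
    rows = [{"model_id": e.model_id, "action": e.action,
             "reaction_id": e.reaction_id,
             "payload": json.dumps(e.payload, sort_keys=True) if e.payload else ""}
            for e in edits]
    pd.DataFrame(rows, columns=["model_id", "action", "reaction_id", "payload"]
                 ).to_csv(path, index=False)


def apply_curation_edits(draft: ModelDraft, edits: list[CurationEdit]) -> list[str]:
    """Apply curation edits addressed to this model, in listed order.

    Returns the edit log (one line per applied edit).  Edits for other model
    ids are ignored; dangling references and duplicate adds are fatal.
    """
    log: list[str] = []
    for e in edits:
        if e.model_id != draft.id:
            continue
        if e.action == "delete_reaction":
            if e.reaction_id not in draft.reactions:
                raise KeyError(f"delete_reaction: no reaction {e.reaction_id!r} "
                               f"in model {draft.id!r}")
            del draft.reactions[e.reaction_id]
            if draft.objective_id == e.reaction_id:
                draft.objective_id = None
        elif e.action == "add_reaction":
            for mid, spec in e.payload.get("metabolites", {}).items():
                if mid not in draft.metabolites:
                    draft.add_metabolite(MetaboliteSpec(
                        id=mid, name=spec.get("name", ""),
                        compartment=spec.get("compartment", "c"),
                        formula=parse_formula(spec["formula"]) if spec.get("formula") else None))
            draft.add_reaction(ReactionSpec(
                id=e.reaction_id,
                stoichiometry={k: float(v) for k, v in e.payload["stoichiometry"].items()},
                reversible=bool(e.payload.get("reversible", False)),
                kind=e.payload.get("kind", "internal"),
                lower_bound=float(e.payload.get("lb",
                                  -float("inf") if e.payload.get("reversible") else 0.0)),
                upper_bound=float(e.payload.get("ub", float("inf")))))
        elif e.action in ("set_reversible", "set_bounds", "set_objective"):
            if e.reaction_id not in draft.reactions:
                raise KeyError(f"{e.action}: no reaction {e.reaction_id!r} "
                               f"in model {draft.id!r}")
            rxn = draft.reactions[e.reaction_id]
            if e.action == "set_reversible":
                rxn.reversible = bool(e.payload.get("reversible", True))
                if rxn.reversible and rxn.lower_bound >= 0:
                    rxn.lower_bound = -float("inf")
                if not rxn.reversible:
                    rxn.lower_bound = max(rxn.lower_bound, 0.0)
            elif e.action == "set_bounds":
                rxn.lower_bound = float(e.payload.get("lb", rxn.lower_bound))
                rxn.upper_bound = float(e.payload.get("ub", rxn.upper_bound))
                rxn.reversible = rxn.lower_bound < 0
            else:
                draft.objective_id = e.reaction_id
        else:
            raise ValueError(f"unknown curation action {e.action!r}")
        log.append(f"{draft.id}: {e.action} {e.reaction_id}")
    draft.validate()
    return log


# ---------------------------------------------------------------------------
# ATP objective
# ---------------------------------------------------------------------------

def _find_species(draft: ModelDraft, base: str) -> str | None:
    for cand in (f"{base}_c", f"{base}[c]", f"M_{base}_c", base,
                 f"{base}_e", f"{base}[e]", f"M_{base}_e"):
        if cand in draft.metabolites:
            return cand
    return None


def set_atp_objective(draft: ModelDraft, reaction_id: str = "ATPM") -> str:
    """Replace the model objective with a mass-neutral ATP drain.

    The drain hydrolyses ATP to ADP + Pi (ATP + H2O -> ADP + Pi, plus a free
    proton when the model's formula conventions require one for elemental
    neutrality), so maximizing its flux maximizes ATP production while
    removing no atoms from the system.  If a reaction with exactly this
    stoichiometry already exists it is reused; the call is idempotent.
    """
    needed = {}
    for base, coef in (("atp", -1.0), ("h2o", -1.0), ("adp", 1.0), ("pi", 1.0)):
        mid = _find_species(draft, base)
        if mid is None:
            raise ValueError(f"model {draft.id!r} lacks species {base!r} for ATP objective")
        needed[mid] = coef
    # add a proton only if the species formulas need it to balance hydrogen
    if all(draft.metabolites[m].formula is not None for m in needed):
        h_gap = -sum(coef * draft.metabolites[m].formula.get("H", 0)
                     for m, coef in needed.items())
        proton = _find_species(draft, "h")
        if h_gap and proton is not None:
            needed[proton] = h_gap

    for rxn in draft.reactions.values():
        if rxn.stoichiometry == needed:
            draft.objective_id = rxn.id
            return rxn.id
    if reaction_id in draft.reactions:
        draft.objective_id = reaction_id
        return reaction_id
    draft.add_reaction(ReactionSpec(id=reaction_id, stoichiometry=needed,
                                    reversible=False, kind="internal",
                                    name="ATP drain (objective)"))
    draft.objective_id = reaction_id
    return reaction_id


# ---------------------------------------------------------------------------
# Compilation
# ---------------------------------------------------------------------------

@dataclass
class CompiledModel:
    """A stoichiometric network compiled for LP.

    All columns are irreversible (reversible reactions are split into a
    forward and a reverse column), so flux is always >= 0.  ``S`` covers every
    metabolite, extracellular ones included; exchange columns are the only
    boundary terms, so ``S f = 0`` enforces the internal steady state while
    routing net production/consumption through the exchange columns.
    """
    species_id: str
    name: str
    S: sparse.csr_matrix                       # metabolites x columns
    met_ids: list[str]
    met_index: dict[str, int]
    columns: list[tuple[str, int]]             # (reaction id, +1 fwd / -1 rev)
    col_upper: np.ndarray                      # per-column upper bounds
    rxn_cols: dict[str, tuple[int, int | None]]
    exchange_in: dict[str, tuple[int, ...]]    # env metabolite -> uptake columns
    exchange_out: dict[str, tuple[int, ...]]   # env metabolite -> secretion columns
    objective_col: int
    formulas: dict[str, dict[str, int]]        # env metabolite -> element counts
    energies: dict[str, float]                 # env metabolite -> dG'f (J/mol)
    reactions: dict[str, ReactionSpec]

    @property
    def n_cols(self) -> int:
        return self.S.shape[1]

    def net_fluxes(self, f: np.ndarray) -> dict[str, float]:
        """Signed net flux per reaction (forward minus reverse column)."""
        out = {}
        for rid, (fwd, rev) in self.rxn_cols.items():
            out[rid] = f[fwd] - (f[rev] if rev is not None else 0.0)
        return out


def compile_model(draft: ModelDraft) -> CompiledModel:
    """Compile a curated draft with an objective into a :class:`CompiledModel`."""
    if draft.objective_id is None:
        raise ValueError(f"model {draft.id!r} has no objective; "
                         "call set_atp_objective first")
    draft.validate()
    met_ids = list(draft.metabolites)
    met_index = {m: i for i, m in enumerate(met_ids)}

    columns: list[tuple[str, int]] = []
    col_upper: list[float] = []
    rxn_cols: dict[str, tuple[int, int | None]] = {}
    rows, cols, vals = [], [], []

    for rxn in draft.reactions.values():
        if not rxn.reversible and rxn.lower_bound > 0:
            raise ValueError(f"reaction {rxn.id!r}: positive lower bounds are "
                             "not supported after the irreversible split")
        fwd = len(columns)
        columns.append((rxn.id, +1))
        col_upper.append(rxn.upper_bound)
        for mid, coef in rxn.stoichiometry.items():
            rows.append(met_index[mid]); cols.append(fwd); vals.append(coef)
        rev = None
        if rxn.reversible:
            rev = len(columns)
            columns.append((rxn.id, -1))
            col_upper.append(-rxn.lower_bound if rxn.lower_bound < 0 else 0.0)
            for mid, coef in rxn.stoichiometry.items():
                rows.append(met_index[mid]); cols.append(rev); vals.append(-coef)
        rxn_cols[rxn.id] = (fwd, rev)

    S = sparse.csr_matrix((vals, (rows, cols)),
                          shape=(len(met_ids), len(columns)))

    exchange_in: dict[str, tuple[int, ...]] = {}
    exchange_out: dict[str, tuple[int, ...]] = {}
    for rxn in draft.reactions.values():
        if rxn.kind != "exchange":
            continue
        (mid, coef), = rxn.stoichiometry.items()
        env = env_id(mid)
        fwd, rev = rxn_cols[rxn.id]
        # secretion removes the metabolite from the system row (coef < 0 fwd)
        out_col, in_col = (fwd, rev) if coef < 0 else (rev, fwd)
        if out_col is not None:
            exchange_out[env] = exchange_out.get(env, ()) + (out_col,)
        if in_col is not None:
            exchange_in[env] = exchange_in.get(env, ()) + (in_col,)

    formulas = {}
    energies = {}
    for met in draft.metabolites.values():
        if met.extracellular:
            if met.formula is not None:
                formulas[env_id(met.id)] = dict(met.formula)
            if met.gibbs_energy is not None:
                energies[env_id(met.id)] = met.gibbs_energy

    obj_fwd, _ = rxn_cols[draft.objective_id]
    return CompiledModel(
        species_id=draft.id, name=draft.name or draft.id, S=S,
        met_ids=met_ids, met_index=met_index, columns=columns,
        col_upper=np.array(col_upper), rxn_cols=rxn_cols,
        exchange_in=exchange_in, exchange_out=exchange_out,
        objective_col=obj_fwd, formulas=formulas, energies=energies,
        reactions={r.id: replace(r, stoichiometry=dict(r.stoichiometry))
                   for r in draft.reactions.values()})


def column_element_balance(draft: ModelDraft, reaction_id: str,
                           elements: tuple[str, ...] = AUDIT_ELEMENTS) -> dict[str, float]:
    """Formula-weighted element sum of one reaction (zero iff balanced)."""
    rxn = draft.reactions[reaction_id]
    out = {el: 0.0 for el in elements}
    for mid, coef in rxn.stoichiometry.items():
        met = draft.metabolites[mid]
        if met.formula is None:
            raise ValueError(f"metabolite {mid!r} has no formula")
        for el in elements:
            out[el] += coef * met.formula.get(el, 0)
    return out
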