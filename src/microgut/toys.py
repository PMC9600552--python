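"""Bundled toy metabolic networks.

Three hand-written archetype species cover the mechanisms the full AGORA
roster exercises, without any download:

* ``bifid_toy`` — a *Bifidobacterium*-like primary fermenter.  Lactose enters
  the fructose-6-phosphate phosphoketolase (bifid shunt) pathway; pyruvate is
  either reduced to lactate (low-yield, few reaction steps) or dismutated via
  pyruvate-formate lyase into acetate/ethanol/formate (high-yield, more
  steps).  Under the summed-flux enzymatic constraint the optimum switches
  between the two branches with substrate availability.  Lactate can be
  re-imported through the reversible lactate dehydrogenase.
* ``facan_toy`` — a facultative anaerobe (E. coli-like): mixed-acid
  fermentation of lactose, aerobic respiration with far higher ATP per
  lactose whenever oxygen is available, and lactate consumption.
* ``cross_toy`` — a lactate specialist (Veillonella-like secondary consumer):
  ferments lactate to propionate + acetate + CO2 at 1 ATP per lactate, and
  grows only weakly on lactose.

A fourth model, ``broken_toy``, deliberately violates carbon conservation and
exists purely as a negative control for the audits.

All stoichiometries are elementally balanced for C, H, O and N under a
neutral-acid formula convention (redox pairs carry two hydrogens:
NADH = NAD + H2), which the test-suite verifies column by column.
"""

from __future__ import annotations

from .models import (CompiledModel, MetaboliteSpec, ModelDraft, ReactionSpec,
                     compile_model, parse_formula, set_atp_objective)

# Extracellular metabolites use BiGG-style ids with an `_e` suffix; the bare
# id (e.g. "lcts") is the environment key.
EXTRACELLULAR_FORMULAS = {
    "lcts": "C12H22O11",
    "ac": "C2H4O2",
    "lac_L": "C3H6O3",
    "lac_D": "C3H6O3",
    "etoh": "C2H6O",
    "for": "CH2O2",
    "o2": "O2",
    "co2": "CO2",
    "h2o": "H2O",
    "ppa": "C3H6O2",
    "succ": "C4H6O4",
    "h2": "H2",
}

# Approximate standard transformed Gibbs energies of formation at pH 7,
# ionic strength 0.1 M, 298 K (J/mol); literature (Alberty-style) values.
GIBBS_ENERGIES = {
    "lcts": -688_500.0,
    "ac": -249_460.0,
    "lac_L": -316_940.0,
    "lac_D": -316_940.0,
    "etoh": 58_100.0,
    "for": -311_040.0,
    "o2": 16_400.0,
    "co2": -547_100.0,
    "h2o": -155_660.0,
    "ppa": -356_180.0,
    "succ": -530_710.0,
    "h2": 97_510.0,
}

_INTERNAL_FORMULAS = {
    "hex_c": "C6H12O6",      # lumped hexose(-phosphate) pool
    "pyr_c": "C3H4O3",
    "lactl_c": "C3H6O3",     # activated lactoyl unit
    "mmal_c": "C3H6O3",      # lumped methylmalonyl-stage isomer
    "actl_c": "C2H4O2",      # lumped acetyl unit (acetyl-P / acetyl-CoA)
    "atp_c": "C10H16N5O13",  # P atoms omitted: audits cover C,H,O,N
    "adp_c": "C10H15N5O10",
    "pi_c": "H3O4",
    "nad_c": "C21H27N7O14",
    "nadh_c": "C21H29N7O14",
}


def _base_draft(model_id: str, name: str, ex_mets: list[str],
                internal: list[str]) -> ModelDraft:
    draft = ModelDraft(id=model_id, name=name)
    for m in ex_mets:
        draft.add_metabolite(MetaboliteSpec(
            id=f"{m}_e", name=m, compartment="e",
            formula=parse_formula(EXTRACELLULAR_FORMULAS[m]),
            gibbs_energy=GIBBS_ENERGIES[m]))
    for m in internal:
        draft.add_metabolite(MetaboliteSpec(
            id=m, name=m[:-2], compartment="c",
            formula=parse_formula(_INTERNAL_FORMULAS[m])))
    for m in ex_mets:
        draft.add_reaction(ReactionSpec(
            id=f"EX_{m}_e", stoichiometry={f"{m}_e": -1.0}, reversible=True,
            kind="exchange", lower_bound=-float("inf")))
    return draft


def _rxn(draft, rid, stoich, reversible=False, name=""):
    draft.add_reaction(ReactionSpec(
        id=rid, stoichiometry=stoich, reversible=reversible, kind="internal",
        lower_bound=-float("inf") if reversible else 0.0, name=name))


def bifid_toy_draft() -> ModelDraft:
    d = _base_draft("bifid_toy", "BifidToy (bifid-shunt primary fermenter)",
                    ["lcts", "ac", "lac_L", "etoh", "for", "h2o"],
                    ["hex_c", "pyr_c", "actl_c", "atp_c", "adp_c", "pi_c",
                     "nad_c", "nadh_c"])
    _rxn(d, "LACZ", {"lcts_e": -1, "h2o_e": -1, "hex_c": 2},
         name="beta-galactosidase (uptake lumped)")
    # bifid shunt core: F6P phosphoketolase + glycolytic leg, per 2 hexose
    _rxn(d, "F6PPK", {"hex_c": -2, "adp_c": -2, "pi_c": -2, "nad_c": -2,
                      "actl_c": 3, "pyr_c": 2, "nadh_c": 2, "atp_c": 2,
                      "h2o_e": 2},
         name="fructose-6-phosphate phosphoketolase pathway (lumped)")
    _rxn(d, "ACK", {"actl_c": -1, "adp_c": -1, "pi_c": -1,
                    "ac_e": 1, "atp_c": 1, "h2o_e": 1}, name="acetate kinase")
    _rxn(d, "LDH", {"pyr_c": -1, "nadh_c": -1, "lac_L_e": 1, "nad_c": 1},
         reversible=True, name="L-lactate dehydrogenase")
    _rxn(d, "PFL", {"pyr_c": -1, "h2o_e": -1, "actl_c": 1, "for_e": 1},
         name="pyruvate formate-lyase")
    _rxn(d, "ADHE", {"actl_c": -1, "nadh_c": -2, "etoh_e": 1, "nad_c": 2,
                     "h2o_e": 1}, name="aldehyde/alcohol dehydrogenase")
    _rxn(d, "ATPM", {"atp_c": -1, "h2o_e": -1, "adp_c": 1, "pi_c": 1},
         name="ATP drain (objective)")
    set_atp_objective(d)
    return d


def facan_toy_draft() -> ModelDraft:
    d = _base_draft("facan_toy", "FacAnToy (facultative anaerobe)",
                    ["lcts", "ac", "lac_L", "etoh", "for", "o2", "co2", "h2o"],
                    ["hex_c", "pyr_c", "actl_c", "atp_c", "adp_c", "pi_c",
                     "nad_c", "nadh_c"])
    _rxn(d, "LACZ", {"lcts_e": -1, "h2o_e": -1, "hex_c": 2},
         name="beta-galactosidase (uptake lumped)")
    _rxn(d, "GLYC", {"hex_c": -1, "adp_c": -2, "pi_c": -2, "nad_c": -2,
                     "pyr_c": 2, "nadh_c": 2, "atp_c": 2, "h2o_e": 2},
         name="glycolysis (lumped)")
    _rxn(d, "LDH", {"pyr_c": -1, "nadh_c": -1, "lac_L_e": 1, "nad_c": 1},
         reversible=True, name="L-lactate dehydrogenase")
    _rxn(d, "PFL", {"pyr_c": -1, "h2o_e": -1, "actl_c": 1, "for_e": 1},
         name="pyruvate formate-lyase")
    _rxn(d, "ACK", {"actl_c": -1, "adp_c": -1, "pi_c": -1,
                    "ac_e": 1, "atp_c": 1, "h2o_e": 1}, name="acetate kinase")
    _rxn(d, "ADHE", {"actl_c": -1, "nadh_c": -2, "etoh_e": 1, "nad_c": 2,
                     "h2o_e": 1}, name="aldehyde/alcohol dehydrogenase")
    _rxn(d, "PDH", {"pyr_c": -1, "nad_c": -1, "h2o_e": -1,
                    "actl_c": 1, "co2_e": 1, "nadh_c": 1},
         name="pyruvate dehydrogenase")
    _rxn(d, "TCA", {"actl_c": -1, "h2o_e": -2, "nad_c": -4,
                    "co2_e": 2, "nadh_c": 4}, name="citric acid cycle (lumped)")
    _rxn(d, "OXPHOS", {"nadh_c": -2, "o2_e": -1, "adp_c": -4, "pi_c": -4,
                       "nad_c": 2, "atp_c": 4, "h2o_e": 6},
         name="oxidative phosphorylation (lumped, P/O = 2)")
    _rxn(d, "ATPM", {"atp_c": -1, "h2o_e": -1, "adp_c": 1, "pi_c": 1},
         name="ATP drain (objective)")
    set_atp_objective(d)
    return d


def cross_toy_draft() -> ModelDraft:
    d = _base_draft("cross_toy", "CrossToy (lactate cross-feeder)",
                    ["lcts", "lac_L", "ac", "ppa", "co2", "h2o"],
                    ["hex_c", "pyr_c", "lactl_c", "mmal_c", "atp_c", "adp_c",
                     "pi_c", "nad_c", "nadh_c"])
    _rxn(d, "LACZ", {"lcts_e": -1, "h2o_e": -1, "hex_c": 2},
         name="beta-galactosidase (uptake lumped)")
    # inefficient glycolysis: one ATP per hexose, so lactose growth is weak
    _rxn(d, "GLYCL", {"hex_c": -1, "adp_c": -1, "pi_c": -1, "nad_c": -2,
                      "pyr_c": 2, "nadh_c": 2, "atp_c": 1, "h2o_e": 1},
         name="low-yield glycolysis (lumped)")
    _rxn(d, "LDH", {"pyr_c": -1, "nadh_c": -1, "lac_L_e": 1, "nad_c": 1},
         name="L-lactate dehydrogenase")
    # methylmalonyl-style propionate fermentation: 3 lactate -> 2 propionate
    # + acetate + CO2, 1 ATP per lactate.  Deliberately kept as three steps
    # (activation, rearrangement, fermentation) so its summed-flux cost
    # reflects the length of the real pathway.
    _rxn(d, "LACTL", {"lac_L_e": -1, "lactl_c": 1},
         name="lactate activation (lumped lactoyl unit)")
    _rxn(d, "MMM", {"lactl_c": -1, "mmal_c": 1},
         name="methylmalonyl rearrangement (lumped)")
    _rxn(d, "PROPF", {"mmal_c": -3, "adp_c": -3, "pi_c": -3,
                      "ppa_e": 2, "ac_e": 1, "co2_e": 1, "atp_c": 3,
                      "h2o_e": 4},
         name="propionate fermentation of lactate (lumped)")
    _rxn(d, "ATPM", {"atp_c": -1, "h2o_e": -1, "adp_c": 1, "pi_c": 1},
         name="ATP drain (objective)")
    set_atp_objective(d)
    return d


def broken_toy_draft() -> ModelDraft:
    """Negative control: fabricates acetate from water (carbon imbalance)."""
    d = _base_draft("broken_toy", "BrokenToy (mass-imbalance negative control)",
                    ["ac", "h2o"], ["atp_c", "adp_c", "pi_c"])
    _rxn(d, "MAGIC", {"h2o_e": -1, "adp_c": -1, "pi_c": -1,
                      "ac_e": 1, "atp_c": 1},
         name="deliberately unbalanced acetogenesis")
    _rxn(d, "ATPM", {"atp_c": -1, "h2o_e": -1, "adp_c": 1, "pi_c": 1},
         name="ATP drain (objective)")
    set_atp_objective(d)
    return d


TOY_DRAFTS = {
    "bifid_toy": bifid_toy_draft,
    "facan_toy": facan_toy_draft,
    "cross_toy": cross_toy_draft,
}


def build_toy_models(include_broken: bool = False) -> dict[str, CompiledModel]:
    """Compile the toy roster (optionally with the negative control)."""
    drafts = {k: fn() for k, fn in TOY_DRAFTS.items()}
    if include_broken:
        drafts["broken_toy"] = broken_toy_draft()
    return {k: compile_model(d) for k, d in drafts.items()}
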