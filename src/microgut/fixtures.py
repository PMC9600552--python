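"""Deterministic synthetic inputs: toy SBML files, formula and Gibbs-energy
tables, a curation-edit table exercising every edit action, and canned
simulation configurations.  Everything regenerates bit-identically and needs
no network access."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .environment import FeedingSchedule, LatticeGeometry, OxygenRegime
from .models import CurationEdit, write_curation_csv, write_sbml
from .simulate import SimConfig
from .toys import (EXTRACELLULAR_FORMULAS, GIBBS_ENERGIES, broken_toy_draft,
                   TOY_DRAFTS)

TOY_SBML_FILES = {name: f"{name}.xml" for name in TOY_DRAFTS}
TOY_SBML_FILES["broken_toy"] = "broken_toy.xml"


@dataclass
class FixtureBundle:
    root: Path
    sbml: dict[str, Path]
    formula_csv: Path
    gibbs_csv: Path
    curation_csv: Path
    configs: dict[str, SimConfig]


def _example_curation_edits() -> list[CurationEdit]:
    """One edit per supported action, against the bifid toy model."""
    return [
        CurationEdit("bifid_toy", "add_reaction", "LACP", {
            "metabolites": {"lcts_c": {"formula": "C12H22O11",
                                       "compartment": "c",
                                       "name": "intracellular lactose"}},
            "stoichiometry": {"lcts_e": -1, "lcts_c": 1},
            "reversible": False, "kind": "internal"}),
        CurationEdit("bifid_toy", "delete_reaction", "LACP"),
        CurationEdit("bifid_toy", "set_reversible", "LDH",
                     {"reversible": True}),
        CurationEdit("bifid_toy", "set_bounds", "PFL",
                     {"lb": 0.0, "ub": 1e6}),
        CurationEdit("bifid_toy", "set_objective", "ATPM"),
    ]


def desk_config(seed: int = 0, width: int = 60, height: int = 4,
                days: float = 2.0,
                oxygen: OxygenRegime | None = None) -> SimConfig:
    """Reduced-lattice run: full dynamics, truncated gut, shorter horizon.

    The feeding pulse is scaled by height/8 so per-site dosing matches the
    default geometry.
    """
    geometry = LatticeGeometry(width=width, height=height)
    feeding = FeedingSchedule(total=211.0 * height / 8.0)
    return SimConfig(geometry=geometry, feeding=feeding,
                     oxygen=oxygen or OxygenRegime(),
                     horizon=int(days * 480), seed=seed)


def tracer_config(seed: int = 0) -> SimConfig:
    """Mixing-only configuration (used with analysis.track_tracers)."""
    from .population import StochasticConfig
    return SimConfig(
        stochastic=StochasticConfig(death_prob=0.0, colonize_prob=0.0,
                                    init_site_prob=1.0),
        horizon=0, seed=seed)


def generate(seed: int = 0, outdir: str | Path = "fixtures") -> FixtureBundle:
    """Write the full fixture bundle; deterministic for a given seed."""
    root = Path(outdir)
    root.mkdir(parents=True, exist_ok=True)

    sbml: dict[str, Path] = {}
    drafts = {name: fn() for name, fn in TOY_DRAFTS.items()}
    drafts["broken_toy"] = broken_toy_draft()
    for name, draft in drafts.items():
        path = root / TOY_SBML_FILES[name]
        write_sbml(draft, path)
        sbml[name] = path

    formula_csv = root / "formulas.csv"
    pd.DataFrame(
        [{"id": k, "formula": v} for k, v in sorted(EXTRACELLULAR_FORMULAS.items())]
    ).to_csv(formula_csv, index=False)

    gibbs_csv = root / "gibbs.csv"
    pd.DataFrame(
        [{"id": k, "dG_J_per_mol": v} for k, v in sorted(GIBBS_ENERGIES.items())]
    ).to_csv(gibbs_csv, index=False)

    curation_csv = root / "curation.csv"
    write_curation_csv(_example_curation_edits(), curation_csv)

    configs = {
        "anaerobic_desk": desk_config(seed=seed),
        "oxygen_desk": desk_config(
            seed=seed, oxygen=OxygenRegime(mode="initial_uniform", amount=1.0)),
        "tracer": tracer_config(seed=seed),
    }
    return FixtureBundle(root=root, sbml=sbml, formula_csv=formula_csv,
                         gibbs_csv=gibbs_csv, curation_csv=curation_csv,
                         configs=configs)
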