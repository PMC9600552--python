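"""Run-record analyses: fecal output, cross-feeding networks, spatial
profiles, tracer diffusion estimation, and replicate dominance summaries."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .environment import WATER

#: steps in the standard analysis window (last 2 days)
DEFAULT_WINDOW = 960

#: display threshold for cross-feeding edges, umol per window
EDGE_THRESHOLD = 0.5


def _pool_lactate(met: str) -> str:
    """d- and l-lactate are tracked separately but displayed pooled."""
    return "lactate" if met in ("lac_L", "lac_D") else met


def fecal_composition(outflows, window: int = DEFAULT_WINDOW,
                      height: int = 8, site_volume_ml: float = 0.05,
                      pool_lactate: bool = True) -> pd.DataFrame:
    """Composition of the distal outflow over the last ``window`` steps.

    Returns per-metabolite totals (umol), molar fractions (water excluded),
    and the mean concentration in mM obtained by spreading each step's
    outflow over the ``height`` exiting sites of ``site_volume_ml`` each.
    """
    if window > 0 and len(outflows) < window:
        raise ValueError(f"run shorter ({len(outflows)}) than window ({window})")
    tail = outflows[-window:] if window > 0 else []
    totals: dict[str, float] = {}
    for rec in tail:
        for met, amt in rec.amounts.items():
            if met == WATER:
                continue
            key = _pool_lactate(met) if pool_lactate else met
            totals[key] = totals.get(key, 0.0) + amt
    grand = sum(totals.values())
    exit_volume_ml = height * site_volume_ml
    rows = []
    for met in sorted(totals, key=totals.get, reverse=True):
        amt = totals[met]
        rows.append({
            "metabolite": met,
            "total_umol": amt,
            "fraction": amt / grand if grand > 0 else 0.0,
            # mean umol/mL (= mM) of the fluid leaving the system per step
            "concentration_mM": amt / (len(tail) * exit_volume_ml) if tail else 0.0,
        })
    return pd.DataFrame(rows, columns=["metabolite", "total_umol",
                                       "fraction", "concentration_mM"])


def crossfeeding_network(ledger: pd.DataFrame,
                         window: tuple[int, int] | None = None,
                         threshold: float = EDGE_THRESHOLD,
                         pool_lactate: bool = True):
    """Species<->metabolite exchange graph over a step window.

    Green production edges run species -> metabolite, yellow consumption
    edges metabolite -> species; edge weight is the summed umol exchanged in
    the window, and edges below ``threshold`` umol are dropped.  Returns a
    networkx DiGraph with node ``kind`` and edge ``role``/``weight``
    attributes.
    """
    import networkx as nx

    g = nx.DiGraph()
    if len(ledger) == 0:
        return g
    df = ledger
    if window is not None:
        lo, hi = window
        df = df[(df["timestep"] >= lo) & (df["timestep"] < hi)]
    df = df.copy()
    if pool_lactate:
        df["metabolite"] = df["metabolite"].map(_pool_lactate)
    produced = df[df["net_umol"] > 0].groupby(
        ["species", "metabolite"])["net_umol"].sum()
    consumed = (-df[df["net_umol"] < 0].groupby(
        ["species", "metabolite"])["net_umol"].sum())
    for (sp, met), w in produced.items():
        if w >= threshold:
            g.add_node(sp, kind="species")
            g.add_node(met, kind="metabolite")
            g.add_edge(sp, met, weight=float(w), role="production")
    for (sp, met), w in consumed.items():
        if w >= threshold:
            g.add_node(sp, kind="species")
            g.add_node(met, kind="metabolite")
            g.add_edge(met, sp, weight=float(w), role="consumption")
    return g


def network_edge_list(graph) -> pd.DataFrame:
    rows = [{"source": u, "target": v, "role": d["role"], "umol": d["weight"]}
            for u, v, d in graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "target", "role", "umol"])


def spatial_profiles(records, window: int = DEFAULT_WINDOW) -> pd.DataFrame:
    """Per-column mean +- sd of grouped abundance over the window, across runs.

    ``records`` is a list of RunRecord with ``column_abundance`` recorded.
    """
    per_run: dict[str, list[np.ndarray]] = {}
    for rec in records:
        if rec.column_abundance is None:
            raise ValueError("run was recorded without spatial data")
        tail = rec.column_abundance[-window:] if window > 0 \
            else rec.column_abundance
        mean_t = tail.mean(axis=0)          # (n_species, width)
        for i, sp in enumerate(rec.species):
            grp = rec.config.groups.get(sp, "others")
            per_run.setdefault(grp, []).append(mean_t[i])
    rows = []
    for grp, vals in per_run.items():
        arr = np.asarray(vals)
        # pool species of a group within a run before averaging across runs
        mean = arr.mean(axis=0)
        sd = arr.std(axis=0, ddof=0)
        for x in range(arr.shape[1]):
            rows.append({"group": grp, "column": x,
                         "mean_biomass": mean[x], "sd_biomass": sd[x]})
    return pd.DataFrame(rows, columns=["group", "column",
                                       "mean_biomass", "sd_biomass"])


def estimate_diffusion(trajectories: np.ndarray, dx_cm: float = 0.2,
                       dt_s: float = 180.0, fit_steps: int = 50,
                       axis: str = "x") -> float:
    """Diffusion constant (cm^2/s) from tracer mean-squared displacement.

    ``trajectories`` has shape (n_tracers, T+1, 2) in (y, x) lattice
    coordinates.  The MSD of the chosen axis is fit through the origin over
    the first ``fit_steps`` steps (MSD_1d = 2 D t), using one axis to avoid
    the saturation of the narrow lattice dimension.
    """
    traj = np.asarray(trajectories, dtype=float)
    if traj.ndim != 3 or traj.shape[1] < max(fit_steps, 2) + 1:
        raise ValueError("trajectories too short for the requested fit")
    comp = {"y": 0, "x": 1}[axis]
    disp = traj[:, :, comp] - traj[:, :1, comp]
    msd = (disp ** 2).mean(axis=0)
    t = np.arange(traj.shape[1])
    sl = slice(1, fit_steps + 1)
    slope = float((msd[sl] * t[sl]).sum() / (t[sl] ** 2).sum())  # sites^2/step
    return slope * dx_cm**2 / (2.0 * dt_s)


def track_tracers(height: int, width: int, steps: int,
                  rng: np.random.Generator, sweeps: float = 1.0,
                  offsets=None, full_mixing: bool = False) -> np.ndarray:
    """Positions over time of per-site tracer populations under mixing only.

    Every site starts with a unique tracer (no growth, death, or washout);
    returns an array (n_sites, steps+1, 2) of (y, x) positions.
    """
    from .population import MOORE8_SELF, BacterialLattice, mix

    lat = BacterialLattice(height, width)
    n = height * width
    lat.species = np.arange(n, dtype=np.int64).reshape(height, width)
    lat.size[:] = 1.0
    pos = np.empty((n, steps + 1, 2), dtype=np.int64)
    ycoord, xcoord = np.indices((height, width))

    def record(t):
        flat = lat.species.ravel()
        inv = np.empty(n, dtype=np.int64)
        inv[flat] = np.arange(n)
        pos[:, t, 0] = ycoord.ravel()[inv]
        pos[:, t, 1] = xcoord.ravel()[inv]

    record(0)
    for t in range(1, steps + 1):
        mix(lat, rng, sweeps=sweeps,
            offsets=offsets or MOORE8_SELF, full_mixing=full_mixing)
        record(t)
    return pos


def dominance_summary(records) -> pd.DataFrame:
    """Which group is most abundant at the horizon, across replicates.

    Returns one row per group with the dominance count and the distribution
    of its final abundance (for bimodality inspection).
    """
    if not records:
        raise ValueError("need at least one replicate")
    finals: dict[str, list[float]] = {}
    wins: dict[str, int] = {}
    for rec in records:
        ga = rec.group_abundance()
        last = {g: traj[-1] for g, traj in ga.items()}
        winner = max(last, key=last.get)
        wins[winner] = wins.get(winner, 0) + 1
        for g, v in last.items():
            finals.setdefault(g, []).append(v)
    rows = []
    for g in sorted(finals):
        vals = np.asarray(finals[g])
        rows.append({"group": g, "dominant_in": wins.get(g, 0),
                     "n": len(records),
                     "final_abundance_mean": vals.mean(),
                     "final_abundance_values": list(vals)})
    return pd.DataFrame(rows, columns=["group", "dominant_in", "n",
                                       "final_abundance_mean",
                                       "final_abundance_values"])
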