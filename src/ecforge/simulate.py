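"""Flux-balance evaluation of reconstructed models.

All solves are plain LPs via scipy's HiGHS backend: maximize an objective
flux subject to steady state (S v = 0) and flux bounds. On top of that sit
the standard model-quality assays: single-gene knockouts (restricted to
reactions associated with exactly one protein, since gene associations are
flat OR sets without complex gene-protein-reaction logic), phenotype arrays
(swap a default nutrient source for an alternate at 10 mmol/gDW/h and call
growth at >= 1e-4 h^-1), and ATP/biomass yields per mmol of substrate with a
zero-substrate control that flags thermodynamically impossible
energy-generating cycles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import linprog

from .model import MediaDefinition, MetabolicModel, Reaction

__all__ = [
    "SimulationReport",
    "GROWTH_THRESHOLD",
    "PHENOTYPE_UPTAKE",
    "LP_TOL",
    "fba",
    "single_gene_knockouts",
    "phenotype_array",
    "yield_analysis",
    "blocked_reactions",
    "ATP_HYDROLYSIS",
]

GROWTH_THRESHOLD = 1e-4  # h^-1; growth call is inclusive (>=)
PHENOTYPE_UPTAKE = 10.0  # mmol/gDW/h for alternate sources
LP_TOL = 1e-9

# ATP + H2O -> ADP + phosphate + proton; added transiently for ATP yields
ATP_HYDROLYSIS = Reaction(
    id="ATPM_hydrolysis",
    stoichiometry={"atp": -1.0, "h2o": -1.0, "adp": 1.0, "pi": 1.0, "h": 1.0},
    reversible=False,
    name="ATP hydrolysis (maintenance-style)",
)


@dataclass(frozen=True)
class SimulationReport:
    objective_value: float
    status: str
    fluxes: dict[str, float] = field(default_factory=dict)


def fba(
    model: MetabolicModel,
    objective_id: str | None = None,
    media: MediaDefinition | None = None,
) -> SimulationReport:
    """Maximize the objective flux at steady state.

    *media*, when given, overrides exchange lower bounds before solving.
    Infeasibility is reported as a status, not raised. Objective values
    below the LP tolerance are clipped to 0.
    """
    m = media.apply(model) if media is not None else model
    if objective_id is None:
        objective_id = m.objective_id
        if objective_id is None:
            raise ValueError("model has no objective reaction")
    if objective_id not in m.reactions:
        raise ValueError(f"objective reaction {objective_id} not in model")

    S, mets, rxns = m.stoichiometric_matrix()
    lbs, ubs = m.bounds_arrays()
    c = np.zeros(len(rxns))
    c[rxns.index(objective_id)] = -1.0  # linprog minimizes
    res = linprog(
        c,
        A_eq=S,
        b_eq=np.zeros(S.shape[0]),
        bounds=list(zip(lbs, ubs)),
        method="highs",
    )
    if res.status != 0:
        return SimulationReport(0.0, "infeasible" if res.status == 2 else "failed")
    value = float(-res.fun)
    if abs(value) < LP_TOL:
        value = 0.0
    return SimulationReport(
        value, "optimal", {rid: float(v) for rid, v in zip(rxns, res.x)}
    )


def single_gene_knockouts(
    model: MetabolicModel,
    media: MediaDefinition | None = None,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> dict[str, str]:
    """Classify each gene as essential / non-essential / untestable.

    A knockout zeroes the flux of every reaction associated with exactly
    that one gene; genes appearing only in multi-gene reactions cannot be
    assessed under flat OR associations and are reported untestable.
    """
    base = media.apply(model) if media is not None else model.copy()
    calls: dict[str, str] = {}
    sole_reactions: dict[str, list[str]] = {}
    for rid, genes in base.gene_associations.items():
        if len(genes) == 1:
            (g,) = genes
            sole_reactions.setdefault(g, []).append(rid)
    for gene in sorted(base.genes):
        rids = sole_reactions.get(gene)
        if not rids:
            calls[gene] = "untestable"
            continue
        ko = base.copy()
        for rid in rids:
            ko.set_bounds(rid, 0.0, 0.0)
        report = fba(ko)
        grows = report.status == "optimal" and report.objective_value >= growth_threshold
        calls[gene] = "non-essential" if grows else "essential"
    return calls


def phenotype_array(
    model: MetabolicModel,
    base_media: MediaDefinition,
    swaps: Sequence[tuple[str, str, str]],
    uptake: float = PHENOTYPE_UPTAKE,
    growth_threshold: float = GROWTH_THRESHOLD,
) -> list[dict]:
    """Simulate nutrient-source swap arrays.

    Each swap is ``(element, default_exchange, alternate_exchange)``: the
    default source's uptake is blocked, the alternate's enabled at *uptake*
    mmol/gDW/h, and growth is called positive when the biomass optimum is at
    least *growth_threshold* (inclusive). Swaps whose alternate exchange is
    missing from the model are recorded as untestable.
    """
    rows: list[dict] = []
    for element, default_ex, alt_ex in swaps:
        row = {"element": element, "default": default_ex, "alternate": alt_ex}
        if alt_ex not in model.reactions:
            row.update(growth=None, call="untestable")
            rows.append(row)
            continue
        rates = dict(base_media.uptake_rates)
        rates.pop(default_ex, None)
        rates[alt_ex] = uptake
        media = MediaDefinition(
            uptake_rates=rates,
            aerobic=base_media.aerobic,
            oxygen_exchange=base_media.oxygen_exchange,
            oxygen_uptake=base_media.oxygen_uptake,
        )
        report = fba(model, media=media)
        growth = report.objective_value if report.status == "optimal" else 0.0
        row.update(
            growth=growth,
            call="positive" if growth >= growth_threshold else "negative",
        )
        rows.append(row)
    return rows


def yield_analysis(
    model: MetabolicModel,
    carbon_exchange: str,
    aerobic: bool = True,
    objective: str = "biomass",
    media: MediaDefinition | None = None,
    substrate_uptake: float = 1.0,
    oxygen_exchange: str = "EX_o2",
) -> dict:
    """Yield of biomass or ATP per mmol of the carbon substrate.

    The substrate uptake is fixed at *substrate_uptake* (1 mmol/gDW/h by
    default); under anaerobic conditions the oxygen uptake is constrained to
    zero. For ``objective='atp_hydrolysis'`` an ATP hydrolysis reaction
    (ATP + H2O -> ADP + phosphate + proton) is added transiently if absent
    and maximized instead of biomass. A zero-substrate control is always run:
    a nonzero control objective reveals an energy-generating cycle.
    """
    if carbon_exchange not in model.reactions:
        raise ValueError(f"carbon exchange {carbon_exchange} not in model")
    m = media.apply(model) if media is not None else model.copy()
    if objective == "atp_hydrolysis":
        if ATP_HYDROLYSIS.id not in m.reactions:
            missing = [
                x for x in ATP_HYDROLYSIS.stoichiometry if x not in set(m.metabolites)
            ]
            if missing:
                raise ValueError(
                    f"cannot add ATP hydrolysis: metabolites {missing} absent"
                )
            m.add_reaction(ATP_HYDROLYSIS)
        obj_id = ATP_HYDROLYSIS.id
    elif objective == "biomass":
        obj_id = m.objective_id
        if obj_id is None:
            raise ValueError("model has no biomass objective")
    else:
        raise ValueError(f"unknown objective {objective!r}")

    if not aerobic and oxygen_exchange in m.reactions:
        ub = m.reactions[oxygen_exchange].upper_bound
        m.set_bounds(oxygen_exchange, 0.0, ub)

    # substrate fixed at the stated uptake
    trial = m.copy()
    trial.set_bounds(carbon_exchange, -substrate_uptake, -substrate_uptake)
    rep = fba(trial, objective_id=obj_id)

    control = m.copy()
    control.set_bounds(carbon_exchange, 0.0, control.reactions[carbon_exchange].upper_bound)
    ctrl = fba(control, objective_id=obj_id)

    return {
        "objective": objective,
        "carbon_exchange": carbon_exchange,
        "aerobic": aerobic,
        "yield": rep.objective_value if rep.status == "optimal" else 0.0,
        "status": rep.status,
        "zero_substrate_control": ctrl.objective_value
        if ctrl.status == "optimal"
        else 0.0,
        "energy_cycle_detected": ctrl.status == "optimal"
        and ctrl.objective_value > LP_TOL,
    }


def blocked_reactions(model: MetabolicModel, tol: float = LP_TOL) -> set[str]:
    """Reactions unable to carry flux in either direction under the model's
    current bounds (per-reaction flux-variability check)."""
    S, mets, rxns = model.stoichiometric_matrix()
    lbs, ubs = model.bounds_arrays()
    blocked: set[str] = set()
    for j, rid in enumerate(rxns):
        c = np.zeros(len(rxns))
        c[j] = -1.0  # maximize v_j
        res_max = linprog(
            c, A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lbs, ubs)), method="highs",
        )
        vmax = -res_max.fun if res_max.status == 0 else 0.0
        if vmax > tol:
            continue
        res_min = linprog(
            -c, A_eq=S, b_eq=np.zeros(S.shape[0]),
            bounds=list(zip(lbs, ubs)), method="highs",
        )
        vmin = res_min.fun if res_min.status == 0 else 0.0
        if abs(vmin) <= tol and abs(vmax) <= tol:
            blocked.add(rid)
    return blocked
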