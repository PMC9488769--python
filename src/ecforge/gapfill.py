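"""Likelihood-weighted gap-filling of draft metabolic models.

The candidate pool R combines (1) database reactions whose ECs were
predicted at low confidence (0.0001 < score <= 0.5) — each such reaction
takes the highest score s_i among its low-confidence EC annotations — or at
no confidence at all, and (2) synthesized exchange reactions for dead-end
metabolites. Scored candidates are normalized to a median of 1,

    s'_i = s_i / s_M,        p_i = 1 / (1 + s'_i),

so a higher annotation likelihood means a cheaper reaction; unscored
candidates and dead-end exchanges default to penalty 1 (raising the dead-end
penalty, e.g. to 10, forces the model onto user-specified media). The MILP

    minimize  sum_{i in R} p_i y_i
    s.t.      S v = 0
              v_L <= v <= v_U
              y_i v_{L,i} <= v_i <= y_i v_{U,i}   for i in R
              y_i in {0, 1}
              c^T v >= beta

then selects the minimum-penalty subset that lets the objective (biomass)
carry at least beta flux (0.1 h^-1 by default). Solved with scipy's HiGHS
backend.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import sparse
from scipy.optimize import Bounds, LinearConstraint, milp

from .ensemble import ScoredAnnotation
from .model import DEFAULT_FLUX_BOUND, MetabolicModel, Reaction
from .reaction_db import ReactionDatabase

__all__ = [
    "GapFillCandidate",
    "GapFillProblem",
    "GapFillResult",
    "GapFillInfeasibleError",
    "LOW_CONF_FLOOR",
    "DEFAULT_BETA",
    "find_dead_end_metabolites",
    "dead_end_exchange",
    "build_candidate_pool",
    "compute_penalties",
    "solve_gapfill_milp",
    "augment_model",
    "gapfill",
]

LOW_CONF_FLOOR = 0.0001  # scores at or below this are treated as unscored
DEFAULT_BETA = 0.1  # minimum objective flux, h^-1
INTEGRALITY_TOL = 1e-6
FEASIBILITY_TOL = 1e-9


class GapFillInfeasibleError(RuntimeError):
    """No candidate subset permits the required objective flux."""

    def __init__(self, message: str, unreachable: set[str] | None = None):
        super().__init__(message)
        self.unreachable = unreachable or set()


@dataclass(frozen=True)
class GapFillCandidate:
    reaction: Reaction
    kind: str  # low_conf_ec | no_conf | deadend_exchange
    raw_score: float | None = None
    scaled_score: float | None = None
    penalty: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("low_conf_ec", "no_conf", "deadend_exchange"):
            raise ValueError(f"unknown candidate kind {self.kind!r}")
        if self.kind == "low_conf_ec":
            if self.raw_score is None or not (LOW_CONF_FLOOR < self.raw_score <= 0.5):
                raise ValueError(
                    f"{self.reaction.id}: low-confidence score must lie in "
                    f"({LOW_CONF_FLOOR}, 0.5], got {self.raw_score}"
                )
        if self.penalty is not None and self.penalty <= 0:
            raise ValueError(f"{self.reaction.id}: penalty must be positive")


@dataclass
class GapFillProblem:
    model: MetabolicModel
    candidates: list[GapFillCandidate]
    beta: float = DEFAULT_BETA

    def __post_init__(self) -> None:
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        overlap = {c.reaction.id for c in self.candidates} & set(self.model.reactions)
        if overlap:
            raise ValueError(f"candidates overlap the base model: {sorted(overlap)}")
        if any(c.penalty is None for c in self.candidates):
            raise ValueError("candidates must carry penalties (run compute_penalties)")


@dataclass(frozen=True)
class GapFillResult:
    selected: tuple[str, ...]
    objective_value: float  # sum of penalties of the selection
    biomass_flux: float
    status: str
    fluxes: dict[str, float] = field(default_factory=dict)


def find_dead_end_metabolites(model: MetabolicModel) -> set[str]:
    """Metabolites that can never be produced or never be consumed.

    A reaction produces a metabolite if a positive coefficient can carry
    forward flux (upper bound > 0) or a negative coefficient can carry
    reverse flux (lower bound < 0); consumption is symmetric. Isolated
    metabolites count as dead ends.
    """
    producible: set[str] = set()
    consumable: set[str] = set()
    for rxn in model.reactions.values():
        lb, ub = rxn.bounds
        for met, coef in rxn.stoichiometry.items():
            if (coef > 0 and ub > 0) or (coef < 0 and lb < 0):
                producible.add(met)
            if (coef < 0 and ub > 0) or (coef > 0 and lb < 0):
                consumable.add(met)
    mets = set(model.metabolites)
    return (mets - producible) | (mets - consumable)


def dead_end_exchange(
    metabolite: str, needs_supply: bool, bound: float = DEFAULT_FLUX_BOUND
) -> Reaction:
    """Synthesize an exchange for a dead-end metabolite: a drain by default,
    reversible (allowing supply) when the metabolite is consumed-only."""
    return Reaction(
        id=f"EX_{metabolite}",
        stoichiometry={metabolite: -1.0},
        reversible=needs_supply,
        lower_bound=-bound if needs_supply else 0.0,
        upper_bound=bound,
        name=f"dead-end exchange for {metabolite}",
    )


def build_candidate_pool(
    db: ReactionDatabase,
    scored: Sequence[ScoredAnnotation],
    model: MetabolicModel,
    include_no_conf: bool = True,
    synthesize_deadend_exchanges: bool = True,
) -> list[GapFillCandidate]:
    """Assemble the candidate pool R from the database and the annotation
    scores, excluding reactions already in the model.

    Per-EC evidence is summarized by the best score over proteins; a
    reaction's s_i is the highest score among its low-confidence ECs. ECs
    predicted at high confidence do not demote their reactions into the pool.
    Dead-end exchanges are synthesized against the combined base+candidate
    network so that metabolites orphaned even after all candidate reactions
    are considered get a boundary route.
    """
    best_ec_score: dict[str, float] = {}
    high_conf_ecs: set[str] = set()
    for ann in scored:
        if ann.high_confidence:
            high_conf_ecs.add(ann.ec)
        if ann.likelihood_score is not None:
            prev = best_ec_score.get(ann.ec)
            if prev is None or ann.likelihood_score > prev:
                best_ec_score[ann.ec] = ann.likelihood_score

    pool: dict[str, GapFillCandidate] = {}
    for rid, rxn in db.reactions.items():
        if rid in model.reactions:
            continue
        if rxn.ec_links & high_conf_ecs:
            continue  # already high-confidence: belongs in the base model
        low_scores = [
            best_ec_score[ec]
            for ec in rxn.ec_links
            if ec in best_ec_score
            and LOW_CONF_FLOOR < best_ec_score[ec] <= 0.5
        ]
        if low_scores:
            pool[rid] = GapFillCandidate(
                reaction=rxn, kind="low_conf_ec", raw_score=max(low_scores)
            )
        elif include_no_conf:
            pool[rid] = GapFillCandidate(reaction=rxn, kind="no_conf")

    candidates = [pool[rid] for rid in sorted(pool)]

    if synthesize_deadend_exchanges:
        combined = model.copy()
        for cand in candidates:
            combined.add_reaction(cand.reaction)
        dead = find_dead_end_metabolites(combined)
        # classify: metabolites nobody can produce need a supply route
        producible: set[str] = set()
        for rxn in combined.reactions.values():
            lb, ub = rxn.bounds
            for met, coef in rxn.stoichiometry.items():
                if (coef > 0 and ub > 0) or (coef < 0 and lb < 0):
                    producible.add(met)
        for met in sorted(dead):
            ex = dead_end_exchange(met, needs_supply=met not in producible)
            if ex.id not in combined.reactions and ex.id not in pool:
                candidates.append(
                    GapFillCandidate(reaction=ex, kind="deadend_exchange")
                )
    return candidates


def compute_penalties(
    candidates: Sequence[GapFillCandidate],
    default_penalty: float = 1.0,
    deadend_penalty: float = 1.0,
) -> list[GapFillCandidate]:
    """Scale scored candidates to median 1 and convert scores to penalties.

    s'_i = s_i / s_M with s_M the median raw score (midpoint interpolation
    for even counts); p_i = 1/(1+s'_i). Unscored candidates get
    *default_penalty*; synthesized dead-end exchanges get *deadend_penalty*.
    """
    if default_penalty <= 0 or deadend_penalty <= 0:
        raise ValueError("penalties must be positive")
    scored = [c for c in candidates if c.kind == "low_conf_ec"]
    out: list[GapFillCandidate] = []
    s_m = None
    if scored:
        s_m = statistics.median(c.raw_score for c in scored)  # type: ignore[arg-type]
        if s_m <= 0:
            raise ValueError("median of raw scores must be positive")
    for c in candidates:
        if c.kind == "low_conf_ec":
            assert s_m is not None
            s_prime = c.raw_score / s_m  # type: ignore[operator]
            out.append(
                replace(c, scaled_score=s_prime, penalty=1.0 / (1.0 + s_prime))
            )
        elif c.kind == "deadend_exchange":
            out.append(replace(c, penalty=deadend_penalty))
        else:
            out.append(replace(c, penalty=default_penalty))
    return out


def _combined_arrays(problem: GapFillProblem):
    model = problem.model
    combined = model.copy()
    for cand in problem.candidates:
        combined.add_reaction(cand.reaction)
    S, mets, rxns = combined.stoichiometric_matrix()
    lbs, ubs = combined.bounds_arrays()
    c = np.zeros(len(rxns))
    for rid, coef in model.objective.items():
        c[rxns.index(rid)] = coef
    cand_idx = {cand.reaction.id: rxns.index(cand.reaction.id) for cand in problem.candidates}
    return combined, S, mets, rxns, lbs, ubs, c, cand_idx


def solve_gapfill_milp(
    problem: GapFillProblem, deterministic_tie_break: bool = False
) -> GapFillResult:
    """Solve the minimum-penalty gap-filling MILP with HiGHS.

    With *deterministic_tie_break*, equal-penalty optima are broken towards
    lexicographically smaller reaction ids (a vanishing perturbation of the
    objective); the reported objective value is always the exact penalty sum
    of the returned selection.
    """
    if not problem.model.objective:
        raise ValueError("model has no objective reaction")
    combined, S, mets, rxns, lbs, ubs, c_obj, cand_idx = _combined_arrays(problem)
    n_v = len(rxns)
    n_y = len(problem.candidates)

    # variable vector x = [v, y]
    lo = np.concatenate([np.minimum(lbs, 0.0), np.zeros(n_y)])
    hi = np.concatenate([np.maximum(ubs, 0.0), np.ones(n_y)])
    # base (non-candidate) reactions keep their own bounds
    cand_cols = set(cand_idx.values())
    for j in range(n_v):
        if j not in cand_cols:
            lo[j], hi[j] = lbs[j], ubs[j]

    obj = np.zeros(n_v + n_y)
    for i, cand in enumerate(problem.candidates):
        obj[n_v + i] = cand.penalty  # type: ignore[assignment]
        if deterministic_tie_break:
            obj[n_v + i] += 1e-9 * sorted(cand_idx).index(cand.reaction.id)

    constraints = []
    # S v = 0
    A_mass = sparse.hstack([S, sparse.csr_matrix((S.shape[0], n_y))])
    constraints.append(LinearConstraint(A_mass, 0.0, 0.0))
    # coupling: v_i - y_i vU_i <= 0 and v_i - y_i vL_i >= 0
    rows_u, rows_l = [], []
    for i, cand in enumerate(problem.candidates):
        j = cand_idx[cand.reaction.id]
        ru = np.zeros(n_v + n_y)
        ru[j] = 1.0
        ru[n_v + i] = -ubs[j]
        rows_u.append(ru)
        rl = np.zeros(n_v + n_y)
        rl[j] = 1.0
        rl[n_v + i] = -lbs[j]
        rows_l.append(rl)
    if rows_u:
        constraints.append(
            LinearConstraint(np.array(rows_u), -np.inf, 0.0)
        )
        constraints.append(LinearConstraint(np.array(rows_l), 0.0, np.inf))
    # biomass floor c^T v >= beta
    c_row = np.concatenate([c_obj, np.zeros(n_y)])
    constraints.append(LinearConstraint(c_row, problem.beta, np.inf))

    integrality = np.concatenate([np.zeros(n_v), np.ones(n_y)])
    res = milp(
        c=obj,
        constraints=constraints,
        integrality=integrality,
        bounds=Bounds(lo, hi),
        options={"mip_rel_gap": 0.0, "presolve": True},
    )
    if res.status != 0 or res.x is None:
        unreachable = _unreachable_objective_precursors(combined, problem)
        raise GapFillInfeasibleError(
            "gap-filling MILP infeasible: the objective cannot reach "
            f"beta={problem.beta} even with all {n_y} candidates; "
            f"unproducible objective precursors: {sorted(unreachable) or 'none found'}",
            unreachable,
        )
    x = res.x
    selected = tuple(
        cand.reaction.id
        for i, cand in enumerate(problem.candidates)
        if x[n_v + i] > 0.5
    )
    penalty_by_id = {c.reaction.id: c.penalty for c in problem.candidates}
    fluxes = {rid: float(x[j]) for j, rid in enumerate(rxns)}
    return GapFillResult(
        selected=selected,
        objective_value=float(sum(penalty_by_id[r] for r in selected)),  # type: ignore[misc]
        biomass_flux=float(c_row @ x),
        status="optimal",
        fluxes=fluxes,
    )


def _unreachable_objective_precursors(
    combined: MetabolicModel, problem: GapFillProblem
) -> set[str]:
    """Objective substrates that remain unproducible even with every
    candidate admitted — reported on infeasibility."""
    obj_id = problem.model.objective_id
    if obj_id is None:
        return set()
    substrates = {
        m for m, c in combined.reactions[obj_id].stoichiometry.items() if c < 0
    }
    producible: set[str] = set()
    for rxn in combined.reactions.values():
        lb, ub = rxn.bounds
        for met, coef in rxn.stoichiometry.items():
            if (coef > 0 and ub > 0) or (coef < 0 and lb < 0):
                producible.add(met)
    return substrates - producible


def augment_model(
    model: MetabolicModel,
    result: GapFillResult,
    candidates: Sequence[GapFillCandidate],
    beta: float = DEFAULT_BETA,
) -> MetabolicModel:
    """Add the selected reactions (provenance ``gapfill``, penalty recorded)
    and re-verify by one LP solve that the objective reaches *beta*."""
    if result.status != "optimal":
        raise ValueError(f"cannot augment from a {result.status} result")
    by_id = {c.reaction.id: c for c in candidates}
    out = model.copy()
    for rid in result.selected:
        cand = by_id[rid]
        out.add_reaction(cand.reaction, provenance="gapfill")
        out.gapfill_penalties[rid] = float(cand.penalty)  # type: ignore[arg-type]

    from .simulate import fba

    report = fba(out)
    if report.status != "optimal" or report.objective_value < beta - 1e-6:
        raise RuntimeError(
            "internal consistency failure: augmented model does not attain "
            f"beta={beta} (LP status {report.status}, "
            f"objective {report.objective_value})"
        )
    return out


def gapfill(
    model: MetabolicModel,
    db: ReactionDatabase,
    scored: Sequence[ScoredAnnotation],
    beta: float = DEFAULT_BETA,
    default_penalty: float = 1.0,
    deadend_penalty: float = 1.0,
    include_no_conf: bool = True,
    deterministic_tie_break: bool = False,
) -> tuple[MetabolicModel, GapFillResult, list[GapFillCandidate]]:
    """End-to-end convenience wrapper: pool, penalties, MILP, augmentation."""
    candidates = compute_penalties(
        build_candidate_pool(db, scored, model, include_no_conf=include_no_conf),
        default_penalty=default_penalty,
        deadend_penalty=deadend_penalty,
    )
    problem = GapFillProblem(model=model, candidates=candidates, beta=beta)
    result = solve_gapfill_milp(problem, deterministic_tie_break=deterministic_tie_break)
    if result.selected:
        augmented = augment_model(model, result, candidates, beta=beta)
    else:
        augmented = model.copy()
    return augmented, result, candidates
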