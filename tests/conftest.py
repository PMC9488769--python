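"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.optimize import linprog

from ecforge import fixtures as fx
from ecforge.model import MetabolicModel, Reaction


def lp_max_objective(model: MetabolicModel, objective_id: str | None = None) -> float:
    """Independent LP solve (direct scipy call) of max objective flux.

    Used as the oracle for FBA and gap-fill feasibility checks so that the
    implementation under test never verifies itself.
    """
    objective_id = objective_id or model.objective_id
    S, mets, rxns = model.stoichiometric_matrix()
    lbs, ubs = model.bounds_arrays()
    c = np.zeros(len(rxns))
    c[rxns.index(objective_id)] = -1.0
    res = linprog(
        c, A_eq=S, b_eq=np.zeros(S.shape[0]), bounds=list(zip(lbs, ubs)),
        method="highs",
    )
    if res.status != 0:
        return float("-inf")
    return float(-res.fun)


def enumerate_min_penalty(model, candidates, beta):
    """Brute-force oracle for the gap-filling MILP: try candidate subsets in
    ascending penalty order and return (penalty, subset) of the first one
    that lets the objective reach beta, or None if none does."""
    n = len(candidates)
    order = sorted(
        range(1 << n),
        key=lambda mask: sum(
            candidates[i].penalty for i in range(n) if mask >> i & 1
        ),
    )
    for mask in order:
        m = model.copy()
        chosen = []
        for i in range(n):
            if mask >> i & 1:
                m.add_reaction(candidates[i].reaction)
                chosen.append(candidates[i].reaction.id)
        if lp_max_objective(m) >= beta - 1e-9:
            pen = sum(candidates[i].penalty for i in range(n) if mask >> i & 1)
            return pen, frozenset(chosen)
    return None


def two_bin_profile(tool: str, ecs, high_cutoff: float = 0.5, binary: bool = False):
    from ecforge.prediction_io import ToolProfile

    return ToolProfile(
        tool_name=tool,
        score_kind="binary" if binary else "probability",
        confidence_bins=(("low", 0.0, high_cutoff), ("high", high_cutoff, 1.0)),
        high_conf_bin="high",
        predictive_range=frozenset(ecs),
    )


@pytest.fixture
def chain3():
    return fx.synth_network("chain", size=3, seed=1)


@pytest.fixture
def toy_model():
    """EX_A -> A->B -> biomass, unit stoichiometry, uptake bound 1."""
    m = MetabolicModel(id="toy")
    m.add_reaction(
        Reaction(id="EX_A", stoichiometry={"A": -1.0}, reversible=True,
                 lower_bound=-1.0)
    )
    m.add_reaction(
        Reaction(id="R_AB", stoichiometry={"A": -1.0, "B": 1.0},
                 ec_links=frozenset({"1.1.1.1"})),
        genes=["g1"],
    )
    m.add_reaction(Reaction(id="biomass", stoichiometry={"B": -1.0}))
    m.set_objective("biomass")
    return m
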