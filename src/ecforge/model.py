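"""Constraint-based model container shared across the reconstruction stages.

A :class:`MetabolicModel` is a single-compartment stoichiometric network:
reactions with flux bounds, a sparse stoichiometric matrix S (metabolites x
reactions), flat-OR gene associations, and one linear objective. Substrates
carry negative coefficients, products positive. Reversible reactions default
to bounds (-1000, 1000) and irreversible to (0, 1000), the usual COBRA-style
convention.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
from scipy import sparse

__all__ = ["Reaction", "MetabolicModel", "MediaDefinition", "DEFAULT_FLUX_BOUND"]

DEFAULT_FLUX_BOUND = 1000.0


@dataclass(frozen=True)
class Reaction:
    id: str
    stoichiometry: Mapping[str, float]
    reversible: bool = False
    ec_links: frozenset[str] = frozenset()
    spontaneous: bool = False
    lower_bound: float | None = None
    upper_bound: float | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if not self.stoichiometry:
            raise ValueError(f"{self.id}: empty stoichiometry")
        if any(c == 0 for c in self.stoichiometry.values()):
            raise ValueError(f"{self.id}: zero stoichiometric coefficient")
        lb = self.lower_bound
        ub = self.upper_bound
        if lb is None:
            lb = -DEFAULT_FLUX_BOUND if self.reversible else 0.0
        if ub is None:
            ub = DEFAULT_FLUX_BOUND
        if lb > ub:
            raise ValueError(f"{self.id}: lower bound {lb} exceeds upper bound {ub}")
        object.__setattr__(self, "lower_bound", float(lb))
        object.__setattr__(self, "upper_bound", float(ub))
        object.__setattr__(self, "ec_links", frozenset(self.ec_links))
        object.__setattr__(self, "stoichiometry", dict(self.stoichiometry))

    @property
    def bounds(self) -> tuple[float, float]:
        return (self.lower_bound, self.upper_bound)  # type: ignore[return-value]

    @property
    def is_exchange(self) -> bool:
        """Boundary reactions touch exactly one metabolite."""
        return len(self.stoichiometry) == 1

    def with_bounds(self, lower: float, upper: float) -> "Reaction":
        return replace(self, lower_bound=lower, upper_bound=upper)

    def equation(self) -> str:
        subs = sorted((m, -c) for m, c in self.stoichiometry.items() if c < 0)
        prods = sorted((m, c) for m, c in self.stoichiometry.items() if c > 0)

        def side(terms):
            return " + ".join(
                m if c == 1 else f"{c:g} {m}" for m, c in terms
            )

        arrow = "<=>" if self.reversible else "-->"
        return f"{side(subs)} {arrow} {side(prods)}".strip()


@dataclass
class MetabolicModel:
    """Reactions, bounds, gene associations and the objective vector."""

    id: str = "model"
    reactions: dict[str, Reaction] = field(default_factory=dict)
    gene_associations: dict[str, set[str]] = field(default_factory=dict)
    objective: dict[str, float] = field(default_factory=dict)
    provenance: dict[str, str] = field(default_factory=dict)
    gapfill_penalties: dict[str, float] = field(default_factory=dict)

    def add_reaction(
        self,
        reaction: Reaction,
        genes: Iterable[str] = (),
        provenance: str | None = None,
    ) -> None:
        if reaction.id in self.reactions:
            raise ValueError(f"duplicate reaction id {reaction.id}")
        self.reactions[reaction.id] = reaction
        genes = set(genes)
        if genes:
            self.gene_associations.setdefault(reaction.id, set()).update(genes)
        if provenance is not None:
            self.provenance[reaction.id] = provenance

    def set_bounds(self, reaction_id: str, lower: float, upper: float) -> None:
        self.reactions[reaction_id] = self.reactions[reaction_id].with_bounds(
            lower, upper
        )

    @property
    def reaction_ids(self) -> list[str]:
        return list(self.reactions)

    @property
    def metabolites(self) -> list[str]:
        seen: dict[str, None] = {}
        for rxn in self.reactions.values():
            for m in rxn.stoichiometry:
                seen.setdefault(m)
        return list(seen)

    @property
    def genes(self) -> set[str]:
        out: set[str] = set()
        for gs in self.gene_associations.values():
            out |= gs
        return out

    @property
    def exchanges(self) -> list[str]:
        return [r.id for r in self.reactions.values() if r.is_exchange]

    def stoichiometric_matrix(
        self,
    ) -> tuple[sparse.csr_matrix, list[str], list[str]]:
        """S (metabolites x reactions) plus the row and column orderings."""
        mets = self.metabolites
        rxns = self.reaction_ids
        mix = {m: i for i, m in enumerate(mets)}
        rows, cols, vals = [], [], []
        for j, rid in enumerate(rxns):
            for m, c in self.reactions[rid].stoichiometry.items():
                rows.append(mix[m])
                cols.append(j)
                vals.append(float(c))
        S = sparse.csr_matrix(
            (vals, (rows, cols)), shape=(len(mets), len(rxns))
        )
        return S, mets, rxns

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lbs = np.array([self.reactions[r].lower_bound for r in self.reaction_ids])
        ubs = np.array([self.reactions[r].upper_bound for r in self.reaction_ids])
        return lbs, ubs

    def objective_vector(self) -> np.ndarray:
        c = np.zeros(len(self.reactions))
        ids = self.reaction_ids
        for rid, coef in self.objective.items():
            if rid not in self.reactions:
                raise ValueError(f"objective refers to unknown reaction {rid}")
            c[ids.index(rid)] = coef
        return c

    def set_objective(self, reaction_id: str, coefficient: float = 1.0) -> None:
        if reaction_id not in self.reactions:
            raise ValueError(f"unknown objective reaction {reaction_id}")
        self.objective = {reaction_id: coefficient}

    @property
    def objective_id(self) -> str | None:
        return next(iter(self.objective), None)

    def copy(self) -> "MetabolicModel":
        m = MetabolicModel(id=self.id)
        m.reactions = dict(self.reactions)
        m.gene_associations = {k: set(v) for k, v in self.gene_associations.items()}
        m.objective = dict(self.objective)
        m.provenance = dict(self.provenance)
        m.gapfill_penalties = dict(self.gapfill_penalties)
        return m

    def validate(self) -> None:
        for rid, coef in self.objective.items():
            if rid not in self.reactions:
                raise ValueError(f"objective reaction {rid} missing")
        for rid in self.gene_associations:
            if rid not in self.reactions:
                raise ValueError(f"gene association for unknown reaction {rid}")
        for rxn in self.reactions.values():
            if not (
                rxn.lower_bound <= rxn.upper_bound
                and math.isfinite(rxn.lower_bound)
                and math.isfinite(rxn.upper_bound)
            ):
                raise ValueError(f"{rxn.id}: invalid bounds {rxn.bounds}")


@dataclass(frozen=True)
class MediaDefinition:
    """Maximum uptake rates (mmol/gDW/h) per exchange reaction.

    Applying a media closes every exchange not listed (uptake lower bound 0)
    and opens listed ones to ``lower bound = -rate``. The aerobic flag opens
    or closes the oxygen exchange if the model has one.
    """

    uptake_rates: Mapping[str, float] = field(default_factory=dict)
    aerobic: bool = True
    oxygen_exchange: str = "EX_o2"
    oxygen_uptake: float = DEFAULT_FLUX_BOUND

    def __post_init__(self) -> None:
        if any(v < 0 for v in self.uptake_rates.values()):
            raise ValueError("uptake rates must be nonnegative")
        object.__setattr__(self, "uptake_rates", dict(self.uptake_rates))

    def apply(self, model: MetabolicModel) -> MetabolicModel:
        m = model.copy()
        for rid in m.exchanges:
            rxn = m.reactions[rid]
            if rid in self.uptake_rates:
                m.set_bounds(rid, -float(self.uptake_rates[rid]), rxn.upper_bound)
            elif rid == self.oxygen_exchange:
                m.set_bounds(
                    rid, -self.oxygen_uptake if self.aerobic else 0.0, rxn.upper_bound
                )
            else:
                m.set_bounds(rid, 0.0, rxn.upper_bound)
        return m
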