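"""Assemble the high-confidence draft model.

The draft collates (i) every database reaction linked to a high-confidence
EC annotation (indiscriminate inclusion: multi-reaction ECs contribute all
their reactions), (ii) spontaneous reactions if requested, (iii) the user's
reactions — exactly one of which must be designated the objective, typically
biomass — and (iv) on the BiGG-like path only, non-EC reactions supported by
sequence similarity. Gene associations are flat OR sets: every protein whose
high-confidence EC links to a reaction supports it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .model import MediaDefinition, MetabolicModel, Reaction
from .reaction_db import ReactionDatabase, parse_equation, reactions_for_ecs

__all__ = [
    "UserReaction",
    "read_user_reactions",
    "read_media",
    "assemble_draft",
]

# provenance priority when one reaction arrives through several routes
_PROVENANCE_ORDER = ("user", "ec_high_conf", "similarity", "spontaneous")


@dataclass(frozen=True)
class UserReaction:
    reaction: Reaction
    is_objective: bool = False


def read_user_reactions(path) -> list[UserReaction]:
    """TSV columns: reaction_id, equation, lower_bound, upper_bound, objective."""
    df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
    out: list[UserReaction] = []
    for i, row in enumerate(df.itertuples(index=False)):
        stoich, reversible = parse_equation(str(row.equation))
        lb = float(row.lower_bound) if str(row.lower_bound) else None
        ub = float(row.upper_bound) if str(row.upper_bound) else None
        out.append(
            UserReaction(
                Reaction(
                    id=str(row.reaction_id),
                    stoichiometry=stoich,
                    reversible=reversible,
                    lower_bound=lb,
                    upper_bound=ub,
                ),
                is_objective=str(getattr(row, "objective", "")).strip().lower()
                in ("1", "true", "yes"),
            )
        )
    return out


def read_media(path, aerobic: bool = True) -> MediaDefinition:
    """TSV columns: exchange_id, max_uptake (mmol/gDW/h)."""
    df = pd.read_csv(path, sep="\t")
    return MediaDefinition(
        uptake_rates={
            str(r.exchange_id): float(r.max_uptake) for r in df.itertuples(index=False)
        },
        aerobic=aerobic,
    )


def assemble_draft(
    high_conf: Iterable[tuple[str, str]],
    db: ReactionDatabase,
    user_reactions: Iterable[UserReaction],
    similarity_reactions: Mapping[str, set[str]] | None = None,
    include_spontaneous: bool = True,
    model_id: str = "draft",
) -> tuple[MetabolicModel, set[str]]:
    """Build the draft model from high-confidence (protein, EC) annotations.

    Returns ``(model, uncovered_ecs)`` where the second element lists
    high-confidence ECs with no reaction in the database. Raises
    ``ValueError`` unless exactly one user reaction is flagged as the
    objective. Similarity-supported reactions are only admitted for a
    BiGG-like database; on the KEGG-like path they are ignored with a
    warning.
    """
    high_conf = set(high_conf)
    user_reactions = list(user_reactions)
    objectives = [u for u in user_reactions if u.is_objective]
    if len(objectives) != 1:
        raise ValueError(
            f"exactly one user reaction must be the objective, got {len(objectives)}"
        )

    ec_to_proteins: dict[str, set[str]] = {}
    for protein, ec in high_conf:
        ec_to_proteins.setdefault(ec, set()).add(protein)

    rxn_ids, uncovered = reactions_for_ecs(db, ec_to_proteins)

    model = MetabolicModel(id=model_id)
    # (i) reactions behind high-confidence ECs, genes = supporting proteins
    for rid in sorted(rxn_ids):
        rxn = db.reactions[rid]
        genes: set[str] = set()
        for ec in rxn.ec_links:
            genes |= ec_to_proteins.get(ec, set())
        model.add_reaction(rxn, genes=genes, provenance="ec_high_conf")

    # (ii) spontaneous reactions
    if include_spontaneous:
        for rid in sorted(db.spontaneous_reactions - set(model.reactions)):
            model.add_reaction(db.reactions[rid], provenance="spontaneous")

    # (iii) similarity-supported non-EC reactions (BiGG-like dialect only)
    if similarity_reactions:
        if db.dialect != "bigg_like":
            warnings.warn(
                "similarity-supported reactions are only included for a "
                "bigg_like database; ignoring them",
                stacklevel=2,
            )
        else:
            for rid in sorted(set(similarity_reactions) - set(model.reactions)):
                model.add_reaction(
                    db.reactions[rid],
                    genes=similarity_reactions[rid],
                    provenance="similarity",
                )

    # (iv) user reactions, incl. the objective
    for u in user_reactions:
        if u.reaction.id in model.reactions:
            # user definition overrides the database copy
            model.reactions[u.reaction.id] = u.reaction
            model.provenance[u.reaction.id] = "user"
        else:
            model.add_reaction(u.reaction, provenance="user")
    model.set_objective(objectives[0].reaction.id)

    obj_mets = set(objectives[0].reaction.stoichiometry)
    other_mets = {
        m
        for rid, rxn in model.reactions.items()
        if rid != objectives[0].reaction.id
        for m in rxn.stoichiometry
    }
    if obj_mets.isdisjoint(other_mets):
        warnings.warn(
            "no objective metabolite appears in any other reaction; "
            "the model will need gap-filling to grow",
            stacklevel=2,
        )
    model.validate()
    return model, uncovered
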