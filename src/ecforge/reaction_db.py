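"""Reaction database loading and querying.

The database schema is deliberately dialect-agnostic JSON (or TSV): each
reaction carries an identifier, an equation (or explicit stoichiometry map),
a reversibility flag, linked ECs, and a spontaneous flag. The ``dialect``
tag records whether identifiers follow a KEGG-like or BiGG-like convention;
it matters downstream because sequence-similarity support for non-EC
reactions is only used on the BiGG-like path.

Equations use the convention ``A + 2 B <=> C`` (reversible) or
``A + 2 B --> C`` (irreversible); substrate coefficients are stored negative.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .model import Reaction

__all__ = [
    "ReactionDatabase",
    "parse_equation",
    "load_reaction_db",
    "reactions_for_ecs",
    "filter_similarity_hits",
    "DEFAULT_EVALUE_CUTOFF",
]

DEFAULT_EVALUE_CUTOFF = 1e-20

_ARROWS = ("<=>", "<->", "-->", "=>", "->")


def parse_equation(equation: str) -> tuple[dict[str, float], bool]:
    """Parse ``A + 2 B <=> C`` into a signed stoichiometry map and a
    reversibility flag."""
    arrow = next((a for a in _ARROWS if a in equation), None)
    if arrow is None:
        raise ValueError(f"no reaction arrow in equation: {equation!r}")
    reversible = arrow in ("<=>", "<->")
    lhs, rhs = equation.split(arrow, 1)
    stoich: dict[str, float] = {}

    def add_side(side: str, sign: float) -> None:
        side = side.strip()
        if not side:
            return
        for term in side.split(" + "):
            term = term.strip()
            if not term:
                continue
            m = re.match(r"^(\d+(?:\.\d+)?)\s+(\S.*)$", term)
            if m:
                coef, met = float(m.group(1)), m.group(2).strip()
            else:
                coef, met = 1.0, term
            if coef == 0:
                raise ValueError(f"zero coefficient in equation: {equation!r}")
            stoich[met] = stoich.get(met, 0.0) + sign * coef

    add_side(lhs, -1.0)
    add_side(rhs, +1.0)
    stoich = {m: c for m, c in stoich.items() if c != 0}
    if not stoich:
        raise ValueError(f"equation cancels to nothing: {equation!r}")
    return stoich, reversible


@dataclass
class ReactionDatabase:
    reactions: dict[str, Reaction] = field(default_factory=dict)
    dialect: str = "kegg_like"
    non_ec_sequence_index: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.dialect not in ("kegg_like", "bigg_like"):
            raise ValueError(f"unknown dialect {self.dialect!r}")

    @property
    def ec_index(self) -> dict[str, set[str]]:
        idx: dict[str, set[str]] = {}
        for rxn in self.reactions.values():
            for ec in rxn.ec_links:
                idx.setdefault(ec, set()).add(rxn.id)
        return idx

    @property
    def spontaneous_reactions(self) -> set[str]:
        return {r.id for r in self.reactions.values() if r.spontaneous}

    def add(self, reaction: Reaction) -> None:
        if reaction.id in self.reactions:
            raise ValueError(f"duplicate reaction id {reaction.id}")
        self.reactions[reaction.id] = reaction

    def __len__(self) -> int:
        return len(self.reactions)


def _reaction_from_dict(d: Mapping, context: str) -> Reaction:
    try:
        if "stoichiometry" in d:
            stoich = {str(m): float(c) for m, c in d["stoichiometry"].items()}
            reversible = bool(d.get("reversible", False))
        else:
            stoich, reversible = parse_equation(d["equation"])
            if "reversible" in d:
                reversible = bool(d["reversible"])
        return Reaction(
            id=str(d["id"]),
            stoichiometry=stoich,
            reversible=reversible,
            ec_links=frozenset(d.get("ec_links", ())),
            spontaneous=bool(d.get("spontaneous", False)),
            lower_bound=d.get("lower_bound"),
            upper_bound=d.get("upper_bound"),
            name=str(d.get("name", "")),
        )
    except (KeyError, ValueError, TypeError) as exc:
        raise ValueError(f"{context}: invalid reaction entry: {exc}") from exc


def load_reaction_db(path, dialect: str | None = None) -> ReactionDatabase:
    """Load a reaction database from JSON or TSV.

    JSON schema: ``{"dialect": ..., "reactions": [...], "non_ec_sequences":
    {reaction_id: [protein, ...]}}``. TSV columns: ``reaction_id  equation
    reversible  ec_links  spontaneous`` with ECs ``;``-separated.
    """
    path = str(path)
    db = ReactionDatabase(dialect=dialect or "kegg_like")
    if path.endswith(".json"):
        with open(path) as fh:
            doc = json.load(fh)
        if dialect is None and "dialect" in doc:
            db.dialect = doc["dialect"]
            db.__post_init__()
        for i, entry in enumerate(doc["reactions"]):
            db.add(_reaction_from_dict(entry, f"{path} reaction #{i}"))
        for rid, prots in doc.get("non_ec_sequences", {}).items():
            if rid not in db.reactions:
                raise ValueError(f"{path}: non_ec_sequences for unknown reaction {rid}")
            db.non_ec_sequence_index[rid] = set(prots)
    else:
        df = pd.read_csv(path, sep="\t", dtype=str).fillna("")
        for i, row in enumerate(df.itertuples(index=False)):
            ecs = [e for e in str(row.ec_links).split(";") if e]
            entry = {
                "id": row.reaction_id,
                "equation": row.equation,
                "reversible": str(row.reversible).strip().lower()
                in ("1", "true", "yes"),
                "ec_links": ecs,
                "spontaneous": str(getattr(row, "spontaneous", "")).strip().lower()
                in ("1", "true", "yes"),
            }
            db.add(_reaction_from_dict(entry, f"{path} row {i + 2}"))
    return db


def reactions_for_ecs(
    db: ReactionDatabase, ec_set: Iterable[str]
) -> tuple[set[str], set[str]]:
    """All reactions linked to any EC in *ec_set* (indiscriminate inclusion:
    a multi-reaction EC contributes every linked reaction). Returns
    ``(reaction_ids, uncovered_ecs)`` where the second element lists ECs with
    no reaction in the database (a coverage statistic)."""
    idx = db.ec_index
    hits: set[str] = set()
    uncovered: set[str] = set()
    for ec in set(ec_set):
        rids = idx.get(ec)
        if rids:
            hits |= rids
        else:
            uncovered.add(ec)
    return hits, uncovered


def filter_similarity_hits(
    hits,
    db: ReactionDatabase,
    evalue_cutoff: float = DEFAULT_EVALUE_CUTOFF,
) -> dict[str, set[str]]:
    """Map BLAST hits against non-EC reaction sequences to supported reactions.

    *hits* is a DataFrame or TSV path with columns ``query``, ``target``,
    ``evalue`` (a 12-column header-less BLAST outfmt-6 table is also
    accepted). Hits with E-value <= *evalue_cutoff* (inclusive boundary) are
    retained; targets not present in the database's non-EC sequence index are
    dropped with a warning.
    """
    if isinstance(hits, (str,)) or hasattr(hits, "__fspath__"):
        probe = pd.read_csv(hits, sep="\t", header=None, nrows=1)
        if probe.shape[1] == 12:
            df = pd.read_csv(hits, sep="\t", header=None)
            df = df.rename(columns={0: "query", 1: "target", 10: "evalue"})
        else:
            df = pd.read_csv(hits, sep="\t")
    else:
        df = hits
    for col in ("query", "target", "evalue"):
        if col not in df.columns:
            raise ValueError(f"similarity table missing column {col!r}")

    protein_to_rxns: dict[str, set[str]] = {}
    for rid, prots in db.non_ec_sequence_index.items():
        for p in prots:
            protein_to_rxns.setdefault(p, set()).add(rid)

    out: dict[str, set[str]] = {}
    n_unmapped = 0
    for row in df.itertuples(index=False):
        if float(row.evalue) > evalue_cutoff:
            continue
        rxns = protein_to_rxns.get(str(row.target))
        if not rxns:
            n_unmapped += 1
            continue
        for rid in rxns:
            out.setdefault(rid, set()).add(str(row.query))
    if n_unmapped:
        warnings.warn(
            f"{n_unmapped} similarity hit(s) targeted proteins absent from the "
            "non-EC sequence index and were dropped",
            stacklevel=2,
        )
    return out
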