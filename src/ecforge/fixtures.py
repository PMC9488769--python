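"""Synthetic data generators: tool predictions with controllable error
profiles, and toy stoichiometric networks with known optimal gap-fills.

All generators are pure functions of their parameters and the seed, so the
same call always returns byte-identical data. They emulate the pipeline's
real inputs at desk scale: multi-tool EC prediction tables with per-tool
(and optionally per-EC) sensitivity and false-positive rates, gold-standard
protein-to-EC labels including multifunctional proteins, and small metabolic
networks (chains, parallel paths, gapped chains with a unique minimum-penalty
repair, and networks with a deliberate energy-generating cycle).

Raw scores for correct predictions are drawn uniformly from the high
confidence bin (0.5, 1]; false-positive scores are drawn uniformly from the
whole score range (0, 1], so true predictions skew high.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .ensemble import ScoredAnnotation
from .model import MediaDefinition, MetabolicModel, Reaction
from .prediction_io import PredictionRecord, PredictionTable, ToolProfile
from .reaction_db import ReactionDatabase

__all__ = [
    "ToolSpec",
    "synth_predictions",
    "SynthNetwork",
    "synth_network",
    "atp_toy_network",
]


@dataclass(frozen=True)
class ToolSpec:
    """Error profile of one emulated annotation tool.

    Per-EC overrides take precedence over the tool-wide sensitivity and
    false-positive rate. ``predictive_range=None`` means the tool can emit
    every EC class in play.
    """

    sensitivity: float = 0.8
    fpr: float = 0.02
    predictive_range: frozenset[str] | None = None
    per_ec_sensitivity: Mapping[str, float] = field(default_factory=dict)
    per_ec_fpr: Mapping[str, float] = field(default_factory=dict)
    binary: bool = False

    def __post_init__(self) -> None:
        vals = [self.sensitivity, self.fpr, *self.per_ec_sensitivity.values(),
                *self.per_ec_fpr.values()]
        if not all(0.0 <= v <= 1.0 for v in vals):
            raise ValueError("sensitivities and FPRs must lie in [0, 1]")

    def sens(self, ec: str) -> float:
        return self.per_ec_sensitivity.get(ec, self.sensitivity)

    def fp(self, ec: str) -> float:
        return self.per_ec_fpr.get(ec, self.fpr)


def _ec_names(n: int) -> list[str]:
    out = []
    for i in range(n):
        a, b, c, d = 1 + i % 6, 1 + (i // 6) % 9, 1 + (i // 54) % 9, 1 + i
        out.append(f"{a}.{b}.{c}.{d}")
    return out


def synth_predictions(
    n_proteins: int,
    ec_classes: int | Sequence[str],
    tool_specs: Mapping[str, ToolSpec],
    multifunctional_rate: float = 0.1,
    n_non_enzymes: int = 0,
    seed: int = 42,
) -> tuple[PredictionTable, dict[str, set[str]], list[ToolProfile]]:
    """Generate gold labels and per-tool predictions.

    Every enzyme protein carries one EC, plus a second distinct EC with
    probability *multifunctional_rate*; non-enzyme proteins carry none but
    can still attract false positives. Each tool emits each true EC inside
    its range with its (per-EC) sensitivity and each false EC with its
    (per-EC) false-positive rate.

    Returns ``(table, gold, profiles)``; profiles use two confidence bins
    split at 0.5 with ``high`` as the high-confidence bin.
    """
    rng = np.random.default_rng(seed)
    ecs = _ec_names(ec_classes) if isinstance(ec_classes, int) else list(ec_classes)
    if not ecs:
        raise ValueError("need at least one EC class")

    gold: dict[str, set[str]] = {}
    for i in range(n_proteins):
        pid = f"prot{i:05d}"
        labels = {ecs[int(rng.integers(len(ecs)))]}
        if len(ecs) > 1 and rng.random() < multifunctional_rate:
            extra = ecs[int(rng.integers(len(ecs)))]
            labels.add(extra)
        gold[pid] = labels
    non_enzymes = [f"nonenz{i:05d}" for i in range(n_non_enzymes)]

    profiles: list[ToolProfile] = []
    table = PredictionTable()
    all_proteins = list(gold) + non_enzymes
    for tool in sorted(tool_specs):
        spec = tool_specs[tool]
        tool_key = zlib.crc32(tool.encode()) % 2**31  # stable across processes
        rng_tool = np.random.default_rng(
            np.random.SeedSequence(entropy=seed, spawn_key=(tool_key,))
        )
        prange = (
            frozenset(ecs) if spec.predictive_range is None else spec.predictive_range
        )
        profiles.append(
            ToolProfile(
                tool_name=tool,
                score_kind="binary" if spec.binary else "probability",
                predictive_range=prange,
            )
        )
        for pid in all_proteins:
            truths = gold.get(pid, set())
            for ec in sorted(prange):
                is_true = ec in truths
                p_emit = spec.sens(ec) if is_true else spec.fp(ec)
                if rng_tool.random() >= p_emit:
                    continue
                if spec.binary:
                    score = 1.0
                elif is_true:
                    score = 0.5 + 0.5 * rng_tool.random()  # uniform (0.5, 1]
                else:
                    score = np.nextafter(rng_tool.random(), 1.0)  # uniform (0, 1]
                level = "high" if score > 0.5 else "low"
                table.add(PredictionRecord(pid, ec, tool, float(score), level))
    return table, gold, profiles


@dataclass
class SynthNetwork:
    """A generated toy network plus everything gap-filling needs."""

    model: MetabolicModel
    db: ReactionDatabase
    scored_annotations: list[ScoredAnnotation]
    known_optimal_gapfill: set[str]
    media: MediaDefinition
    uptake_bound: float = 1.0


def _chain_reactions(size: int, uptake: float) -> list[Reaction]:
    rxns = [
        Reaction(
            id="EX_A0",
            stoichiometry={"A0": -1.0},
            reversible=True,
            lower_bound=-uptake,
        )
    ]
    for i in range(1, size + 1):
        rxns.append(
            Reaction(id=f"R{i}", stoichiometry={f"A{i-1}": -1.0, f"A{i}": 1.0},
                     ec_links=frozenset({f"1.1.1.{i}"}))
        )
    rxns.append(
        Reaction(id="biomass", stoichiometry={f"A{size}": -1.0})
    )
    return rxns


def synth_network(
    spec: str = "chain",
    size: int = 3,
    seed: int = 42,
    uptake_bound: float = 1.0,
) -> SynthNetwork:
    """Generate a toy network of the requested shape.

    ``chain``
        linear pathway EX_A0 -> R1 -> ... -> R<size> -> biomass; the FBA
        optimum equals the uptake bound.
    ``parallel``
        two independent routes from the substrate to the biomass precursor;
        knocking out either leaves growth intact.
    ``gapped``
        a chain with 1-3 internal reactions withheld from the model but
        present in the database at low-confidence scores; decoy reactions
        among disconnected metabolites make the pool bigger without offering
        an alternative repair, so the withheld set is the unique
        minimum-penalty gap-fill.
    ``energy_cycle``
        a chain plus an irreversible two-reaction loop that produces the
        biomass precursor from nothing — the zero-substrate control of a
        yield analysis fires on it.
    """
    if size < 2:
        raise ValueError("size must be >= 2")
    rng = np.random.default_rng(seed)
    chain = _chain_reactions(size, uptake_bound)
    media = MediaDefinition(uptake_rates={"EX_A0": uptake_bound})

    db = ReactionDatabase(dialect="kegg_like")
    for rxn in chain:
        db.add(rxn)

    model = MetabolicModel(id=f"{spec}_{size}")
    scored: list[ScoredAnnotation] = []
    known: set[str] = set()

    if spec == "chain":
        for rxn in chain:
            model.add_reaction(rxn, genes=[f"g_{rxn.id}"] if rxn.id.startswith("R") else [])
    elif spec == "parallel":
        model.add_reaction(chain[0])  # EX_A0
        model.add_reaction(
            Reaction(id="P1", stoichiometry={"A0": -1.0, "B": 1.0}), genes=["gP1"]
        )
        model.add_reaction(
            Reaction(id="P2", stoichiometry={"A0": -1.0, "B": 1.0}), genes=["gP2"]
        )
        model.add_reaction(
            Reaction(id="Rb", stoichiometry={"B": -1.0, "A1": 1.0}), genes=["gRb"]
        )
        model.add_reaction(Reaction(id="biomass", stoichiometry={"A1": -1.0}))
        for rxn in model.reactions.values():
            if rxn.id not in db.reactions:
                db.add(rxn)
    elif spec == "gapped":
        n_gaps = int(rng.integers(1, min(3, size) + 1))
        internal = [f"R{i}" for i in range(1, size + 1)]
        removed = set(rng.choice(internal, size=n_gaps, replace=False).tolist())
        for rxn in chain:
            if rxn.id not in removed:
                model.add_reaction(rxn)
        known = set(removed)
        # low-confidence scores for the withheld reactions' ECs
        for rid in sorted(removed):
            ec = next(iter(db.reactions[rid].ec_links))
            score = float(0.05 + 0.45 * rng.random())  # in (0.0001, 0.5]
            scored.append(ScoredAnnotation(f"p_{rid}", ec, score, False, "classifier"))
        # decoy reactions among disconnected metabolites
        n_decoys = int(rng.integers(1, 4))
        for d in range(n_decoys):
            db.add(
                Reaction(
                    id=f"D{d}",
                    stoichiometry={f"X{d}": -1.0, f"X{d}b": 1.0},
                    ec_links=frozenset({f"9.9.9.{d+1}"}),
                )
            )
            if rng.random() < 0.5:
                score = float(0.05 + 0.45 * rng.random())
                scored.append(
                    ScoredAnnotation(f"p_D{d}", f"9.9.9.{d+1}", score, False, "classifier")
                )
    elif spec == "energy_cycle":
        for rxn in chain:
            model.add_reaction(rxn)
        model.add_reaction(
            Reaction(id="Loop1", stoichiometry={"L1": -1.0, "L2": 1.0})
        )
        model.add_reaction(
            Reaction(
                id="Loop2", stoichiometry={"L2": -1.0, "L1": 1.0, f"A{size}": 1.0}
            )
        )
        model.add_reaction(
            Reaction(id="EX_L1", stoichiometry={"L1": -1.0}, reversible=True)
        )
        for rxn in model.reactions.values():
            if rxn.id not in db.reactions:
                db.add(rxn)
    else:
        raise ValueError(f"unknown network spec {spec!r}")

    if "biomass" in model.reactions:
        model.set_objective("biomass")
    return SynthNetwork(
        model=model,
        db=db,
        scored_annotations=scored,
        known_optimal_gapfill=known,
        media=media,
        uptake_bound=uptake_bound,
    )


def atp_toy_network(atp_per_substrate: float = 2.0) -> MetabolicModel:
    """A minimal fermentation-style network yielding a fixed number of ATP
    per substrate: glc + n adp + n pi -> n atp + n h2o + byp, with the ATP
    moiety recycled through hydrolysis and the byproduct and protons drained.
    """
    n = float(atp_per_substrate)
    m = MetabolicModel(id="atp_toy")
    m.add_reaction(
        Reaction(id="EX_glc", stoichiometry={"glc": -1.0}, reversible=True,
                 lower_bound=-1.0)
    )
    m.add_reaction(
        Reaction(
            id="ferment",
            stoichiometry={"glc": -1.0, "adp": -n, "pi": -n, "atp": n,
                           "h2o": n, "byp": 1.0},
            ec_links=frozenset({"2.7.1.1"}),
        ),
        genes=["g_ferment"],
    )
    m.add_reaction(Reaction(id="EX_byp", stoichiometry={"byp": -1.0}))
    m.add_reaction(Reaction(id="EX_h", stoichiometry={"h": -1.0}))
    m.add_reaction(Reaction(id="biomass", stoichiometry={"byp": -1.0}))
    m.set_objective("biomass")
    return m
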