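"""Annotation performance metrics and the cross-validation harness.

Macro-averaged metrics weigh every EC class equally so that small classes
are represented; micro-averaged metrics pool (protein, EC) decisions across
classes. Specificity is reported on proteins without any enzymatic
annotation: the fraction receiving zero high-confidence EC calls.

Conventions (reported alongside the numbers):
- macro precision averages only over ECs with at least one prediction
  (precision is undefined otherwise); the number of excluded ECs is returned;
- macro F1 is the unweighted mean of per-class F1 (the harmonic mean of
  macro precision and macro recall is also returned for transparency).
"""

from __future__ import annotations

import random
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

__all__ = [
    "ConfusionCounts",
    "MacroMetrics",
    "per_ec_confusion",
    "macro_metrics",
    "micro_metrics",
    "specificity_non_enzymes",
    "kfold_split",
]

Pair = tuple[str, str]  # (protein_id, ec)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be nonnegative")

    @property
    def precision(self) -> float | None:
        d = self.tp + self.fp
        return self.tp / d if d else None

    @property
    def recall(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def f1(self) -> float:
        d = 2 * self.tp + self.fp + self.fn
        return 2 * self.tp / d if d else 0.0


@dataclass(frozen=True)
class MacroMetrics:
    precision: float
    recall: float
    f1: float  # mean of per-class F1
    f1_harmonic: float  # harmonic mean of macro P and macro R
    n_ecs: int
    n_excluded_from_precision: int


def _as_pairs(predictions: Iterable[Pair]) -> set[Pair]:
    return set(predictions)


def _gold_pairs(gold: Mapping[str, set[str]]) -> set[Pair]:
    return {(p, ec) for p, ecs in gold.items() for ec in ecs}


def per_ec_confusion(
    predictions: Iterable[Pair],
    gold: Mapping[str, set[str]],
    ec_universe: Sequence[str],
) -> dict[str, ConfusionCounts]:
    pred = _as_pairs(predictions)
    gp = _gold_pairs(gold)
    out: dict[str, ConfusionCounts] = {}
    for ec in ec_universe:
        p = {pair for pair in pred if pair[1] == ec}
        g = {pair for pair in gp if pair[1] == ec}
        out[ec] = ConfusionCounts(len(p & g), len(p - g), len(g - p))
    return out


def macro_metrics(
    predictions: Iterable[Pair],
    gold: Mapping[str, set[str]],
    ec_universe: Sequence[str] | None = None,
) -> MacroMetrics:
    """Unweighted per-EC means of precision, recall and F1.

    ECs with no predictions have undefined precision and are excluded from
    the precision mean only; they still contribute recall 0 (if they have
    gold support) and F1.
    """
    if not any(gold.values()):
        raise ValueError("empty gold standard")
    if ec_universe is None:
        ec_universe = sorted({ec for ecs in gold.values() for ec in ecs})
    if not ec_universe:
        raise ValueError("empty EC universe")
    conf = per_ec_confusion(predictions, gold, ec_universe)
    precisions = [c.precision for c in conf.values() if c.precision is not None]
    recalls = [c.recall if c.recall is not None else 0.0 for c in conf.values()]
    f1s = [c.f1 for c in conf.values()]
    macro_p = sum(precisions) / len(precisions) if precisions else 0.0
    macro_r = sum(recalls) / len(recalls)
    macro_f1 = sum(f1s) / len(f1s)
    harm = (
        2 * macro_p * macro_r / (macro_p + macro_r) if (macro_p + macro_r) else 0.0
    )
    return MacroMetrics(
        precision=macro_p,
        recall=macro_r,
        f1=macro_f1,
        f1_harmonic=harm,
        n_ecs=len(ec_universe),
        n_excluded_from_precision=len(ec_universe) - len(precisions),
    )


def micro_metrics(
    predictions: Iterable[Pair], gold: Mapping[str, set[str]]
) -> tuple[float | None, float]:
    """Pooled precision and recall over all (protein, EC) pairs.

    Precision is None (not applicable) when there are no predictions at all.
    """
    pred = _as_pairs(predictions)
    gp = _gold_pairs(gold)
    tp = len(pred & gp)
    precision = tp / len(pred) if pred else None
    recall = tp / len(gp) if gp else 0.0
    return precision, recall


def specificity_non_enzymes(
    predictions: Iterable[Pair], non_enzyme_proteins: Iterable[str]
) -> float:
    """Fraction of non-enzyme proteins receiving zero high-confidence ECs."""
    non_enz = set(non_enzyme_proteins)
    if not non_enz:
        raise ValueError("empty non-enzyme set")
    flagged = {p for p, _ in predictions if p in non_enz}
    return 1.0 - len(flagged) / len(non_enz)


def kfold_split(
    gold: Mapping[str, set[str]],
    k: int = 5,
    seed: int = 42,
) -> list[tuple[set[str], set[str]]]:
    """Partition proteins into k folds so every EC keeps training examples.

    Returns ``[(train_proteins, test_proteins), ...]`` with each protein in
    exactly one test fold. Multifunctional proteins (several ECs) are placed
    greedily so that each of their ECs stays balanced across folds, which
    guarantees every EC appears in every training fold whenever every EC has
    at least *k* member proteins; an EC with fewer raises ``ValueError``.
    """
    support: dict[str, int] = {}
    for ecs in gold.values():
        for ec in ecs:
            support[ec] = support.get(ec, 0) + 1
    thin = sorted(ec for ec, n in support.items() if n < k)
    if thin:
        raise ValueError(
            f"EC(s) with fewer than k={k} proteins cannot keep training "
            f"coverage in every fold: {thin[:5]}"
        )

    rng = random.Random(seed)
    proteins = sorted(gold)
    rng.shuffle(proteins)
    # handle rare ECs and multifunctional proteins first: they are hardest
    # to balance across folds
    proteins.sort(key=lambda p: (min(support[ec] for ec in gold[p]), -len(gold[p])))

    fold_ec_counts: list[dict[str, int]] = [dict() for _ in range(k)]
    fold_sizes = [0] * k
    assignment: dict[str, int] = {}
    for p in proteins:
        # prefer the fold where this protein's ECs are least represented,
        # then the smallest fold
        def load(i: int) -> tuple[int, int, int]:
            return (
                max(fold_ec_counts[i].get(ec, 0) for ec in gold[p]),
                sum(fold_ec_counts[i].get(ec, 0) for ec in gold[p]),
                fold_sizes[i],
            )

        best = min(range(k), key=load)
        assignment[p] = best
        fold_sizes[best] += 1
        for ec in gold[p]:
            fold_ec_counts[best][ec] = fold_ec_counts[best].get(ec, 0) + 1

    folds: list[tuple[set[str], set[str]]] = []
    all_proteins = set(gold)
    for i in range(k):
        test = {p for p, f in assignment.items() if f == i}
        folds.append((all_proteins - test, test))
    # audit: every EC must retain at least one training example per fold
    for train, _ in folds:
        covered = set().union(*(gold[p] for p in train)) if train else set()
        missing = set(support) - covered
        if missing:
            raise ValueError(
                f"fold split failed to keep training coverage for {sorted(missing)[:5]}"
            )
    return folds
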