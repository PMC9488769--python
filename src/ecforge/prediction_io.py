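"""Read, normalize and merge per-tool EC prediction tables.

Upstream enzyme-annotation tools emit, per protein, candidate EC numbers with
tool-specific raw scores (probabilities, profile likelihoods, bit-score-like
quantities, or nothing at all for binary callers). This module normalizes
those outputs into a canonical :class:`PredictionTable` and builds the per-EC
feature matrices the ensemble classifiers train on.

Only complete four-field EC numbers (e.g. ``1.1.1.1``) are retained; rows
with partial ECs (``1.1.1.-``) are dropped and counted.
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ToolProfile",
    "PredictionRecord",
    "PredictionTable",
    "IngestSummary",
    "is_complete_ec",
    "read_tool_predictions",
    "write_prediction_table",
    "read_gold_standard",
    "build_feature_matrix",
    "load_tool_profiles",
]

_EC_COMPLETE = re.compile(r"^\d+\.\d+\.\d+\.(\d+|n\d+)$")

Encoding = Literal["binary_high_conf", "one_hot_levels", "ordinal_levels"]


def is_complete_ec(ec: str) -> bool:
    """True if *ec* has four numeric fields (transferred ``n``-serials count)."""
    return bool(_EC_COMPLETE.match(ec.strip()))


@dataclass(frozen=True)
class ToolProfile:
    """Score semantics and coverage of one upstream annotation tool.

    Parameters
    ----------
    tool_name:
        Identifier used in merged tables.
    score_kind:
        One of ``probability``, ``likelihood``, ``bitscore-like``, ``binary``.
    confidence_bins:
        Ordered ``(label, lower, upper)`` half-open intervals ``(lower, upper]``
        partitioning the raw-score domain. Binary tools may use a single bin.
    high_conf_bin:
        Label of the bin that counts as a high-confidence call.
    predictive_range:
        ECs the tool is able to emit; predictions outside it are invalid.
    """

    tool_name: str
    score_kind: str = "probability"
    confidence_bins: tuple[tuple[str, float, float], ...] = (
        ("low", 0.0, 0.5),
        ("high", 0.5, 1.0),
    )
    high_conf_bin: str = "high"
    predictive_range: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        labels = [b[0] for b in self.confidence_bins]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{self.tool_name}: duplicate bin labels {labels}")
        if self.high_conf_bin not in labels:
            raise ValueError(
                f"{self.tool_name}: high_conf_bin {self.high_conf_bin!r} "
                f"is not one of {labels}"
            )
        lo = [b[1] for b in self.confidence_bins]
        hi = [b[2] for b in self.confidence_bins]
        for i in range(1, len(self.confidence_bins)):
            if lo[i] != hi[i - 1]:
                raise ValueError(
                    f"{self.tool_name}: bins must be contiguous and ordered"
                )
        object.__setattr__(self, "predictive_range", frozenset(self.predictive_range))

    @property
    def is_binary(self) -> bool:
        return self.score_kind == "binary"

    @property
    def score_domain(self) -> tuple[float, float]:
        return self.confidence_bins[0][1], self.confidence_bins[-1][2]

    @property
    def bin_labels(self) -> tuple[str, ...]:
        return tuple(b[0] for b in self.confidence_bins)

    def bin_for_score(self, raw_score: float) -> str:
        """Map a raw score to its confidence bin (half-open ``(lo, hi]``;
        the lowest bin additionally admits its own lower edge)."""
        lo_dom, hi_dom = self.score_domain
        if not (lo_dom <= raw_score <= hi_dom):
            raise ValueError(
                f"{self.tool_name}: score {raw_score} outside declared "
                f"domain [{lo_dom}, {hi_dom}]"
            )
        for i, (label, lo, hi) in enumerate(self.confidence_bins):
            if (lo < raw_score <= hi) or (i == 0 and raw_score == lo):
                return label
        raise AssertionError("unreachable: bins partition the domain")

    def level_index(self, label: str) -> int:
        """Ordinal index of a bin label, 1-based (0 is reserved for
        'no prediction')."""
        return self.bin_labels.index(label) + 1


@dataclass(frozen=True)
class PredictionRecord:
    protein_id: str
    ec: str
    tool: str
    raw_score: float
    confidence_level: str


@dataclass(frozen=True)
class IngestSummary:
    n_rows: int
    n_kept: int
    n_partial_ec_dropped: int
    n_duplicates_merged: int


class PredictionTable:
    """Canonical merged store of per-tool EC predictions.

    At most one record per ``(protein, ec, tool)``; duplicates are resolved
    upstream by keeping the maximum raw score.
    """

    def __init__(self, records: Iterable[PredictionRecord] = ()) -> None:
        self._records: dict[tuple[str, str, str], PredictionRecord] = {}
        for rec in records:
            self.add(rec)

    def add(self, rec: PredictionRecord, keep_max: bool = True) -> bool:
        """Insert a record; on a (protein, ec, tool) collision keep the one
        with the larger raw score. Returns True if a collision occurred."""
        key = (rec.protein_id, rec.ec, rec.tool)
        prev = self._records.get(key)
        if prev is None:
            self._records[key] = rec
            return False
        if not keep_max or rec.raw_score > prev.raw_score:
            self._records[key] = rec
        return True

    @property
    def records(self) -> list[PredictionRecord]:
        return list(self._records.values())

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(k[0] for k in self._records)

    @property
    def ecs(self) -> frozenset[str]:
        return frozenset(k[1] for k in self._records)

    @property
    def tools(self) -> frozenset[str]:
        return frozenset(k[2] for k in self._records)

    def __len__(self) -> int:
        return len(self._records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PredictionTable):
            return NotImplemented
        return self._records == other._records

    def get(self, protein_id: str, ec: str, tool: str) -> PredictionRecord | None:
        return self._records.get((protein_id, ec, tool))

    def merge(self, other: "PredictionTable") -> "PredictionTable":
        merged = PredictionTable(self.records)
        for rec in other.records:
            merged.add(rec)
        return merged

    def for_ec(self, ec: str) -> list[PredictionRecord]:
        return [r for r in self._records.values() if r.ec == ec]

    def high_confidence_sets(
        self, profiles: Sequence[ToolProfile]
    ) -> dict[str, dict[str, set[str]]]:
        """Per protein, per tool: the set of ECs called at that tool's
        high-confidence bin."""
        high = {p.tool_name: p.high_conf_bin for p in profiles}
        out: dict[str, dict[str, set[str]]] = {}
        for rec in self._records.values():
            if high.get(rec.tool) == rec.confidence_level:
                out.setdefault(rec.protein_id, {}).setdefault(rec.tool, set()).add(
                    rec.ec
                )
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.protein_id, r.ec, r.tool, r.raw_score, r.confidence_level)
                for r in sorted(
                    self._records.values(),
                    key=lambda r: (r.protein_id, r.ec, r.tool),
                )
            ],
            columns=["protein_id", "ec", "tool", "raw_score", "confidence_level"],
        )


def read_tool_predictions(
    path, profile: ToolProfile
) -> tuple[PredictionTable, IngestSummary]:
    """Parse one tool's TSV (``protein_id  ec  raw_score``) into a table.

    Partial ECs are dropped and counted; binary tools may omit the score
    column entirely, in which case every row is taken at the tool's
    high-confidence bin. A raw score outside the profile's declared domain
    raises :class:`ValueError` naming the offending row.
    """
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ec": str})
    if "protein_id" not in df.columns or "ec" not in df.columns:
        raise ValueError(f"{path}: header must include protein_id and ec")
    has_score = "raw_score" in df.columns
    if not has_score and not profile.is_binary:
        raise ValueError(
            f"{path}: raw_score column required for non-binary tool "
            f"{profile.tool_name}"
        )
    table = PredictionTable()
    n_partial = 0
    n_dup = 0
    hi_edge = profile.score_domain[1]
    for idx, row in enumerate(df.itertuples(index=False)):
        ec = str(row.ec).strip()
        if not is_complete_ec(ec):
            n_partial += 1
            continue
        if has_score and not (profile.is_binary and pd.isna(row.raw_score)):
            score = float(row.raw_score)
            try:
                level = profile.bin_for_score(score)
            except ValueError as exc:
                raise ValueError(f"{path} row {idx + 2}: {exc}") from exc
        else:
            score, level = hi_edge, profile.high_conf_bin
        rec = PredictionRecord(
            protein_id=str(row.protein_id).strip(),
            ec=ec,
            tool=profile.tool_name,
            raw_score=score,
            confidence_level=level,
        )
        if table.add(rec):
            n_dup += 1
    if n_dup:
        warnings.warn(
            f"{profile.tool_name}: merged {n_dup} duplicate (protein, ec) rows "
            "keeping the maximum raw score",
            stacklevel=2,
        )
    return table, IngestSummary(len(df), len(table), n_partial, n_dup)


def write_prediction_table(table: PredictionTable, path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def read_prediction_table(path) -> PredictionTable:
    """Re-read a table written by :func:`write_prediction_table` (round-trip)."""
    df = pd.read_csv(path, sep="\t", dtype={"protein_id": str, "ec": str, "tool": str})
    return PredictionTable(
        PredictionRecord(r.protein_id, r.ec, r.tool, float(r.raw_score), r.confidence_level)
        for r in df.itertuples(index=False)
    )


def read_gold_standard(path) -> dict[str, set[str]]:
    """Read a gold-label TSV (``protein_id  ec``, one annotation per row).

    Partial ECs are dropped, matching the training-data convention. Proteins
    may appear with zero ECs elsewhere (non-enzymes) and simply be absent.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    gold: dict[str, set[str]] = {}
    for row in df.itertuples(index=False):
        ec = str(row.ec).strip()
        if is_complete_ec(ec):
            gold.setdefault(str(row.protein_id).strip(), set()).add(ec)
    return gold


def tools_predicting(ec: str, profiles: Sequence[ToolProfile]) -> list[ToolProfile]:
    """Profiles whose predictive range contains *ec*, in input order (the k
    tools behind this EC's feature vector)."""
    return [p for p in profiles if ec in p.predictive_range]


def build_feature_matrix(
    table: PredictionTable,
    ec: str,
    profiles: Sequence[ToolProfile],
    encoding: Encoding = "binary_high_conf",
    proteins: Sequence[str] | None = None,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Encode per-tool evidence for one EC as a proteins x features matrix.

    ``binary_high_conf``
        one column per predicting tool; 1 iff that tool called *ec* at its
        high-confidence bin (the Bernoulli features of the naive Bayes model).
    ``one_hot_levels``
        one column per (tool, confidence bin); absence of a prediction leaves
        the tool's whole block at zero.
    ``ordinal_levels``
        one integer column per tool; 0 = no prediction, 1..B = bin index.

    Returns ``(X, protein_ids, feature_names)``. Rows follow *proteins* if
    given (proteins without predictions get the all-zero encoding), otherwise
    the sorted set of proteins with at least one prediction for *ec*.
    """
    preds = tools_predicting(ec, profiles)
    if not preds:
        raise ValueError(f"EC {ec} is outside every tool's predictive range")
    recs = [r for r in table.for_ec(ec) if any(p.tool_name == r.tool for p in preds)]
    if proteins is None:
        proteins = sorted({r.protein_id for r in recs})
    prot_ix = {p: i for i, p in enumerate(proteins)}
    by_key = {(r.protein_id, r.tool): r for r in recs}

    if encoding == "binary_high_conf":
        names = [p.tool_name for p in preds]
        X = np.zeros((len(proteins), len(preds)), dtype=np.int8)
        for j, prof in enumerate(preds):
            for prot in proteins:
                r = by_key.get((prot, prof.tool_name))
                if r is not None and r.confidence_level == prof.high_conf_bin:
                    X[prot_ix[prot], j] = 1
    elif encoding == "one_hot_levels":
        names = [f"{p.tool_name}:{lbl}" for p in preds for lbl in p.bin_labels]
        X = np.zeros((len(proteins), len(names)), dtype=np.int8)
        col = {n: j for j, n in enumerate(names)}
        for prof in preds:
            for prot in proteins:
                r = by_key.get((prot, prof.tool_name))
                if r is not None:
                    X[prot_ix[prot], col[f"{prof.tool_name}:{r.confidence_level}"]] = 1
    elif encoding == "ordinal_levels":
        names = [p.tool_name for p in preds]
        X = np.zeros((len(proteins), len(preds)), dtype=np.int64)
        for j, prof in enumerate(preds):
            for prot in proteins:
                r = by_key.get((prot, prof.tool_name))
                if r is not None:
                    X[prot_ix[prot], j] = prof.level_index(r.confidence_level)
    else:
        raise ValueError(f"unknown encoding {encoding!r}")
    return X, list(proteins), names


def load_tool_profiles(path) -> list[ToolProfile]:
    """Load tool profiles from a JSON file: a list of objects with keys
    tool_name, score_kind, confidence_bins, high_conf_bin, predictive_range."""
    with open(path) as fh:
        raw = json.load(fh)
    return [
        ToolProfile(
            tool_name=d["tool_name"],
            score_kind=d.get("score_kind", "probability"),
            confidence_bins=tuple(
                (str(b[0]), float(b[1]), float(b[2])) for b in d["confidence_bins"]
            ),
            high_conf_bin=d["high_conf_bin"],
            predictive_range=frozenset(d.get("predictive_range", [])),
        )
        for d in raw
    ]
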