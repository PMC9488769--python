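"""Per-EC ensemble classifiers over multi-tool enzyme predictions.

Each EC number predictable by ``k`` tools gets its own small classifier over
the k-dimensional evidence vector of the tools' calls. The default is a
Bernoulli naive Bayes on binary high-confidence indicators: the posterior

    p(y=1 | F=f) = p(y=1) prod_i p(F_i=f_i | y=1)
                   / sum_C p(y=C) prod_i p(F_i=f_i | y=C)

is the annotation's likelihood score; scores strictly above 0.5 are deemed
high-confidence. Two rule-based alternatives (majority vote among the tools
able to predict the EC; the EC-specific best tool from training performance)
and two learned alternatives (logistic regression on one-hot confidence
levels; random forest on ordinal levels) are provided.

Two selection rules complement the classifiers: an auto-assign rule for ECs
that every tool can predict and on which no tool made a training false
positive, and a pass-through rule that promotes a designated wide-range
tool's high-confidence calls for ECs the classifier cannot cover (e.g.
ECs filtered from training for having fewer than 10 reference sequences).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .prediction_io import (
    PredictionTable,
    ToolProfile,
    build_feature_matrix,
    tools_predicting,
)

__all__ = [
    "NBParameters",
    "SklearnScorer",
    "EnsembleModel",
    "ScoredAnnotation",
    "TrainingDegenerateError",
    "build_training_sets",
    "fit_naive_bayes",
    "nb_posterior",
    "fit_alt_classifier",
    "majority_rule_assign",
    "best_tool_assign",
    "select_high_confidence",
    "multifunctional_filter",
    "train_ensemble",
    "score_proteins",
    "build_cooccurrence",
    "model_to_json",
    "model_from_json",
]

HIGH_CONFIDENCE_THRESHOLD = 0.5  # strict: score must exceed it
DEFAULT_MIN_EC_SUPPORT = 10


class TrainingDegenerateError(ValueError):
    """Raised when an EC's training set lacks positives or negatives."""


@dataclass(frozen=True)
class NBParameters:
    """Bernoulli naive Bayes parameters for one EC.

    ``cond_pos[i]`` = p(F_i = 1 | y = 1), ``cond_neg[i]`` = p(F_i = 1 | y = 0),
    estimated with add-alpha smoothing so every probability lies strictly
    inside (0, 1).
    """

    ec: str
    tools: tuple[str, ...]
    prior_pos: float
    cond_pos: tuple[float, ...]
    cond_neg: tuple[float, ...]

    def __post_init__(self) -> None:
        probs = (self.prior_pos, *self.cond_pos, *self.cond_neg)
        if not all(0.0 < p < 1.0 for p in probs):
            raise ValueError(f"{self.ec}: probabilities must lie strictly in (0,1)")
        if len(self.cond_pos) != len(self.tools) or len(self.cond_neg) != len(self.tools):
            raise ValueError(f"{self.ec}: parameter/tool arity mismatch")

    @property
    def k(self) -> int:
        return len(self.tools)


def build_training_sets(
    table: PredictionTable, gold: Mapping[str, set[str]], ec: str
) -> tuple[set[str], set[str]]:
    """Positives = proteins carrying *ec* in the gold labels; negatives =
    proteins predicted *ec* by at least one tool but lacking it in gold.

    The sets are disjoint by construction. Raises
    :class:`TrainingDegenerateError` if either side is empty (the caller may
    fall back to the auto-assign rule).
    """
    positives = {p for p, ecs in gold.items() if ec in ecs}
    predicted = {r.protein_id for r in table.for_ec(ec)}
    negatives = predicted - positives
    if not positives or not negatives:
        raise TrainingDegenerateError(
            f"EC {ec}: {len(positives)} positives, {len(negatives)} negatives"
        )
    return positives, negatives


def fit_naive_bayes(
    X: np.ndarray,
    y: np.ndarray,
    ec: str,
    tools: Sequence[str],
    alpha: float = 1.0,
) -> NBParameters:
    """Estimate Bernoulli likelihoods and the class prior by smoothed counting.

    prior = (n_pos + alpha) / (n + 2 alpha);
    p(F_i=1 | y=c) = (count_i,c + alpha) / (n_c + 2 alpha).
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive to keep parameters inside (0,1)")
    X = np.asarray(X)
    y = np.asarray(y).astype(bool)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("feature/label shape mismatch")
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise TrainingDegenerateError(f"EC {ec}: single-class labels")
    prior = (n_pos + alpha) / (len(y) + 2 * alpha)
    cond_pos = (X[y].sum(axis=0) + alpha) / (n_pos + 2 * alpha)
    cond_neg = (X[~y].sum(axis=0) + alpha) / (n_neg + 2 * alpha)
    return NBParameters(
        ec=ec,
        tools=tuple(tools),
        prior_pos=float(prior),
        cond_pos=tuple(float(p) for p in cond_pos),
        cond_neg=tuple(float(p) for p in cond_neg),
    )


def nb_posterior(f: Sequence[int], params: NBParameters) -> float:
    """Posterior p(y=1 | F=f) for a binary evidence vector.

    Evaluated in log space for numerical stability; exact normalization over
    the two classes keeps the value strictly inside (0, 1).
    """
    f = np.asarray(f)
    if f.shape != (params.k,):
        raise ValueError(f"feature vector length {f.shape} != k={params.k}")
    cp = np.asarray(params.cond_pos)
    cn = np.asarray(params.cond_neg)
    log_pos = np.log(params.prior_pos) + np.sum(
        np.where(f == 1, np.log(cp), np.log1p(-cp))
    )
    log_neg = np.log(1.0 - params.prior_pos) + np.sum(
        np.where(f == 1, np.log(cn), np.log1p(-cn))
    )
    m = max(log_pos, log_neg)
    num = np.exp(log_pos - m)
    den = num + np.exp(log_neg - m)
    return float(num / den)


class SklearnScorer:
    """Thin wrapper giving LR/RF classifiers a [0,1] scoring interface."""

    def __init__(self, estimator, ec: str, feature_names: Sequence[str], method: str):
        self.estimator = estimator
        self.ec = ec
        self.feature_names = tuple(feature_names)
        self.method = method

    @property
    def k(self) -> int:
        return len(self.feature_names)

    def score(self, f: Sequence[float]) -> float:
        f = np.asarray(f, dtype=float).reshape(1, -1)
        if f.shape[1] != self.k:
            raise ValueError("feature vector length mismatch")
        proba = self.estimator.predict_proba(f)
        pos_col = list(self.estimator.classes_).index(1)
        return float(proba[0, pos_col])


def fit_alt_classifier(
    method: str,
    X: np.ndarray,
    y: np.ndarray,
    ec: str,
    feature_names: Sequence[str],
    seed: int = 42,
    **kwargs,
) -> SklearnScorer:
    """Fit a logistic-regression or random-forest scorer for one EC.

    Deterministic given *seed*. Extra keyword arguments pass through to the
    underlying scikit-learn estimator.
    """
    y = np.asarray(y).astype(int)
    if len(np.unique(y)) < 2:
        raise TrainingDegenerateError(f"EC {ec}: single-class labels")
    if method == "logistic_regression":
        from sklearn.linear_model import LogisticRegression

        est = LogisticRegression(max_iter=1000, random_state=seed, **kwargs)
    elif method == "random_forest":
        from sklearn.ensemble import RandomForestClassifier

        est = RandomForestClassifier(random_state=seed, **kwargs)
    else:
        raise ValueError(f"unknown method {method!r}")
    est.fit(np.asarray(X, dtype=float), y)
    return SklearnScorer(est, ec, feature_names, method)


def majority_rule_assign(
    tool_high_sets: Mapping[str, set[str]],
    tool_ranges: Mapping[str, frozenset[str] | set[str]],
) -> set[str]:
    """Assign an EC iff strictly more than half of the tools able to predict
    it called it at high confidence."""
    assigned: set[str] = set()
    candidates = set().union(*tool_high_sets.values()) if tool_high_sets else set()
    for ec in candidates:
        able = [t for t, rng in tool_ranges.items() if ec in rng]
        if not able:
            continue
        votes = sum(1 for t in able if ec in tool_high_sets.get(t, set()))
        if votes > len(able) / 2:
            assigned.add(ec)
    return assigned


def best_tool_assign(
    tool_high_sets: Mapping[str, set[str]],
    performance: Mapping[tuple[str, str], float],
    tool_ranges: Mapping[str, frozenset[str] | set[str]],
) -> set[str]:
    """Assign an EC iff a tool with maximal training F1 for that EC called it
    at high confidence (ties: any tied-best tool suffices). ECs missing from
    the performance table fall back to the majority rule, with a warning."""
    assigned: set[str] = set()
    fallback_ecs: set[str] = set()
    candidates = set().union(*tool_high_sets.values()) if tool_high_sets else set()
    for ec in candidates:
        scored = {t: f1 for (e, t), f1 in performance.items() if e == ec}
        if not scored:
            fallback_ecs.add(ec)
            continue
        best = max(scored.values())
        best_tools = {t for t, f1 in scored.items() if f1 == best}
        if any(ec in tool_high_sets.get(t, set()) for t in best_tools):
            assigned.add(ec)
    if fallback_ecs:
        warnings.warn(
            f"{len(fallback_ecs)} EC(s) absent from the performance table; "
            "falling back to majority rule",
            stacklevel=2,
        )
        restricted = {t: s & fallback_ecs for t, s in tool_high_sets.items()}
        assigned |= majority_rule_assign(restricted, tool_ranges)
    return assigned


@dataclass(frozen=True)
class ScoredAnnotation:
    protein_id: str
    ec: str
    likelihood_score: float | None  # None for rule-assigned annotations
    high_confidence: bool
    source: str  # classifier | auto_rule | passthrough

    def __post_init__(self) -> None:
        if self.high_confidence and self.source == "classifier":
            assert self.likelihood_score is not None
            assert self.likelihood_score > HIGH_CONFIDENCE_THRESHOLD


@dataclass
class EnsembleModel:
    """A trained ensemble: per-EC classifiers plus the rule tables."""

    method: str
    profiles: list[ToolProfile]
    per_ec_params: dict[str, NBParameters | SklearnScorer] = field(default_factory=dict)
    auto_assign_ecs: set[str] = field(default_factory=set)
    cooccurrence: dict[str, set[str]] = field(default_factory=dict)
    passthrough_tool: str | None = None
    performance: dict[tuple[str, str], float] = field(default_factory=dict)
    skipped_ecs: dict[str, str] = field(default_factory=dict)
    seed: int = 42

    @property
    def tool_ranges(self) -> dict[str, frozenset[str]]:
        return {p.tool_name: p.predictive_range for p in self.profiles}

    @property
    def predictive_range(self) -> set[str]:
        """ECs the trained model itself can decide on (classifier or auto rule)."""
        return set(self.per_ec_params) | set(self.auto_assign_ecs)

    def __post_init__(self) -> None:
        union_range = set().union(*(p.predictive_range for p in self.profiles))
        if not self.auto_assign_ecs <= union_range:
            raise ValueError("auto_assign_ecs must lie within the tools' ranges")


def build_cooccurrence(
    gold: Mapping[str, set[str]],
    min_count: int = 10,
    min_frac: float = 0.5,
) -> dict[str, set[str]]:
    """Directed EC co-occurrence from gold labels: ``b in cooccurrence[a]``
    iff at least *min_count* proteins carry both and at least *min_frac* of
    the proteins carrying *a* also carry *b*."""
    from collections import Counter

    single: Counter[str] = Counter()
    pair: Counter[tuple[str, str]] = Counter()
    for ecs in gold.values():
        for a in ecs:
            single[a] += 1
            for b in ecs:
                if a != b:
                    pair[(a, b)] += 1
    out: dict[str, set[str]] = {}
    for (a, b), n in pair.items():
        if n >= min_count and n / single[a] >= min_frac:
            out.setdefault(a, set()).add(b)
    return out


def _encoding_for(method: str) -> str:
    return {
        "naive_bayes": "binary_high_conf",
        "logistic_regression": "one_hot_levels",
        "random_forest": "ordinal_levels",
    }[method]


def _training_f1(tp: int, fp: int, fn: int) -> float:
    return 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 0.0


def train_ensemble(
    table: PredictionTable,
    gold: Mapping[str, set[str]],
    profiles: Sequence[ToolProfile],
    method: str = "naive_bayes",
    seed: int = 42,
    alpha: float = 1.0,
    min_ec_support: int = DEFAULT_MIN_EC_SUPPORT,
    passthrough_tool: str | None = None,
    cooccur_min_count: int = 10,
    cooccur_min_frac: float = 0.5,
) -> EnsembleModel:
    """Train per-EC classifiers and derive the rule tables from training data.

    ECs supported by fewer than *min_ec_support* gold proteins are excluded
    from classifier training (they stay reachable through the pass-through
    tool). ECs whose training sets are degenerate are skipped and recorded.
    The auto-assign rule covers ECs inside every tool's predictive range for
    which no tool produced a training false positive.
    """
    profiles = list(profiles)
    high_sets = table.high_confidence_sets(profiles)
    gold = {p: set(ecs) for p, ecs in gold.items()}
    support: dict[str, int] = {}
    for ecs in gold.values():
        for ec in ecs:
            support[ec] = support.get(ec, 0) + 1

    union_range = set().union(*(p.predictive_range for p in profiles))
    trainable = sorted(
        ec
        for ec, n in support.items()
        if n >= min_ec_support and ec in union_range
    )

    model = EnsembleModel(
        method=method,
        profiles=profiles,
        passthrough_tool=passthrough_tool,
        seed=seed,
        cooccurrence=build_cooccurrence(gold, cooccur_min_count, cooccur_min_frac),
    )

    for ec in trainable:
        try:
            pos, neg = build_training_sets(table, gold, ec)
        except TrainingDegenerateError as exc:
            model.skipped_ecs[ec] = str(exc)
            continue
        prots = sorted(pos | neg)
        y = np.array([p in pos for p in prots], dtype=int)
        X, _, names = build_feature_matrix(
            table, ec, profiles, encoding=_encoding_for(method), proteins=prots
        )
        if method == "naive_bayes":
            model.per_ec_params[ec] = fit_naive_bayes(X, y, ec, names, alpha=alpha)
        else:
            try:
                model.per_ec_params[ec] = fit_alt_classifier(
                    method, X, y, ec, names, seed=seed
                )
            except TrainingDegenerateError as exc:
                model.skipped_ecs[ec] = str(exc)
                continue
        # per-(EC, tool) training F1 feeds the EC-specific best-tool rule
        for prof in tools_predicting(ec, profiles):
            pred = {
                p
                for p in prots
                if ec in high_sets.get(p, {}).get(prof.tool_name, set())
            }
            tp = len(pred & pos)
            model.performance[(ec, prof.tool_name)] = _training_f1(
                tp, len(pred - pos), len(pos - pred)
            )

    # auto-assign rule: EC predictable by every tool, no training false positive
    common_range = frozenset.intersection(*(p.predictive_range for p in profiles))
    predicted_by_ec: dict[str, set[str]] = {}
    for rec in table.records:
        predicted_by_ec.setdefault(rec.ec, set()).add(rec.protein_id)
    for ec in common_range:
        predicted = predicted_by_ec.get(ec)
        if not predicted:
            continue
        positives = {p for p, ecs in gold.items() if ec in ecs}
        if predicted <= positives:
            model.auto_assign_ecs.add(ec)
    return model


def _classifier_score(
    model: EnsembleModel, table: PredictionTable, protein: str, ec: str
) -> float:
    params = model.per_ec_params[ec]
    X, _, _ = build_feature_matrix(
        table,
        ec,
        model.profiles,
        encoding=_encoding_for(model.method),
        proteins=[protein],
    )
    if isinstance(params, NBParameters):
        return nb_posterior(X[0], params)
    return params.score(X[0])


def score_proteins(
    model: EnsembleModel,
    table: PredictionTable,
    proteins: Sequence[str] | None = None,
) -> list[ScoredAnnotation]:
    """Score every (protein, EC) pair predicted by at least one tool.

    Sources, in precedence order: the auto-assign rule, the per-EC
    classifier, and the pass-through tool for ECs outside the model's own
    range. Rule-assigned annotations carry no numeric likelihood score.
    """
    high_sets = table.high_confidence_sets(model.profiles)
    pairs: dict[str, set[str]] = {}
    for rec in table.records:
        pairs.setdefault(rec.protein_id, set()).add(rec.ec)
    if proteins is not None:
        pairs = {p: pairs.get(p, set()) for p in proteins}

    out: list[ScoredAnnotation] = []
    for protein in sorted(pairs):
        for ec in sorted(pairs[protein]):
            if ec in model.auto_assign_ecs:
                out.append(
                    ScoredAnnotation(protein, ec, None, True, "auto_rule")
                )
            elif ec in model.per_ec_params:
                s = _classifier_score(model, table, protein, ec)
                out.append(
                    ScoredAnnotation(
                        protein, ec, s, s > HIGH_CONFIDENCE_THRESHOLD, "classifier"
                    )
                )
            elif (
                model.passthrough_tool is not None
                and ec
                in high_sets.get(protein, {}).get(model.passthrough_tool, set())
            ):
                out.append(
                    ScoredAnnotation(protein, ec, None, True, "passthrough")
                )
    return out


def select_high_confidence(
    scored: Sequence[ScoredAnnotation],
) -> set[tuple[str, str]]:
    """High-confidence (protein, EC) pairs: classifier score strictly above
    0.5, auto-rule assignments, and pass-through assignments."""
    return {
        (a.protein_id, a.ec)
        for a in scored
        if a.high_confidence
        and (
            a.source in ("auto_rule", "passthrough")
            or (a.likelihood_score is not None and a.likelihood_score > HIGH_CONFIDENCE_THRESHOLD)
        )
    }


def multifunctional_filter(
    scores: Mapping[str, float],
    cooccurrence: Mapping[str, set[str]],
) -> set[str]:
    """Retain only the top-scoring EC(s) of one protein plus ECs that
    frequently co-occur with them in training. Off by default downstream
    because it trades recall on multifunctional enzymes for precision."""
    if not scores:
        return set()
    top = max(scores.values())
    tops = {ec for ec, s in scores.items() if s == top}
    keep = set(tops)
    for ec in tops:
        keep |= cooccurrence.get(ec, set()) & set(scores)
    return keep


# ---------------------------------------------------------------------------
# JSON serialization (naive Bayes and rule tables; LR coefficient blocks)

def model_to_json(model: EnsembleModel) -> str:
    blocks: dict[str, dict] = {}
    for ec, params in model.per_ec_params.items():
        if isinstance(params, NBParameters):
            blocks[ec] = {
                "kind": "naive_bayes",
                "tools": list(params.tools),
                "prior_pos": params.prior_pos,
                "cond_pos": list(params.cond_pos),
                "cond_neg": list(params.cond_neg),
            }
        elif params.method == "logistic_regression":
            est = params.estimator
            blocks[ec] = {
                "kind": "logistic_regression",
                "features": list(params.feature_names),
                "coef": est.coef_[0].tolist(),
                "intercept": float(est.intercept_[0]),
                "classes": [int(c) for c in est.classes_],
            }
        else:
            raise NotImplementedError(
                "JSON serialization covers naive Bayes and logistic regression; "
                "persist random forests with joblib instead"
            )
    doc = {
        "method": model.method,
        "seed": model.seed,
        "passthrough_tool": model.passthrough_tool,
        "auto_assign_ecs": sorted(model.auto_assign_ecs),
        "cooccurrence": {a: sorted(b) for a, b in model.cooccurrence.items()},
        "performance": [
            {"ec": ec, "tool": tool, "f1": f1}
            for (ec, tool), f1 in sorted(model.performance.items())
        ],
        "skipped_ecs": model.skipped_ecs,
        "profiles": [
            {
                "tool_name": p.tool_name,
                "score_kind": p.score_kind,
                "confidence_bins": [list(b) for b in p.confidence_bins],
                "high_conf_bin": p.high_conf_bin,
                "predictive_range": sorted(p.predictive_range),
            }
            for p in model.profiles
        ],
        "per_ec_params": blocks,
    }
    return json.dumps(doc, indent=1)


def model_from_json(text: str) -> EnsembleModel:
    doc = json.loads(text)
    profiles = [
        ToolProfile(
            tool_name=d["tool_name"],
            score_kind=d["score_kind"],
            confidence_bins=tuple(
                (str(b[0]), float(b[1]), float(b[2])) for b in d["confidence_bins"]
            ),
            high_conf_bin=d["high_conf_bin"],
            predictive_range=frozenset(d["predictive_range"]),
        )
        for d in doc["profiles"]
    ]
    model = EnsembleModel(
        method=doc["method"],
        profiles=profiles,
        passthrough_tool=doc.get("passthrough_tool"),
        auto_assign_ecs=set(doc.get("auto_assign_ecs", [])),
        cooccurrence={a: set(b) for a, b in doc.get("cooccurrence", {}).items()},
        performance={
            (e["ec"], e["tool"]): e["f1"] for e in doc.get("performance", [])
        },
        skipped_ecs=doc.get("skipped_ecs", {}),
        seed=doc.get("seed", 42),
    )
    for ec, blk in doc["per_ec_params"].items():
        if blk["kind"] == "naive_bayes":
            model.per_ec_params[ec] = NBParameters(
                ec=ec,
                tools=tuple(blk["tools"]),
                prior_pos=blk["prior_pos"],
                cond_pos=tuple(blk["cond_pos"]),
                cond_neg=tuple(blk["cond_neg"]),
            )
        elif blk["kind"] == "logistic_regression":
            from sklearn.linear_model import LogisticRegression

            est = LogisticRegression()
            est.coef_ = np.array([blk["coef"]])
            est.intercept_ = np.array([blk["intercept"]])
            est.classes_ = np.array(blk["classes"])
            model.per_ec_params[ec] = SklearnScorer(
                est, ec, blk["features"], "logistic_regression"
            )
    return model
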