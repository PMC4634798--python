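"""Greedy forward feature selection with information-theoretic objectives.

The search starts from an empty relevant set F and, for k iterations, adds
the candidate feature X maximizing a score of the general linear form

    J(X, Y, F) = I(X;Y) - alpha(|F|) * sum_{X' in F} I(X;X')
                        + beta(|F|)  * sum_{X' in F} I(X;X'|Y)

with alpha, beta >= 0: relevancy, minus redundancy with the already-selected
set, plus conditional redundancy (rewarded, because features that are jointly
informative about the class help).  MIM (alpha=beta=0), MIFS (alpha const,
beta=0), mRMR (alpha=1/|F|), JMI (alpha=beta=1/|F|) and CIFE (alpha=beta=1)
are instances of this form; CMIM, ICAP, DISR and CondMI use criterion-specific
aggregation following Brown et al.'s unifying survey of information-theoretic
selection criteria.  Ties in the argmax go to the lowest feature index.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .infotheory import (
    DiscreteVector,
    conditional_mutual_information,
    discretize,
    entropy,
    joint_variable,
    mutual_information,
)

__all__ = [
    "Rule",
    "ObjectiveParams",
    "SelectionState",
    "SelectionResult",
    "make_objective",
    "objective_score",
    "greedy_select",
    "OBJECTIVE_NAMES",
]


@dataclass(frozen=True)
class Rule:
    """A coefficient rule: a constant, or 1/|F| (0 when F is empty)."""

    kind: str  # "const" | "inverse"
    value: float = 0.0

    def __call__(self, n_selected: int) -> float:
        if self.kind == "const":
            return self.value
        if self.kind == "inverse":
            return 0.0 if n_selected == 0 else 1.0 / n_selected
        raise ValueError(f"unknown rule kind {self.kind!r}")

    @property
    def is_zero(self) -> bool:
        return self.kind == "const" and self.value == 0.0


@dataclass(frozen=True)
class ObjectiveParams:
    """A named selection criterion: linear (alpha, beta) or a nonlinear form."""

    name: str
    alpha_rule: Rule = Rule("const", 0.0)
    beta_rule: Rule = Rule("const", 0.0)
    form: str = "linear"  # "linear" | "cmim" | "icap" | "disr" | "condmi"


_CATALOG = {
    "mim": ObjectiveParams("MIM", Rule("const", 0.0), Rule("const", 0.0)),
    "mifs": ObjectiveParams("MIFS", Rule("const", 1.0), Rule("const", 0.0)),
    "mrmr": ObjectiveParams("mRMR", Rule("inverse"), Rule("const", 0.0)),
    "jmi": ObjectiveParams("JMI", Rule("inverse"), Rule("inverse")),
    "cife": ObjectiveParams("CIFE", Rule("const", 1.0), Rule("const", 1.0)),
    "cmim": ObjectiveParams("CMIM", form="cmim"),
    "icap": ObjectiveParams("ICAP", form="icap"),
    "disr": ObjectiveParams("DISR", form="disr"),
    "condmi": ObjectiveParams("CondMI", form="condmi"),
}

OBJECTIVE_NAMES = tuple(_CATALOG)


def make_objective(name: str) -> ObjectiveParams:
    """Look up a criterion by (case-insensitive) name."""
    key = name.strip().lower()
    if key not in _CATALOG:
        raise ValueError(
            f"unknown objective {name!r}; valid names: {', '.join(OBJECTIVE_NAMES)}"
        )
    return _CATALOG[key]


@dataclass
class SelectionState:
    """Mutable search state: the ordered relevant set F and the candidate pool."""

    selected: list[int] = field(default_factory=list)
    remaining: set[int] = field(default_factory=set)
    step_scores: list[float] = field(default_factory=list)


@dataclass
class SelectionResult:
    """An ordered selection; order is selection order (F1, F2, ...)."""

    feature_indices: list[int]
    feature_ids: list[str]
    scores: list[float]
    method: str
    k: int

    def __post_init__(self) -> None:
        if not (len(self.feature_indices) == len(self.feature_ids) == len(self.scores)):
            raise ValueError("feature_indices, feature_ids, scores lengths differ")


def _disr_term(x: DiscreteVector, xp: DiscreteVector, y: DiscreteVector) -> float:
    """Symmetric relevance I(X,X';Y) / H(X,X',Y); 0 if the joint entropy is 0."""
    pair = joint_variable(x, xp)
    h = entropy(joint_variable(pair, y))
    if h <= 0.0:
        return 0.0
    return mutual_information(pair, y) / h


def objective_score(
    candidate: int,
    features: Sequence[DiscreteVector],
    labels: DiscreteVector,
    state: SelectionState,
    params: ObjectiveParams,
) -> float:
    """Score one candidate from scratch against the current relevant set."""
    if candidate in state.selected:
        raise ValueError(f"feature {candidate} already selected")
    x = features[candidate]
    rel = mutual_information(x, labels)
    if not state.selected:
        return rel
    chosen = [features[j] for j in state.selected]
    if params.form == "linear":
        nf = len(chosen)
        red = 0.0
        for xp in chosen:
            red += mutual_information(x, xp)
        cred = 0.0
        for xp in chosen:
            cred += conditional_mutual_information(x, xp, labels)
        return rel - params.alpha_rule(nf) * red + params.beta_rule(nf) * cred
    if params.form == "cmim":
        return min(conditional_mutual_information(x, labels, xp) for xp in chosen)
    if params.form == "icap":
        penalty = 0.0
        for xp in chosen:
            penalty += max(
                0.0,
                mutual_information(x, xp)
                - conditional_mutual_information(x, xp, labels),
            )
        return rel - penalty
    if params.form == "disr":
        return sum(_disr_term(x, xp, labels) for xp in chosen)
    if params.form == "condmi":
        z = chosen[0]
        for xp in chosen[1:]:
            z = joint_variable(z, xp)
        return conditional_mutual_information(x, labels, z)
    raise ValueError(f"unknown objective form {params.form!r}")


def _greedy_core(
    counts: np.ndarray,
    labels: DiscreteVector,
    k: int,
    params: ObjectiveParams,
    n_bins: int = 10,
) -> tuple[list[int], list[float]]:
    """Greedy search on a raw feature-by-sample matrix.

    Caches per-candidate redundancy sums so each step costs O(K) MI
    evaluations instead of O(K|F|) (the accumulation order matches the
    from-scratch :func:`objective_score`, so the two agree bitwise).
    """
    n_features = counts.shape[0]
    if not 1 <= k <= n_features:
        raise ValueError(f"k={k} out of range for {n_features} features")
    if labels.cardinality < 2:
        raise ValueError("labels must have at least two classes")

    feats = [discretize(counts[j], n_bins) for j in range(n_features)]
    rel = np.array([mutual_information(f, labels) for f in feats])

    use_red = params.form == "linear" and not params.alpha_rule.is_zero
    use_cred = params.form == "linear" and not params.beta_rule.is_zero
    red_sum = np.zeros(n_features)
    cred_sum = np.zeros(n_features)
    cmim_min = np.full(n_features, np.inf)
    icap_sum = np.zeros(n_features)
    disr_sum = np.zeros(n_features)
    z: DiscreteVector | None = None

    alive = np.ones(n_features, dtype=bool)
    selected: list[int] = []
    step_scores: list[float] = []

    for _ in range(k):
        nf = len(selected)
        if nf == 0:
            scores = rel
        elif params.form == "linear":
            scores = (
                rel
                - params.alpha_rule(nf) * red_sum
                + params.beta_rule(nf) * cred_sum
            )
        elif params.form == "cmim":
            scores = cmim_min
        elif params.form == "icap":
            scores = rel - icap_sum
        elif params.form == "disr":
            scores = disr_sum
        elif params.form == "condmi":
            scores = np.array(
                [
                    conditional_mutual_information(feats[j], labels, z)
                    if alive[j]
                    else -np.inf
                    for j in range(n_features)
                ]
            )
        else:
            raise ValueError(f"unknown objective form {params.form!r}")

        masked = np.where(alive, scores, -np.inf)
        best = int(np.argmax(masked))  # first occurrence -> lowest index on ties
        selected.append(best)
        step_scores.append(float(masked[best]))
        alive[best] = False

        if len(selected) == k:
            break

        new = feats[best]
        live = np.flatnonzero(alive)
        if use_red:
            for j in live:
                red_sum[j] += mutual_information(feats[j], new)
        if use_cred:
            for j in live:
                cred_sum[j] += conditional_mutual_information(feats[j], new, labels)
        if params.form == "cmim":
            for j in live:
                cmim_min[j] = min(
                    cmim_min[j],
                    conditional_mutual_information(feats[j], labels, new),
                )
        elif params.form == "icap":
            for j in live:
                icap_sum[j] += max(
                    0.0,
                    mutual_information(feats[j], new)
                    - conditional_mutual_information(feats[j], new, labels),
                )
        elif params.form == "disr":
            for j in live:
                disr_sum[j] += _disr_term(feats[j], new, labels)
        elif params.form == "condmi":
            z = new if z is None else joint_variable(z, new)

    return selected, step_scores


def greedy_select(table, labels, k: int, params: ObjectiveParams, n_bins: int = 10) -> SelectionResult:
    """Select k features from an AbundanceTable under the given criterion."""
    if list(labels.sample_ids) != list(table.sample_ids):
        raise ValueError("labels are not aligned to the table's samples")
    y = DiscreteVector(labels.as_states(), len(labels.classes))
    indices, scores = _greedy_core(table.counts, y, k, params, n_bins)
    return SelectionResult(
        feature_indices=indices,
        feature_ids=[table.feature_ids[j] for j in indices],
        scores=scores,
        method=params.name,
        k=k,
    )
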